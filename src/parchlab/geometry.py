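"""Shared heavy-atom geometry helpers (coordinate arrays, residue distances)."""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.distance import cdist


def heavy_atom_arrays(structure) -> tuple[np.ndarray, np.ndarray]:
    """Flatten a ProteinStructure into heavy-atom coordinates and owner indices.

    Returns ``(coords, owner)`` where ``coords`` is (A, 3) and ``owner[j]`` is
    the positional residue index owning atom ``j``.
    """
    coords, owner = [], []
    for i, res in enumerate(structure.residues):
        for atom in res.atoms:
            if atom.is_heavy:
                coords.append(atom.coords)
                owner.append(i)
    if not coords:
        return np.empty((0, 3)), np.empty(0, dtype=int)
    return np.asarray(coords, dtype=float), np.asarray(owner, dtype=int)


def residue_min_distance_matrix(structure, metric: str = "heavy") -> np.ndarray:
    """(N, N) matrix of minimum inter-residue heavy-atom distances.

    ``metric='ca'`` restricts each residue to its CA atom (falling back to the
    first heavy atom when no CA is present, as for pseudo-atom residues).
    Diagonal entries are 0.  Computed in row blocks to bound memory.
    """
    n = len(structure.residues)
    if metric == "ca":
        coords = []
        for res in structure.residues:
            ca = next((a for a in res.atoms if a.name.strip() == "CA" and a.is_heavy), None)
            if ca is None:
                ca = next(a for a in res.atoms if a.is_heavy)
            coords.append(ca.coords)
        pts = np.asarray(coords, dtype=float)
        return cdist(pts, pts)
    if metric != "heavy":
        raise ValueError(f"unknown neighbor metric {metric!r}")

    coords, owner = heavy_atom_arrays(structure)
    out = np.full((n, n), np.inf)
    block = max(1, int(2e7) // max(1, len(coords)))
    for start in range(0, len(coords), block):
        stop = min(start + block, len(coords))
        d = cdist(coords[start:stop], coords)  # (b, A)
        rows = owner[start:stop]
        # reduce atom-atom distances to residue-residue minima
        for k in range(stop - start):
            np.minimum.at(out[rows[k]], owner, d[k])
    np.fill_diagonal(out, 0.0)
    return out


def neighbor_counts(structure, r_nbr: float) -> np.ndarray:
    """Number of other residues with any heavy atom within ``r_nbr`` of each residue."""
    coords, owner = heavy_atom_arrays(structure)
    n = len(structure.residues)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r_nbr, output_type="ndarray")
    counts = np.zeros(n, dtype=int)
    if len(pairs):
        a, b = owner[pairs[:, 0]], owner[pairs[:, 1]]
        mask = a != b
        seen = np.unique(np.stack([np.minimum(a[mask], b[mask]),
                                   np.maximum(a[mask], b[mask])], axis=1), axis=0)
        np.add.at(counts, seen[:, 0], 1)
        np.add.at(counts, seen[:, 1], 1)
    return counts
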