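"""Ranked residue neighbors and dyad/triad/polyad colocalization statistics.

A residue's neighbors are the other residues ranked by minimum heavy-atom
pair distance (side chains included, so neighbors may be bonded or merely
proximal); distance ties break toward the lower sequence position.  Each
residue anchors exactly one polyad of each order n: itself plus its n−1
nearest neighbors, the neighbor multiset stored canonically (sorted) because
neighbor rank is not part of the motif.  Tables are stratified by the focal
residue's zone, so per-zone counts sum to the number of residues in that zone.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import AA_ORDER, CHARGED_RESIDUES
from .geometry import residue_min_distance_matrix
from .structure import CompositionTable, ProteinStructure
from .zonation import ZONES, ZoneAssignment

__all__ = [
    "NeighborList",
    "Polyad",
    "PolyadTable",
    "nearest_neighbors",
    "polyad_table",
    "classify_triad",
    "classify_k_triad",
    "heatmap_matrix",
    "zone_composition",
]

#: residue_index -> [(neighbor_index, distance), ...] ascending by distance
NeighborList = dict[int, list[tuple[int, float]]]


@dataclass(frozen=True)
class Polyad:
    """A focal residue with its n−1 nearest neighbors (canonical multiset)."""

    focal: str
    neighbors: tuple[str, ...]
    zone: str = "all"

    def __post_init__(self):
        object.__setattr__(self, "neighbors", tuple(sorted(self.neighbors)))

    @property
    def order(self) -> int:
        return 1 + len(self.neighbors)


@dataclass
class PolyadTable:
    """Counts of (focal, neighbor multiset, zone) polyads of one order."""

    order: int
    counts: Counter = field(default_factory=Counter)
    zone_totals: dict[str, int] = field(default_factory=dict)

    def count(self, focal: str, neighbors, zone: str = "all") -> int:
        return self.counts.get((focal, tuple(sorted(neighbors)), zone), 0)


def nearest_neighbors(structure: ProteinStructure, k: int,
                      metric: str = "heavy") -> NeighborList:
    """The k nearest residues of every residue, by minimum heavy-atom distance.

    Sequence-adjacent residues count like any others.  ``metric='ca'`` uses
    Cα positions instead of all heavy atoms.  Neighbor relations need not be
    symmetric.
    """
    n = len(structure.residues)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the residue count {n}")
    if k < 1:
        raise ValueError("k must be at least 1")
    D = residue_min_distance_matrix(structure, metric=metric)
    out: NeighborList = {}
    for i in range(n):
        order = sorted((j for j in range(n) if j != i), key=lambda j: (D[i, j], j))
        out[i] = [(j, float(D[i, j])) for j in order[:k]]
    return out


def polyad_table(structure: ProteinStructure, neighbors: NeighborList,
                 assignment: ZoneAssignment | None, n: int) -> PolyadTable:
    """One polyad of order ``n`` per residue, stratified by the focal zone.

    Overlapping neighborhoods are intentional: every residue contributes its
    own neighborhood, so per-zone counts sum to per-zone residue counts.
    """
    if not 2 <= n <= 6:
        raise ValueError("polyad order must be between 2 (dyad) and 6 (hexad)")
    depth = n - 1
    table = PolyadTable(order=n)
    for i, res in enumerate(structure.residues):
        nbrs = neighbors.get(i, [])
        if len(nbrs) < depth:
            raise ValueError(
                f"residue {i}: neighbor list depth {len(nbrs)} < required {depth}"
            )
        zone = assignment.zones.get(i, "all") if assignment is not None else "all"
        key = (res.aa_type,
               tuple(sorted(structure.residues[j].aa_type for j, _ in nbrs[:depth])),
               zone)
        table.counts[key] += 1
        table.zone_totals[zone] = table.zone_totals.get(zone, 0) + 1
    return table


def classify_triad(triad: Polyad,
                   charged: frozenset[str] = CHARGED_RESIDUES) -> str:
    """Charge class of a triad's two neighbors: '±±', '±0' or '00'.

    Charged residues are D, E, K, R (histidine neutral by default).
    """
    if triad.order != 3:
        raise ValueError("charge classes are defined for triads (order 3)")
    n_charged = sum(1 for aa in triad.neighbors if aa in charged)
    return {2: "±±", 1: "±0", 0: "00"}[n_charged]


def classify_k_triad(triad: Polyad) -> str:
    """Charge class of a lysine-focal triad (K±±, K±0, K00)."""
    if triad.focal != "K":
        raise ValueError(
            f"focal residue is {triad.focal!r}, not K; use classify_triad for "
            "generic focal residues"
        )
    return classify_triad(triad)


def heatmap_matrix(table: PolyadTable, focal: str, zone: str = "all") -> pd.DataFrame:
    """20×20 symmetric neighbor-pair count matrix for one focal type and zone.

    Entry (a, b) is the count of triads (focal, {a, b}); homotypic pairs sit
    on the diagonal and are counted once.
    """
    if table.order != 3:
        raise ValueError("heatmaps are defined for triad tables (order 3)")
    M = pd.DataFrame(0, index=list(AA_ORDER), columns=list(AA_ORDER), dtype=int)
    for (f, nbrs, z), c in table.counts.items():
        if f != focal or z != zone:
            continue
        a, b = nbrs
        M.loc[a, b] += c
        if a != b:
            M.loc[b, a] += c
    return M


def zone_composition(structure: ProteinStructure,
                     assignment: ZoneAssignment) -> dict[str, CompositionTable]:
    """Amino-acid composition of each zone; empty zones are absent."""
    out: dict[str, CompositionTable] = {}
    for zone in ZONES:
        members = [structure.residues[i].aa_type for i in assignment.residues_in(zone)]
        if not members:
            continue
        counts = {aa: 0 for aa in sorted(AA_ORDER)}
        for aa in members:
            counts[aa] += 1
        total = len(members)
        out[zone] = CompositionTable(
            counts=counts,
            fractions={aa: 100.0 * c / total for aa, c in counts.items()},
        )
    return out
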