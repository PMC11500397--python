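"""Build the annealing simulation system: protein, water shell, counterions.

The protein sits at the center of an empty cubic box, enveloped in a water
shell of uniform thickness; counterions neutralize the system at a fixed
stand-off distance from the protein surface so they perturb neither the
protein nor its hydration shell.

Water placement is a seeded, jittered cubic grid filtered to the shell band
``r_excl <= d <= d_shell`` around the protein's heavy atoms.  Candidate grid
sites are additionally flood-filled from the box boundary so that occluded
interior cavities — points far enough from every atom but unreachable by bulk
solvent — receive no water.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import ParameterError, PlacementError
from .geometry import heavy_atom_arrays
from .structure import ProteinStructure, write_structure

__all__ = [
    "WaterSite",
    "IonSite",
    "SolvationParams",
    "HydrationSystem",
    "build_shell",
    "neutralize",
    "write_system",
]


@dataclass(frozen=True)
class WaterSite:
    """A water molecule represented by its oxygen position."""

    id: int
    coords: np.ndarray


@dataclass(frozen=True)
class IonSite:
    species: str  # "Na+" or "Cl-"
    coords: np.ndarray


@dataclass(frozen=True)
class SolvationParams:
    """Geometry of the hydration shell.

    d_shell : shell thickness from the protein surface, Å
    r_excl : minimum water-oxygen to protein heavy-atom distance, Å
    d_ion : ion stand-off distance from the protein surface, Å
    water_spacing : placement grid pitch, Å
    jitter : uniform jitter amplitude applied per grid axis, Å
    min_water_sep : minimum water-water distance retained, Å
    """

    d_shell: float = 6.0
    r_excl: float = 2.4
    d_ion: float | None = None
    water_spacing: float = 3.1
    jitter: float = 0.4
    min_water_sep: float = 2.6

    def __post_init__(self):
        if self.d_ion is None:
            object.__setattr__(self, "d_ion", self.d_shell + 4.0)
        for name in ("d_shell", "r_excl", "d_ion", "water_spacing", "min_water_sep"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if self.jitter < 0:
            raise ParameterError("jitter must be non-negative")
        if self.r_excl > self.d_shell:
            raise ParameterError("r_excl must not exceed d_shell")
        if self.d_ion <= self.d_shell:
            raise ParameterError("d_ion must exceed d_shell")


@dataclass
class HydrationSystem:
    structure: ProteinStructure
    waters: list[WaterSite]
    ions: list[IonSite] = field(default_factory=list)
    box_edge: float = 0.0
    box_center: np.ndarray = field(default_factory=lambda: np.zeros(3))
    params: SolvationParams = field(default_factory=SolvationParams)
    seed: int | None = None

    @property
    def water_coords(self) -> np.ndarray:
        if not self.waters:
            return np.empty((0, 3))
        return np.asarray([w.coords for w in self.waters])

    @property
    def water_ids(self) -> np.ndarray:
        return np.asarray([w.id for w in self.waters], dtype=int)

    @property
    def total_charge(self) -> int:
        ion_charge = sum(1 if i.species == "Na+" else -1 for i in self.ions)
        return self.structure.net_charge + ion_charge


def build_shell(structure: ProteinStructure, params: SolvationParams | None = None,
                seed: int = 0) -> HydrationSystem:
    """Envelop a protein in a uniform-thickness water shell inside a cubic box.

    Every placed water oxygen lies at distance d from its nearest protein
    heavy atom with ``r_excl <= d <= d_shell``, is reachable from bulk solvent
    (interior cavities stay dry) and is at least ``min_water_sep`` from every
    other water.  Placement is deterministic for a given seed.
    """
    if params is None:
        params = SolvationParams()
    atoms, _ = heavy_atom_arrays(structure)
    if len(atoms) == 0:
        raise ParameterError("structure has no heavy atoms")

    center = atoms.mean(axis=0)
    extent = float(np.max(atoms.max(axis=0) - atoms.min(axis=0)))
    box_edge = extent + 2.0 * (params.d_shell + 10.0)

    pitch = params.water_spacing
    lo = atoms.min(axis=0) - params.d_shell - pitch
    hi = atoms.max(axis=0) + params.d_shell + pitch
    axes = [np.arange(lo[k], hi[k] + pitch, pitch) for k in range(3)]
    shape = tuple(len(ax) for ax in axes)
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)

    tree = cKDTree(atoms)
    dist, _ = tree.query(grid, k=1)
    dist = dist.reshape(shape)

    # flood fill from the grid boundary through sites outside the exclusion
    # radius; anything not connected to the outside is an occluded cavity
    accessible = dist >= params.r_excl
    labels, _ = ndimage.label(accessible, structure=ndimage.generate_binary_structure(3, 1))
    boundary = np.zeros(shape, dtype=bool)
    for ax in range(3):
        boundary[(slice(None),) * ax + (0,)] = True
        boundary[(slice(None),) * ax + (-1,)] = True
    outside_labels = np.unique(labels[boundary & accessible])
    outside_labels = outside_labels[outside_labels > 0]
    reachable = np.isin(labels, outside_labels)

    candidate = reachable & (dist <= params.d_shell)
    points = grid[candidate.reshape(-1)]

    rng = np.random.default_rng(seed)
    if params.jitter > 0 and len(points):
        points = points + rng.uniform(-params.jitter, params.jitter, size=points.shape)

    if len(points):
        d_exact, _ = tree.query(points, k=1)
        keep = (d_exact >= params.r_excl) & (d_exact <= params.d_shell)
        points = points[keep]

    # enforce pairwise water separation deterministically (drop higher index)
    if len(points):
        wtree = cKDTree(points)
        removed = np.zeros(len(points), dtype=bool)
        pairs = wtree.query_pairs(params.min_water_sep, output_type="ndarray")
        if len(pairs):
            order = np.lexsort((pairs[:, 1], pairs[:, 0]))
            for i, j in pairs[order]:
                if not removed[i] and not removed[j]:
                    removed[max(i, j)] = True
        points = points[~removed]

    waters = [WaterSite(id=i, coords=p) for i, p in enumerate(points)]
    return HydrationSystem(
        structure=structure, waters=waters, box_edge=box_edge,
        box_center=center, params=params, seed=seed,
    )


def neutralize(system: HydrationSystem, seed: int | None = None,
               max_attempts: int = 5000) -> HydrationSystem:
    """Add counterions so the total system charge is zero.

    Ions of sign opposite to the protein's net charge are placed at least
    ``d_ion`` from every protein heavy atom, 3.0 Å from every water and from
    each other, inside the box.  Returns a new system; the input is unchanged.
    """
    net = system.structure.net_charge
    if net == 0:
        return replace(system, ions=[])
    species = "Na+" if net < 0 else "Cl-"
    n_ions = abs(net)
    params = system.params
    atoms, _ = heavy_atom_arrays(system.structure)
    atom_tree = cKDTree(atoms)
    water_coords = system.water_coords
    water_tree = cKDTree(water_coords) if len(water_coords) else None

    rng = np.random.default_rng(system.seed if seed is None else seed)
    center = system.box_center
    half = system.box_edge / 2.0 - 1.0

    placed: list[np.ndarray] = []
    attempts = 0
    while len(placed) < n_ions:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {n_ions} ions after {max_attempts} attempts; "
                "consider a larger box"
            )
        attempts += 1
        pos = center + rng.uniform(-half, half, size=3)
        if atom_tree.query(pos[None, :], k=1)[0][0] < params.d_ion:
            continue
        if water_tree is not None and water_tree.query(pos[None, :], k=1)[0][0] < 3.0:
            continue
        if placed and min(np.linalg.norm(pos - q) for q in placed) < 3.0:
            continue
        placed.append(pos)

    ions = [IonSite(species=species, coords=p) for p in placed]
    out = replace(system, ions=ions)
    assert out.total_charge == 0
    return out


def write_system(system: HydrationSystem, path) -> None:
    """Write protein + HOH + ion records as a single PDB file."""
    write_structure(
        system.structure, path,
        waters=[(w.id, w.coords) for w in system.waters],
        ions=[(i.species, i.coords) for i in system.ions],
    )
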