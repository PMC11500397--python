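"""Water-contact dynamics and the parch score.

The score for residue *i* is built from the survival of its initial
hydration-shell contacts during a constant-rate temperature ramp:

    C_i(t_m) = |S_i(0) ∩ S_i(t_m)| / |S_i(0)|

where S_i(t) is the set of water molecules in contact with residue *i* at
recorded frame *t*.  C̄_i is the time average of C_i over frames 1..M (the
origin frame is excluded), and

    parch_i = 10 · C̄_i / C̄_Lys

with C̄_Lys the same quantity for an isolated, fully hydrated zwitterionic
lysine run under the identical schedule.  Residues with no initial water
contact have C̄_i = 0 and therefore parch 0 by definition; a residue whose
contact dynamics match the lysine reference scores 10.  The ramp is one-way
(waters evaporate and do not return), so the survival fraction uses a single
time origin; a multi-origin average is available but off by default because
the annealed system is not stationary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConsistencyError, NormalizationError, ParameterError

__all__ = [
    "AnnealingSchedule",
    "ContactParams",
    "ContactTrajectory",
    "ParchResult",
    "count_contacts",
    "survival_series",
    "c_bar",
    "parch_value",
    "reference_c_bar",
    "parch_pipeline",
    "read_contact_trajectory",
]


@dataclass(frozen=True)
class AnnealingSchedule:
    """Constant-rate heating ramp: T(m) = T0 + rate·m at recorded frame m."""

    T0: float = 300.0
    rate: float = 2.0
    n_frames: int = 100
    dt_record: float = 1.0

    def __post_init__(self):
        if self.rate <= 0:
            raise ParameterError("annealing rate must be positive (heating)")
        if self.n_frames < 2:
            raise ParameterError("need at least 2 recorded frames")

    def temperature(self, m) -> np.ndarray:
        return self.T0 + self.rate * np.asarray(m, dtype=float)


@dataclass(frozen=True)
class ContactParams:
    """Contact definition: water oxygen within ``r_contact`` of any heavy atom."""

    r_contact: float = 3.5

    def __post_init__(self):
        if self.r_contact <= 0:
            raise ParameterError("r_contact must be positive")


@dataclass
class ContactTrajectory:
    """Per-residue contacting-water id sets at each recorded frame.

    ``frames[m]`` maps residue index → frozenset of water ids.  Frame 0 must
    carry every residue index (empty sets allowed); later frames may omit
    residues whose sets have emptied.  Under the evaporation model the sets
    shrink monotonically; synthetic trajectories satisfy this by construction
    and real trajectories are checked and warned.
    """

    frames: list[dict[int, frozenset[int]]]
    schedule: AnnealingSchedule
    replicate_seed: int = 0

    def __post_init__(self):
        if len(self.frames) != self.schedule.n_frames:
            raise ParameterError(
                f"trajectory has {len(self.frames)} frames but the schedule "
                f"declares {self.schedule.n_frames}"
            )

    @property
    def residue_indices(self) -> list[int]:
        return sorted(self.frames[0])

    def is_monotone(self) -> bool:
        for m in range(1, len(self.frames)):
            prev, cur = self.frames[m - 1], self.frames[m]
            for i, s in cur.items():
                if not s <= prev.get(i, frozenset()):
                    return False
        return True

    def check_monotone(self) -> None:
        if not self.is_monotone():
            warnings.warn(
                "contact trajectory is not evaporation-monotone: waters re-enter "
                "some contact sets (expected for real trajectories)",
                stacklevel=2,
            )


@dataclass
class ParchResult:
    """Per-residue parch estimate across annealing replicates."""

    residue_index: int
    C_bar: float
    parch_replicates: list[float]
    parch: float
    parch_sd: float


# ---------------------------------------------------------------------------
# Contact counting
# ---------------------------------------------------------------------------

def count_contacts(water_coords: np.ndarray, structure,
                   params: ContactParams | None = None,
                   water_ids: np.ndarray | None = None) -> dict[int, frozenset[int]]:
    """Waters within ``r_contact`` of any heavy atom, per residue.

    A water may contact several residues at once; membership is independent
    per residue.  Returns a map with an entry (possibly empty) for every
    residue of the structure.
    """
    if params is None:
        params = ContactParams()
    water_coords = np.asarray(water_coords, dtype=float)
    if water_ids is None:
        water_ids = np.arange(len(water_coords))
    out: dict[int, frozenset[int]] = {}
    if len(water_coords) == 0:
        return {i: frozenset() for i in range(len(structure.residues))}
    tree = cKDTree(water_coords)
    for i, res in enumerate(structure.residues):
        hits: set[int] = set()
        atoms = np.asarray([a.coords for a in res.atoms if a.is_heavy])
        for idx_list in tree.query_ball_point(atoms, params.r_contact):
            hits.update(idx_list)
        out[i] = frozenset(int(water_ids[j]) for j in hits)
    return out


# ---------------------------------------------------------------------------
# Survival / autocorrelation
# ---------------------------------------------------------------------------

def survival_series(traj: ContactTrajectory, residue_index: int,
                    multi_origin: bool = False) -> list[float]:
    """C_i(t_m) for m = 1..M, with the origin fixed at the first recorded frame.

    An empty initial contact set yields an all-zero series.  With
    ``multi_origin=True`` each lag averages the survival fraction over all
    admissible origins (only meaningful for stationary trajectories).
    """
    if residue_index not in traj.frames[0]:
        raise IndexError(f"residue index {residue_index} not present in trajectory")
    M = len(traj.frames) - 1
    if multi_origin:
        sets = [traj.frames[m].get(residue_index, frozenset()) for m in range(M + 1)]
        series = []
        for lag in range(1, M + 1):
            vals = [len(sets[o] & sets[o + lag]) / len(sets[o])
                    for o in range(M + 1 - lag) if sets[o]]
            series.append(float(np.mean(vals)) if vals else 0.0)
        return series
    s0 = traj.frames[0][residue_index]
    if not s0:
        return [0.0] * M
    n0 = len(s0)
    return [len(s0 & traj.frames[m].get(residue_index, frozenset())) / n0
            for m in range(1, M + 1)]


def c_bar(series: list[float]) -> float:
    """Time-averaged autocorrelation: arithmetic mean of C_i over recorded frames."""
    if len(series) == 0:
        raise ValueError("cannot average an empty survival series")
    return float(np.mean(series))


def parch_value(c_bar_i: float, c_bar_lys: float) -> float:
    """parch = 10 · C̄_i / C̄_Lys, clamped to [0, 10].

    Sampling noise can push C̄_i marginally above C̄_Lys; such values are
    clamped to 10 with a warning.  A zero reference is a hard error.
    """
    if c_bar_lys <= 0:
        raise NormalizationError("lysine reference autocorrelation must be positive")
    ratio = c_bar_i / c_bar_lys
    if ratio > 1.0:
        warnings.warn(
            f"C_bar ratio {ratio:.4f} exceeds 1; parch clamped to 10", stacklevel=2
        )
        ratio = 1.0
    if ratio < 0.0:
        ratio = 0.0
    return 10.0 * ratio


_reference_cache: dict[tuple, float] = {}


def reference_c_bar(reference_traj: ContactTrajectory,
                    expected_schedule: AnnealingSchedule | None = None) -> float:
    """C̄ of the isolated lysine reference trajectory.

    The trajectory must contain exactly one residue.  If ``expected_schedule``
    is given it must match the reference's schedule (same ramp, same frame
    count), otherwise normalization across runs is meaningless.  Results are
    cached per (schedule, seed, contact fingerprint).
    """
    if expected_schedule is not None and reference_traj.schedule != expected_schedule:
        raise ConsistencyError(
            "reference trajectory schedule differs from the analysis schedule"
        )
    indices = reference_traj.residue_indices
    if len(indices) != 1:
        raise ParameterError(
            f"reference trajectory must hold a single residue, found {len(indices)}"
        )
    key = (reference_traj.schedule, reference_traj.replicate_seed,
           len(reference_traj.frames[0][indices[0]]))
    if key not in _reference_cache:
        _reference_cache[key] = c_bar(survival_series(reference_traj, indices[0]))
    return _reference_cache[key]


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

def parch_pipeline(trajs: list[ContactTrajectory], reference: float,
                   strict_triplicate: bool = True) -> list[ParchResult]:
    """Per-residue parch values averaged over annealing replicates.

    Each replicate yields one parch value per residue; the final value is the
    replicate mean and its uncertainty the sample standard deviation.  The
    protocol calls for triplicates: with ``strict_triplicate=True`` (default)
    any other replicate count raises; with ``False`` it warns and any n ≥ 1
    is accepted.
    """
    if len(trajs) == 0:
        raise ParameterError("at least one replicate trajectory is required")
    if len(trajs) != 3:
        msg = f"expected 3 annealing replicates, got {len(trajs)}"
        if strict_triplicate:
            raise ParameterError(msg)
        warnings.warn(msg, stacklevel=2)
    schedule = trajs[0].schedule
    for t in trajs[1:]:
        if t.schedule != schedule:
            raise ConsistencyError("replicates were recorded under different schedules")

    indices = sorted(set().union(*(t.frames[0].keys() for t in trajs)))
    results = []
    for i in indices:
        cbars = [c_bar(survival_series(t, i)) for t in trajs]
        reps = [parch_value(cb, reference) for cb in cbars]
        sd = float(np.std(reps, ddof=1)) if len(reps) > 1 else 0.0
        results.append(ParchResult(
            residue_index=i,
            C_bar=float(np.mean(cbars)),
            parch_replicates=reps,
            parch=float(np.mean(reps)),
            parch_sd=sd,
        ))
    return results


# ---------------------------------------------------------------------------
# Trajectory ingestion (multi-model PDB)
# ---------------------------------------------------------------------------

def read_contact_trajectory(path, params: ContactParams | None = None,
                            schedule: AnnealingSchedule | None = None,
                            replicate_seed: int = 0) -> ContactTrajectory:
    """Build a ContactTrajectory from a multi-model PDB of the hydrated system.

    Each MODEL must contain the (position-restrained) protein plus the waters
    still present at that frame; water identity is taken from the water
    residue sequence number so ids persist across frames.  Contact sets are
    recomputed per frame with :func:`count_contacts`.
    """
    from Bio.PDB import PDBParser

    from .constants import THREE_TO_ONE, WATER_RESNAMES
    from .structure import read_structure

    if params is None:
        params = ContactParams()
    protein = read_structure(path, model_index=0)
    parser = PDBParser(QUIET=True)
    bp = parser.get_structure("traj", str(path))
    frames = []
    for model in bp:
        coords, ids = [], []
        for chain in model:
            for res in chain:
                if res.get_resname().strip() in WATER_RESNAMES:
                    for atom in res:
                        if (atom.element or "O").upper() == "O":
                            coords.append(atom.get_coord())
                            ids.append(res.id[1])
                elif res.get_resname().strip() not in THREE_TO_ONE:
                    continue
        coords = np.asarray(coords, dtype=float) if coords else np.empty((0, 3))
        frames.append(count_contacts(coords, protein, params,
                                     water_ids=np.asarray(ids, dtype=int)))
    if schedule is None:
        schedule = AnnealingSchedule(n_frames=len(frames))
    traj = ContactTrajectory(frames=frames, schedule=schedule,
                             replicate_seed=replicate_seed)
    traj.check_monotone()
    return traj
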