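"""Synthetic protein-like worlds with planted ground truth.

Structures are single-pseudo-atom residues packed into a sphere by seeded
rejection sampling, with the charged types {K,R,D,E} enriched toward the
surface through a logistic profile in the fractional radius — mimicking the
surface charge enrichment seen in real globular proteins.  Contact dynamics
are emulated directly: each initial water contact of residue *i* escapes
independently with an Arrhenius-style hazard

    h_i(T) = a_i · exp(−E_i / T),      T(m) = T0 + rate·m,

so the per-residue-type activation parameter E_aa *is* the planted ground
truth hydropathy (larger E → water retained longer → higher parch).  Escaped
waters never return, which keeps every survival series monotone and the
closed form E[C_i(t_m)] = Π_{m'≤m}(1−h_i(T(m'))) exact.

Escape is contact-level: a water touching two residues leaves each contact
set independently.  This keeps per-residue series independent of each other;
a shared-water mode (``water_level_escape=True``) exists for realism checks.

Because a residue here is one pseudo-atom of ~1.9 Å radius, the synthetic
defaults use residue-center distances: waters sit 3.8–7.0 Å from centers and
a contact is a water within 4.8 Å — the all-atom defaults (2.4/6.0/3.5 Å)
apply only to real multi-atom structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .constants import (
    CHARGED_RESIDUES,
    CHARGED_TYPE_WEIGHTS,
    DEFAULT_HAZARD_MODEL,
    UNCHARGED_TYPE_WEIGHTS,
)
from .contacts import (
    AnnealingSchedule,
    ContactParams,
    ContactTrajectory,
    count_contacts,
    reference_c_bar,
)
from .errors import DensityError, ParameterError
from .solvation import HydrationSystem, SolvationParams, build_shell
from .structure import Atom, ProteinStructure, ResidueRecord

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "SyntheticWorld",
    "generate_structure",
    "generate_trajectory",
    "reference_trajectory",
    "generate_world",
    "constant_escape_trajectory",
]

#: Solvation geometry for single-pseudo-atom residues (center-based distances).
SYNTHETIC_SOLVATION = SolvationParams(d_shell=7.0, r_excl=3.8, d_ion=11.0,
                                      water_spacing=3.1)
#: Contact cutoff for pseudo-atom residues: first water layer around a
#: ~1.9 Å residue sphere plus the water radius.
SYNTHETIC_CONTACTS = ContactParams(r_contact=4.8)

#: Zonation feature cutoffs for pseudo-atom residues.  Exposure and burial of
#: a coarse single-site residue live on the packing scale (3.8 Å), so both
#: kernels span ~2.5 packing radii; the all-atom defaults (3.5 / 5.0 Å) are
#: far too local for this representation.
SYNTHETIC_ZONE_CONTACTS = ContactParams(r_contact=9.5)
SYNTHETIC_ZONE_R_NBR = 9.0

#: Denser shell for the isolated lysine reference: C̄_Lys is a normalization
#: constant, so the reference run uses a finer water grid (more contacts,
#: smaller sampling variance) — per-contact survival statistics are unchanged.
REFERENCE_SOLVATION = SolvationParams(d_shell=7.0, r_excl=3.8, d_ion=11.0,
                                      water_spacing=2.2, jitter=0.25,
                                      min_water_sep=1.9)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic world.

    packing_radius : minimum residue-center separation, Å.
    packing_fraction : target volume fraction of the packing (sets the sphere
        radius); rejection sampling saturates near 0.38, default 0.30.
    surface_enrichment : charged-type probability rises logistically with the
        fractional radius from ``p_charged_core`` to ``p_charged_surface``
        (midpoint/width in fractional-radius units); when off, a flat
        ``charged_fraction`` applies everywhere.
    hazard_model : aa → (a_aa, E_aa) escape kinetics; the planted hydropathy.
    """

    n_residues: int
    packing_radius: float = 3.8
    packing_fraction: float = 0.30
    surface_enrichment: bool = True
    p_charged_core: float = 0.10
    p_charged_surface: float = 0.45
    enrichment_midpoint: float = 0.75
    enrichment_width: float = 0.08
    charged_fraction: float = 0.22
    hazard_model: dict = field(default_factory=lambda: dict(DEFAULT_HAZARD_MODEL))
    schedule: AnnealingSchedule = field(default_factory=AnnealingSchedule)
    solvation: SolvationParams = field(default_factory=lambda: SYNTHETIC_SOLVATION)
    contact_params: ContactParams = field(default_factory=lambda: SYNTHETIC_CONTACTS)
    zone_contact_params: ContactParams = field(
        default_factory=lambda: SYNTHETIC_ZONE_CONTACTS)
    zone_r_nbr: float = SYNTHETIC_ZONE_R_NBR
    water_level_escape: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 1:
            raise ParameterError("n_residues must be at least 1")
        for name in ("packing_radius", "packing_fraction", "enrichment_width"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")

    def p_charged(self, radial_fraction: np.ndarray) -> np.ndarray:
        """Probability that a residue at fractional radius u is charged."""
        u = np.asarray(radial_fraction, dtype=float)
        if not self.surface_enrichment:
            return np.full_like(u, self.charged_fraction)
        lo, hi = self.p_charged_core, self.p_charged_surface
        return lo + (hi - lo) / (1.0 + np.exp(-(u - self.enrichment_midpoint)
                                              / self.enrichment_width))

    def expected_frequencies(self) -> dict[str, float]:
        """Marginal residue-type probabilities implied by the spec.

        Radial positions are uniform in the ball, so the fractional radius has
        density 3u²; the charged fraction is averaged against it numerically.
        """
        u = np.linspace(0.0, 1.0, 2001)
        p_charged = float(np.trapezoid(3.0 * u**2 * self.p_charged(u), u))
        freqs = {aa: p_charged * w for aa, w in CHARGED_TYPE_WEIGHTS.items()}
        freqs.update({aa: (1.0 - p_charged) * w
                      for aa, w in UNCHARGED_TYPE_WEIGHTS.items()})
        return freqs


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted, recorded at generation time.

    ``hydropathy_rank[aa]`` ranks the types present by planted E_aa
    (1 = most hydrophilic).  ``planted_zone`` is the radial tercile of the
    packing: outer third 'shell', middle 'mantle', inner 'core'.
    """

    radial_fraction: tuple[float, ...]
    planted_zone: tuple[str, ...]
    aa_types: tuple[str, ...]
    escape_hazards: tuple[tuple[float, float], ...]  # (a_aa, E_aa) per residue
    hydropathy_rank: dict[str, int]


@dataclass
class SyntheticWorld:
    """A fully generated study system: structure, solvent, replicates, reference."""

    spec: SyntheticSpec
    structure: ProteinStructure
    ground_truth: GroundTruth
    system: HydrationSystem
    trajectories: tuple[ContactTrajectory, ...]
    reference_c_bar: float


# ---------------------------------------------------------------------------
# Structure generation
# ---------------------------------------------------------------------------

def _pack_sphere(n: int, min_sep: float, radius: float, rng,
                 max_attempts_per_point: int = 400) -> np.ndarray:
    """Random sequential addition of n points in a ball with minimum separation."""
    points = np.empty((n, 3))
    placed = 0
    attempts_left = max_attempts_per_point * n
    while placed < n:
        if attempts_left <= 0:
            raise DensityError(
                f"packed only {placed}/{n} residues at separation {min_sep} Å in a "
                f"{radius:.1f} Å sphere; lower packing_fraction"
            )
        attempts_left -= 1
        direction = rng.normal(size=3)
        norm = np.linalg.norm(direction)
        if norm == 0:
            continue
        pos = direction / norm * radius * rng.uniform() ** (1.0 / 3.0)
        if placed and np.min(np.linalg.norm(points[:placed] - pos, axis=1)) < min_sep:
            continue
        points[placed] = pos
        placed += 1
    return points


def generate_structure(spec: SyntheticSpec) -> tuple[ProteinStructure, GroundTruth]:
    """Pack pseudo-residues in a sphere and draw types with radial enrichment."""
    rng = np.random.default_rng(spec.seed)
    pseudo_radius = spec.packing_radius / 2.0
    R = pseudo_radius * (spec.n_residues / spec.packing_fraction) ** (1.0 / 3.0)
    if spec.n_residues == 1:
        points = np.zeros((1, 3))
        R = pseudo_radius
    else:
        points = _pack_sphere(spec.n_residues, spec.packing_radius, R, rng)

    radii = np.linalg.norm(points, axis=1)
    u = radii / max(R, 1e-9)

    charged_types = sorted(CHARGED_TYPE_WEIGHTS)
    charged_w = np.asarray([CHARGED_TYPE_WEIGHTS[a] for a in charged_types])
    uncharged_types = sorted(UNCHARGED_TYPE_WEIGHTS)
    uncharged_w = np.asarray([UNCHARGED_TYPE_WEIGHTS[a] for a in uncharged_types])

    p = spec.p_charged(u)
    is_charged = rng.uniform(size=spec.n_residues) < p
    aa_types = np.empty(spec.n_residues, dtype="U1")
    n_ch = int(is_charged.sum())
    if n_ch:
        aa_types[is_charged] = rng.choice(charged_types, size=n_ch,
                                          p=charged_w / charged_w.sum())
    if spec.n_residues - n_ch:
        aa_types[~is_charged] = rng.choice(uncharged_types,
                                           size=spec.n_residues - n_ch,
                                           p=uncharged_w / uncharged_w.sum())

    residues = [
        ResidueRecord(
            chain_id="A", seq_index=i + 1, aa_type=str(aa_types[i]),
            atoms=[Atom(name="CA", element="C", coords=points[i])],
        )
        for i in range(spec.n_residues)
    ]
    structure = ProteinStructure(
        id=f"synthetic-n{spec.n_residues}-s{spec.seed}", residues=residues
    )

    terciles = np.array_split(np.argsort(radii), 3)
    zone_arr = np.empty(spec.n_residues, dtype="U6")
    for label, block in zip(("core", "mantle", "shell"), terciles):
        zone_arr[block] = label

    present = sorted(set(aa_types.tolist()))
    by_E = sorted(present, key=lambda aa: -spec.hazard_model[aa][1])
    rank = {aa: r + 1 for r, aa in enumerate(by_E)}

    truth = GroundTruth(
        radial_fraction=tuple(float(x) for x in u),
        planted_zone=tuple(str(z) for z in zone_arr),
        aa_types=tuple(str(a) for a in aa_types),
        escape_hazards=tuple(
            (float(spec.hazard_model[a][0]), float(spec.hazard_model[a][1]))
            for a in aa_types
        ),
        hydropathy_rank=rank,
    )
    return structure, truth


# ---------------------------------------------------------------------------
# Contact-trajectory simulation
# ---------------------------------------------------------------------------

def _frame_hazards(a: float, E: float, schedule: AnnealingSchedule) -> np.ndarray:
    """Per-frame escape probabilities h(T(m)) for m = 1..M, clipped to [0, 1]."""
    m = np.arange(1, schedule.n_frames)
    T = schedule.temperature(m)
    return np.clip(a * np.exp(-E / T), 0.0, 1.0)


def _simulate_decay(initial: dict[int, frozenset[int]],
                    hazards: dict[int, tuple[float, float]],
                    schedule: AnnealingSchedule, seed: int,
                    water_level: bool = False) -> list[dict[int, frozenset[int]]]:
    """Evolve contact sets under per-residue Arrhenius escape hazards.

    Each contact draws an Exp(1) escape threshold; the contact survives frame
    m while its cumulative hazard Σ_{m'≤m} −log(1−h(T(m'))) stays below the
    threshold.  This is exactly the sequential Bernoulli process with
    per-frame escape probability h, but common random numbers make survival
    monotone in the hazard (used by rate-sweep properties).  With
    ``water_level=True`` a single threshold per water makes it leave all of
    its contact sets at once.
    """
    rng = np.random.default_rng(seed)
    M = schedule.n_frames - 1
    contacts = [(i, w) for i in sorted(initial) for w in sorted(initial[i])]

    if water_level:
        water_ids = sorted({w for _, w in contacts})
        thresholds_by_water = dict(zip(water_ids, rng.exponential(size=len(water_ids))))
        thresholds = np.asarray([thresholds_by_water[w] for _, w in contacts])
    else:
        thresholds = rng.exponential(size=len(contacts))

    cum_by_residue: dict[int, np.ndarray] = {}
    for i in sorted(initial):
        a, E = hazards[i]
        h = _frame_hazards(a, E, schedule)
        with np.errstate(divide="ignore"):
            step = -np.log1p(-h)
        cum_by_residue[i] = np.cumsum(step)

    # escape frame: first m in 1..M whose cumulative hazard reaches the threshold
    by_residue: dict[int, list[tuple[int, int]]] = {i: [] for i in initial}
    for k, (i, w) in enumerate(contacts):
        cum = cum_by_residue[i]
        pos = int(np.searchsorted(cum, thresholds[k], side="left"))
        escape = pos + 1 if pos < M else M + 1  # M+1 = never escapes
        by_residue[i].append((w, escape))

    frames: list[dict[int, frozenset[int]]] = [dict(initial)]
    for m in range(1, M + 1):
        frames.append({
            i: frozenset(w for w, escape in lst if escape > m)
            for i, lst in by_residue.items()
        })
    return frames


def generate_trajectory(system: HydrationSystem, spec: SyntheticSpec,
                        replicate_seed: int) -> ContactTrajectory:
    """One annealing replicate: initial contacts plus stochastic evaporation."""
    initial = count_contacts(system.water_coords, system.structure,
                             spec.contact_params, water_ids=system.water_ids)
    hazards = {
        i: spec.hazard_model[res.aa_type]
        for i, res in enumerate(system.structure.residues)
    }
    frames = _simulate_decay(initial, hazards, spec.schedule, replicate_seed,
                             water_level=spec.water_level_escape)
    return ContactTrajectory(frames=frames, schedule=spec.schedule,
                             replicate_seed=replicate_seed)


def reference_trajectory(spec: SyntheticSpec, replicate_seed: int) -> ContactTrajectory:
    """Isolated, fully hydrated zwitterionic lysine under the same schedule.

    The single-residue trajectory that defines C̄_Lys for normalization; by
    construction the reference residue's own parch is 10.
    """
    lys = ProteinStructure(
        id="LYS-reference",
        residues=[ResidueRecord(chain_id="A", seq_index=1, aa_type="K",
                                atoms=[Atom(name="CA", element="C",
                                            coords=np.zeros(3))])],
    )
    system = build_shell(lys, REFERENCE_SOLVATION, seed=replicate_seed)
    ref_spec = replace(spec, water_level_escape=False)
    return generate_trajectory(system, ref_spec, replicate_seed)


def constant_escape_trajectory(n_waters: int, q: float, n_recorded: int,
                               seed: int) -> ContactTrajectory:
    """Single residue whose every contact escapes with constant probability q.

    ``n_recorded`` counts the frames after the origin (M); useful as the exact
    Bernoulli benchmark E[C(t_m)] = (1−q)^m.
    """
    schedule = AnnealingSchedule(T0=300.0, rate=1.0, n_frames=n_recorded + 1)
    initial = {0: frozenset(range(n_waters))}
    frames = _simulate_decay(initial, {0: (q, 0.0)}, schedule, seed)
    return ContactTrajectory(frames=frames, schedule=schedule, replicate_seed=seed)


# ---------------------------------------------------------------------------
# World orchestration
# ---------------------------------------------------------------------------

def generate_world(spec: SyntheticSpec, n_replicates: int = 3,
                   n_reference_runs: int = 8) -> SyntheticWorld:
    """Structure → solvation → replicate trajectories → lysine reference.

    Replicate seeds are {seed, seed+1, seed+2, ...}.  C̄_Lys is the mean over
    ``n_reference_runs`` independent reference runs (seeds offset by 1000):
    reference runs are cheap, and averaging keeps normalization noise well
    below the per-residue sampling noise.
    """
    structure, truth = generate_structure(spec)
    system = build_shell(structure, spec.solvation, seed=spec.seed)
    seeds = [spec.seed + r for r in range(n_replicates)]
    trajectories = tuple(generate_trajectory(system, spec, s) for s in seeds)
    refs = [reference_c_bar(reference_trajectory(spec, spec.seed + 1000 + r),
                            spec.schedule)
            for r in range(n_reference_runs)]
    return SyntheticWorld(
        spec=spec, structure=structure, ground_truth=truth, system=system,
        trajectories=trajectories, reference_c_bar=float(np.mean(refs)),
    )


# ---------------------------------------------------------------------------
# Ground-truth recovery helpers
# ---------------------------------------------------------------------------

def type_mean_parch(world: SyntheticWorld, results, min_residues: int = 3,
                    hydrated_only: bool = True) -> dict[str, float]:
    """Mean estimated parch per residue type.

    Escape kinetics are only observable for residues with a non-empty initial
    contact set, so buried residues are excluded by default (their planted
    hazard never acts).  Types with fewer than ``min_residues`` qualifying
    residues are dropped: one or two residues do not estimate a type effect.
    """
    truth = world.ground_truth
    by_type: dict[str, list[float]] = {}
    for r in results:
        if hydrated_only and not any(
            t.frames[0][r.residue_index] for t in world.trajectories
        ):
            continue
        by_type.setdefault(truth.aa_types[r.residue_index], []).append(r.parch)
    return {aa: float(np.mean(v)) for aa, v in by_type.items()
            if len(v) >= min_residues}


def hydropathy_recovery(world: SyntheticWorld, results,
                        min_residues: int = 3) -> float:
    """Spearman correlation between planted E_aa and estimated type-mean parch."""
    from scipy.stats import spearmanr

    means = type_mean_parch(world, results, min_residues=min_residues)
    aas = sorted(means)
    planted = [world.spec.hazard_model[a][1] for a in aas]
    return float(spearmanr(planted, [means[a] for a in aas]).statistic)


def planted_zone_agreement(world: SyntheticWorld, assignment) -> float:
    """Fraction of residues whose clustered zone matches the planted radial tercile."""
    truth = world.ground_truth
    n = len(truth.planted_zone)
    return float(np.mean([assignment.zones[i] == truth.planted_zone[i]
                          for i in range(n)]))
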