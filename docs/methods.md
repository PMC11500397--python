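# Methods

## The estimator

The hydropathy score of residue *i* is built from identity-tracked water
contacts during a one-way heating ramp.  A water oxygen within `r_contact`
of any heavy atom of the residue is a contact; a water may contact several
residues at once.  With `S_i(t)` the contacting-water id set at recorded
frame *t*,

    C_i(t_m) = |S_i(0) ∩ S_i(t_m)| / |S_i(0)|,   m = 1..M,

and `C̄_i` is the arithmetic mean over the M post-origin frames.  The score
is `parch_i = 10 · C̄_i / C̄_Lys`, clamped to [0, 10], where `C̄_Lys` comes
from an isolated, fully hydrated zwitterionic lysine run under the same
schedule.  Three independent ramps are run; the reported value is the
replicate mean and its uncertainty the sample standard deviation.

Two choices here were genuinely open and deserve justification:

* **Single-origin survival, not a multi-origin autocorrelation.**  The ramp
  is non-stationary by construction (waters leave and never return), so
  averaging over time origins mixes different temperatures and has no clear
  estimand.  The origin is fixed at the first recorded frame; a multi-origin
  mode exists (`survival_series(..., multi_origin=True)`) but is off by
  default.
* **Identity tracking, not count ratios.**  `C_i` intersects the initial set
  with the current set rather than dividing counts `N_i(t)/N_i(0)`.  On
  strictly evaporating trajectories the two coincide; on real trajectories
  with exchange, identity tracking measures retention of the original shell,
  which is the quantity the score is meant to capture.

Residues with `S_i(0) = ∅` have `C̄_i = 0` and parch exactly 0 — this is an
identity, not a numerical outcome.  Sampling noise can push `C̄_i` slightly
above `C̄_Lys` for residues with few contacts; the ratio is clamped to 1 with
a warning rather than letting scores exceed the scale.

## Parameters

| parameter | default | units | why |
|---|---|---|---|
| `r_contact` (all-atom) | 3.5 | Å | standard first-hydration-shell oxygen–heavy-atom cutoff |
| `d_shell` | 6.0 | Å | covers the first two hydration layers |
| `r_excl` | 2.4 | Å | water–protein steric exclusion |
| `d_ion` | `d_shell` + 4 | Å | keeps counterions off the protein and its shell |
| `water_spacing` / jitter | 3.1 / ±0.4 | Å | ≈ bulk-water density on a seeded, deterministic grid |
| schedule | T0=300, rate=2/frame, 100 frames | arbitrary | spreads default C̄ values across (0, 1) |
| `r_nbr` (all-atom zonation) | 5.0 | Å | first-contact residue shell |
| replicates | 3 (seeds base, base+1, base+2) | — | protocol triplicate |

All distance criteria use heavy atoms only.  Protein and ion coordinates are
never moved, so position restraints hold trivially.

## Solvation

`build_shell` places water oxygens on a jittered cubic grid restricted to the
band `r_excl ≤ d ≤ d_shell` around the protein's heavy atoms, then enforces a
minimum water–water separation of 2.6 Å deterministically.  One step goes
beyond the band criterion: candidate sites are flood-filled from the box
boundary, and sites not connected to bulk solvent are rejected.  Without
this, occluded interior cavities — frequent in the coarse synthetic packings
below — would be hydrated and buried residues would not be buried.
`neutralize` rejection-samples ion positions uniformly in the box subject to
`d ≥ d_ion` from the protein, ≥ 3 Å from every water and every other ion.

## Zonation

Residues are clustered into shell/mantle/core with k-means (k = 3, 10
restarts, fixed seed) on z-scored features `(n_water, n_neighbors)`:
contacting waters in the initial solvated frame and residues with any heavy
atom within `r_nbr`.  `n_water` is measured *before* annealing because
zonation is a static topographic property.  Cluster labels are made
identifiable by centroid ordering — highest water centroid → shell, lowest →
core, ties broken toward fewer neighbors for the shell.  Fewer than three
distinct feature vectors is a degenerate case that raises (or, on request,
returns a flagged single-zone assignment): small peptides may genuinely lack
a core.  Each protein is clustered on its own features by default; pooling
features across a dataset before clustering is supported by passing the
concatenated feature list.

## The synthetic generator

The generator exists to make every stage testable against planted truth; it
emulates the *statistics* of annealing contact dynamics, not water physics.

* **Structures** are single-pseudo-atom residues (radius ≈ 1.9 Å) packed
  into a sphere by seeded rejection sampling at volume fraction 0.30 with
  minimum separation 3.8 Å.  Residue types are drawn with the charged types
  {K, R, D, E} enriched logistically toward the surface (10% charged at the
  center rising to 45% at the surface, midpoint 0.75·R, width 0.08·R),
  mirroring the surface charge enrichment of real globular proteins;
  within-class frequencies follow natural abundances.
* **Contact dynamics**: each initial contact of residue *i* escapes per
  frame with hazard `h_i(T) = a_i·exp(−E_i/T)`, `T(m) = T0 + rate·m`, and
  never returns.  The activation parameter `E_aa` (linearly spaced 2200 → 600
  over a fixed hydrophilicity ordering with lysine highest) *is* the planted
  hydropathy.  Escapes are realised by drawing one Exp(1) threshold per
  contact and comparing it to the cumulative hazard — exactly the sequential
  Bernoulli process, but common random numbers make survival monotone in the
  hazard, which is what lets rate-sweep and paired-hazard properties hold
  deterministically.  Escape is contact-level (a shared water leaves each
  residue's set independently), keeping per-residue series independent and
  the closed form `E[C(t_m)] = Π(1−h(T(m')))` exact; a water-level mode
  exists for realism checks.
* **Pseudo-atom geometry.**  Because a residue is a single site, all
  synthetic distances are center-based and the defaults scale accordingly:
  waters occupy 3.8–7.0 Å from centers, a contact is a water within 4.8 Å,
  and the zonation features use coarser kernels (water count within 9.5 Å,
  neighbors within 9.0 Å ≈ 2.5 packing radii) because exposure and burial of
  a coarse site live on the packing scale, not the atomic scale.  These
  zonation kernels were fixed once, when the generator was designed, such
  that k-means zones recover the planted radial terciles at ≈ 86% on default
  geometry — the residual disagreement is intrinsic overlap of the features,
  present by design.
* **The reference** is a single lysine pseudo-residue solvated with a finer
  water grid (2.2 Å pitch): `C̄_Lys` is a normalization constant, so the
  reference run buys variance reduction with more contacts, which leaves
  per-contact survival statistics untouched.  `generate_world` additionally
  averages the reference over 8 independent runs.

### What passing tests do and do not show

The generator reproduces: monotone evaporation, hazard-ranked retention,
surface charge enrichment, a dry packed core, and triplicate averaging.  It
does not reproduce water exchange and rebinding, side-chain geometry,
temperature-dependent structural relaxation, or force-field physics.  Tests
passing on synthetic worlds therefore validate the *estimator* — counting,
survival algebra, normalization, clustering, bookkeeping — not the physical
accuracy of annealing simulations on real proteins.

### Recovery analyses

Type-level hydropathy recovery compares planted `E_aa` with the mean
estimated parch per residue type, restricted to residues with a non-empty
initial contact set (escape kinetics never act on dry residues, whose zeros
only add burial noise) and to types with at least 3 such residues (one or
two residues do not estimate a type effect).  Under the default study
conditions (500-residue world, triplicate ramps) the Spearman correlation is
≥ 0.95.

## Neighborhoods

Neighbor ranking uses minimum heavy-atom pair distance with ties broken
toward the lower sequence index (deterministic); a Cα-distance mode is
available.  Each residue contributes exactly one polyad of each order — its
own neighborhood — so per-zone polyad counts conserve per-zone residue
counts, and neighbor multisets are stored sorted because the two triad
neighbors are exchangeable.  Charge classes count D, E, K, R as charged;
histidine is neutral by default and configurable.

## Reporting

Distributions use 0.1-wide bins over [0, 10] (fine enough to resolve modal
statements at the 0.1 level); the most probable value is reported as the left
edge of the highest-density bin.  Shell rankings order proteins by the mean
parch of their shell residues; proteins without shell residues are flagged,
not ranked.  All exports are plain TSV/CSV/JSON and byte-reproducible under
fixed seeds.

## Problem sizes

Validation runs use worlds of 120–600 residues with 100-frame schedules and
triplicate ramps — large enough that type- and zone-level statistics
stabilise, small enough that the whole suite runs in well under a minute.
The closed-form check uses 500 single-residue trajectories of 100 waters and
50 frames, where the Bernoulli expectation is exact.

## Known limitations

* Zonation criteria are one consistent realisation (k-means on two z-scored
  features); other feature scalings or algorithms would draw slightly
  different shell/mantle/core boundaries.
* The annealing schedule, contact cutoff and autocorrelation form are
  configurable defaults, not values fitted to any external dataset.
* PDB parsing keeps the highest-occupancy altloc conformer and skips
  nonstandard residues with a warning; no structure repair is attempted.
* The solvent-accessibility flood fill operates at grid resolution: channels
  narrower than the grid pitch may be classified as occluded.
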