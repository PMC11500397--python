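# parchlab

Residue hydropathy is not a fixed property of an amino acid: the same residue
type can be strongly hydrophilic on a protein's surface and completely
hydrophobic when buried in its fold.  `parchlab` implements a context-based
hydropathy pipeline for people studying protein surfaces, binding and design:
it scores every residue of a structure on a 0–10 scale from the dynamics of
its hydration-shell water contacts, classifies residues into shell, mantle
and core zones, and tabulates which residues colocalize with which neighbors
in each zone.

## The score

During a constant-rate temperature ramp, waters progressively evaporate from
a position-restrained protein.  For residue *i* with initial contact set
*S_i(0)* (waters within a cutoff of any heavy atom), the survival
autocorrelation at recorded frame *t_m* is

```
C_i(t_m) = |S_i(0) ∩ S_i(t_m)| / |S_i(0)|
```

and `C̄_i` is its time average over frames 1…M.  The hydropathy score is

```
parch_i = 10 · C̄_i / C̄_Lys ∈ [0, 10]
```

where `C̄_Lys` is the same quantity for an isolated, fully hydrated
zwitterionic lysine run under the identical annealing schedule.  0 is most
hydrophobic; 10 most hydrophilic.  Two identities define the scale: a residue
whose contact dynamics match the lysine reference scores exactly 10, and a
residue that never contacts water (a buried core residue) scores exactly 0.
The ramp is run in triplicate and the final value is the replicate mean.

The package consumes either real multi-frame trajectories of the hydrated
system (multi-model PDB) or synthetic contact trajectories from the packaged
generator, which plants per-residue-type escape kinetics
`h(T) = a·exp(−E/T)` as ground truth so every stage of the pipeline can be
validated against known answers.

## Worked example

```python
from parchlab import (SyntheticSpec, generate_world, ParchModel,
                      ZonationModel, compute_features)

spec = SyntheticSpec(n_residues=150, seed=7)
world = generate_world(spec)                 # pack, solvate, anneal ×3
fit = ParchModel.from_world(world).fit()     # per-residue parch estimates
zones = ZonationModel(
    compute_features(world.system, spec.zone_contact_params,
                     r_nbr=spec.zone_r_nbr)
).fit(seed=7)
print(fit.summary())
print(zones.summary())
```

prints (abridged):

```
Parch hydropathy estimates
============================================================
residues: 150    replicates: 3
reference C_bar (Lys): 0.8678
parch range: [0.00, 10.00]    median: 0.48
zero-parch residues: 73

Shell/mantle/core zonation (k-means, k=3)
============================================================
residues: 150
fractions: shell 46.0%  mantle 22.0%  core 32.0%
centroid[shell]: n_water 29.57, n_neighbors 13.17
```

Half of the residues never touch water and score exactly 0 — they are the
packed interior.  The zone summary
(`fit.zone_summary(zones.assignment)`) shows the expected hydropathy
gradient: mean parch 5.68 in the shell, 2.56 in the mantle, 0.00 in the core.
Because the generator enriches charged residues toward the surface, the shell
is both the wettest and the most hydrophilic zone, exactly as in real
globular proteins.

For real structures, `read_structure` parses a PDB file,
`build_shell`/`neutralize` construct the solvated, charge-neutral system, and
`read_contact_trajectory` ingests multi-model PDB annealing trajectories.
The same steps are exposed on the command line:

```
parchlab composition protein.pdb
parchlab solvate protein.pdb --thickness 6.0 --seed 1 -o system.pdb
parchlab parch --traj r1.pdb --traj r2.pdb --traj r3.pdb --reference-cbar 0.87
parchlab zones system.pdb --r-nbr 5.0
parchlab neighbors protein.pdb --order 3
parchlab run --n 200 --seed 0 -o report/   # synthetic end-to-end bundle
```

## Neighborhood statistics

`nearest_neighbors` ranks every residue's neighbors by minimum heavy-atom
distance; `polyad_table` counts each residue's dyad/triad/…/hexad motif,
stratified by zone, and `heatmap_matrix` renders a triad table as the
standard symmetric 20×20 neighbor-pair matrix.  `classify_k_triad` assigns
lysine triads to the K±±, K±0 and K00 charge classes (charged = D, E, K, R).

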