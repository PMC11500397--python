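"""Ground-truth planting and recovery in the synthetic generator."""

import numpy as np
import pytest
from scipy.stats import binomtest, wilcoxon

from parchlab import (
    AnnealingSchedule,
    ParchModel,
    SyntheticSpec,
    build_shell,
    c_bar,
    cluster_zones,
    compute_features,
    generate_structure,
    generate_trajectory,
    generate_world,
    parch_value,
    reference_c_bar,
    survival_series,
)
from parchlab.errors import DensityError
from parchlab.synthetic import (
    constant_escape_trajectory,
    hydropathy_recovery,
    planted_zone_agreement,
    reference_trajectory,
)


class TestGenerateStructure:
    def test_single_residue_at_origin(self):
        s, truth = generate_structure(SyntheticSpec(n_residues=1, seed=0))
        np.testing.assert_allclose(s.residues[0].atoms[0].coords, [0, 0, 0])
        assert truth.planted_zone == ("core",)

    def test_same_seed_is_identical(self):
        spec = SyntheticSpec(n_residues=60, seed=4)
        s1, t1 = generate_structure(spec)
        s2, t2 = generate_structure(spec)
        assert s1.sequence == s2.sequence
        c1 = np.array([r.atoms[0].coords for r in s1.residues])
        c2 = np.array([r.atoms[0].coords for r in s2.residues])
        np.testing.assert_array_equal(c1, c2)
        assert t1 == t2

    def test_minimum_separation_respected(self):
        spec = SyntheticSpec(n_residues=200, seed=6)
        s, _ = generate_structure(spec)
        pts = np.array([r.atoms[0].coords for r in s.residues])
        from scipy.spatial.distance import pdist

        assert pdist(pts).min() >= spec.packing_radius - 1e-9

    def test_overpacked_sphere_raises(self):
        with pytest.raises(DensityError):
            generate_structure(SyntheticSpec(n_residues=200, seed=0,
                                             packing_fraction=0.9))

    def test_surface_charge_enrichment_sign_test(self):
        # planted effect: charged fraction higher in the outer radial tercile
        wins = 0
        n_seeds = 40
        for seed in range(n_seeds):
            spec = SyntheticSpec(n_residues=300, seed=seed)
            _, truth = generate_structure(spec)
            charged = np.array([aa in "KRDE" for aa in truth.aa_types])
            u = np.array(truth.radial_fraction)
            outer = u >= np.quantile(u, 2 / 3)
            inner = u <= np.quantile(u, 1 / 3)
            wins += charged[outer].mean() > charged[inner].mean()
        assert binomtest(wins, n_seeds, 0.5, alternative="greater").pvalue < 0.01

    def test_expected_frequencies_are_a_distribution(self):
        spec = SyntheticSpec(n_residues=10, seed=0)
        freqs = spec.expected_frequencies()
        assert len(freqs) == 20
        assert sum(freqs.values()) == pytest.approx(1.0)
        p_charged = sum(freqs[aa] for aa in "KRDE")
        assert spec.p_charged_core < p_charged < spec.p_charged_surface


class TestGenerateTrajectory:
    def build_system(self, n=40, seed=0):
        spec = SyntheticSpec(n_residues=n, seed=seed)
        s, _ = generate_structure(spec)
        return spec, build_shell(s, spec.solvation, seed=seed)

    def test_infinite_activation_freezes_contacts(self):
        spec, system = self.build_system()
        frozen = dict.fromkeys(spec.hazard_model, (1.0, 1e12))
        spec_frozen = SyntheticSpec(n_residues=40, seed=0, hazard_model=frozen)
        traj = generate_trajectory(system, spec_frozen, replicate_seed=1)
        for i in traj.residue_indices:
            if traj.frames[0][i]:
                assert survival_series(traj, i) == [1.0] * (len(traj.frames) - 1)

    def test_contact_sets_shrink_monotonically(self):
        spec, system = self.build_system(seed=3)
        traj = generate_trajectory(system, spec, replicate_seed=3)
        assert traj.is_monotone()

    def test_same_seed_bit_identical(self):
        spec, system = self.build_system(seed=5)
        t1 = generate_trajectory(system, spec, replicate_seed=9)
        t2 = generate_trajectory(system, spec, replicate_seed=9)
        assert t1.frames == t2.frames

    def test_constant_escape_probability_binomial(self):
        # with q = 0.5 the first-frame survival is Binomial(1000, 0.5)/1000
        traj = constant_escape_trajectory(n_waters=1000, q=0.5, n_recorded=3, seed=2)
        c1 = survival_series(traj, 0)[0]
        se = np.sqrt(0.25 / 1000)
        assert abs(c1 - 0.5) <= 3 * se

    def test_hazard_ordering_drives_parch_ordering(self):
        # paired single-residue runs: the lower-hazard type must keep water
        # longer (Wilcoxon over 200 replicates)
        schedule = AnnealingSchedule(T0=300, rate=2, n_frames=60)
        diffs = []
        from parchlab.synthetic import _simulate_decay

        initial = {0: frozenset(range(40))}
        for seed in range(200):
            high_E = _simulate_decay(initial, {0: (1.0, 1800.0)}, schedule, seed)
            low_E = _simulate_decay(initial, {0: (1.0, 900.0)}, schedule, seed + 10_000)
            cb_hi = c_bar([len(f[0]) / 40 for f in high_E[1:]])
            cb_lo = c_bar([len(f[0]) / 40 for f in low_E[1:]])
            diffs.append(cb_hi - cb_lo)
        assert wilcoxon(diffs, alternative="greater").pvalue < 0.01


class TestReference:
    def test_reference_parch_of_itself_is_ten(self):
        spec = SyntheticSpec(n_residues=5, seed=0)
        ref = reference_trajectory(spec, replicate_seed=1)
        cb = reference_c_bar(ref, spec.schedule)
        assert parch_value(cb, cb) == pytest.approx(10.0)

    def test_reference_beats_higher_hazard_residue_under_crn(self):
        # common random numbers: with every other type's E below lysine's,
        # survival can only be shorter, so C̄_Lys dominates pairwise
        from parchlab.synthetic import _simulate_decay

        spec = SyntheticSpec(n_residues=5, seed=0)
        initial = {0: frozenset(range(30))}
        for seed in range(100):
            cb = {}
            for aa in ("K", "L"):
                frames = _simulate_decay(initial, {0: spec.hazard_model[aa]},
                                         spec.schedule, seed)
                cb[aa] = c_bar([len(f[0]) / 30 for f in frames[1:]])
            assert cb["K"] >= cb["L"]

    def test_cbar_monotone_in_annealing_rate(self):
        # faster heating strips water sooner; same seed across the sweep
        spec0 = SyntheticSpec(n_residues=5, seed=0)
        rates = np.linspace(0.5, 10.0, 20)
        values = []
        for rate in rates:
            schedule = AnnealingSchedule(T0=300.0, rate=float(rate), n_frames=100)
            spec = SyntheticSpec(n_residues=5, seed=0, schedule=schedule)
            values.append(reference_c_bar(reference_trajectory(spec, 3), schedule))
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert values[0] > values[-1]


class TestGroundTruthRecovery:
    def test_hydropathy_ranking_recovered(self):
        import warnings

        world = generate_world(SyntheticSpec(n_residues=500, seed=21))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # occasional C̄ clamping
            fit = ParchModel.from_world(world).fit()
        assert hydropathy_recovery(world, fit.results) >= 0.95

    def test_planted_zone_terciles_recovered(self):
        agreements = []
        for seed in range(6):
            spec = SyntheticSpec(n_residues=300, seed=seed)
            s, truth = generate_structure(spec)
            system = build_shell(s, spec.solvation, seed=seed)
            feats = compute_features(system, spec.zone_contact_params,
                                     r_nbr=spec.zone_r_nbr)
            za = cluster_zones(feats, seed=0)
            from parchlab.synthetic import SyntheticWorld

            world = SyntheticWorld(spec, s, truth, system, (), 0.0)
            agreements.append(planted_zone_agreement(world, za))
        assert np.mean(agreements) >= 0.85
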