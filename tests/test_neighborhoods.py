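"""Nearest-neighbor rankings, polyad tables, charge classes and heatmaps."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from parchlab import (
    Atom,
    Polyad,
    ProteinStructure,
    ResidueRecord,
    ZoneAssignment,
    classify_k_triad,
    classify_triad,
    heatmap_matrix,
    nearest_neighbors,
    polyad_table,
    zone_composition,
)
from parchlab.constants import AA_ORDER

from conftest import make_point_structure


def random_multiatom_structure(rng, n_res=30, atoms_per_res=3):
    residues = []
    for i in range(n_res):
        center = rng.uniform(-15, 15, 3)
        atoms = [Atom(name=f"C{k}", element="C",
                      coords=center + rng.uniform(-1.5, 1.5, 3))
                 for k in range(atoms_per_res)]
        residues.append(ResidueRecord(chain_id="A", seq_index=i + 1,
                                      aa_type=rng.choice(list(AA_ORDER)),
                                      atoms=atoms))
    return ProteinStructure(id="rand", residues=residues)


def brute_force_ranking(structure, k):
    n = len(structure.residues)
    coords = [np.array([a.coords for a in r.atoms if a.is_heavy])
              for r in structure.residues]
    out = {}
    for i in range(n):
        dists = []
        for j in range(n):
            if j == i:
                continue
            dists.append((float(cdist(coords[i], coords[j]).min()), j))
        dists.sort(key=lambda t: (t[0], t[1]))
        out[i] = [(j, d) for d, j in dists[:k]]
    return out


class TestNearestNeighbors:
    def test_hand_distances_on_a_line(self, point_structure):
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0)), ("L", (9, 0, 0))])
        nbrs = nearest_neighbors(s, k=2)
        assert [j for j, _ in nbrs[1]] == [0, 2]
        assert nbrs[1][0][1] == pytest.approx(4.0)
        assert nbrs[1][1][1] == pytest.approx(5.0)

    def test_two_residues_are_mutual_neighbors(self, point_structure):
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0))])
        nbrs = nearest_neighbors(s, k=1)
        assert nbrs[0][0][0] == 1 and nbrs[1][0][0] == 0

    def test_k_bounds(self, point_structure):
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0))])
        with pytest.raises(ValueError):
            nearest_neighbors(s, k=2)

    def test_matches_bruteforce_on_random_structures(self):
        rng = np.random.default_rng(7)
        for _ in range(3):
            s = random_multiatom_structure(rng)
            fast = nearest_neighbors(s, k=4)
            brute = brute_force_ranking(s, k=4)
            for i in fast:
                assert [j for j, _ in fast[i]] == [j for j, _ in brute[i]]
                np.testing.assert_allclose(
                    [d for _, d in fast[i]], [d for _, d in brute[i]], atol=1e-9
                )

    def test_distance_tie_broken_by_sequence_index(self, point_structure):
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0)), ("L", (-4, 0, 0))])
        nbrs = nearest_neighbors(s, k=2)
        assert [j for j, _ in nbrs[0]] == [1, 2]  # both at 4.0; lower index first


class TestPolyads:
    def test_canonicalization_of_neighbor_order(self):
        assert Polyad("K", ("E", "L")) == Polyad("K", ("L", "E"))
        assert Polyad("K", ("E", "L")).neighbors == ("E", "L")

    def test_dyad_table_hand_enumeration(self, point_structure):
        # square: A(0,0) G(4,0) L(0,4) K(4,4); each residue's nearest is at 4.0,
        # tie-broken toward the lower index
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0)),
                             ("L", (0, 4, 0)), ("K", (4, 4, 0))])
        nbrs = nearest_neighbors(s, k=1)
        table = polyad_table(s, nbrs, None, n=2)
        assert table.count("A", ("G",)) == 1  # A -> G (index 1 beats index 2)
        assert table.count("G", ("A",)) == 1
        assert table.count("L", ("A",)) == 1
        assert table.count("K", ("G",)) == 1
        assert sum(table.counts.values()) == 4

    def test_insufficient_depth_raises(self, point_structure):
        s = point_structure([("A", (0, 0, 0)), ("G", (4, 0, 0)), ("L", (8, 0, 0))])
        nbrs = nearest_neighbors(s, k=1)
        with pytest.raises(ValueError):
            polyad_table(s, nbrs, None, n=3)

    def test_per_zone_conservation(self, small_world):
        from parchlab import cluster_zones, compute_features

        world = small_world
        feats = compute_features(world.system, world.spec.zone_contact_params,
                                 r_nbr=world.spec.zone_r_nbr)
        za = cluster_zones(feats, seed=0)
        nbrs = nearest_neighbors(world.structure, k=2)
        table = polyad_table(world.structure, nbrs, za, n=3)
        for zone in ("shell", "mantle", "core"):
            total = sum(c for (f, ns, z), c in table.counts.items() if z == zone)
            assert total == len(za.residues_in(zone))


class TestChargeClasses:
    @pytest.mark.parametrize("neighbors,label", [
        (("E", "D"), "±±"),
        (("E", "L"), "±0"),
        (("L", "A"), "00"),
        (("K", "R"), "±±"),
        (("G", "E"), "±0"),
    ])
    def test_k_triad_classes(self, neighbors, label):
        assert classify_k_triad(Polyad("K", neighbors)) == label

    def test_non_k_focal_rejected(self):
        with pytest.raises(ValueError):
            classify_k_triad(Polyad("E", ("K", "L")))
        assert classify_triad(Polyad("E", ("K", "L"))) == "±0"

    def test_histidine_counts_as_uncharged(self):
        assert classify_k_triad(Polyad("K", ("H", "H"))) == "00"


class TestHeatmap:
    def test_single_homotypic_entry(self):
        from parchlab import PolyadTable

        table = PolyadTable(order=3)
        table.counts[("K", ("E", "E"), "all")] = 5
        M = heatmap_matrix(table, "K")
        assert M.loc["E", "E"] == 5
        assert M.values.sum() == 5

    def test_symmetry_and_mass(self, small_world):
        nbrs = nearest_neighbors(small_world.structure, k=2)
        table = polyad_table(small_world.structure, nbrs, None, n=3)
        M = heatmap_matrix(table, "K")
        assert (M.values == M.values.T).all()
        total_k = sum(c for (f, _, _), c in table.counts.items() if f == "K")
        upper = np.triu(M.values, k=1).sum() + np.diag(M.values).sum()
        assert upper == total_k


class TestZoneComposition:
    def test_all_leucine_core(self, point_structure):
        s = point_structure([("L", (0, 0, 0)), ("L", (4, 0, 0)), ("K", (20, 0, 0))])
        za = ZoneAssignment(zones={0: "core", 1: "core", 2: "shell"}, centroids={},
                            fractions={"shell": 33.3, "mantle": 33.3, "core": 33.4})
        tables = zone_composition(s, za)
        assert tables["core"].fractions["L"] == pytest.approx(100.0)
        assert "mantle" not in tables
        for t in tables.values():
            assert sum(t.fractions.values()) == pytest.approx(100.0)

    def test_planted_surface_charge_enrichment(self, small_world):
        from parchlab import cluster_zones, compute_features

        world = small_world
        feats = compute_features(world.system, world.spec.zone_contact_params,
                                 r_nbr=world.spec.zone_r_nbr)
        za = cluster_zones(feats, seed=0)
        tables = zone_composition(world.structure, za)
        charged = list("KRDE")
        shell_frac = sum(tables["shell"].fractions[aa] for aa in charged)
        core_frac = sum(tables["core"].fractions[aa] for aa in charged)
        assert shell_frac > core_frac
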