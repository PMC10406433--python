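"""Descriptor layer: contacts, valency, clusters, enrichment, Rg, compactness."""

import math

import numpy as np
import pandas as pd
import pytest

from condenscale.descriptors import (
    ContactStats,
    box_concentration,
    chain_contacts,
    cluster_chains,
    compactness,
    contact_enrichment,
    contact_probability,
    enrichment_from_counts,
    entropy_mutation_difference,
    interaction_profiles,
    radius_of_gyration,
    random_coil_rg,
    representative_mode,
    valency_series,
)
from condenscale.ensemble import Chain, ChainEnsemble
from condenscale.fixtures import gen_polymer, gen_scene


def brute_force_adjacency(ensemble, cutoff):
    """O(N^2) all-atom-pairs oracle with explicit minimum-image arithmetic."""
    L = ensemble.box if ensemble.periodic else None
    C = ensemble.n_chains
    adj = np.zeros((ensemble.n_frames, C, C), dtype=bool)
    for f, frame in enumerate(ensemble.frames):
        for i in range(C):
            for j in range(i + 1, C):
                delta = frame[i][:, None, :] - frame[j][None, :, :]
                if L is not None:
                    delta -= L * np.round(delta / L)
                dmin = np.sqrt((delta**2).sum(axis=-1)).min()
                adj[f, i, j] = adj[f, j, i] = dmin <= cutoff
    return adj


def stats_from_adjacency(adj):
    """Minimal ContactStats carrying only a synthetic adjacency stack."""
    adj = np.asarray(adj, dtype=bool)
    F, C, _ = adj.shape
    return ContactStats(
        adjacency=adj,
        min_dist=np.where(adj, 0.1, 10.0),
        inter_counts=np.zeros((F, 1, 1)),
        intra_counts=np.zeros((F, 1, 1)),
        inter_profiles=np.zeros((F, C, 1)),
        intra_profiles=np.zeros((F, C, 1)),
        types=["G"],
        composition=pd.Series({"G": 1.0}),
        sequences=["G"] * C,
        times=np.arange(F, dtype=float),
        cutoff=0.35,
    )


class TestChainContacts:
    def test_touching_and_separated_pairs(self):
        chain = Chain(elements=np.array(["C"], dtype=object),
                      residue_index=np.array([0]), sequence="G")
        near = ChainEnsemble(
            chains=[chain, chain],
            frames=[[np.array([[1.0, 1.0, 1.0]]), np.array([[1.2, 1.0, 1.0]])]],
            box=10.0, periodic=True)
        far = ChainEnsemble(
            chains=[chain, chain],
            frames=[[np.array([[1.0, 1.0, 1.0]]), np.array([[3.0, 1.0, 1.0]])]],
            box=10.0, periodic=True)
        assert chain_contacts(near).adjacency[0, 0, 1]
        assert not chain_contacts(far).adjacency[0].any()

    def test_minimum_image_wraps_across_box(self):
        chain = Chain(elements=np.array(["C"], dtype=object),
                      residue_index=np.array([0]), sequence="G")
        ens = ChainEnsemble(
            chains=[chain, chain],
            frames=[[np.array([[0.1, 5.0, 5.0]]), np.array([[9.9, 5.0, 5.0]])]],
            box=10.0, periodic=True)
        assert chain_contacts(ens).adjacency[0, 0, 1]  # 0.2 nm across the seam

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        ens, _ = gen_scene(5, 6.0, None, seed=seed, atoms_per_chain=40)
        stats = chain_contacts(ens)
        oracle = brute_force_adjacency(ens, 0.35)
        np.testing.assert_array_equal(stats.adjacency, oracle)


class TestValency:
    def test_planted_ring(self):
        ring = np.zeros((1, 6, 6), dtype=bool)
        for k in range(6):
            ring[0, k, (k + 1) % 6] = ring[0, (k + 1) % 6, k] = True
        val = valency_series(stats_from_adjacency(ring))
        assert np.all(val.degrees == 2)
        assert val.window_mean == pytest.approx(2.0)

    def test_planted_star(self):
        star = np.zeros((1, 5, 5), dtype=bool)
        star[0, 0, 1:] = star[0, 1:, 0] = True
        val = valency_series(stats_from_adjacency(star))
        assert val.degrees[0, 0] == 4
        assert np.all(val.degrees[0, 1:] == 1)
        assert val.mean_per_frame[0] == pytest.approx(1.6)

    def test_degrees_equal_graph_oracle(self):
        rng = np.random.default_rng(3)
        adj = np.zeros((2, 8, 8), dtype=bool)
        for f in range(2):
            upper = rng.random((8, 8)) < 0.3
            a = np.triu(upper, 1)
            adj[f] = a | a.T
        val = valency_series(stats_from_adjacency(adj))
        np.testing.assert_array_equal(val.degrees, adj.sum(axis=2))


class TestContactProbability:
    def test_complete_empty_and_mean(self):
        full = ~np.eye(24, dtype=bool)[None, :, :]
        assert contact_probability(stats_from_adjacency(full))[0] == pytest.approx(1.0)
        empty = np.zeros((1, 5, 5), dtype=bool)
        assert contact_probability(stats_from_adjacency(empty))[0] == 0.0
        star = np.zeros((1, 24, 24), dtype=bool)
        # mean valency 4 on 24 chains -> p = 4/23
        for k in range(24):
            for d in range(1, 3):
                star[0, k, (k + d) % 24] = star[0, (k + d) % 24, k] = True
        p = contact_probability(stats_from_adjacency(star))[0]
        assert p == pytest.approx(4 / 23)


class TestClusterChains:
    def test_pair_plus_singleton(self):
        adj = np.zeros((1, 3, 3), dtype=bool)
        adj[0, 0, 1] = adj[0, 1, 0] = True
        part = cluster_chains(stats_from_adjacency(adj))
        assert part.partitions[0] == [[0, 1], [2]]
        assert part.largest_size[0] == 2

    def test_chain_of_24_is_single_percolating_cluster(self):
        adj = np.zeros((1, 24, 24), dtype=bool)
        for k in range(23):
            adj[0, k, k + 1] = adj[0, k + 1, k] = True
        part = cluster_chains(stats_from_adjacency(adj))
        assert part.largest_size[0] == 24

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        a = np.triu(rng.random((n, n)) < 0.15, 1)
        adj = (a | a.T)[None, :, :]
        part = cluster_chains(stats_from_adjacency(adj))

        parent = list(range(n))

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                if adj[0, i, j]:
                    parent[find(i)] = find(j)
        oracle = {}
        for k in range(n):
            oracle.setdefault(find(k), []).append(k)
        expected = sorted([sorted(b) for b in oracle.values()],
                          key=lambda b: (-len(b), b))
        got = sorted([sorted(b) for b in part.partitions[0]],
                     key=lambda b: (-len(b), b))
        assert got == expected


class TestEnrichment:
    def test_uniform_null_converges_to_one(self):
        rng = np.random.default_rng(0)
        types = list("GYRS")
        counts = np.zeros((4, 4))
        draws = rng.integers(0, 4, size=(100_000, 2))
        for a, b in draws:
            i, j = sorted((a, b))
            counts[i, j] += 1
        comp = pd.Series(0.25, index=types)
        table = enrichment_from_counts(counts, types, comp)
        assert np.all(np.abs(table.enrichment.to_numpy() - 1.0) < 0.05)

    def test_tables_sum_to_one_over_unordered_pairs(self):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 50, size=(4, 4)).astype(float)
        comp = pd.Series([0.4, 0.3, 0.2, 0.1], index=list("GYRS"))
        table = enrichment_from_counts(counts, list("GYRS"), comp)
        assert np.triu(table.observed.to_numpy()).sum() == pytest.approx(1.0, abs=1e-9)
        assert np.triu(table.expected.to_numpy()).sum() == pytest.approx(1.0, abs=1e-9)

    def test_homotypic_only_contacts_hand_value(self):
        # sequence YRYR...: f_Y = f_R = 1/2; only Y-Y observed
        counts = np.zeros((2, 2))
        counts[1, 1] = 17.0  # index 1 = Y
        comp = pd.Series({"R": 0.5, "Y": 0.5})
        table = enrichment_from_counts(counts, ["R", "Y"], comp)
        assert table.enrichment.loc["Y", "Y"] == pytest.approx(1 / 0.5**2)
        assert table.enrichment.loc["R", "R"] == 0.0
        assert table.enrichment.loc["R", "Y"] == 0.0

    def test_geometry_pipeline_enrichment(self):
        ens, _ = gen_scene(6, 10.0, [(0, 1), (2, 3), (4, 5)], seed=2)
        tables = contact_enrichment(chain_contacts(ens), window=1.0)
        assert "inter" in tables
        enr = tables["inter"].enrichment
        assert (enr.fillna(0) >= 0).all().all()


class TestInteractionProfiles:
    @staticmethod
    def _two_chain_ensemble(contact_positions, n_res=10):
        """Chain 1 approaches chain 0 only at the given residue positions."""
        spacing = 1.0
        c0 = np.column_stack([np.arange(n_res) * spacing,
                              np.zeros(n_res), np.zeros(n_res)])
        c1 = c0 + np.array([0.0, 5.0, 0.0])
        for k in contact_positions:
            c1[k, 1] = 0.3  # within cutoff of chain 0 position k
        chain = Chain(elements=np.array(["C"] * n_res, dtype=object),
                      residue_index=np.arange(n_res), sequence="G" * n_res)
        return ChainEnsemble(chains=[chain, chain], frames=[[c0, c1]],
                             box=40.0, periodic=True)

    def test_delta_profile(self):
        stats = chain_contacts(self._two_chain_ensemble([4]))
        prof = interaction_profiles(stats, "inter", window=1.0)
        assert prof[0].argmax() == 4
        assert prof[0][4] > 0
        assert np.delete(prof[0], 4).sum() == 0

    def test_two_hotspot_recovery(self):
        stats = chain_contacts(self._two_chain_ensemble([3, 7]))
        prof = interaction_profiles(stats, "inter", window=1.0)
        planted = np.zeros(10)
        planted[[3, 7]] = 1.0
        r = np.corrcoef(prof[0], planted)[0, 1]
        assert r > 0.99

    def test_invalid_scope(self):
        stats = chain_contacts(self._two_chain_ensemble([1]))
        with pytest.raises(ValueError):
            interaction_profiles(stats, "both")


class TestRepresentativeMode:
    def test_identical_profiles(self):
        profiles = np.tile(np.array([0.1, 0.5, 0.2, 0.9]), (6, 1))
        mode = representative_mode(profiles, np.full(6, 4.0))
        np.testing.assert_allclose(mode.profile, profiles[0])
        assert mode.qc_pearson == pytest.approx(1.0)
        assert mode.passed

    def test_selects_coherent_subset_over_outliers(self):
        rng = np.random.default_rng(5)
        base = np.sin(np.linspace(0, 3, 20)) + 1.5
        profiles = np.vstack([np.tile(base, (4, 1)),
                              rng.random((3, 20))])
        mode = representative_mode(profiles, np.full(7, 4.0))
        assert set(mode.members) == {0, 1, 2, 3}

    def test_matches_exhaustive_oracle_on_eight_profiles(self):
        import itertools
        rng = np.random.default_rng(7)
        profiles = rng.random((8, 15))
        valencies = np.full(8, 3.0)
        mode = representative_mode(profiles, valencies)

        def corr(a, b):
            return np.corrcoef(profiles[a], profiles[b])[0, 1]

        best = max(itertools.combinations(range(8), 4),
                   key=lambda c: sum(corr(a, b)
                                     for a, b in itertools.combinations(c, 2)))
        assert set(mode.members) == set(best)

    def test_too_few_eligible_chains(self):
        profiles = np.random.default_rng(0).random((6, 10))
        valencies = np.array([4.0, 4.0, 4.0, 1.0, 1.0, 1.0])
        with pytest.raises(ValueError, match="fall back"):
            representative_mode(profiles, valencies)


class TestRadiusOfGyration:
    def test_single_atom(self):
        assert radius_of_gyration(np.zeros((1, 3))) == 0.0

    def test_two_unit_masses_two_nm_apart(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_random_cloud_matches_direct_formula(self):
        rng = np.random.default_rng(11)
        coords = rng.normal(size=(100, 3))
        masses = rng.uniform(1, 16, size=100)
        com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
        direct = math.sqrt(
            sum(m * ((c - com) ** 2).sum() for m, c in zip(masses, coords))
            / masses.sum())
        assert radius_of_gyration(coords, masses) == pytest.approx(direct, abs=1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.zeros((2, 3)), np.zeros(2))


class TestRandomCoilRg:
    @pytest.mark.parametrize("n, expected", [(80, 2.50), (1, 0.25), (238, 4.42)])
    def test_idp_scaling_law(self, n, expected):
        assert round(random_coil_rg(n), 2) == expected


class TestCompactness:
    def test_single_atom_sphere(self):
        res = compactness(np.zeros((1, 3)), np.array(["C"]), grid_spacing=0.01)
        sphere = 4 / 3 * math.pi * 0.17**3
        assert res.V_vdw == pytest.approx(sphere, rel=0.02)
        assert res.phi == pytest.approx(1.0, rel=0.02)

    def test_disjoint_spheres_volume(self):
        coords = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        res = compactness(coords, np.array(["C", "C"]), grid_spacing=0.01,
                          radii_override={"C": 0.2}, rh_override=1.0)
        assert res.V_vdw == pytest.approx(2 * 4 / 3 * math.pi * 0.2**3, rel=0.01)

    def test_overlapping_spheres_analytic_union(self):
        # two r = 0.2 spheres at distance 0.2: union = 2V - lens overlap
        d, r = 0.2, 0.2
        coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
        res = compactness(coords, np.array(["C", "C"]), grid_spacing=0.008,
                          radii_override={"C": r}, rh_override=1.0)
        lens = math.pi * (2 * r - d) ** 2 * (d**2 + 4 * d * r) / (12 * d)
        expected = 2 * 4 / 3 * math.pi * r**3 - lens
        assert res.V_vdw == pytest.approx(expected, rel=0.01)

    def test_compact_more_packed_than_extended(self):
        chain_c, xyz_c = gen_polymer(60, "compact", seed=4)
        chain_e, xyz_e = gen_polymer(60, "extended", seed=4)
        phi_c = compactness(xyz_c, chain_c.elements, grid_spacing=0.08).phi
        phi_e = compactness(xyz_e, chain_e.elements, grid_spacing=0.08).phi
        assert phi_c > phi_e

    def test_rigid_motion_invariance(self):
        from scipy.spatial.transform import Rotation
        chain, xyz = gen_polymer(40, "compact", seed=9)
        ref = compactness(xyz, chain.elements, grid_spacing=0.05)
        moved = Rotation.from_euler("zyx", [0.7, -0.3, 1.9]).apply(xyz) + 5.0
        rot = compactness(moved, chain.elements, grid_spacing=0.05)
        assert rot.phi == pytest.approx(ref.phi, rel=0.01)

    def test_unknown_element_rejected(self):
        with pytest.raises(ValueError, match="element"):
            compactness(np.zeros((1, 3)), np.array(["Xx"]))


class TestBoxConcentration:
    @pytest.mark.parametrize("n, L, expected", [
        (1, 9.0, 2.3),
        (24, 19.0, 5.8),
    ])
    def test_simulation_box_rows(self, n, L, expected):
        assert round(box_concentration(n, L), 1) == expected

    def test_crowded_box(self):
        # 24 chains in an 18 nm box: ~6.8-6.9 mM depending on the exact
        # (NPT-average vs nominal) box volume
        assert box_concentration(24, 18.0) == pytest.approx(6.9, abs=0.1)


class TestEntropyNormalisation:
    def test_identical_systems_vanish(self):
        assert entropy_mutation_difference(1.5, 100, 1.5, 100) == 0.0

    def test_equal_sizes_reduce_to_plain_difference(self):
        got = entropy_mutation_difference(2.0, 10, 1.0, 10, T=310.0)
        assert got == pytest.approx((2.0 - 1.0) * 310.0)

    def test_asymmetric_sizes_match_hand_evaluation(self):
        S_mut, N_mut, S_wt, N_wt, T = -3.1, 120, -2.9, 150, 310.0
        dof_mut, dof_wt = 3 * N_mut - 6, 3 * N_wt - 6
        hand = (S_mut / dof_mut - S_wt / dof_wt) * dof_mut * T
        assert entropy_mutation_difference(S_mut, N_mut, S_wt, N_wt, T) == \
            pytest.approx(hand)
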