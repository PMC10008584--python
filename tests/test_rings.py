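"""Composition distributions, necklace classes and independence tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gjctools import (
    MetadataSimConfig,
    adjacency_coupling_stat,
    arrangement_distribution,
    binomial_expectation,
    canonical_necklace,
    composition_distribution,
    estimate_state_fraction,
    group_by_particle,
    independence_test,
    necklace_census,
    simulate_metadata,
)
from gjctools.metadata import ParticleComposition
from gjctools.rings import adjacent_same_state_pairs
from gjctools.simulate import exact_ring_distribution, sample_rings


def comp_with_k(k, pid="p"):
    ring0 = "P" * min(k, 6) + "F" * (6 - min(k, 6))
    k2 = max(0, k - 6)
    ring1 = "P" * k2 + "F" * (6 - k2)
    return ParticleComposition(
        particle_id=pid, n_pln=k, n_fn=12 - k, n_other=0, n_unassigned=0,
        rings=(ring0, ring1),
    )


class TestCompositionDistribution:
    def test_all_full_pln(self):
        dist = composition_distribution([comp_with_k(12, f"p{i}") for i in range(10)])
        assert dist.counts[12] == 10 and dist.counts[:12].sum() == 0

    def test_mixed_ks(self):
        dist = composition_distribution([comp_with_k(k) for k in (0, 6, 6, 12)])
        assert dist.counts[0] == 1 and dist.counts[6] == 2 and dist.counts[12] == 1

    def test_thirteen_bins_and_normalization(self, small_sim):
        table, _ = small_sim
        comps, _ = group_by_particle(table)
        dist = composition_distribution(comps)
        assert len(dist.counts) == 13
        assert dist.counts.sum() == dist.n_particles
        assert abs(dist.fractions.sum() - 1.0) < 1e-12

    def test_matches_binomial_at_scale(self):
        """Independent protomers at p=0.5: histogram fits Binomial(12, 0.5)."""
        table, _ = simulate_metadata(
            MetadataSimConfig(n_particles=50_000, p_pln=0.5, seed=101)
        )
        comps, _ = group_by_particle(table)
        dist = composition_distribution(comps)
        expected = binomial_expectation(0.5, 12, dist.n_particles)
        res = independence_test(dist.counts, expected, p_estimated=False)
        assert res.p_value > 0.01

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            composition_distribution([])


class TestBinomialExpectation:
    def test_central_mass_p_half(self):
        # brute force: 924 of the 4096 equiprobable outcomes have k = 6
        expected = binomial_expectation(0.5, 12, 1)
        assert expected[6] == pytest.approx(924 / 4096, abs=1e-12)

    def test_full_pln_mass_at_study_fraction(self):
        expected = binomial_expectation(0.57, 12, 1)
        assert expected[12] == pytest.approx(0.57**12, rel=1e-12)
        assert expected[12] == pytest.approx(1.18e-3, rel=0.01)

    def test_degenerate_p_zero(self):
        expected = binomial_expectation(0.0, 12, 100)
        assert expected[0] == 100 and expected[1:].sum() == 0

    def test_sums_to_n(self):
        for p in (0.1, 0.57, 0.9):
            assert binomial_expectation(p, 12, 1000).sum() == pytest.approx(1000, abs=1e-6)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            binomial_expectation(1.5, 12, 10)


class TestStateFraction:
    def test_simple_counting(self, default_class_map):
        from gjctools import ParticleTable, assign_states
        import pandas as pd

        df = pd.DataFrame(
            {"particle_id": [f"p{i}" for i in range(100)],
             "class_id": [1] * 57 + [5] * 43}
        )
        est = estimate_state_fraction(assign_states(ParticleTable(df), default_class_map))
        assert est.p_hat == pytest.approx(0.57)
        assert est.ci_low < 0.57 < est.ci_high

    def test_zero_pln_boundary(self, default_class_map):
        from gjctools import ParticleTable, assign_states
        import pandas as pd

        df = pd.DataFrame({"particle_id": [f"p{i}" for i in range(100)],
                           "class_id": [5] * 100})
        est = estimate_state_fraction(assign_states(ParticleTable(df), default_class_map))
        assert est.p_hat == 0.0 and est.ci_low == 0.0

    def test_unclassified_only_rejected(self):
        from gjctools import ParticleTable
        import pandas as pd

        table = ParticleTable(pd.DataFrame({"particle_id": ["a"], "class_id": [1]}))
        with pytest.raises(ValueError):
            estimate_state_fraction(table)


class TestNecklaces:
    def test_alternating_ring(self):
        canon, orbit = canonical_necklace("PFPFPF")
        assert canon == "FPFPFP" and orbit == 2

    def test_uniform_ring(self):
        assert canonical_necklace("PPPPPP") == ("PPPPPP", 1)

    def test_census_matches_brute_force_orbits(self):
        """Orbit partition of all 64 strings: 14 classes, multiplicities
        {1,1,3,4,3,1,1} over k = 0..6 (Burnside: (64+8+8+4)/6 = 14)."""
        orbits = {}
        for bits in range(64):
            s = "".join("P" if bits >> i & 1 else "F" for i in range(6))
            rots = {s[i:] + s[:i] for i in range(6)}
            orbits[min(rots)] = len(rots)
        assert len(orbits) == 14
        census = necklace_census()
        assert {a.canonical: a.orbit_size for a in census} == orbits
        by_k = [sum(1 for a in census if a.k_pln == k) for k in range(7)]
        assert by_k == [1, 1, 3, 4, 3, 1, 1]

    @given(st.text(alphabet="PF", min_size=6, max_size=6),
           st.integers(min_value=0, max_value=5))
    @settings(max_examples=100, deadline=None)
    def test_rotation_invariance(self, s, shift):
        rotated = s[shift:] + s[:shift]
        assert canonical_necklace(rotated)[0] == canonical_necklace(s)[0]

    def test_rejects_bad_input(self):
        with pytest.raises(ValueError):
            canonical_necklace("PFPFP")
        with pytest.raises(ValueError):
            canonical_necklace("PFPFPX")


class TestArrangementDistribution:
    def test_expected_normalizes_for_any_p(self, small_sim):
        table, _ = small_sim
        comps, _ = group_by_particle(table)
        for p in (0.0, 0.25, 0.5, 0.57, 1.0):
            classes, _ = arrangement_distribution(comps, p=p)
            n_rings = sum(a.observed for a in classes)
            assert sum(a.expected for a in classes) == pytest.approx(n_rings, rel=1e-12)

    def test_uniform_rings_single_class(self):
        comps = [comp_with_k(12, f"p{i}") for i in range(5)]
        classes, _ = arrangement_distribution(comps, p=1.0)
        full = next(a for a in classes if a.canonical == "PPPPPP")
        assert full.observed == 10 and full.expected == pytest.approx(10)

    def test_k2_splits_into_three_classes(self):
        k2 = [a.canonical for a in necklace_census() if a.k_pln == 2]
        assert sorted(k2) == ["FFFFPP", "FFFPFP", "FFPFFP"]


class TestIndependenceTest:
    def test_perfect_fit(self):
        obs = np.array([50.0, 30.0, 20.0])
        res = independence_test(obs, obs, p_estimated=False)
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_sparse_bins_are_pooled(self):
        obs = np.array([100.0, 50.0, 3.0, 1.0])
        exp = np.array([100.0, 50.0, 2.0, 2.0])
        res = independence_test(obs, exp, p_estimated=False)
        assert "pooled 2 bins" in res.pooled_bins
        assert res.df == 2  # 3 bins after pooling - 1

    def test_monte_carlo_agrees_with_chi2(self):
        rng = np.random.default_rng(3)
        exp = np.array([400.0, 300.0, 200.0, 100.0])
        obs = rng.multinomial(1000, exp / 1000).astype(float)
        r1 = independence_test(obs, exp, p_estimated=False)
        r2 = independence_test(obs, exp, method="exact_multinomial_mc", seed=4,
                               n_replicates=20_000)
        assert abs(r1.p_value - r2.p_value) < 0.03

    def test_power_against_coupled_rings(self):
        """Strong nearest-neighbour coupling at 10,000 rings is always detected."""
        probs = exact_ring_distribution(0.57, 0.8)
        census = necklace_census()
        class_p = np.zeros(len(census))
        lookup = {a.canonical: i for i, a in enumerate(census)}
        for s, pr in probs.items():
            canon = min(s[i:] + s[:i] for i in range(6))
            class_p[lookup[canon]] += pr
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            obs = rng.multinomial(10_000, class_p).astype(float)
            p_hat = sum(o * a.k_pln for o, a in zip(obs, census)) / (6 * 10_000)
            exp = np.array(
                [10_000 * a.orbit_size * p_hat**a.k_pln * (1 - p_hat) ** (6 - a.k_pln)
                 for a in census]
            )
            res = independence_test(obs, exp, p_estimated=True)
            assert res.p_value < 0.05

    def test_all_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            independence_test([1.0], [0.0])


class TestAdjacencyCoupling:
    def test_alternating_ring_has_no_equal_pairs(self):
        assert adjacent_same_state_pairs("PFPFPF") == 0

    def test_blocked_ring_has_four_pairs(self):
        # cyclic edges of PPPFFF: PP, PP, PF, FF, FF, FP -> 4 equal
        assert adjacent_same_state_pairs("PPPFFF") == 4

    def test_coupled_rings_detected(self):
        table, _ = simulate_metadata(
            MetadataSimConfig(n_particles=500, p_pln=0.57, coupling_J=1.0, seed=7)
        )
        comps, _ = group_by_particle(table)
        stat, p = adjacency_coupling_stat(comps, n_perm=2000, seed=1)
        assert p < 0.01

    def test_independent_rings_not_flagged(self):
        table, _ = simulate_metadata(
            MetadataSimConfig(n_particles=500, p_pln=0.57, coupling_J=0.0, seed=8)
        )
        comps, _ = group_by_particle(table)
        _, p = adjacency_coupling_stat(comps, n_perm=2000, seed=1)
        assert p > 0.05

    def test_small_n_perm_warns(self):
        comps = [comp_with_k(6)]
        with pytest.warns(UserWarning):
            adjacency_coupling_stat(comps, n_perm=50, seed=0)


class TestRingSamplerAgainstExactDistribution:
    @pytest.mark.parametrize("p,J", [(0.57, 0.8), (0.3, -0.5), (0.5, 1.5)])
    def test_gibbs_total_variation(self, p, J):
        """Gibbs samples on the 6-ring Ising model match exact enumeration."""
        rng = np.random.default_rng(42)
        n = 1_000_000
        rings = sample_rings(n, p, J, rng)
        idx = rings @ (2 ** np.arange(6))
        freq = np.bincount(idx, minlength=64) / n
        probs = np.zeros(64)
        for s, pr in exact_ring_distribution(p, J).items():
            i = sum((c == "P") << k for k, c in enumerate(s))
            probs[i] = pr
        tv = 0.5 * np.abs(freq - probs).sum()
        assert tv < 0.01

    def test_exact_distribution_normalizes(self):
        assert sum(exact_ring_distribution(0.57, 0.8).values()) == pytest.approx(1.0)

    def test_j_zero_is_product_bernoulli(self):
        probs = exact_ring_distribution(0.3, 0.0)
        assert probs["PPPPPP"] == pytest.approx(0.3**6, rel=1e-9)
        assert probs["PFFFFF"] == pytest.approx(0.3 * 0.7**5, rel=1e-9)
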