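import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gdrep.diversity import (
    AbundanceVector,
    RarefactionSpec,
    asymptotic_entropy,
    bootstrap_diversity,
    build_bootstrap_assemblage,
    compare_diversity_at_point,
    d50,
    diversity_curve,
    extrapolate_richness,
    frequency_counts,
    hill_number,
    rarefied_richness,
    rarefied_shannon,
    rarefied_shannon_hill,
    shannon_entropy,
)
from oracles import enumerate_subsample_stats

abundance_vectors = st.lists(st.integers(1, 8), min_size=1, max_size=8).map(AbundanceVector)
# small enough that exhaustive subsample enumeration (C(n, m) subsets) is cheap
oracle_vectors = (
    st.lists(st.integers(1, 5), min_size=1, max_size=5)
    .filter(lambda c: sum(c) <= 12)
    .map(AbundanceVector)
)


class TestAbundanceVector:
    def test_totals(self):
        x = AbundanceVector([3, 2, 1])
        assert x.n == 6 and x.s_obs == 3

    def test_empty_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            AbundanceVector([])

    def test_zero_count_is_error(self):
        with pytest.raises(ValueError, match=">= 1"):
            AbundanceVector([2, 0])

    def test_from_sizes_drops_zeros(self):
        assert AbundanceVector.from_sizes([2, 0, 1]).s_obs == 2


class TestHillNumber:
    def test_uniform_q1(self):
        assert hill_number(AbundanceVector([1, 1, 1, 1]), 1) == pytest.approx(4.0)

    def test_richness(self):
        assert hill_number(AbundanceVector([1, 1, 1, 1, 1]), 0) == 5

    def test_plugin_entropy_2_1_1(self):
        # H = -(1/2 ln 1/2 + 2 * 1/4 ln 1/4) = 1.03972...
        x = AbundanceVector([2, 1, 1])
        assert hill_number(x, 1) == pytest.approx(math.exp(1.0397207708399179), rel=1e-9)
        assert hill_number(x, 1) == pytest.approx(2.8284271247, rel=1e-6)

    def test_bad_q(self):
        with pytest.raises(ValueError):
            hill_number(AbundanceVector([1]), 2)


class TestRarefiedRichness:
    def test_one_draw_sees_one_clone(self):
        assert rarefied_richness(AbundanceVector([1, 1, 1]), 1) == pytest.approx(1.0)

    def test_m_equals_n_returns_s_obs(self):
        assert rarefied_richness(AbundanceVector([3, 2]), 5) == pytest.approx(2.0)

    def test_enumeration_2_2_at_2(self):
        # all C(4,2)=6 subsamples: 4 mixed see 2 clones, 2 pure see 1 -> 10/6
        assert rarefied_richness(AbundanceVector([2, 2]), 2) == pytest.approx(5 / 3)

    def test_m_above_n_is_error(self):
        with pytest.raises(ValueError, match="extrapolate"):
            rarefied_richness(AbundanceVector([2, 2]), 5)

    @settings(max_examples=25, deadline=None)
    @given(x=oracle_vectors, data=st.data())
    def test_matches_enumeration_oracle(self, x, data):
        m = data.draw(st.integers(1, x.n))
        expected, _ = enumerate_subsample_stats(x.counts.tolist(), m)
        assert rarefied_richness(x, m) == pytest.approx(expected, abs=1e-9)


class TestRarefiedShannon:
    def test_census_of_two_singletons(self):
        x = AbundanceVector([1, 1])
        assert rarefied_shannon(x, 2) == pytest.approx(math.log(2))
        est = rarefied_shannon_hill(x, 2)
        assert est.estimate == pytest.approx(2.0)

    def test_enumeration_2_2_at_2(self):
        # 6 subsamples: 4 mixed (H=ln2), 2 pure (H=0) -> (4/6) ln2
        assert rarefied_shannon(AbundanceVector([2, 2]), 2) == pytest.approx((4 / 6) * math.log(2))

    def test_m_equals_n_is_plugin(self):
        x = AbundanceVector([5, 5])
        est = rarefied_shannon_hill(x, 10)
        assert est.estimate == pytest.approx(2.0)
        assert est.entropy == pytest.approx(shannon_entropy(x))

    @settings(max_examples=25, deadline=None)
    @given(x=oracle_vectors, data=st.data())
    def test_matches_enumeration_oracle(self, x, data):
        m = data.draw(st.integers(1, x.n))
        _, expected = enumerate_subsample_stats(x.counts.tolist(), m)
        assert rarefied_shannon(x, m, mode="exact") == pytest.approx(expected, abs=1e-9)

    def test_monte_carlo_agrees_with_exact(self):
        x = AbundanceVector([8, 5, 3, 2, 1, 1])
        exact = rarefied_shannon(x, 10, mode="exact")
        mc = rarefied_shannon(x, 10, mode="monte_carlo", seed=0, n_draws=20000)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_monte_carlo_needs_1000_draws(self):
        with pytest.raises(ValueError, match="1000"):
            rarefied_shannon(AbundanceVector([2, 2]), 2, mode="monte_carlo", n_draws=10)

    def test_m_above_n_is_error(self):
        with pytest.raises(ValueError):
            rarefied_shannon(AbundanceVector([2, 2]), 5)


class TestExtrapolateRichness:
    def test_no_singletons_returns_s_obs(self):
        x = AbundanceVector([2, 2, 3])
        for m_star in (0, 1, 10, 1000):
            assert extrapolate_richness(x, m_star) == 3.0

    def test_m_star_zero_is_identity(self):
        assert extrapolate_richness(AbundanceVector([2, 1, 1, 1]), 0) == 4.0

    def test_chao1_limit(self):
        # x=[2,1,1]: n=4, f1=2, f2=1 -> f0 = (3/4)*4/2 = 1.5
        x = AbundanceVector([2, 1, 1])
        assert frequency_counts(x).f0_hat == pytest.approx(1.5)
        assert extrapolate_richness(x, 10**9) == pytest.approx(3 + 1.5, abs=1e-6)

    def test_monotone_in_m_star(self):
        x = AbundanceVector([4, 2, 1, 1])
        vals = [extrapolate_richness(x, m) for m in range(0, 50, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestAsymptoticEntropy:
    def test_at_least_plugin(self):
        x = AbundanceVector([5, 3, 2, 1, 1, 1])
        assert asymptotic_entropy(x) >= shannon_entropy(x)

    def test_single_clone_zero(self):
        assert asymptotic_entropy(AbundanceVector([7])) == 0.0

    def test_recovers_truth_on_large_uniform_sample(self, rng):
        # independent oracle: a census of 50 equiprobable clones has H = ln 50
        counts = np.bincount(rng.choice(50, size=5000), minlength=50)
        est = asymptotic_entropy(AbundanceVector(counts.tolist()))
        assert est == pytest.approx(math.log(50), abs=0.01)


class TestBootstrapAssemblage:
    def test_single_clone(self):
        asm = build_bootstrap_assemblage(AbundanceVector([9]))
        assert asm.coverage == 1.0
        assert asm.n_unseen == 0
        assert asm.probabilities().tolist() == [1.0]

    def test_worked_example_4_2_1_1(self):
        # n=8, f1=2, f2=1: C = 1 - (2/8)(14/16) = 0.78125; f0 = (7/8)*4/2 = 1.75
        asm = build_bootstrap_assemblage(AbundanceVector([4, 2, 1, 1]))
        assert asm.coverage == pytest.approx(0.78125)
        assert asm.n_unseen == 2
        assert asm.n_unseen * asm.p_unseen == pytest.approx(1 - 0.78125)

    @settings(max_examples=50, deadline=None)
    @given(x=abundance_vectors)
    def test_probabilities_sum_to_one(self, x):
        asm = build_bootstrap_assemblage(x)
        probs = asm.probabilities()
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(probs >= 0)


class TestBootstrapDiversity:
    def test_deterministic_under_seed(self):
        x = AbundanceVector([5, 4, 3, 2, 1, 1])
        spec = RarefactionSpec(q=1, m=10, B=50, seed=42)
        a = bootstrap_diversity(x, spec)
        b = bootstrap_diversity(x, spec)
        assert a.replicate_values == b.replicate_values
        assert a.ci_low == b.ci_low

    def test_ci_contains_truth_for_uniform_census(self):
        x = AbundanceVector([10] * 100)
        est = bootstrap_diversity(x, RarefactionSpec(q=0, m=x.n, B=50, seed=1))
        assert est.ci_low <= 100 <= est.ci_high

    def test_b_below_two_is_error(self):
        with pytest.raises(ValueError, match="B"):
            RarefactionSpec(q=0, m=5, B=1)

    def test_m_above_n_is_error(self):
        with pytest.raises(ValueError, match="exceeds"):
            bootstrap_diversity(AbundanceVector([2, 2]), RarefactionSpec(q=0, m=10, B=10))

    def test_subsample_mode_runs(self):
        x = AbundanceVector([5, 4, 3, 2, 1])
        spec = RarefactionSpec(q=1, m=8, B=20, seed=3, resampling="subsample")
        est = bootstrap_diversity(x, spec)
        assert est.ci_low <= est.estimate <= est.ci_high


class TestCompareDiversityAtPoint:
    def test_identical_inputs_same_seed(self):
        x = AbundanceVector([6, 4, 3, 2, 1, 1])
        spec = RarefactionSpec(q=1, m=10, B=20, seed=5)
        res = compare_diversity_at_point(x, AbundanceVector(x.counts.tolist()), spec)
        assert res.mean_a == res.mean_b
        assert res.p_value == pytest.approx(1.0)

    def test_separated_samples_detected(self, rng):
        counts_a = np.bincount(rng.choice(250, size=5000), minlength=250)
        counts_b = np.bincount(rng.choice(150, size=5000), minlength=150)
        res = compare_diversity_at_point(
            AbundanceVector(counts_a.tolist()),
            AbundanceVector(counts_b.tolist()),
            RarefactionSpec(q=1, m=3500, B=50, seed=9),
        )
        assert res.mean_a > res.mean_b
        assert res.p_value < 0.01

    def test_m_exceeding_sample_names_it(self):
        x_a = AbundanceVector([1000, 1000, 1000, 500])  # n=3500
        x_b = AbundanceVector([1500, 1500])  # n=3000
        with pytest.raises(ValueError, match="sample_b"):
            compare_diversity_at_point(
                x_a, x_b, RarefactionSpec(q=1, m=3500, B=10), labels=("sample_a", "sample_b")
            )

    def test_student_flavor(self):
        x = AbundanceVector([5, 4, 3, 2, 1])
        res = compare_diversity_at_point(
            x, AbundanceVector([9, 3, 2, 1]), RarefactionSpec(q=1, m=10, B=20, seed=2),
            flavor="student",
        )
        assert 0 < res.p_value <= 1


class TestD50:
    def test_uniform_ten_clones(self):
        res = d50(AbundanceVector([1] * 10))
        assert res.k == 5 and res.normalized == 0.5

    def test_dominant_clone(self):
        res = d50(AbundanceVector([5, 3, 1, 1]))
        assert res.k == 1 and res.normalized == 0.25

    def test_cumulative_boundary(self):
        res = d50(AbundanceVector([4, 3, 2, 1]))
        assert res.k == 2 and res.normalized == 0.5

    @settings(max_examples=50, deadline=None)
    @given(x=abundance_vectors)
    def test_doubling_counts_preserves_normalized(self, x):
        doubled = AbundanceVector((x.counts * 2).tolist())
        assert d50(doubled).normalized == d50(x).normalized

    @settings(max_examples=50, deadline=None)
    @given(x=abundance_vectors)
    def test_k_bounds(self, x):
        res = d50(x)
        assert 1 <= res.k <= x.s_obs
        assert 0 < res.normalized <= 1


class TestDiversityCurve:
    @pytest.mark.parametrize("q", [0, 1])
    def test_value_at_n_is_plugin(self, q):
        x = AbundanceVector([5, 3, 2, 1, 1])
        curve = diversity_curve(x, q, knots=12)
        at_n = curve.estimates[curve.sizes == x.n][0]
        assert at_n == pytest.approx(hill_number(x, q), rel=1e-9)

    @pytest.mark.parametrize("q", [0, 1])
    @pytest.mark.parametrize("seed", range(6))
    def test_monotone_nondecreasing(self, q, seed, rng):
        counts = np.random.default_rng(seed).integers(1, 20, size=12)
        curve = diversity_curve(AbundanceVector(counts.tolist()), q, knots=25)
        diffs = np.diff(curve.estimates)
        assert np.all(diffs >= -1e-9)

    def test_single_clone_flat_at_one(self):
        curve = diversity_curve(AbundanceVector([10]), 0, knots=8)
        assert np.allclose(curve.estimates, 1.0)
        curve1 = diversity_curve(AbundanceVector([10]), 1, knots=8)
        assert np.allclose(curve1.estimates, 1.0)

    def test_bootstrap_band_brackets_point(self):
        x = AbundanceVector([8, 5, 3, 2, 1, 1])
        curve = diversity_curve(x, 1, knots=10, B=20, seed=0)
        assert np.all(curve.ci_low <= curve.estimates + 1e-12)
        assert np.all(curve.ci_high >= curve.estimates - 1e-12)

    def test_richness_dominates_shannon(self):
        x = AbundanceVector([6, 3, 2, 1])
        c0 = diversity_curve(x, 0, knots=10)
        c1 = diversity_curve(x, 1, knots=10)
        assert np.all(c0.estimates >= c1.estimates - 1e-9)

    def test_uniform_census_equality_at_n(self):
        x = AbundanceVector([4] * 6)
        c0 = diversity_curve(x, 0, knots=5)
        c1 = diversity_curve(x, 1, knots=5)
        at_n0 = c0.estimates[c0.sizes == x.n][0]
        at_n1 = c1.estimates[c1.sizes == x.n][0]
        assert at_n0 == pytest.approx(at_n1, rel=1e-9)

    def test_knots_below_two_is_error(self):
        with pytest.raises(ValueError, match="knots"):
            diversity_curve(AbundanceVector([2, 1]), 0, knots=1)
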