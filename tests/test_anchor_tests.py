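"""Unit and property tests for the trio likelihood-ratio statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import integrate, special, stats

from anchornet import anchor_tests as at

from ._oracles import anova_llr, ml_llrs, null_density, optimizer_llrs, quadrature_pvalue
from .conftest import random_correlated_trios


def _corrs(e, a, b):
    n = len(e)
    return (
        at.pair_correlation(e, a),
        at.pair_correlation(e, b),
        at.pair_correlation(a, b),
        n,
    )


class TestRankNormalTransform:
    def test_moments_and_order(self, rng):
        x = rng.random(37)
        out = at.rank_normal_transform(x)
        assert abs(out.mean()) < 1e-10
        assert abs(out.var() - 1.0) < 1e-10
        assert np.array_equal(np.argsort(out), np.argsort(x, kind="stable"))

    def test_simple_ordering(self):
        out = at.rank_normal_transform([3.0, 1.0, 2.0, 5.0, 4.0])
        assert out[1] < out[2] < out[0] < out[4] < out[3]

    @given(
        x=hnp.arrays(
            np.float64,
            st.integers(5, 60),
            elements=st.floats(-1e6, 1e6, allow_nan=False),
        ).filter(lambda a: np.unique(a).size > 1)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_transform_invariance(self, x):
        """A strictly increasing transform of the input leaves the output bit-identical."""
        base = at.rank_normal_transform(x)
        scaled = at.rank_normal_transform(x * 4.0)  # exact in floating point
        ranked = at.rank_normal_transform(stats.rankdata(x))  # monotone, tie-preserving
        assert np.array_equal(base, scaled)
        assert np.array_equal(base, ranked)

    def test_ties_get_average_rank_quantile(self):
        x = np.array([4.0, 1.0, 4.0, 2.0, 7.0, 0.5])
        out = at.rank_normal_transform(x)
        assert out[0] == out[2]
        # explicit average-rank computation: the two 4s occupy ranks 4 and 5
        n = x.size
        raw = special.ndtri((stats.rankdata(x) - 0.5) / n)
        expected = (raw - raw.mean()) / raw.std()
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_errors(self):
        with pytest.raises(at.DegenerateVariableError):
            at.rank_normal_transform([2.0] * 8)
        with pytest.raises(at.InsufficientSamplesError):
            at.rank_normal_transform([1.0, 2.0, 3.0])


class TestPairCorrelation:
    def test_self_and_negation(self, rng):
        x = at.rank_normal_transform(rng.random(20))
        assert at.pair_correlation(x, x) == pytest.approx(1.0, abs=1e-12)
        assert at.pair_correlation(x, -x) == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pearson(self, rng):
        x = at.rank_normal_transform(rng.random(20))
        y = at.rank_normal_transform(rng.random(20))
        assert at.pair_correlation(x, y) == pytest.approx(
            stats.pearsonr(x, y).statistic, abs=1e-12
        )

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            at.pair_correlation(np.zeros(5), np.zeros(6))


class TestLLRClosedForms:
    def test_linkage_null_and_symmetry(self):
        assert at.llr_linkage(0.0, 36) == 0.0
        assert at.llr_linkage(0.5, 20) == at.llr_linkage(-0.5, 20)
        assert at.llr_linkage(0.5, 20) == pytest.approx(-10 * np.log(0.75), rel=1e-12)

    def test_chain_cancellation(self):
        """rho_EB = rho_EA * rho_AB saturates the conditional-independence null."""
        rho_ea, rho_ab = 0.6, 0.5
        assert at.llr_conditional_independence(rho_ea, rho_ea * rho_ab, rho_ab, 30) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_pleiotropy_cancellation(self):
        """rho_AB = rho_EA * rho_EB saturates the controlled-test null."""
        rho_ea, rho_eb = 0.6, 0.3
        assert at.llr_controlled(rho_ea, rho_eb, rho_ea * rho_eb, 30) == (
            pytest.approx(0.0, abs=1e-9)
        )

    def test_relevance_zero_when_b_unrelated(self):
        assert at.llr_relevance(0.7, 0.0, 0.0, 25) == pytest.approx(0.0, abs=1e-12)

    def test_relevance_b_negation_invariance(self):
        a = at.llr_relevance(0.7, 0.4, 0.5, 25)
        b = at.llr_relevance(0.7, -0.4, -0.5, 25)
        assert a == pytest.approx(b, rel=1e-12)
        assert a > 0

    def test_singular_matrix_raises(self):
        with pytest.raises(at.SingularCorrelationError):
            at.llr_conditional_independence(0.9, -0.9, 0.9, 20)

    def test_nesting_nonnegative_on_random_triples(self, rng):
        """Nested hypotheses force every LLR to be non-negative."""
        for _ in range(200):
            x = rng.standard_normal((3, 12))
            x = at.rank_normal_transform(x, axis=1)
            rho_ea, rho_eb, rho_ab, n = _corrs(*x)
            assert at.llr_linkage(rho_ea, n) >= 0
            assert at.llr_conditional_independence(rho_ea, rho_eb, rho_ab, n) >= 0
            assert at.llr_relevance(rho_ea, rho_eb, rho_ab, n) >= 0
            assert at.llr_controlled(rho_ea, rho_eb, rho_ab, n) >= 0

    def test_agrees_with_numerical_ml_fits(self):
        """All five closed forms match maximized-log-likelihood differences
        on 200 random trios spanning n in {8, 20, 50}."""
        for e, a, b in random_correlated_trios(seed=42, n_trios=200):
            rho_ea, rho_eb, rho_ab, n = _corrs(e, a, b)
            got = {
                1: at.llr_linkage(rho_ea, n),
                2: at.llr_linkage(rho_eb, n),
                3: at.llr_conditional_independence(rho_ea, rho_eb, rho_ab, n),
                4: at.llr_relevance(rho_ea, rho_eb, rho_ab, n),
                5: at.llr_controlled(rho_ea, rho_eb, rho_ab, n),
            }
            expected = ml_llrs(e, a, b)
            for t in range(1, 6):
                assert got[t] == pytest.approx(expected[t], abs=1e-6), f"test {t}, n={n}"

    def test_agrees_with_generic_optimizer(self):
        """Spot-check against explicit numerical optimization of each model's
        log-likelihood (slower, fully formula-free)."""
        for e, a, b in random_correlated_trios(seed=7, n_trios=4, sizes=(20,)):
            rho_ea, rho_eb, rho_ab, n = _corrs(e, a, b)
            got = {
                1: at.llr_linkage(rho_ea, n),
                2: at.llr_linkage(rho_eb, n),
                3: at.llr_conditional_independence(rho_ea, rho_eb, rho_ab, n),
                4: at.llr_relevance(rho_ea, rho_eb, rho_ab, n),
                5: at.llr_controlled(rho_ea, rho_eb, rho_ab, n),
            }
            expected = optimizer_llrs(e, a, b)
            for t in range(1, 6):
                assert got[t] == pytest.approx(expected[t], abs=1e-4), f"test {t}"


class TestNullFamily:
    def test_density_zero_for_nonpositive_z(self):
        spec = at.NullSpec(1.0, 18.0)
        assert at.null_log_density(-1.0, spec) == -np.inf
        assert at.null_log_density(0.0, spec) == -np.inf

    @pytest.mark.parametrize("k1,k2", [(1, 18), (2, 33), (1, 220)])
    def test_density_integrates_to_one(self, k1, k2):
        spec = at.NullSpec(float(k1), float(k2))
        f = lambda z: np.exp(at.null_log_density(z, spec))
        v1, _ = integrate.quad(f, 0, 1, limit=400)
        v2, _ = integrate.quad(f, 1, np.inf, limit=400)
        assert v1 + v2 == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("k1,k2", [(1, 18), (2, 33), (1, 220)])
    def test_change_of_variable_is_beta(self, k1, k2):
        """x = 1 - e^{-2z} maps D(k1,k2) onto Beta(k1/2, k2/2) (Jacobian 2 e^{-2z})."""
        spec = at.NullSpec(float(k1), float(k2))
        for z in (0.01, 0.1, 0.5, 1.5):
            x = 1.0 - np.exp(-2.0 * z)
            lhs = np.exp(at.null_log_density(z, spec))
            rhs = stats.beta.pdf(x, k1 / 2.0, k2 / 2.0) * 2.0 * np.exp(-2.0 * z)
            assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_density_matches_direct_formula(self):
        spec = at.NullSpec(1.0, 18.0)
        z = np.array([0.05, 0.3, 2.0])
        np.testing.assert_allclose(
            np.exp(at.null_log_density(z, spec)), null_density(z, 1.0, 18.0), rtol=1e-12
        )

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            at.NullSpec(0.0, 5.0)
        with pytest.raises(at.InsufficientSamplesError):
            at.null_spec_for_test(3, 3)


class TestNullPvalue:
    def test_boundaries(self):
        assert at.null_pvalue(0.0, 20, 1) == pytest.approx(1.0)
        assert at.null_pvalue(500.0, 20, 1) == pytest.approx(0.0, abs=1e-12)

    def test_monotone_in_llr(self):
        llrs = np.linspace(0, 10, 50)
        p = at.null_pvalue(llrs, 20, 4)
        assert np.all(np.diff(p) <= 0)

    @pytest.mark.parametrize("test_id,n", [(1, 20), (2, 8), (3, 30), (4, 30), (5, 10)])
    def test_matches_quadrature(self, test_id, n):
        spec = at.null_spec_for_test(test_id, n)
        for llr in (0.01, 0.2, 1.0, 2.8768, 6.0):
            p = at.null_pvalue(llr, n, test_id)
            q = quadrature_pvalue(llr, n, spec.k1, spec.k2)
            assert p == pytest.approx(q, abs=1e-8)

    def test_rejects_negative_llr(self):
        with pytest.raises(ValueError):
            at.null_pvalue(-0.5, 20, 1)


class TestPosteriors:
    def test_pure_null_posteriors_near_zero(self, rng):
        p = rng.random(10_000)
        post = at.posteriors_from_pvalues(p)
        assert post.mean() <= 0.05

    def test_mixture_detects_signal(self, rng):
        """50:50 mix of near-zero and uniform p-values: small p -> posterior
        near 1, and pi0 is recovered within 0.1."""
        m = 5000
        p = np.concatenate([rng.random(m) * 1e-4, rng.random(m)])
        post = at.posteriors_from_pvalues(p)
        assert post[:m].mean() > 0.9
        assert at.estimate_pi0(p) == pytest.approx(0.5, abs=0.1)

    def test_equal_pvalues_equal_posteriors(self, rng):
        p = rng.random(200)
        p[10] = p[57] = 0.003
        post = at.posteriors_from_pvalues(p)
        assert post[10] == post[57]

    def test_monotone_nonincreasing_in_p(self, rng):
        p = np.concatenate([rng.random(500) ** 3, rng.random(500)])
        post = at.posteriors_from_pvalues(p)
        order = np.argsort(p)
        assert np.all(np.diff(post[order]) <= 1e-12)

    def test_small_input_fallback_and_sides(self):
        p = np.array([0.01, 0.5, 0.99])
        with pytest.warns(UserWarning):
            post = at.posteriors_from_pvalues(p)
        np.testing.assert_allclose(post, 1.0 - p)
        with pytest.warns(UserWarning):
            null_post = at.posteriors_from_pvalues(p, side="null")
        np.testing.assert_allclose(null_post, p)

    def test_empty_and_nan(self):
        assert at.posteriors_from_pvalues([]).size == 0
        with pytest.raises(ValueError):
            at.posteriors_from_pvalues([0.1, np.nan, 0.2])


class TestBinaryAnchor:
    def test_two_levels_standardized(self):
        enc = at.encode_binary_anchor([0, 0, 5, 7, 0, 3])
        assert np.unique(enc).size == 2
        assert abs(enc.mean()) < 1e-12
        assert abs(enc.var() - 1.0) < 1e-12
        assert enc[0] < enc[2]  # zeros map to the low level

    def test_linkage_equals_anova(self, rng):
        """Binary-anchor linkage LLR equals -(n/2) ln(RSS_group/RSS_total)
        from an explicit two-group ANOVA on 100 random instances."""
        for _ in range(100):
            n = int(rng.integers(6, 40))
            raw = rng.random(n) * (rng.random(n) > 0.4)
            if (raw == 0).all() or (raw != 0).all():
                continue
            y = at.rank_normal_transform(rng.standard_normal(n))
            enc = at.encode_binary_anchor(raw)
            llr = at.llr_linkage(at.pair_correlation(enc, y), n)
            assert llr == pytest.approx(anova_llr(raw != 0, y), abs=1e-10)

    def test_degenerate_raises(self):
        with pytest.raises(at.DegenerateVariableError):
            at.encode_binary_anchor([0.0] * 10)
        with pytest.raises(at.DegenerateVariableError):
            at.encode_binary_anchor([1.0] * 10)


def test_trio_statistics_contract(random_trio):
    res = at.trio_statistics(*random_trio)
    assert res.llr.shape == (5,)
    assert np.all(res.llr >= 0)
    assert np.all((res.pvalue >= 0) & (res.pvalue <= 1))
    assert np.all((res.posterior >= 0) & (res.posterior <= 1))
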