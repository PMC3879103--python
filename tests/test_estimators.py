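"""Heritability measures and the seven accuracy estimators."""

import numpy as np
import pytest

from gsacc import estimators as est
from gsacc.genomes import code_genotypes, generate_dh_markers
from gsacc.estimators import (
    accuracy_m5,
    accuracy_m6,
    accuracy_m7,
    centering_operator,
    expected_sample_variance,
    h2_blue,
    h2_blup,
    h2_expected_variance,
    h2_standard,
    indirect_accuracy,
    predictive_ability,
    reliability_from_components,
    true_accuracy,
    true_heritability,
)


class TestCenteringOperator:
    def test_two_by_two(self):
        Pu = centering_operator(2).Pu
        assert np.allclose(Pu, [[0.5, -0.5], [-0.5, 0.5]])

    @pytest.mark.parametrize("n", [2, 5, 40])
    def test_trace_one_and_annihilates_constants(self, n):
        Pu = centering_operator(n).Pu
        assert np.isclose(np.trace(Pu), 1.0)
        assert np.allclose(Pu @ np.ones(n), 0.0, atol=1e-12)
        assert np.allclose(Pu, Pu.T)

    def test_quadratic_form_is_sample_variance(self):
        rng = np.random.default_rng(2)
        g = rng.normal(size=37)
        Pu = centering_operator(37).Pu
        assert np.isclose(g @ Pu @ g, np.var(g, ddof=1), atol=1e-12)

    def test_trace_product_shortcut(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(20, 20))
        A = A @ A.T
        Pu = centering_operator(20).Pu
        assert np.isclose(expected_sample_variance(A), np.trace(Pu @ A), atol=1e-10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            centering_operator(1)


class TestHeritabilityMeasures:
    def test_standard_measure_values(self):
        assert h2_standard(1.0, 1.0, 2) == pytest.approx(2 / 3)
        assert h2_standard(0.0, 5.0, 2) == 0.0
        assert h2_standard(0.5, 48.6728, 2) == pytest.approx(0.5 / 24.8364)

    def test_standard_measure_errors(self):
        with pytest.raises(ValueError):
            h2_standard(1.0, 1.0, 0)

    def test_blue_measure_values(self):
        assert h2_blue(1.0, 2.0) == 0.5
        assert h2_blue(0.0, 3.0) == 0.0

    def test_blue_equals_standard_on_balanced_design(self):
        # balanced RCBD: v_bar = 2 sigma_e2 / r
        for sg, se, r in [(1.0, 4.0, 2), (0.3, 48.6728, 2), (2.5, 1.0, 5)]:
            assert h2_blue(sg, 2 * se / r) == pytest.approx(h2_standard(sg, se, r))

    def test_blup_measure_values(self):
        assert h2_blup(0.0, 1.0) == 1.0
        assert h2_blup(3.0, 1.0) == pytest.approx(-0.5)  # negative is possible
        assert h2_blup(2 * 0.7, 0.7) == pytest.approx(0.0)
        with pytest.raises(ZeroDivisionError):
            h2_blup(1.0, 0.0)

    def test_expected_variance_iid_case(self):
        n = 10
        assert h2_expected_variance(np.eye(n) * 2.0, np.eye(n) * 3.0) == pytest.approx(
            2.0 / 5.0
        )

    def test_expected_variance_ignores_constant_offsets(self):
        rng = np.random.default_rng(8)
        A = rng.normal(size=(12, 12))
        G = A @ A.T
        R = np.eye(12) * 2.0
        h = h2_expected_variance(G, R)
        assert h2_expected_variance(G + 5.0, R) == pytest.approx(h, abs=1e-10)

    def test_expected_genetic_variance_matches_monte_carlo(self):
        rng = np.random.default_rng(11)
        A = rng.normal(size=(8, 8))
        G = A @ A.T
        L = np.linalg.cholesky(G)
        draws = L @ rng.normal(size=(8, 100_000))
        s2 = draws.var(axis=0, ddof=1)
        se = s2.std(ddof=1) / np.sqrt(s2.size)
        assert abs(expected_sample_variance(G) - s2.mean()) < 3 * se


class TestCorrelations:
    def test_perfect_and_inverted(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        assert predictive_ability(x, x).value == pytest.approx(1.0)
        assert predictive_ability(-x, x).value == pytest.approx(-1.0)

    def test_toy_vectors_match_textbook_formula(self):
        g_hat = np.array([1.0, 2.0, 3.0])
        p = np.array([2.0, 4.0, 7.0])
        sxy = np.sum((g_hat - 2) * (p - 13 / 3)) / 2
        r_manual = sxy / np.sqrt(np.var(g_hat, ddof=1) * np.var(p, ddof=1))
        assert predictive_ability(g_hat, p).value == pytest.approx(r_manual)

    def test_zero_variance_flagged(self):
        r = predictive_ability(np.ones(5), np.arange(5.0))
        assert np.isnan(r.value) and r.flag == est.FLAG_UNDEFINED

    def test_true_accuracy_affine_invariance(self):
        rng = np.random.default_rng(3)
        g = rng.normal(size=30)
        assert true_accuracy(g, 2.5 * g + 4).value == pytest.approx(1.0)
        assert true_accuracy(g, g).value == pytest.approx(1.0)

    def test_true_heritability_is_squared_accuracy(self):
        rng = np.random.default_rng(4)
        g = rng.normal(size=50)
        gh = g + rng.normal(size=50)
        r = true_accuracy(g, gh).value
        assert true_heritability(g, gh) == pytest.approx(r**2)


class TestIndirectAccuracy:
    def test_simple_ratio(self):
        e = indirect_accuracy(0.6, 0.64)
        assert e.value == pytest.approx(0.75)
        assert e.flag == est.FLAG_OK

    def test_zero_heritability_breaks_down(self):
        e = indirect_accuracy(0.6, 0.0)
        assert e.flag == est.FLAG_BREAKDOWN and np.isnan(e.value)

    def test_overshoot_truncated_with_flag(self):
        e = indirect_accuracy(0.9, 0.64)
        assert e.untruncated == pytest.approx(1.125)
        assert e.value == 1.0
        assert e.flag == est.FLAG_OVERSHOOT


class TestMethod5:
    @pytest.mark.parametrize("n", [3, 10, 50])
    def test_iid_unit_case_collapses_to_root_half(self, n):
        e = accuracy_m5(np.eye(n), 2.0 * np.eye(n))
        assert abs(e.value - np.sqrt(0.5)) < 1e-10

    def test_zero_genetic_variance_flagged(self):
        e = accuracy_m5(np.zeros((5, 5)), np.eye(5))
        assert e.value == 0.0 and e.flag == est.FLAG_DEGENERATE

    def test_scale_equivariance(self):
        raw = generate_dh_markers(20, 30, seed=3)
        G = code_genotypes(raw).Z @ code_genotypes(raw).Z.T * 0.1
        V = G + np.eye(20) * 2.0
        a = accuracy_m5(G, V).value
        b = accuracy_m5(10 * G, 10 * V).value
        assert a == pytest.approx(b, abs=1e-12)

    def test_monotone_in_genetic_variance_iid(self):
        vals = [accuracy_m5(np.eye(8) * s, np.eye(8) * (s + 1.0)).value
                for s in [0.1, 0.5, 1.0, 2.0, 5.0]]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        # and matches the closed form sqrt(s / (s + 1))
        for s, v in zip([0.1, 0.5, 1.0, 2.0, 5.0], vals):
            assert v == pytest.approx(np.sqrt(s / (s + 1.0)), abs=1e-10)

    def test_constant_kernel_component_is_annihilated(self):
        raw = generate_dh_markers(15, 25, seed=9)
        Z = code_genotypes(raw).Z
        G = Z @ Z.T * 0.2
        V = G + np.eye(15) * 3.0
        a = accuracy_m5(G, V).value
        c = 4.0
        b = accuracy_m5(G + c, V + c).value
        assert a == pytest.approx(b, abs=1e-8)


class TestMethod6:
    def test_exact_unit_value(self):
        e = accuracy_m6(0.5, 0.25, 1.0)
        assert e.value == pytest.approx(1.0) and e.flag == est.FLAG_OK

    def test_half(self):
        assert accuracy_m6(0.5, 0.25, 4.0).value == pytest.approx(0.5)

    def test_overshoot_truncation(self):
        e = accuracy_m6(0.6, 0.25, 0.25)
        assert e.untruncated == pytest.approx(2.4)
        assert e.value == 1.0 and e.flag == est.FLAG_OVERSHOOT

    def test_nonpositive_variance_flagged(self):
        assert accuracy_m6(0.5, 0.0, 1.0).flag == est.FLAG_BREAKDOWN
        assert accuracy_m6(0.5, 1.0, 0.0).flag == est.FLAG_BREAKDOWN


class TestMethod7:
    def test_perfect_information_limit(self):
        raw = generate_dh_markers(10, 40, seed=21)
        Z = code_genotypes(raw).Z
        G = Z @ Z.T * 0.5  # full rank for n << p
        rho2, e = reliability_from_components(G, 1e-12, absorb_mean=False)
        assert np.all(rho2 > 1 - 1e-6)
        assert e.value == pytest.approx(1.0, abs=1e-6)

    def test_independent_case_closed_form(self):
        s2g, s2e, n = 3.0, 2.0, 25
        rho2, e = reliability_from_components(np.eye(n) * s2g, s2e, absorb_mean=False)
        assert np.allclose(rho2, s2g / (s2g + s2e))
        assert e.value == pytest.approx(np.sqrt(s2g / (s2g + s2e)))

    def test_bounds_hold_over_random_fits(self):
        # Methods 5 and 7 stay inside [0, 1] by construction
        rng = np.random.default_rng(17)
        for trial in range(500):
            n = int(rng.integers(5, 15))
            p = int(rng.integers(3, 25))
            Z = rng.choice([-1.0, 0.0, 1.0], size=(n, p))
            s2u = float(rng.uniform(1e-4, 5.0))
            s2e = float(rng.uniform(1e-3, 10.0))
            G = Z @ Z.T * s2u
            V = G + np.eye(n) * s2e
            m5 = accuracy_m5(G, V)
            assert 0.0 <= m5.value <= 1.0
            _, m7 = reliability_from_components(G, s2e)
            if np.isfinite(m7.value):
                assert 0.0 <= m7.value <= 1.0
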