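"""Orthant kernel, tetrachoric correlations and the ACE model family."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats
from scipy.integrate import quad
from scipy.special import ndtr

from twinace.liability import (
    GroupTable,
    ModelFit,
    VarianceComponents,
    bvn_cdf,
    bvn_upper_orthant,
    fit_saturated,
    fit_variance_model,
    implied_correlations,
    likelihood_ratio_test,
    profile_ci,
    tetrachoric_ml,
)

from conftest import exact_group_tables


def orthant_quadrature(h, k, r):
    """Independent oracle: P(X>h, Y>k) by 1-D adaptive quadrature."""
    s = math.sqrt(1.0 - r * r)
    f = lambda x: stats.norm.pdf(x) * stats.norm.sf((k - r * x) / s)
    val, _ = quad(f, h, 40.0, epsabs=1e-13, epsrel=1e-13, limit=400)
    return val


class TestOrthant:
    def test_independence_factorizes(self):
        for h, k in [(0.5, 1.0), (-1.2, 2.0), (0.0, 0.7)]:
            assert bvn_upper_orthant(h, k, 0.0) == pytest.approx(
                stats.norm.sf(h) * stats.norm.sf(k), abs=1e-12)

    def test_zero_threshold_closed_form(self):
        # P(X>0, Y>0) = 1/4 + asin(r) / (2 pi)
        assert bvn_upper_orthant(0.0, 0.0, 0.5) == pytest.approx(1.0 / 3.0, abs=1e-12)
        for r in np.linspace(-0.999, 0.999, 41):
            expect = 0.25 + math.asin(r) / (2.0 * math.pi)
            assert bvn_upper_orthant(0.0, 0.0, r) == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("h,k,r", [
        (0.5, 1.0, 0.3), (1.2, -0.4, 0.85), (-2.0, 0.3, -0.6),
        (0.0, 1.5, 0.4), (2.5, 2.5, 0.95), (1.0, 1.0, -0.95),
    ])
    def test_matches_quadrature(self, h, k, r):
        assert bvn_upper_orthant(h, k, r) == pytest.approx(
            orthant_quadrature(h, k, r), abs=1e-10)

    @given(st.floats(-0.99, 0.99), st.floats(-0.99, 0.99),
           st.floats(-3, 3), st.floats(-3, 3))
    def test_monotone_in_correlation(self, r1, r2, h, k):
        lo, hi = sorted((r1, r2))
        assert bvn_upper_orthant(h, k, hi) >= bvn_upper_orthant(h, k, lo) - 1e-12

    def test_degenerate_correlations(self):
        assert bvn_upper_orthant(0.5, 1.0, 1.0) == pytest.approx(stats.norm.sf(1.0), abs=1e-12)
        assert bvn_upper_orthant(-1.0, 0.5, -1.0) == pytest.approx(
            max(0.0, stats.norm.sf(-1.0) + stats.norm.sf(0.5) - 1.0), abs=1e-12)

    def test_invalid_correlation_rejected(self):
        with pytest.raises(ValueError, match="correlation"):
            bvn_upper_orthant(0.0, 0.0, 1.5)


class TestTetrachoric:
    def test_exact_half_correlation_table(self):
        # orthant probabilities at tau1 = tau2 = 0, r = 0.5 are
        # (1/3, 1/6, 1/6, 1/3); scaled by 1200 -> counts (400, 200, 200, 400)
        t = GroupTable("MZ", 400, 200, 200, 400, symmetrized=True)
        res = tetrachoric_ml(t, ci=False)
        assert res.r == pytest.approx(0.5, abs=1e-3)
        assert res.tau1 == pytest.approx(0.0, abs=1e-12)

    def test_margin_product_table_gives_zero(self):
        # cells proportional to the product of the margins -> independence
        n, p1, p2 = 10000, 0.3, 0.2
        t = GroupTable("DZ", n * (1 - p1) * (1 - p2), n * (1 - p1) * p2,
                       n * p1 * (1 - p2), n * p1 * p2)
        res = tetrachoric_ml(t, ci=False)
        assert res.r == pytest.approx(0.0, abs=1e-9)

    def test_matches_full_numeric_optimization(self):
        # the analytic MLE (margin probits + orthant match) must agree with
        # a brute 3-parameter maximization of the multinomial likelihood
        t = GroupTable("MZ", 820, 55, 45, 80)
        res = tetrachoric_ml(t, ci=False)

        counts = t.counts

        def m2ll(theta):
            tau1, tau2, z = theta
            r = math.tanh(z)
            p11 = bvn_upper_orthant(tau1, tau2, r)
            p10 = ndtr(-tau1) - p11
            p01 = ndtr(-tau2) - p11
            p00 = 1 - p11 - p10 - p01
            p = np.clip([p00, p01, p10, p11], 1e-12, 1)
            return -2 * np.sum(counts * np.log(p))

        brute = optimize.minimize(m2ll, [1.0, 1.0, 0.3], method="Nelder-Mead",
                                  options={"xatol": 1e-10, "fatol": 1e-12})
        assert res.r == pytest.approx(math.tanh(brute.x[2]), abs=1e-5)
        assert res.minus2ll == pytest.approx(brute.fun, abs=1e-6)

    def test_profile_ci_brackets_estimate(self):
        t = GroupTable("MZ", 900, 30, 30, 40, symmetrized=True)
        res = tetrachoric_ml(t)
        assert res.ci_low < res.r < res.ci_high

    def test_empty_off_diagonals_hit_boundary(self):
        res = tetrachoric_ml(GroupTable("MZ", 400, 0, 0, 100), ci=False)
        assert res.r == 1.0
        assert res.boundary

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError):
            tetrachoric_ml(GroupTable("MZ", 0, 0, 0, 50))
        with pytest.raises(ValueError):
            tetrachoric_ml(GroupTable("MZ", 100, 0, 0, 0))


class TestSaturated:
    def test_reproduces_observed_proportions(self):
        tables = {"MZM": GroupTable("MZM", 2100, 55, 55, 85, symmetrized=True),
                  "DZOS": GroupTable("DZOS", 5000, 260, 420, 92)}
        fit = fit_saturated(tables)
        for label, t in tables.items():
            tau1, tau2 = fit.params["thresholds"][label]
            r = fit.params["correlations"][label]
            p11 = bvn_upper_orthant(tau1, tau2, r)
            p10 = ndtr(-tau1) - p11
            p01 = ndtr(-tau2) - p11
            fitted = np.array([1 - p11 - p10 - p01, p01, p10, p11])
            assert np.allclose(fitted, t.proportions, atol=1e-9)
        analytic = sum(-2 * np.sum(t.counts * np.log(t.proportions))
                       for t in tables.values())
        assert fit.minus2ll == pytest.approx(analytic, abs=1e-8)

    def test_threshold_equality_free_on_symmetric_table(self):
        # equal affected margins in both groups: constraining the threshold
        # equal across them costs ~0 chi-square
        tables = {"MZM": GroupTable("MZM", 840, 60, 60, 40, symmetrized=True),
                  "DZM": GroupTable("DZM", 850, 50, 50, 50, symmetrized=True)}
        free = fit_saturated(tables)
        constrained = fit_saturated(tables, threshold_pattern="by_sex",
                                    correlation_pattern="by_group")
        assert constrained.minus2ll - free.minus2ll == pytest.approx(0.0, abs=1e-4)

    def test_constrained_fit_matches_grid_oracle(self):
        # asymmetric margins: shared threshold + shared r, versus a dense
        # grid maximization over (tau, r)
        tables = {"MZM": GroupTable("MZM", 700, 90, 90, 120, symmetrized=True),
                  "DZM": GroupTable("DZM", 820, 70, 70, 40, symmetrized=True)}
        fit = fit_saturated(tables, threshold_pattern="single",
                            correlation_pattern="pooled_dz")
        # grid oracle over shared tau and (r_MZ, r_DZ) factorizes per group
        taus = np.linspace(0.3, 1.5, 241)
        best = math.inf
        for tau in taus:
            total = 0.0
            for t in tables.values():
                rs = np.linspace(-0.5, 0.99, 150)
                vals = []
                for r in rs:
                    p11 = bvn_upper_orthant(tau, tau, r)
                    p10 = ndtr(-tau) - p11
                    p = np.clip([1 - p11 - 2 * p10, p10, p10, p11], 1e-12, 1)
                    vals.append(-2 * np.sum(t.counts * np.log(p)))
                total += min(vals)
            best = min(best, total)
        # grid is coarse; agreement to ~0.05 on -2LL is grid resolution
        assert fit.minus2ll <= best + 1e-6
        assert fit.minus2ll == pytest.approx(best, abs=0.05)


class TestVarianceModels:
    def test_e_model_is_independence(self):
        tables = {"MZM": GroupTable("MZM", 800, 60, 60, 80, symmetrized=True),
                  "DZM": GroupTable("DZM", 820, 70, 70, 40, symmetrized=True)}
        comp, fit = fit_variance_model(tables, model="E")
        assert comp.a2 == 0.0 and comp.c2 == 0.0
        # -2LL equals the independence model at the fitted threshold
        tau = fit.params["thresholds"]["male"]
        total = 0.0
        for t in tables.values():
            q = ndtr(-tau)
            p = np.array([(1 - q) ** 2, (1 - q) * q, q * (1 - q), q * q])
            total += -2 * np.sum(t.counts * np.log(p))
        assert fit.minus2ll == pytest.approx(total, abs=1e-6)

    def test_recovers_exact_fixture(self):
        tables = exact_group_tables(a2=0.6, c2=0.2, tau_m=1.2)
        comp, fit = fit_variance_model(tables, model="ACE")
        assert fit.converged
        assert comp.a2 == pytest.approx(0.6, abs=1e-2)
        assert comp.c2 == pytest.approx(0.2, abs=1e-2)
        assert comp.e2 == pytest.approx(0.2, abs=1e-2)
        assert fit.params["thresholds"]["male"] == pytest.approx(1.2, abs=1e-3)

    def test_agrees_with_simplex_grid_oracle(self):
        tables = exact_group_tables(a2=0.55, c2=0.25, tau_m=1.25, tau_f=1.64)
        comp, fit = fit_variance_model(tables, model="ACE")
        # margin probits are exact on probability-exact tables, so the grid
        # oracle only needs to sweep the component simplex
        tau = {"male": 1.25, "female": 1.64}
        sexes = {"MZM": ("male", "male"), "MZF": ("female", "female"),
                 "DZM": ("male", "male"), "DZF": ("female", "female"),
                 "DZOS": ("male", "female")}
        step = 0.005
        grid = []
        for a2 in np.arange(0.0, 1.0 + step / 2, step):
            for c2 in np.arange(0.0, 1.0 - a2 + step / 2, step):
                total = 0.0
                for label, t in tables.items():
                    r = a2 + c2 if label.startswith("MZ") else 0.5 * a2 + c2
                    t1, t2 = (tau[s] for s in sexes[label])
                    p11 = bvn_upper_orthant(t1, t2, r)
                    p10 = ndtr(-t1) - p11
                    p01 = ndtr(-t2) - p11
                    p = np.clip([1 - p11 - p10 - p01, p01, p10, p11], 1e-300, 1)
                    total += -2 * np.sum(t.counts * np.log(p))
                grid.append((total, a2, c2))
        _, a2_star, c2_star = min(grid)
        assert comp.a2 == pytest.approx(a2_star, abs=0.01)
        assert comp.c2 == pytest.approx(c2_star, abs=0.01)

    def test_minus2ll_monotone_along_nested_ladder(self, study_analysis):
        from twinace import build_group_tables, fit_model_ladder
        tables = build_group_tables(study_analysis.pairs)
        ladder = fit_model_ladder(tables, ci=False)
        fits = ladder["fits"]
        assert fits["saturated"].minus2ll <= fits["ACE"].minus2ll + 1e-6
        assert fits["ACE"].minus2ll <= fits["AE"].minus2ll + 1e-6
        assert fits["ACE"].minus2ll <= fits["CE"].minus2ll + 1e-6
        assert fits["AE"].minus2ll <= fits["E"].minus2ll + 1e-6
        assert fits["CE"].minus2ll <= fits["E"].minus2ll + 1e-6

    def test_requires_both_zygosities(self):
        tables = {"MZM": GroupTable("MZM", 800, 60, 60, 80, symmetrized=True)}
        with pytest.raises(ValueError, match="MZ and one DZ"):
            fit_variance_model(tables, model="ACE")

    def test_unknown_model_rejected(self):
        tables = exact_group_tables(0.5, 0.2, 1.2, n=100)
        with pytest.raises(ValueError, match="model"):
            fit_variance_model(tables, model="ADE")


class TestLRT:
    def _fit(self, name, m2ll, k):
        return ModelFit(model=name, minus2ll=m2ll, n_parameters=k, df=0,
                        params={}, converged=True)

    def test_self_comparison_is_null(self):
        f = self._fit("ACE", 100.0, 4)
        res = likelihood_ratio_test(f, f)
        assert res.delta_chi2 == 0.0
        assert res.p == 1.0

    def test_chi2_critical_value(self):
        res = likelihood_ratio_test(self._fit("AE", 103.84, 3), self._fit("ACE", 100.0, 4))
        assert res.delta_df == 1
        assert res.p == pytest.approx(0.05, abs=2e-4)

    def test_non_nested_rejected(self):
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(self._fit("ACE", 90.0, 4), self._fit("AE", 100.0, 3))

    def test_tiny_negative_delta_clipped(self):
        res = likelihood_ratio_test(self._fit("AE", 100.0 - 1e-8, 3),
                                    self._fit("ACE", 100.0, 4))
        assert res.delta_chi2 == 0.0


class TestProfileCI:
    def test_interior_interval_matches_wald(self):
        # at a smooth interior optimum, profile interval ~ +-1.96 SE from
        # the local quadratic of the profiled -2LL
        tables = exact_group_tables(a2=0.5, c2=0.3, tau_m=1.0, n=20000)
        comp, fit = fit_variance_model(tables, model="ACE")
        lo, hi, flags = profile_ci(fit, "a2")
        assert not flags["lower_at_boundary"] and not flags["upper_at_boundary"]

        from twinace.liability import _profiled_m2ll, _threshold_index
        tnames, tidx = _threshold_index(tables, "by_sex")
        tau0 = np.array([fit.params["thresholds"][n] for n in tnames])
        h = 0.02
        f0 = fit.minus2ll
        fp = _profiled_m2ll(tables, tidx, len(tnames), tau0, "ACE", "a2", comp.a2 + h)
        fm = _profiled_m2ll(tables, tidx, len(tnames), tau0, "ACE", "a2", comp.a2 - h)
        curv = (fp + fm - 2 * f0) / h**2  # = 2 / SE^2 locally
        se = math.sqrt(2.0 / curv)
        assert (hi - lo) / 2 == pytest.approx(1.96 * se, rel=0.05)

    def test_component_at_zero_is_flagged(self):
        # data generated with no shared environment: c2 estimate sits at 0
        tables = exact_group_tables(a2=0.6, c2=0.0, tau_m=1.0, n=50000)
        comp, fit = fit_variance_model(tables, model="ACE")
        assert comp.c2 == pytest.approx(0.0, abs=1e-4)
        lo, hi, flags = profile_ci(fit, "c2")
        assert lo == 0.0
        assert flags["lower_at_boundary"]

    def test_invalid_component_rejected(self):
        tables = exact_group_tables(0.5, 0.2, 1.2, n=1000)
        _, fit = fit_variance_model(tables, model="ACE")
        with pytest.raises(ValueError, match="component"):
            profile_ci(fit, "d2")


class TestImpliedCorrelations:
    def test_study_estimates_imply_mz_097(self):
        comp = VarianceComponents(a2=0.75, c2=0.22, e2=0.03)
        r_mz, r_dz = implied_correlations(comp)
        assert r_mz == pytest.approx(0.97)
        assert r_dz == pytest.approx(0.595)

    def test_pure_nonshared_implies_zero(self):
        assert implied_correlations(VarianceComponents(0.0, 0.0, 1.0)) == (0.0, 0.0)

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            VarianceComponents(a2=0.9, c2=0.3, e2=0.1)
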