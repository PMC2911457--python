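"""Mixture model, deconvolution, adaptive-BH threshold, power curves."""

import numpy as np
import pytest
from scipy import stats

from cnapower import (
    EffectDensity,
    InputError,
    adaptive_bh_threshold,
    deconvolve_effect_density,
    density_G,
    estimate_gamma,
    fit_parametric_alternative,
    nonparametric_G,
    parametric_G,
    power_curve,
    region_tests,
)
from cnapower.power import T_GRID, drop_degenerate

from conftest import make_region_set, two_group_assignment


def _point_mass(theta0: float) -> EffectDensity:
    theta = np.round(np.arange(-10, 10.0001, 0.05), 6)
    w = np.zeros_like(theta)
    w[np.argmin(np.abs(theta - theta0))] = 1.0
    return EffectDensity(theta, w, "deconvolution")


class TestRegionTests:
    def test_welch_example(self):
        # group A = (1,2,3), B = (3,4,5): t = -2/sqrt(2/3) = -2.449,
        # two-sided normal p = 0.01431 (hand-computed)
        rwlr = np.array([[1.0, 2.0, 3.0, 3.0, 4.0, 5.0]] * 25)
        rs = make_region_set(rwlr)
        res = region_tests(rs, two_group_assignment(3, 3))
        assert res.t[0] == pytest.approx(-2.449489, abs=1e-5)
        assert res.p[0] == pytest.approx(0.014306, abs=1e-5)

    def test_identical_groups(self):
        rwlr = np.tile([0.5, 0.7, 0.9, 0.5, 0.7, 0.9], (25, 1))
        res = region_tests(make_region_set(rwlr), two_group_assignment(3, 3))
        assert np.all(res.t == 0)
        assert np.all(res.p == 1)

    def test_zero_variance_unequal_means_warns(self):
        rwlr = np.tile([0.0, 0.0, 1.0, 1.0], (25, 1))
        res = region_tests(make_region_set(rwlr), two_group_assignment(2, 2))
        assert np.all(res.p == 0)
        assert res.warnings
        dropped = drop_degenerate(res)
        assert len(dropped.t) == 0

    def test_null_pvalues_uniform(self, rng):
        rwlr = rng.normal(size=(2000, 30))
        res = region_tests(make_region_set(rwlr), two_group_assignment(15, 15))
        ks = stats.kstest(res.p, "uniform").statistic
        assert ks < 0.04

    def test_group_label_swap_flips_sign_only(self, rng):
        rwlr = rng.normal(size=(50, 12))
        ga = two_group_assignment(6, 6)
        swapped = {s: ("B" if g == "A" else "A") for s, g in ga.mapping.items()}
        from cnapower import GroupAssignment

        res1 = region_tests(make_region_set(rwlr), ga)
        res2 = region_tests(make_region_set(rwlr), GroupAssignment(swapped))
        np.testing.assert_allclose(res1.t, -res2.t)
        np.testing.assert_allclose(res1.p, res2.p)


class TestNonparametricG:
    def test_uniform_pvalues_give_identity(self, rng):
        p = rng.uniform(size=100_000)
        for gamma in (0.2, 0.6, 0.9):
            G = nonparametric_G(p, gamma)
            assert np.max(np.abs(G - T_GRID)) < 0.05

    def test_gamma_zero_is_ecdf(self, rng):
        p = rng.uniform(size=5000) ** 2
        G = nonparametric_G(p, 0.0)
        F = np.searchsorted(np.sort(p), T_GRID, side="right") / len(p)
        assert np.max(np.abs(G - F)) < 1e-9

    def test_mixture_closed_form(self, rng):
        m = 100_000
        n_alt = int(0.2 * m)
        p = np.concatenate(
            [rng.uniform(size=m - n_alt), np.full(n_alt, 0.001)]
        )
        G = nonparametric_G(p, 0.8)
        idx = np.argmin(np.abs(T_GRID - 0.01))
        assert G[idx] == pytest.approx(1.0, abs=0.02)

    def test_monotone_in_unit_interval(self, rng):
        G = nonparametric_G(rng.uniform(size=50), 0.5)
        assert np.all(np.diff(G) >= -1e-12)
        assert G.min() >= 0 and G.max() <= 1

    def test_gamma_one_rejected(self, rng):
        with pytest.raises(InputError):
            nonparametric_G(rng.uniform(size=100), 1.0)


class TestParametricAlternative:
    def test_null_alternative_is_uniform(self):
        G = parametric_G(T_GRID, 0.0, 0.0)
        assert np.max(np.abs(G - T_GRID)) < 1e-12

    def test_closed_form_value(self):
        # G(0.05; a=3, b=0) = 1 - Phi(1.95996 - 3) + Phi(-1.95996 - 3)
        assert parametric_G(np.array([0.05]), 3.0, 0.0)[0] == pytest.approx(
            0.8508, abs=2e-4
        )

    @pytest.mark.parametrize("symmetric", [True, False])
    def test_parameter_recovery(self, symmetric):
        rng = np.random.default_rng(8)
        m, n_alt = 5000, 1000
        t = np.concatenate(
            [rng.standard_normal(m - n_alt), 3.0 + rng.standard_normal(n_alt)]
        )
        a, b, _, _ = fit_parametric_alternative(t, 0.8, symmetric=symmetric)
        assert a == pytest.approx(3.0, abs=0.15)
        assert abs(b) <= 0.2

    def test_sign_balanced_recovery_needs_symmetric(self):
        rng = np.random.default_rng(9)
        signs = rng.choice([-1.0, 1.0], 1000)
        t = np.concatenate(
            [rng.standard_normal(4000), signs * 3.0 + rng.standard_normal(1000)]
        )
        a, b, _, _ = fit_parametric_alternative(t, 0.8, symmetric=True)
        assert a == pytest.approx(3.0, abs=0.2)
        assert abs(b) <= 0.3


class TestEstimateGamma:
    def test_recovery(self):
        rng = np.random.default_rng(41)
        hits = 0
        for _ in range(10):
            m, gamma = 1000, 0.9
            n_alt = m - int(m * gamma)
            theta = rng.normal(3.0, 0.5, n_alt)
            t = np.concatenate(
                [rng.standard_normal(m - n_alt), theta + rng.standard_normal(n_alt)]
            )
            p = 2 * stats.norm.sf(np.abs(t))
            fit = estimate_gamma(t, p)
            hits += 0.85 <= fit.gamma_hat <= 0.95
        assert hits >= 7

    def test_pure_null_flagged_not_crashed(self, rng):
        t = rng.standard_normal(500)
        p = 2 * stats.norm.sf(np.abs(t))
        fit = estimate_gamma(t, p)
        assert not fit.failed
        assert np.isfinite(fit.gof)

    def test_too_few_regions(self, rng):
        t = rng.standard_normal(10)
        with pytest.raises(InputError, match="at least 20"):
            estimate_gamma(t, 2 * stats.norm.sf(np.abs(t)))

    def test_curves_are_proper(self, rng):
        t = np.concatenate([rng.standard_normal(400), 3 + rng.standard_normal(100)])
        fit = estimate_gamma(t, 2 * stats.norm.sf(np.abs(t)))
        for curve in (fit.G_nonparam, fit.G_param):
            assert np.all(np.diff(curve) >= -1e-9)
            assert curve.min() >= -1e-12 and curve.max() <= 1 + 1e-12
        assert fit.gof == pytest.approx(
            np.max(np.abs(fit.G_nonparam - fit.G_param)), abs=1e-12
        )


class TestDeconvolution:
    def test_point_mass_recovery(self):
        rng = np.random.default_rng(2)
        m, n_alt = 20_000, 4000
        t = np.concatenate(
            [rng.standard_normal(m - n_alt), 3.0 + rng.standard_normal(n_alt)]
        )
        lam = deconvolve_effect_density(t, 0.8)
        assert lam.mean() == pytest.approx(3.0, abs=0.1)
        assert lam.sd() <= 0.5

    def test_normal_density_recovery(self):
        rng = np.random.default_rng(5)
        m, n_alt = 20_000, 4000
        theta = rng.normal(2.0, 1.0, n_alt)
        t = np.concatenate(
            [rng.standard_normal(m - n_alt), theta + rng.standard_normal(n_alt)]
        )
        lam = deconvolve_effect_density(t, 0.8)
        assert lam.mean() == pytest.approx(2.0, abs=0.15)

    def test_null_limit_concentrates_near_zero(self, rng):
        t = rng.standard_normal(5000)
        lam = deconvolve_effect_density(t, 0.9)
        assert abs(lam.mean()) < 0.5

    def test_no_alternative_mass_rejected(self, rng):
        t = rng.standard_normal(100)
        with pytest.raises(InputError, match="alternative mass"):
            deconvolve_effect_density(t, 0.995)

    def test_weights_are_distribution(self, rng):
        t = np.concatenate([rng.standard_normal(800), 2 + rng.standard_normal(200)])
        lam = deconvolve_effect_density(t, 0.8)
        assert np.all(lam.weights >= 0)
        assert lam.weights.sum() == pytest.approx(1.0)


class TestAdaptiveBH:
    def test_closed_form_saturated_G(self):
        # G == 1: u* = alpha (1-gamma) / (gamma (1-alpha))
        u = adaptive_bh_threshold(0.9, lambda x: np.ones_like(np.asarray(x, float)), 0.1)
        assert u == pytest.approx(0.012345679, abs=1e-6)

    def test_closed_form_sqrt_G(self):
        u = adaptive_bh_threshold(0.5, lambda x: np.sqrt(np.asarray(x, float)), 0.1)
        assert u == pytest.approx(0.012345679, abs=1e-6)

    def test_no_signal_returns_none(self):
        u = adaptive_bh_threshold(0.5, lambda x: np.asarray(x, float), 0.1)
        assert u is None

    def test_matches_empirical_step_up(self):
        """Asymptotic threshold vs the empirical plug-in BH boundary."""
        rng = np.random.default_rng(12)
        m, gamma, theta = 100_000, 0.9, 3.0
        n_alt = m - int(m * gamma)
        t = np.concatenate(
            [rng.standard_normal(m - n_alt), theta + rng.standard_normal(n_alt)]
        )
        p = np.sort(2 * stats.norm.sf(np.abs(t)))
        alpha = 0.1
        # adaptive step-up: largest k with p_(k) <= k alpha / (gamma m)
        k = np.max(np.flatnonzero(p <= np.arange(1, m + 1) * alpha / (gamma * m)))
        empirical_u = p[k]
        u = adaptive_bh_threshold(gamma, density_G(_point_mass(theta)), alpha)
        assert u == pytest.approx(empirical_u, rel=0.2)


class TestPowerCurve:
    def _fit(self, gamma=0.9):
        from cnapower.power import MixtureFit, GAMMA_GRID

        return MixtureFit(
            gamma, 3.0, 0.0, T_GRID, T_GRID, T_GRID, GAMMA_GRID,
            np.zeros_like(GAMMA_GRID), 0.01,
        )

    def test_monotone_and_bounded(self):
        curve = power_curve(self._fit(), _point_mass(3.0), 15, 15, alpha=0.1)
        pw = curve.table["avg_power"].to_numpy()
        assert np.all(np.diff(pw) >= -1e-9)
        assert np.all((pw >= 0) & (pw <= 1))
        assert not curve.flat_line

    def test_large_n_saturates(self):
        curve = power_curve(
            self._fit(), _point_mass(1.0), 15, 15,
            candidate_sizes=[2, 500, 5000], alpha=0.1,
        )
        assert curve.table["avg_power"].iloc[-1] > 0.99

    def test_pilot_scaling_factor(self):
        curve = power_curve(self._fit(), _point_mass(3.0), 15, 15)
        row = curve.table[curve.table["n"] == 15].iloc[0]
        assert row["s"] == pytest.approx(1.0)
        assert curve.pilot_equivalent_n == pytest.approx(15.0)

    def test_monte_carlo_oracle_at_pilot(self):
        """Pi at the pilot size matches empirical adaptive BH on simulated
        p-values (point mass theta=3, gamma=0.9, alpha=0.1)."""
        gamma, theta, alpha = 0.9, 3.0, 0.1
        curve = power_curve(
            self._fit(gamma), _point_mass(theta), 15, 15,
            candidate_sizes=[15], alpha=alpha,
        )
        pi_model = float(curve.table["avg_power"].iloc[0])

        rng = np.random.default_rng(3)
        m = 100_000
        n_alt = m - int(m * gamma)
        is_alt = np.zeros(m, bool)
        is_alt[m - n_alt:] = True
        t = np.where(is_alt, theta + rng.standard_normal(m), rng.standard_normal(m))
        p = 2 * stats.norm.sf(np.abs(t))
        order = np.argsort(p)
        ps = p[order]
        k = np.max(np.flatnonzero(ps <= np.arange(1, m + 1) * alpha / (gamma * m)))
        rejected = p <= ps[k]
        pi_emp = (rejected & is_alt).sum() / n_alt
        assert pi_model == pytest.approx(pi_emp, abs=0.02)

    def test_failed_fit_gives_flat_line(self):
        from cnapower.power import MixtureFit, GAMMA_GRID

        failed = MixtureFit(
            float("nan"), float("nan"), float("nan"), T_GRID,
            np.zeros_like(T_GRID), np.zeros_like(T_GRID), GAMMA_GRID,
            np.full(len(GAMMA_GRID), np.inf), float("inf"), failed=True,
        )
        curve = power_curve(failed, None, 15, 15)
        assert curve.flat_line
        assert np.all(curve.table["avg_power"] == 0)

    def test_unbalanced_pilot_effective_size(self):
        curve = power_curve(self._fit(), _point_mass(3.0), 10, 40,
                            candidate_sizes=[16])
        # h0 = (1/10 + 1/40)^-1 = 8; n = 16 gives s = 1
        assert curve.table["s"].iloc[0] == pytest.approx(1.0)
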