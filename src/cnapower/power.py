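"""The statistical core: mixture model, effect-size density, average power.

Each region is tested for a group difference with a Welch t statistic on
its region-wise log ratios, with two-sided p-values taken from the standard
normal.  Under the null a region's p-value is uniform; differentially
behaving regions contribute an unknown p-value distribution G.  With
gamma the proportion of non-differential regions, the observed p-values
follow the mixture  F(t) = gamma * t + (1 - gamma) * G(t).

Two estimators of G are computed for a candidate gamma: a non-parametric
one obtained by inverting the mixture on the empirical CDF, and a
parametric one that assumes the alternative t statistics are
N(a, 1 + b^2), i.e. noncentralities theta ~ N(a, b^2) on top of unit
sampling noise.  The two estimators drift apart as gamma moves away from
its true value, so gamma is estimated by minimizing their discrepancy.
The limiting density of effect sizes (lambda) is then recovered from the
t statistics by characteristic-function deconvolution.

For a candidate per-group sample size n the noncentralities scale by
s = sqrt((n/2) / h0) with h0 = (1/n_A + 1/n_B)^-1 the pilot's effective
size.  The rejection threshold u* is the largest u whose plug-in FDR
    gamma * u / (gamma * u + (1 - gamma) * G_n(u))
stays below the nominal level (an asymptotic, adaptive Benjamini-Hochberg
rule), and the average power is Pi(n) = G_n(u*).  When no threshold
satisfies the bound the curve is zero: the flat-line failure state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.isotonic import IsotonicRegression

from .io import GroupAssignment, InputError, RegionSet, logger

GAMMA_GRID = np.round(np.arange(0.50, 0.9951, 0.005), 4)
T_GRID = np.linspace(0.001, 1.0, 1000)
_U_GRID = np.logspace(-8, 0, 400)


# ---------------------------------------------------------------------------
# region-wise tests
# ---------------------------------------------------------------------------

@dataclass
class TestResult:
    """Welch statistics and normal p-values per region."""

    table: pd.DataFrame            # t, p, mean_a, mean_b, var_a, var_b
    warnings: list[str] = field(default_factory=list)

    @property
    def t(self) -> np.ndarray:
        return self.table["t"].to_numpy()

    @property
    def p(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def region_tests(regions: RegionSet, groups: GroupAssignment) -> TestResult:
    """Welch's t-test per region, p-values from the standard normal.

    t = (mean_A - mean_B) / sqrt(s2_A/n_A + s2_B/n_B) with unbiased group
    variances; p = 2 * (1 - Phi(|t|)).  A region with zero variance in both
    groups gets t = 0, p = 1 if the means agree, else p = 0 with a warning.
    """
    ia, ib = groups.indices(regions.sample_ids)
    if len(ia) < 2 or len(ib) < 2:
        raise InputError("each group needs at least 2 samples")
    xa, xb = regions.rwlr[:, ia], regions.rwlr[:, ib]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    var_a = xa.var(axis=1, ddof=1)
    var_b = xb.var(axis=1, ddof=1)
    se = np.sqrt(var_a / len(ia) + var_b / len(ib))
    warnings: list[str] = []
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (mean_a - mean_b) / se
    degenerate = se == 0
    equal = degenerate & (mean_a == mean_b)
    t[equal] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(t))
    p[equal] = 1.0
    unequal = degenerate & ~equal
    if unequal.any():
        warnings.append(
            f"{int(unequal.sum())} zero-variance regions with unequal means (p=0)"
        )
        p[unequal] = 0.0
    table = pd.DataFrame(
        {
            "t": t, "p": p, "mean_a": mean_a, "mean_b": mean_b,
            "var_a": var_a, "var_b": var_b,
        }
    )
    return TestResult(table, warnings)


def drop_degenerate(tests: TestResult) -> TestResult:
    """Remove zero-variance regions before mixture fitting.

    Their degenerate p-values of exactly 0 or 1 carry no usable signal and
    would distort the mixture fit.
    """
    keep = (tests.table["var_a"] + tests.table["var_b"]) > 0
    n_drop = int((~keep).sum())
    warnings = list(tests.warnings)
    if n_drop:
        warnings.append(f"dropped {n_drop} zero-variance regions before fitting")
        logger.warning("dropped %d zero-variance regions before fitting", n_drop)
    return TestResult(tests.table[keep].reset_index(drop=True), warnings)


# ---------------------------------------------------------------------------
# G estimators
# ---------------------------------------------------------------------------

def nonparametric_G(
    pvals: np.ndarray, gamma: float, t_grid: np.ndarray = T_GRID
) -> np.ndarray:
    """Mixture-inverted empirical CDF estimate of G on ``t_grid``.

    G_hat(t) = (F_hat(t) - gamma * t) / (1 - gamma), clipped to [0, 1] and
    monotonized by isotonic regression (pool-adjacent-violators).
    """
    if not 0 <= gamma < 1:
        raise InputError("gamma must lie in [0, 1) for the mixture inversion")
    pvals = np.asarray(pvals, dtype=float)
    if len(pvals) < 10:
        raise InputError("need at least 10 p-values")
    sorted_p = np.sort(pvals)
    F = np.searchsorted(sorted_p, t_grid, side="right") / len(pvals)
    G = np.clip((F - gamma * t_grid) / (1.0 - gamma), 0.0, 1.0)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")
    return iso.fit_transform(t_grid, G)


def parametric_G(
    t_grid: np.ndarray, a: float, b: float
) -> np.ndarray:
    """P-value CDF implied by alternative t ~ N(a, 1 + b^2).

    G(t) = 1 - Phi((c_t - a)/v) + Phi((-c_t - a)/v),  c_t = Phi^-1(1 - t/2).
    """
    v = np.sqrt(1.0 + b * b)
    c = stats.norm.isf(np.asarray(t_grid) / 2.0)
    return stats.norm.sf((c - a) / v) + stats.norm.cdf((-c - a) / v)


def fit_parametric_alternative(
    tstats: np.ndarray,
    gamma: float,
    t_grid: np.ndarray = T_GRID,
    x0: tuple[float, float] | None = None,
    symmetric: bool = True,
) -> tuple[float, float, np.ndarray, bool]:
    """Fixed-gamma maximum-likelihood fit of the normal alternative.

    The t statistics are modelled as gamma N(0,1) plus a (1-gamma)
    alternative with noncentrality magnitude a and spread b: by default the
    sign-balanced mixture 0.5 N(a, 1+b^2) + 0.5 N(-a, 1+b^2), since copy
    number differences comprise both gains and losses; ``symmetric=False``
    fits a single N(a, 1+b^2) instead.  Both imply the same two-sided
    p-value distribution G.  Returns (a, b, G curve on ``t_grid``,
    converged).
    """
    t = np.asarray(tstats, dtype=float)
    null_pdf = np.exp(-0.5 * t * t) / np.sqrt(2.0 * np.pi)

    def nll(params: np.ndarray) -> float:
        a, b = params
        v2 = 1.0 + b * b
        if symmetric:
            alt_pdf = (
                np.exp(-0.5 * (t - a) ** 2 / v2)
                + np.exp(-0.5 * (t + a) ** 2 / v2)
            ) / (2.0 * np.sqrt(2.0 * np.pi * v2))
        else:
            alt_pdf = np.exp(-0.5 * (t - a) ** 2 / v2) / np.sqrt(
                2.0 * np.pi * v2
            )
        mix = gamma * null_pdf + (1.0 - gamma) * alt_pdf
        return -np.sum(np.log(np.maximum(mix, 1e-300)))

    if x0 is not None:
        starts = [x0]          # warm start along the gamma grid
    else:
        tail = t[np.abs(t) > 2]
        moment_a = float(tail.mean()) if len(tail) else float(t.mean())
        starts = [(moment_a, 1.0), (0.0, 1.0)]

    best = None
    for s0 in starts:
        res = optimize.minimize(
            nll, np.asarray(s0, dtype=float), method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-8, "maxiter": 400},
        )
        if best is None or res.fun < best.fun:
            best = res
    a, b = float(best.x[0]), abs(float(best.x[1]))
    if symmetric:
        a = abs(a)             # sign not identified in the balanced mixture
    return a, b, parametric_G(t_grid, a, b), bool(best.success)


# ---------------------------------------------------------------------------
# gamma estimation by dual-estimator discrepancy
# ---------------------------------------------------------------------------

@dataclass
class MixtureFit:
    """Estimated uniform + G mixture for one data set."""

    gamma_hat: float
    a: float
    b: float
    t_grid: np.ndarray
    G_nonparam: np.ndarray         # at gamma_hat
    G_param: np.ndarray            # at gamma_hat
    gamma_grid: np.ndarray
    discrepancy: np.ndarray        # D(gamma) profile
    gof: float                     # D(gamma_hat)
    warnings: list[str] = field(default_factory=list)
    failed: bool = False

    @property
    def v(self) -> float:
        return float(np.sqrt(1.0 + self.b * self.b))


def estimate_gamma(
    tstats: np.ndarray,
    pvals: np.ndarray,
    gamma_grid: np.ndarray = GAMMA_GRID,
    t_grid: np.ndarray = T_GRID,
    metric: str = "sup",
    symmetric: bool = True,
) -> MixtureFit:
    """Estimate the null proportion gamma and the alternative (a, b).

    For every gamma on the grid both G estimators are computed and their
    distance D(gamma) recorded (sup-norm over the t grid by default, L2 as
    an option).  The estimate is the gamma minimizing D, ties broken toward
    the smallest gamma.  Warnings flag gamma_hat > 0.95 (too close to 1 for
    reliable estimation) and D(gamma_hat) > 0.10 (poor goodness-of-fit).

    Candidate gammas are first screened by the mixture's feasibility bound:
    G <= 1 forces F(t) <= gamma t + (1 - gamma) for every t, hence
    gamma <= (1 - F(t)) / (1 - t).  Gammas above the minimum of this bound
    over the ECDF (plus a ~2/sqrt(m) sampling allowance) would require more
    than unit alternative mass; the clipped G estimator hides that excess,
    so without the screen the discrepancy can degenerate at the upper grid
    edge when the signal is strong.
    """
    t = np.asarray(tstats, dtype=float)
    p = np.asarray(pvals, dtype=float)
    if len(t) < 20:
        raise InputError("need at least 20 regions to fit the mixture")

    sorted_p = np.sort(p)
    F = np.searchsorted(sorted_p, t_grid, side="right") / len(p)
    iso = IsotonicRegression(y_min=0.0, y_max=1.0, out_of_bounds="clip")

    window = (t_grid >= 0.05) & (t_grid <= 0.95)
    band = 2.0 / np.sqrt(len(p))
    feasible_max = float(
        np.min((1.0 - F[window] + band) / (1.0 - t_grid[window]))
    )
    gamma_grid = gamma_grid[gamma_grid <= max(feasible_max, float(gamma_grid[0]))]

    D = np.full(len(gamma_grid), np.inf)
    fits: list[tuple[float, float, np.ndarray, np.ndarray]] = []
    warm: tuple[float, float] | None = None
    any_converged = False
    for gi, gamma in enumerate(gamma_grid):
        a, b, Gp, ok = fit_parametric_alternative(
            t, float(gamma), t_grid, warm, symmetric
        )
        warm = (a, b)
        any_converged = any_converged or ok
        Gn = iso.fit_transform(
            t_grid, np.clip((F - gamma * t_grid) / (1.0 - gamma), 0.0, 1.0)
        )
        if metric == "sup":
            D[gi] = float(np.max(np.abs(Gn - Gp)))
        elif metric == "l2":
            D[gi] = float(np.sqrt(np.trapezoid((Gn - Gp) ** 2, t_grid)))
        else:
            raise InputError(f"unknown discrepancy metric {metric!r}")
        fits.append((a, b, Gn, Gp))

    warnings: list[str] = []
    if not any_converged:
        logger.warning("mixture estimation failed: no converged fit")
        return MixtureFit(
            float("nan"), float("nan"), float("nan"), t_grid,
            np.zeros_like(t_grid), np.zeros_like(t_grid), gamma_grid, D,
            float("inf"), ["estimation failure: no converged fit"], failed=True,
        )

    best = int(np.argmin(D))    # ties resolve to the smallest gamma
    gamma_hat = float(gamma_grid[best])
    a, b, Gn, Gp = fits[best]
    if gamma_hat > 0.95:
        warnings.append(
            f"gamma_hat = {gamma_hat:.3f} > 0.95: too close to 1 for "
            "reliable estimation"
        )
    if D[best] > 0.10:
        warnings.append(
            f"poor goodness-of-fit: sup-distance {D[best]:.3f} > 0.10"
        )
    return MixtureFit(
        gamma_hat, a, b, t_grid, Gn, Gp, gamma_grid, D, float(D[best]), warnings
    )


# ---------------------------------------------------------------------------
# effect-size density by deconvolution
# ---------------------------------------------------------------------------

@dataclass
class EffectDensity:
    """Discrete density of noncentralities theta on the pilot scale."""

    theta: np.ndarray
    weights: np.ndarray            # non-negative, sum to 1
    provenance: str                # "deconvolution" or "parametric-fallback"

    def mean(self) -> float:
        return float(np.sum(self.theta * self.weights))

    def sd(self) -> float:
        mu = self.mean()
        return float(np.sqrt(np.sum((self.theta - mu) ** 2 * self.weights)))


def deconvolve_effect_density(
    tstats: np.ndarray,
    gamma_hat: float,
    a: float = 0.0,
    b: float = 1.0,
    theta_grid: np.ndarray | None = None,
    max_iter: int = 1000,
    tol: float = 1e-9,
) -> EffectDensity:
    """Deconvolve the effect-size density from the t statistics.

    Under the mixture model the t statistics have density
    gamma phi(t) + (1-gamma) integral phi(t - theta) lambda(theta) dtheta,
    a Gaussian convolution of the unknown effect density lambda.  lambda is
    recovered as the nonparametric maximum-likelihood mixing density on the
    theta grid, computed by expectation-maximization with gamma held at its
    estimate (the classical NPMLE of a mixing distribution, which enforces
    non-negativity and unit mass by construction).  Observations are
    pooled into fine bins first, which leaves the likelihood essentially
    unchanged but makes the iteration cost independent of m.

    If the result is degenerate (>= 99% of the mass in a single grid cell)
    the parametric density N(a, b^2) from the mixture fit is returned
    instead, flagged as the fallback.
    """
    t = np.asarray(tstats, dtype=float)
    m = len(t)
    if not 0 < gamma_hat < 1 or gamma_hat >= 1.0 - 1.0 / m:
        raise InputError(
            f"gamma_hat = {gamma_hat} leaves no alternative mass for m = {m}"
        )
    if theta_grid is None:
        theta_grid = np.round(np.arange(-10.0, 10.0 + 1e-9, 0.05), 6)

    counts, edges = np.histogram(
        t, bins=2000, range=(t.min() - 0.05, t.max() + 0.05)
    )
    x = 0.5 * (edges[:-1] + edges[1:])
    nonzero = counts > 0
    x, counts = x[nonzero], counts[nonzero].astype(float)
    kernel = stats.norm.pdf(x[:, None] - theta_grid[None, :])
    null_part = gamma_hat * stats.norm.pdf(x)

    weights = np.full(len(theta_grid), 1.0 / len(theta_grid))
    ll_old = -np.inf
    for _ in range(max_iter):
        mix = np.maximum(null_part + (1.0 - gamma_hat) * (kernel @ weights), 1e-300)
        ll = float(counts @ np.log(mix))
        if ll - ll_old < tol * abs(ll):
            break
        ll_old = ll
        responsibility = (counts / mix)[:, None] * kernel * weights[None, :]
        new = responsibility.sum(axis=0)
        weights = new / new.sum()

    total = float(weights.sum())
    degenerate = total <= 0 or weights.max() / total >= 0.99
    if degenerate:
        logger.warning(
            "deconvolved density degenerate; falling back to parametric N(a, b^2)"
        )
        if b > 1e-8:
            weights = stats.norm.pdf(theta_grid, loc=a, scale=b)
        else:
            weights = np.zeros_like(theta_grid)
            weights[int(np.argmin(np.abs(theta_grid - a)))] = 1.0
        return EffectDensity(theta_grid, weights / weights.sum(), "parametric-fallback")
    return EffectDensity(theta_grid, weights / total, "deconvolution")


def density_G(lam: EffectDensity, scale: float = 1.0):
    """P-value CDF implied by an effect density, noncentralities scaled by
    ``scale``: G(t) = sum_k w_k [1 - Phi(c_t - s theta_k) + Phi(-c_t - s theta_k)].
    Returns a vectorized callable."""
    theta = scale * lam.theta
    w = lam.weights

    def G(t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        c = stats.norm.isf(t_arr / 2.0)
        out = (
            stats.norm.sf(c[:, None] - theta[None, :])
            + stats.norm.cdf(-c[:, None] - theta[None, :])
        ) @ w
        return out if np.ndim(t) else float(out[0])

    return G


# ---------------------------------------------------------------------------
# adaptive BH threshold and power extrapolation
# ---------------------------------------------------------------------------

def adaptive_bh_threshold(gamma: float, G, alpha: float) -> float | None:
    """Asymptotic plug-in threshold of the adaptive Benjamini-Hochberg rule.

    u* = sup{u in (0, 1] : gamma u / (gamma u + (1-gamma) G(u)) <= alpha},
    located on a log-spaced grid (1e-8..1, 400 points) and refined by
    bisection to relative tolerance 1e-6.  Returns None when the bound
    fails everywhere (flat-line condition).
    """
    if not 0 < alpha < 1:
        raise InputError("alpha must lie in (0, 1)")

    def fdr(u: np.ndarray) -> np.ndarray:
        g = np.maximum(np.asarray(G(u), dtype=float), 0.0)
        return gamma * u / (gamma * u + (1.0 - gamma) * g)

    ok = fdr(_U_GRID) <= alpha
    if not ok.any():
        return None
    i = int(np.flatnonzero(ok)[-1])
    if i == len(_U_GRID) - 1:
        return 1.0
    lo, hi = _U_GRID[i], _U_GRID[i + 1]
    while (hi - lo) / lo > 1e-6:
        mid = np.sqrt(lo * hi)
        if fdr(np.array([mid]))[0] <= alpha:
            lo = mid
        else:
            hi = mid
    return float(lo)


@dataclass
class PowerCurve:
    """Average power versus per-group sample size at fixed FDR."""

    table: pd.DataFrame            # n, s, u_star, avg_power
    fdr_level: float
    pilot_h0: float                # effective pilot size (1/n_A + 1/n_B)^-1
    flat_line: bool

    @property
    def pilot_equivalent_n(self) -> float:
        """Balanced per-group size with the pilot's effective size."""
        return 2.0 * self.pilot_h0


def power_curve(
    fit: MixtureFit,
    lam: EffectDensity | None,
    n_a: int,
    n_b: int,
    candidate_sizes: list[int] | None = None,
    alpha: float = 0.10,
) -> PowerCurve:
    """Average power Pi(n) for balanced candidate designs of n per group.

    The pilot's effective size is h0 = (1/n_A + 1/n_B)^-1; a candidate
    balanced design scales every noncentrality by s = sqrt((n/2)/h0).  For
    each n the adaptive-BH threshold u*(n) is computed from gamma_hat and
    the scaled G; Pi(n) = G_n(u*(n)), or 0 when no threshold exists.  An
    estimation-failure fit, or a curve with no rejection threshold at any
    n, is flagged as a flat line.
    """
    if candidate_sizes is None:
        candidate_sizes = list(range(2, 101))
    h0 = 1.0 / (1.0 / n_a + 1.0 / n_b)
    rows = []
    if fit.failed or lam is None:
        for n in candidate_sizes:
            rows.append((n, float(np.sqrt((n / 2.0) / h0)), np.nan, 0.0))
        table = pd.DataFrame(rows, columns=["n", "s", "u_star", "avg_power"])
        return PowerCurve(table, alpha, h0, flat_line=True)

    for n in candidate_sizes:
        s = float(np.sqrt((n / 2.0) / h0))
        G = density_G(lam, scale=s)
        u = adaptive_bh_threshold(fit.gamma_hat, G, alpha)
        pi = float(G(u)) if u is not None else 0.0
        rows.append((n, s, u if u is not None else np.nan, pi))
    table = pd.DataFrame(rows, columns=["n", "s", "u_star", "avg_power"])
    # a curve that never exceeds 0.1% average power is indistinguishable
    # from "no rejection threshold anywhere" and is flagged the same way
    flat = bool(np.all(table["avg_power"].to_numpy() <= 1e-3))
    if flat:
        logger.warning("no rejection threshold at any candidate size: flat line")
    return PowerCurve(table, alpha, h0, flat_line=flat)
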