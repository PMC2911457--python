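"""Assessment instruments for judging whether power estimates are trustworthy.

The power extrapolation rests on assumptions that real data sets violate
often enough that every run should be inspected: the null proportion gamma
must be substantially below 1, the p-value density should rise toward 0 and
be convex, and the RWLRs should be roughly normal within groups.  This
module provides the corresponding instruments: agreement of the two G
estimators (goodness-of-fit), the binned p-value density with a convexity
check, skewness/kurtosis of group-centered RWLRs against a Monte-Carlo
normal reference, and the pilot-consistency resampling study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import AnalysisConfig, GroupAssignment, InputError, LogRatioMatrix, RegionSet, logger
from .power import MixtureFit

GRADES = ("satisfactory", "mediocre", "failed")


# ---------------------------------------------------------------------------
# goodness of fit
# ---------------------------------------------------------------------------

@dataclass
class GofTable:
    """Both G estimators tabulated on the shared t grid, with a grade."""

    table: pd.DataFrame            # t, G_nonparam, G_param
    gof: float                     # sup-distance at gamma_hat
    grade: str                     # satisfactory / mediocre / failed


def gof_table(fit: MixtureFit, flat_line: bool = False) -> GofTable:
    """Tabulate the two G estimators and grade their agreement.

    Grades: satisfactory (sup-distance <= 0.10), mediocre (<= 0.15), failed
    (> 0.15, an estimation failure, or a flat-line power curve).  The
    cutoffs are calibrated so that a well-specified strong-signal fit at
    around a thousand regions grades satisfactory despite the sampling
    noise of the mixture-inverted ECDF, which is amplified by
    1 / (1 - gamma).
    """
    if fit.failed:
        return GofTable(
            pd.DataFrame(columns=["t", "G_nonparam", "G_param"]),
            float("inf"), "failed",
        )
    table = pd.DataFrame(
        {"t": fit.t_grid, "G_nonparam": fit.G_nonparam, "G_param": fit.G_param}
    )
    if flat_line or fit.gof > 0.15:
        grade = "failed"
    elif fit.gof > 0.10:
        grade = "mediocre"
    else:
        grade = "satisfactory"
    return GofTable(table, fit.gof, grade)


# ---------------------------------------------------------------------------
# p-value density
# ---------------------------------------------------------------------------

@dataclass
class DensityTable:
    """Binned p-value density with convexity and low-p enrichment."""

    edges: np.ndarray
    density: np.ndarray
    smoothed: np.ndarray
    convex: bool
    enrichment: float              # mean density on [0, 0.1] / uniform's 1


def pvalue_density(
    pvals: np.ndarray,
    n_bins: int = 20,
    convex_fraction: float = 0.80,
    convex_tol: float = 0.05,
) -> DensityTable:
    """Histogram density of the p-values on [0, 1].

    A healthy differential signal shows enrichment at small p-values and a
    convex decreasing density; a flat density means no detectable signal
    and a concave/increasing one indicates assumption violations.  The
    convex flag requires (a) at least ``convex_fraction`` of the second
    differences of the 3-bin moving average to be >= -tol and (b) the
    density not to increase from the first to the last smoothed bin beyond
    tol, which rules out rising densities (depleted low p-values) that are
    technically convex but signal failure.  The tolerance is the larger of
    ``convex_tol`` and twice the binomial noise of a smoothed histogram
    bin, so the flag stays calibrated for small region counts.
    """
    p = np.asarray(pvals, dtype=float)
    if len(p) < 20:
        raise InputError("need at least 20 p-values")
    density, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0), density=True)
    smoothed = np.convolve(density, np.ones(3) / 3.0, mode="valid")
    # second difference of a 3-bin average of iid-noise bins: sd ~
    # sqrt(6)/3 times the per-bin binomial sd sqrt(n_bins / m)
    noise = 2.0 * np.sqrt(6.0 * n_bins / len(p)) / 3.0
    tol = max(convex_tol, noise)
    d2 = np.diff(smoothed, n=2)
    mostly_convex = bool(np.mean(d2 >= -tol) >= convex_fraction) if len(d2) else True
    not_rising = bool(smoothed[0] >= smoothed[-1] - tol)
    convex = mostly_convex and not_rising
    low = edges[1:] <= 0.1 + 1e-12
    enrichment = float(density[low].mean()) if low.any() else float("nan")
    return DensityTable(edges, density, smoothed, convex, enrichment)


def density_frame(d: DensityTable) -> pd.DataFrame:
    return pd.DataFrame(
        {"bin_start": d.edges[:-1], "bin_end": d.edges[1:], "density": d.density}
    )


# ---------------------------------------------------------------------------
# RWLR moments
# ---------------------------------------------------------------------------

@dataclass
class MomentDiagnostics:
    """Per-region skewness/kurtosis with Monte-Carlo normal reference bands."""

    table: pd.DataFrame            # region, skewness, kurtosis, flagged
    bands: dict[str, tuple[float, float]]
    n_excluded: int                # zero-variance regions left out


def rwlr_moments(
    regions: RegionSet,
    groups: GroupAssignment,
    rng: np.random.Generator,
    n_reference: int | None = None,
) -> MomentDiagnostics:
    """Skewness g1 and excess kurtosis g2 of group-centered RWLRs.

    Each region's RWLRs are centered at their group means; the pooled
    residuals give g1 = m3 / m2^1.5 and g2 = m4 / m2^2 - 3.  The reference
    band is the 0.5%-99.5% quantile range of the same statistics over
    ``n_reference`` (default 1000 x n_regions) standard-normal samples of
    equal size; regions falling outside either band are flagged.
    """
    ia, ib = groups.indices(regions.sample_ids)
    n = len(ia) + len(ib)
    if n < 4:
        raise InputError("need at least 4 samples for moment diagnostics")
    resid = regions.rwlr.copy()
    resid[:, ia] -= resid[:, ia].mean(axis=1, keepdims=True)
    resid[:, ib] -= resid[:, ib].mean(axis=1, keepdims=True)
    resid = resid[:, np.concatenate([ia, ib])]

    m2 = (resid**2).mean(axis=1)
    keep = m2 > 0
    n_excluded = int((~keep).sum())
    g1, g2 = _moments(resid[keep])

    if n_reference is None:
        n_reference = 1000 * regions.n_regions
    ref_g1 = np.empty(n_reference)
    ref_g2 = np.empty(n_reference)
    done = 0
    while done < n_reference:
        todo = min(20000, n_reference - done)
        draws = rng.standard_normal((todo, n))
        draws[:, : len(ia)] -= draws[:, : len(ia)].mean(axis=1, keepdims=True)
        draws[:, len(ia):] -= draws[:, len(ia):].mean(axis=1, keepdims=True)
        r1, r2 = _moments(draws)
        ref_g1[done: done + todo] = r1
        ref_g2[done: done + todo] = r2
        done += todo
    bands = {
        "skewness": tuple(np.quantile(ref_g1, [0.005, 0.995])),
        "kurtosis": tuple(np.quantile(ref_g2, [0.005, 0.995])),
    }
    flagged = (
        (g1 < bands["skewness"][0]) | (g1 > bands["skewness"][1])
        | (g2 < bands["kurtosis"][0]) | (g2 > bands["kurtosis"][1])
    )
    table = pd.DataFrame(
        {
            "region": np.flatnonzero(keep),
            "skewness": g1,
            "kurtosis": g2,
            "flagged": flagged,
        }
    )
    return MomentDiagnostics(table, bands, n_excluded)


def _moments(resid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    m2 = (resid**2).mean(axis=1)
    m3 = (resid**3).mean(axis=1)
    m4 = (resid**4).mean(axis=1)
    g1 = m3 / m2**1.5
    g2 = m4 / m2**2 - 3.0
    return g1, g2


# ---------------------------------------------------------------------------
# pilot-consistency resampling study
# ---------------------------------------------------------------------------

@dataclass
class ConsistencyResult:
    """Averaged power curves from stratified subsets of the pilot."""

    per_fraction: dict[float, pd.DataFrame]   # fraction -> (n, avg_power)
    n_reps: dict[float, int]
    n_excluded: dict[float, int]
    warnings: list[str] = field(default_factory=list)


def consistency_study(
    matrix: LogRatioMatrix,
    groups: GroupAssignment,
    config: AnalysisConfig,
    fractions: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    reps: int = 10,
    rng: np.random.Generator | None = None,
) -> ConsistencyResult:
    """Re-run the full pipeline on stratified subsets of the pilot.

    For each subset fraction, ``reps`` subsets are drawn without
    replacement (group sizes rounded, at least 2 per group), the pipeline
    is run on each, runs that end in the flat-line failure state are
    excluded, and the surviving power curves are averaged.  Stable averaged
    curves across fractions indicate that a pilot of that size already
    predicts the power of a larger study.
    """
    from .pipeline import analyze_regions   # late import to avoid a cycle
    from .preprocess import preprocess

    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    ids = np.array(matrix.sample_ids)
    ia, ib = groups.indices(matrix.sample_ids)

    per_fraction: dict[float, pd.DataFrame] = {}
    n_excl: dict[float, int] = {}
    n_reps: dict[float, int] = {}
    warnings: list[str] = []
    for f in fractions:
        na = max(2, round(f * len(ia)))
        nb = max(2, round(f * len(ib)))
        curves = []
        excluded = 0
        for _ in range(reps):
            keep = np.concatenate(
                [rng.choice(ia, na, replace=False), rng.choice(ib, nb, replace=False)]
            )
            sub = LogRatioMatrix(
                matrix.probes.copy(), matrix.values[keep], list(ids[keep])
            )
            sub_groups = groups.subset(list(ids[keep]))
            try:
                regions, _, _ = preprocess(
                    sub, config.segmentation, config.calling, config.collapsing, rng
                )
                result = analyze_regions(regions, sub_groups, config)
                curve = result.curve
            except InputError as exc:
                logger.warning("consistency subset failed: %s", exc)
                excluded += 1
                continue
            if curve.flat_line:
                excluded += 1
            else:
                curves.append(curve.table[["n", "avg_power"]])
        n_excl[f] = excluded
        n_reps[f] = reps
        if curves:
            stacked = pd.concat(curves).groupby("n", as_index=False).mean()
            per_fraction[f] = stacked
        else:
            per_fraction[f] = pd.DataFrame(columns=["n", "avg_power"])
            warnings.append(f"all {reps} repetitions failed at fraction {f}")
    return ConsistencyResult(per_fraction, n_reps, n_excl, warnings)
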