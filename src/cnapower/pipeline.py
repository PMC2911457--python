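"""Orchestration of full and power-only runs, with report writing.

``run_pipeline`` ties the stages together: (full mode) normalize, segment,
call and collapse the probe matrix into regions, then (both modes) test
each region, fit the p-value mixture, deconvolve the effect-size density
and extrapolate average power over candidate sample sizes, emitting TSV
tables, a JSON run summary and a plain-text log.  Estimation failures do
not crash a run; they produce a report flagged as a flat line.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diagnostics as diag
from .io import (
    AnalysisConfig,
    CnapowerError,
    GroupAssignment,
    InputError,
    LogRatioMatrix,
    RegionSet,
    logger,
    write_region_matrix,
    write_run_summary,
)
from .power import (
    EffectDensity,
    MixtureFit,
    PowerCurve,
    TestResult,
    deconvolve_effect_density,
    drop_degenerate,
    estimate_gamma,
    power_curve,
    region_tests,
)
from .preprocess import preprocess


@dataclass
class AnalysisResult:
    """Core power-analysis results for one region set."""

    tests: TestResult
    fit: MixtureFit
    lam: EffectDensity | None
    curve: PowerCurve


@dataclass
class PowerReport:
    """Everything a pipeline run produced, plus where it was written."""

    config: AnalysisConfig
    regions: RegionSet
    result: AnalysisResult
    gof: diag.GofTable
    density: diag.DensityTable | None
    moments: diag.MomentDiagnostics | None
    summary: dict
    paths: dict[str, Path]


def _failed_fit(reason: str) -> MixtureFit:
    from .power import T_GRID, GAMMA_GRID

    return MixtureFit(
        float("nan"), float("nan"), float("nan"), T_GRID,
        np.zeros_like(T_GRID), np.zeros_like(T_GRID), GAMMA_GRID,
        np.full(len(GAMMA_GRID), np.inf), float("inf"),
        [f"estimation failure: {reason}"], failed=True,
    )


def analyze_regions(
    regions: RegionSet, groups: GroupAssignment, config: AnalysisConfig
) -> AnalysisResult:
    """Region tests, mixture fit, deconvolution and power extrapolation.

    Estimation failures (too few regions, no alternative mass, no
    convergent fit) yield a flat-line power curve instead of an exception.
    """
    tests = drop_degenerate(region_tests(regions, groups))
    try:
        fit = estimate_gamma(
            tests.t, tests.p, metric=config.discrepancy_metric,
            symmetric=config.alternative == "symmetric",
        )
    except InputError as exc:
        logger.warning("mixture estimation failed: %s", exc)
        fit = _failed_fit(str(exc))

    lam = None
    if not fit.failed:
        try:
            lam = deconvolve_effect_density(
                tests.t, fit.gamma_hat, fit.a, fit.b,
                theta_grid=np.round(
                    np.arange(
                        config.deconvolution.theta_min,
                        config.deconvolution.theta_max + 1e-9,
                        config.deconvolution.theta_step,
                    ),
                    6,
                ),
                max_iter=config.deconvolution.em_max_iter,
                tol=config.deconvolution.em_tol,
            )
        except InputError as exc:
            logger.warning("deconvolution failed: %s", exc)
            fit.warnings.append(f"deconvolution failed: {exc}")

    ia, ib = groups.indices(regions.sample_ids)
    curve = power_curve(
        fit, lam, len(ia), len(ib), config.candidate_sizes, config.fdr_level
    )
    return AnalysisResult(tests, fit, lam, curve)


def run_pipeline(
    config: AnalysisConfig,
    groups: GroupAssignment,
    matrix: LogRatioMatrix | None = None,
    regions: RegionSet | None = None,
    outdir: str | Path | None = None,
) -> PowerReport:
    """Run the full (probe matrix) or power-only (region matrix) pipeline.

    Given a fixed ``config.rng_seed`` and identical inputs the written
    numeric tables are byte-identical across runs.
    """
    rng = np.random.default_rng(config.rng_seed)
    paths: dict[str, Path] = {}
    handler = None
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        logger.addHandler(handler)
        paths["log"] = outdir / "run.log"

    try:
        if config.mode == "full":
            if matrix is None:
                raise InputError("full mode requires a probe matrix")
            try:
                regions, _, _ = preprocess(
                    matrix, config.segmentation, config.calling,
                    config.collapsing, rng,
                )
            except CnapowerError:
                raise
            except Exception as exc:   # pragma: no cover - defensive
                raise CnapowerError(f"preprocessing: {exc}") from exc
        elif regions is None:
            raise InputError("power-only mode requires a region matrix")

        result = analyze_regions(regions, groups, config)
        gof = diag.gof_table(result.fit, result.curve.flat_line)
        density = None
        if len(result.tests.p) >= 20:
            density = diag.pvalue_density(result.tests.p)
        moments = diag.rwlr_moments(regions, groups, rng)

        summary = {
            "mode": config.mode,
            "rng_seed": config.rng_seed,
            "fdr_level": config.fdr_level,
            "n_regions": regions.n_regions,
            "n_a": groups.n_a,
            "n_b": groups.n_b,
            "gamma_hat": result.fit.gamma_hat,
            "a": result.fit.a,
            "b": result.fit.b,
            "v": result.fit.v if not result.fit.failed else float("nan"),
            "gof": result.fit.gof,
            "gof_grade": gof.grade,
            "flat_line": result.curve.flat_line,
            "effect_density_provenance": (
                result.lam.provenance if result.lam is not None else "none"
            ),
            "warnings": result.fit.warnings + result.tests.warnings,
        }
        if result.curve.flat_line:
            logger.warning(
                "power curve is a flat line: estimation failed or no "
                "rejection threshold satisfies the FDR bound"
            )

        if outdir is not None:
            paths.update(_write_outputs(
                outdir, regions, result, gof, density, moments, summary
            ))
        return PowerReport(
            config, regions, result, gof, density, moments, summary, paths
        )
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()


def _write_outputs(
    outdir: Path,
    regions: RegionSet,
    result: AnalysisResult,
    gof: diag.GofTable,
    density: diag.DensityTable | None,
    moments: diag.MomentDiagnostics | None,
    summary: dict,
) -> dict[str, Path]:
    paths: dict[str, Path] = {}

    def _save(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name.removesuffix(".tsv")] = path

    _save("power_curve.tsv", result.curve.table)
    write_region_matrix(regions, outdir / "regions.tsv")
    paths["regions"] = outdir / "regions.tsv"
    _save("region_tests.tsv", result.tests.table)
    _save("gof_curve.tsv", gof.table)
    if density is not None:
        _save("pvalue_density.tsv", diag.density_frame(density))
    if moments is not None:
        _save("rwlr_moments.tsv", moments.table)
    if result.lam is not None:
        _save(
            "effect_density.tsv",
            pd.DataFrame({"theta": result.lam.theta, "weight": result.lam.weights}),
        )
    write_run_summary(summary, outdir / "run_summary.json")
    paths["run_summary"] = outdir / "run_summary.json"
    return paths
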