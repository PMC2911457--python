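"""Probe-level preprocessing: normalization, segmentation, calling, regions.

The chain turns a normalized probe matrix into the testing units of the
method: per-sample profiles are segmented with a clean-room circular binary
segmentation (CBS), segments are called as loss/normal/gain/amplification
by fixed log2-ratio thresholds, call breakpoints shared between most
samples delimit cross-sample *regions*, and each region is summarised per
sample by the median of its normalized log ratios (the region-wise log
ratio, RWLR).  The calls only delineate regions; all downstream statistics
are computed from the RWLRs.

Users who prefer their own segmentation/calling stack can bypass this
module entirely and supply a region-level matrix (power-only mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .io import (
    CallThresholds,
    CollapseParams,
    InputError,
    LogRatioMatrix,
    RegionSet,
    SegParams,
    logger,
)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def median_normalize(matrix: LogRatioMatrix) -> LogRatioMatrix:
    """Subtract each sample's median log ratio (per-sample median becomes 0)."""
    if matrix.n_probes < 1:
        raise InputError("cannot normalize an empty matrix")
    med = np.median(matrix.values, axis=1, keepdims=True)
    if np.isnan(med).any():
        raise InputError("sample with all values missing")
    return LogRatioMatrix(
        matrix.probes.copy(), matrix.values - med, list(matrix.sample_ids)
    )


# ---------------------------------------------------------------------------
# segmentation (clean-room CBS)
# ---------------------------------------------------------------------------

@dataclass
class SegmentedProfile:
    """Per-sample, per-chromosome segments with median levels.

    ``segments`` columns: sample_idx, chrom, start_probe, end_probe
    (global 0-based closed probe indices) and level (median log2 ratio).
    """

    segments: pd.DataFrame
    n_samples: int
    n_probes: int


class _SplitGeometry:
    """Precomputed arc-length factors for one segment.

    The split statistic Z(i, j) compares the mean of arc x[i:j] with the
    mean of its complement, standardized by the segment's standard
    deviation (which is permutation-invariant, so it enters once).  Work is
    organized per arc length: for a fixed length the arc sums of every
    start position come from one shifted difference of the prefix sums.
    """

    def __init__(self, n: int, min_width: int, sd: float) -> None:
        self.n = n
        self.lengths = np.arange(min_width, n - min_width + 1)
        L = self.lengths.astype(float)
        self.inv_L = 1.0 / L
        self.inv_nL = 1.0 / (n - L)
        self.inv_scale = 1.0 / (sd * np.sqrt(1.0 / L + 1.0 / (n - L)))

    def max_stats(self, X: np.ndarray) -> np.ndarray:
        """Max |Z| for each row of a (batch, n) matrix of segment values."""
        P = np.concatenate(
            [np.zeros((X.shape[0], 1)), np.cumsum(X, axis=1)], axis=1
        )
        total = P[:, -1:]
        best = np.zeros(X.shape[0])
        for k, ell in enumerate(self.lengths):
            S = P[:, ell:] - P[:, :-ell]
            Z = np.abs(
                S * self.inv_L[k] - (total - S) * self.inv_nL[k]
            ).max(axis=1) * self.inv_scale[k]
            np.maximum(best, Z, out=best)
        return best

    def argmax_stat(self, x: np.ndarray) -> tuple[float, int, int]:
        P = np.concatenate(([0.0], np.cumsum(x)))
        best, bi, bj = 0.0, 0, 0
        for k, ell in enumerate(self.lengths):
            S = P[ell:] - P[:-ell]
            Z = np.abs(
                S * self.inv_L[k] - (P[-1] - S) * self.inv_nL[k]
            ) * self.inv_scale[k]
            i = int(np.argmax(Z))
            if Z[i] > best:
                best, bi, bj = float(Z[i]), i, i + int(ell)
        return best, bi, bj


def _max_circular_stat(
    x: np.ndarray, min_width: int
) -> tuple[float, int, int, "_SplitGeometry | None"]:
    """Maximal standardized circular split statistic of one segment."""
    n = len(x)
    sd = float(np.std(x))
    # rounding noise in an effectively constant segment must not register
    if sd <= 1e-10 * max(1.0, float(np.abs(x).max())) or n < 2 * min_width:
        return 0.0, 0, 0, None
    geom = _SplitGeometry(n, min_width, sd)
    if len(geom.lengths) == 0:
        return 0.0, 0, 0, None
    stat, i, j = geom.argmax_stat(x)
    return stat, i, j, geom


def _split_p_value(
    x: np.ndarray,
    observed: float,
    geom: _SplitGeometry,
    alpha: float,
    n_permutations: int,
    rng: np.random.Generator,
) -> float:
    """Sequential permutation p-value of the maximal split statistic.

    Permutations run in batches with two early exits: once enough
    exceedances have accrued that the final p-value cannot fall below
    ``alpha``, and once a clean run is long enough that the estimate is
    already decisively below ``alpha``.
    """
    n = len(x)
    reject_at = int(np.ceil(alpha * (n_permutations + 1)))   # p >= alpha certain
    accept_len = min(n_permutations, int(np.ceil(3.0 / alpha)))
    batch = max(1, min(100, 4_000_000 // ((n + 1) * (n + 1))))
    cnt, done = 0, 0
    while done < n_permutations:
        todo = min(batch, n_permutations - done)
        X = rng.permuted(np.tile(x, (todo, 1)), axis=1)
        cnt += int(np.count_nonzero(geom.max_stats(X) >= observed))
        done += todo
        if cnt >= reject_at:
            return (1 + cnt) / (1 + done)
        if cnt == 0 and done >= accept_len:
            return 1.0 / (1 + done)
    return (1 + cnt) / (1 + n_permutations)


def _segment_recursive(
    x: np.ndarray,
    offset: int,
    params: SegParams,
    rng: np.random.Generator,
    out: list[tuple[int, int]],
) -> None:
    n = len(x)
    if n < 2 * params.min_width:
        out.append((offset, offset + n - 1))
        return
    stat, i, j, geom = _max_circular_stat(x, params.min_width)
    if stat == 0.0 or geom is None:
        out.append((offset, offset + n - 1))
        return
    # A Bonferroni bound over all ~n^2/2 arcs caps the p-value of the max
    # statistic; splits far beyond it cannot fail the permutation test at
    # alpha, so the sampling is skipped for them.
    certain = float(sp_stats.norm.isf(params.alpha / (20.0 * n * n)))
    if stat < certain:
        p = _split_p_value(
            x, stat, geom, params.alpha, params.n_permutations, rng
        )
        if p >= params.alpha:
            out.append((offset, offset + n - 1))
            return
    cuts = sorted({c for c in (i, j) if 0 < c < n})
    pieces = [0] + cuts + [n]
    for a, b in zip(pieces, pieces[1:]):
        _segment_recursive(x[a:b], offset + a, params, rng, out)


def segment_sample(
    values: np.ndarray,
    params: SegParams,
    rng: np.random.Generator,
    offset: int = 0,
) -> list[tuple[int, int, float]]:
    """Segment one chromosome's log-ratio vector for one sample.

    Recursive CBS: the two-sample statistic is maximized over all circular
    splits of the current segment and the split is accepted when its
    permutation p-value falls below ``params.alpha``.  Returns
    ``(start, end, level)`` tuples (closed probe indices shifted by
    ``offset``; level is the median of member probes).
    """
    if len(values) < 1:
        raise InputError("cannot segment an empty vector")
    spans: list[tuple[int, int]] = []
    _segment_recursive(np.asarray(values, dtype=float), 0, params, rng, spans)
    spans.sort()
    return [
        (s + offset, e + offset, float(np.median(values[s: e + 1])))
        for s, e in spans
    ]


def segment_matrix(
    matrix: LogRatioMatrix, params: SegParams, rng: np.random.Generator
) -> SegmentedProfile:
    """Segment every sample on every chromosome."""
    rows = []
    slices = matrix.chrom_slices()
    for si in range(matrix.n_samples):
        for chrom, sl in slices.items():
            for s, e, level in segment_sample(
                matrix.values[si, sl], params, rng, offset=sl.start
            ):
                rows.append((si, chrom, s, e, level))
    return SegmentedProfile(
        pd.DataFrame(
            rows,
            columns=["sample_idx", "chrom", "start_probe", "end_probe", "level"],
        ),
        matrix.n_samples,
        matrix.n_probes,
    )


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_segments(seg: SegmentedProfile, thr: CallThresholds) -> np.ndarray:
    """Map segment levels to per-probe calls.

    Codes: -1 loss, 0 normal, +1 gain, +2 amplification.  Thresholds are
    inclusive on the aberrant side (a level exactly at ``gain_min`` is a
    gain).
    """
    calls = np.zeros((seg.n_samples, seg.n_probes), dtype=np.int8)
    levels = seg.segments["level"].to_numpy()
    codes = np.zeros(len(levels), dtype=np.int8)
    codes[levels <= thr.loss_max] = -1
    codes[levels >= thr.gain_min] = 1
    codes[levels >= thr.amp_min] = 2
    for (si, s, e), code in zip(
        seg.segments[["sample_idx", "start_probe", "end_probe"]].itertuples(
            index=False
        ),
        codes,
    ):
        calls[si, s: e + 1] = code
    return calls


# ---------------------------------------------------------------------------
# collapsing into regions
# ---------------------------------------------------------------------------

def collapse_to_regions(
    calls: np.ndarray, chroms: np.ndarray, params: CollapseParams
) -> list[tuple[int, int]]:
    """Collapse probes into regions shared between most of the samples.

    Scanning in genomic order, a new region opens at a chromosome boundary
    or wherever the call vector across samples differs from the current
    region's opening call vector in more than ``ceil(tau * n_samples)``
    samples.  Comparing against the region's opening profile (rather than
    only the adjacent probe) lets boundaries that are slightly misaligned
    across samples still accumulate into a shared breakpoint.  Returns
    closed global probe spans partitioning all probes.
    """
    n_samples, n_probes = calls.shape
    limit = int(np.ceil(params.tau * n_samples))
    spans: list[tuple[int, int]] = []
    start = 0
    ref = calls[:, 0]
    for p in range(1, n_probes):
        if chroms[p] != chroms[p - 1] or int(
            np.count_nonzero(calls[:, p] != ref)
        ) > limit:
            spans.append((start, p - 1))
            start = p
            ref = calls[:, p]
    spans.append((start, n_probes - 1))
    return spans


def compute_rwlr(
    matrix: LogRatioMatrix, spans: list[tuple[int, int]]
) -> RegionSet:
    """Median log ratio of each region in each sample.

    Even probe counts use the midpoint of the two central order statistics.
    """
    if not spans:
        raise InputError("no regions")
    probes = matrix.probes
    rows, rwlr = [], np.empty((len(spans), matrix.n_samples))
    for r, (s, e) in enumerate(spans):
        rows.append(
            (
                int(probes["chrom"].iloc[s]),
                int(probes["start_bp"].iloc[s]),
                int(probes["end_bp"].iloc[e]),
                e - s + 1,
                s,
                e,
            )
        )
        rwlr[r] = np.median(matrix.values[:, s: e + 1], axis=1)
    regions = pd.DataFrame(
        rows,
        columns=["chrom", "start_bp", "end_bp", "n_probes",
                 "start_probe", "end_probe"],
    )
    return RegionSet(regions, rwlr, list(matrix.sample_ids))


# ---------------------------------------------------------------------------
# full chain
# ---------------------------------------------------------------------------

def preprocess(
    matrix: LogRatioMatrix,
    seg_params: SegParams,
    thresholds: CallThresholds,
    collapse_params: CollapseParams,
    rng: np.random.Generator,
) -> tuple[RegionSet, SegmentedProfile, np.ndarray]:
    """Normalize, segment, call and collapse a probe matrix into regions.

    Returns the RegionSet plus the segmentation and call audit trails.
    """
    normalized = median_normalize(matrix)
    seg = segment_matrix(normalized, seg_params, rng)
    calls = call_segments(seg, thresholds)
    spans = collapse_to_regions(
        calls, normalized.probes["chrom"].to_numpy(), collapse_params
    )
    regions = compute_rwlr(normalized, spans)
    logger.info(
        "preprocessing: %d probes -> %d regions", matrix.n_probes, len(spans)
    )
    return regions, seg, calls
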