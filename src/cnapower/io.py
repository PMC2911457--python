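"""File formats, domain containers and configuration.

The pipeline's raw currency is a probe-level matrix of log2 ratios with
genomic annotation (one row per array element, one column per sample),
accompanied by a two-group sample assignment.  After preprocessing the
probes are collapsed into *regions* and summarised as region-wise log
ratios (RWLRs); a region-level matrix can also be supplied directly to run
the power calculations alone ("power-only" mode).

All tabular formats are tab-delimited text with a header row.  Genomic
coordinates are 1-based, fully closed base-pair intervals; only autosomes
1-22 are retained (sex chromosomes are excluded at load time).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("cnapower")

AUTOSOMES = tuple(range(1, 23))
#: chromosome tokens silently removed at load time (with a logged count)
SEX_TOKENS = {"X", "Y", "23", "24", "CHRX", "CHRY"}


class CnapowerError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(CnapowerError):
    """A file does not conform to the expected tabular dialect."""


class InputError(CnapowerError):
    """Inputs are well-formed but violate a contract (sizes, groups...)."""


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class LogRatioMatrix:
    """Probe annotation plus a samples x probes matrix of log2 ratios.

    Attributes
    ----------
    probes
        DataFrame with columns ``probe_id``, ``chrom`` (int, 1-22),
        ``start_bp``, ``end_bp``; sorted by (chrom, start_bp).
    values
        Array of shape ``(n_samples, n_probes)``; finite after loading
        (missing cells are dropped or imputed by :func:`read_probe_matrix`).
    sample_ids
        Column labels, one per row of ``values``.
    """

    probes: pd.DataFrame
    values: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.probes)):
            raise InputError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probes)} probes"
            )
        bad = set(self.probes["chrom"]) - set(AUTOSOMES)
        if bad:
            raise InputError(f"non-autosomal chromosomes present: {sorted(bad)}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def chrom_slices(self) -> dict[int, slice]:
        """Contiguous probe-index slice for each chromosome, genomic order."""
        out: dict[int, slice] = {}
        chroms = self.probes["chrom"].to_numpy()
        for c in np.unique(chroms):
            idx = np.flatnonzero(chroms == c)
            out[int(c)] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def copy(self) -> "LogRatioMatrix":
        return LogRatioMatrix(
            self.probes.copy(), self.values.copy(), list(self.sample_ids)
        )


@dataclass
class GroupAssignment:
    """Two-group sample assignment.

    Group A is the lexicographically smaller label; the ordering only fixes
    the sign of the test statistic and has no effect on two-sided results.
    """

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        labels = sorted(set(self.mapping.values()))
        if len(labels) != 2:
            raise InputError(
                f"exactly two group labels required, got {labels}"
            )
        self.labels: tuple[str, str] = (labels[0], labels[1])
        counts = {lab: sum(1 for v in self.mapping.values() if v == lab)
                  for lab in labels}
        if min(counts.values()) < 2:
            raise InputError(
                f"each group needs >= 2 samples, got counts {counts}"
            )
        self.n_a = counts[labels[0]]
        self.n_b = counts[labels[1]]

    def indices(self, sample_ids: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
        """Row indices of the two groups within ``sample_ids``.

        Raises :class:`InputError` if any sample is unassigned.
        """
        missing = [s for s in sample_ids if s not in self.mapping]
        if missing:
            raise InputError(f"samples missing from group file: {missing}")
        a = np.array([i for i, s in enumerate(sample_ids)
                      if self.mapping[s] == self.labels[0]], dtype=int)
        b = np.array([i for i, s in enumerate(sample_ids)
                      if self.mapping[s] == self.labels[1]], dtype=int)
        return a, b

    def subset(self, sample_ids: Sequence[str]) -> "GroupAssignment":
        return GroupAssignment({s: self.mapping[s] for s in sample_ids})


@dataclass
class RegionSet:
    """Genomic regions and their region-wise log ratios.

    ``regions`` has columns ``chrom``, ``start_bp``, ``end_bp``,
    ``n_probes`` and (when produced by the preprocessing step rather than
    read from file) ``start_probe``/``end_probe`` holding 0-based probe
    index spans.  ``rwlr`` is ``(n_regions, n_samples)``: the median
    normalized log2 ratio of each region's probes in each sample.
    """

    regions: pd.DataFrame
    rwlr: np.ndarray
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.rwlr = np.asarray(self.rwlr, dtype=float)
        if self.rwlr.shape != (len(self.regions), len(self.sample_ids)):
            raise InputError(
                f"rwlr shape {self.rwlr.shape} does not match "
                f"{len(self.regions)} regions x {len(self.sample_ids)} samples"
            )
        if len(self.regions) == 0:
            raise InputError("no regions")
        _check_no_overlap(self.regions)
        if len(self.regions) < 20:
            logger.warning(
                "only %d regions: mixture estimation needs a reasonably "
                "large region count to be stable", len(self.regions)
            )

    @property
    def n_regions(self) -> int:
        return len(self.regions)


def _check_no_overlap(regions: pd.DataFrame) -> None:
    for c, grp in regions.groupby("chrom"):
        g = grp.sort_values("start_bp")
        prev_end = -1
        for s, e in zip(g["start_bp"], g["end_bp"]):
            if e < s:
                raise InputError(f"region with end < start on chromosome {c}")
            if s <= prev_end:
                raise InputError(f"overlapping regions on chromosome {c}")
            prev_end = e


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SegParams:
    """Circular binary segmentation settings."""

    alpha: float = 0.01          # permutation significance per split test
    n_permutations: int = 1000
    min_width: int = 2           # minimum segment length in probes


@dataclass
class CallThresholds:
    """Fixed log2-ratio thresholds mapping segment levels to copy-number calls."""

    loss_max: float = -0.15
    gain_min: float = 0.15
    amp_min: float = 0.90

    def __post_init__(self) -> None:
        if not (self.loss_max < 0 < self.gain_min < self.amp_min):
            raise InputError("call thresholds must satisfy loss < 0 < gain < amp")


@dataclass
class CollapseParams:
    tau: float = 0.10            # tolerated fraction of discordant samples


@dataclass
class DeconvParams:
    theta_min: float = -10.0
    theta_max: float = 10.0
    theta_step: float = 0.05
    em_max_iter: int = 1000
    em_tol: float = 1e-9


@dataclass
class AnalysisConfig:
    """Everything a pipeline run needs besides the data files."""

    mode: str = "full"                       # "full" or "power_only"
    fdr_level: float = 0.10
    candidate_sizes: list[int] = field(default_factory=lambda: list(range(2, 101)))
    rng_seed: int = 0
    segmentation: SegParams = field(default_factory=SegParams)
    calling: CallThresholds = field(default_factory=CallThresholds)
    collapsing: CollapseParams = field(default_factory=CollapseParams)
    deconvolution: DeconvParams = field(default_factory=DeconvParams)
    gamma_grid_step: float = 0.005
    discrepancy_metric: str = "sup"          # "sup" or "l2"
    alternative: str = "symmetric"           # "symmetric" (+-a mixture) or "signed"
    wave_correction: bool = False            # hook only; logs and does nothing

    def __post_init__(self) -> None:
        if not 0 < self.fdr_level < 1:
            raise InputError("fdr_level must lie in (0, 1)")
        sizes = list(self.candidate_sizes)
        if any(n < 2 for n in sizes) or any(
            b <= a for a, b in zip(sizes, sizes[1:])
        ):
            raise InputError("candidate sizes must be >= 2 and strictly increasing")
        if self.mode not in ("full", "power_only"):
            raise InputError(f"unknown mode {self.mode!r}")
        if self.wave_correction:
            logger.warning(
                "wave-pattern correction not implemented; "
                "preprocess externally if needed"
            )


def load_config(path: str | Path) -> AnalysisConfig:
    """Read an :class:`AnalysisConfig` from a YAML file.

    Flat dotted keys (``segmentation.alpha: 0.05``) and nested mappings are
    both accepted; unknown keys raise :class:`FormatError`.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise FormatError("config file must be a mapping")
    nested: dict = {}
    for key, value in raw.items():
        parts = str(key).split(".")
        d = nested
        for p in parts[:-1]:
            d = d.setdefault(p, {})
        if isinstance(value, dict):
            d.setdefault(parts[-1], {}).update(value)
        else:
            d[parts[-1]] = value
    return _config_from_dict(nested)


def _config_from_dict(d: Mapping) -> AnalysisConfig:
    blocks = {
        "segmentation": SegParams,
        "calling": CallThresholds,
        "collapsing": CollapseParams,
        "deconvolution": DeconvParams,
    }
    kwargs: dict = {}
    valid = {f.name for f in dataclasses.fields(AnalysisConfig)}
    for key, value in d.items():
        if key not in valid:
            raise FormatError(f"unknown config key {key!r}")
        if key in blocks:
            sub_valid = {f.name for f in dataclasses.fields(blocks[key])}
            bad = set(value) - sub_valid
            if bad:
                raise FormatError(f"unknown config keys under {key}: {sorted(bad)}")
            kwargs[key] = blocks[key](**value)
        else:
            kwargs[key] = value
    return AnalysisConfig(**kwargs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PROBE_COLS = ["ProbeID", "Chromosome", "Start", "End"]


def _parse_chrom(token: object) -> int | None:
    """Map a chromosome token to 1-22, or None for sex chromosomes."""
    s = str(token).strip()
    if s.upper() in SEX_TOKENS:
        return None
    if s.lower().startswith("chr"):
        s = s[3:]
        if s.upper() in ("X", "Y"):
            return None
    try:
        c = int(s)
    except ValueError:
        raise FormatError(f"unrecognized chromosome token {token!r}") from None
    if c in (23, 24):
        return None
    if c not in AUTOSOMES:
        raise FormatError(f"chromosome {c} outside 1-22")
    return c


def read_probe_matrix(path: str | Path) -> LogRatioMatrix:
    """Load a probe-level log2-ratio matrix from a tab-delimited file.

    Expected columns: ``ProbeID``, ``Chromosome``, ``Start``, ``End``, then
    one numeric column per sample.  Sex-chromosome rows are removed (and
    counted in the log), probes are sorted genomically, and missing cells
    are either dropped with the probe (missing in more than 10% of samples)
    or imputed by the sample's chromosome median.
    """
    df = pd.read_csv(path, sep="\t", dtype={"ProbeID": str, "Chromosome": str})
    missing_cols = [c for c in _PROBE_COLS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"probe matrix missing columns: {missing_cols}")
    sample_ids = [c for c in df.columns if c not in _PROBE_COLS]
    if len(sample_ids) < 2:
        raise InputError("probe matrix must contain at least 2 sample columns")

    chroms = df["Chromosome"].map(_parse_chrom)
    n_sex = int(chroms.isna().sum())
    if n_sex:
        logger.info("excluded %d sex-chromosome probes", n_sex)
        df = df[chroms.notna()]
        chroms = chroms[chroms.notna()]

    probes = pd.DataFrame(
        {
            "probe_id": df["ProbeID"].to_numpy(),
            "chrom": chroms.astype(int).to_numpy(),
            "start_bp": pd.to_numeric(df["Start"]).astype(int).to_numpy(),
            "end_bp": pd.to_numeric(df["End"]).astype(int).to_numpy(),
        }
    )
    try:
        values = df[sample_ids].apply(pd.to_numeric).to_numpy(dtype=float).T
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric log-ratio cell: {exc}") from exc

    order = np.lexsort((probes["start_bp"].to_numpy(), probes["chrom"].to_numpy()))
    probes = probes.iloc[order].reset_index(drop=True)
    values = values[:, order]

    values, probes = _handle_missing(values, probes)
    return LogRatioMatrix(probes, values, sample_ids)


def _handle_missing(
    values: np.ndarray, probes: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Drop probes missing in >10% of samples, impute the rest by the
    sample's chromosome median."""
    miss = np.isnan(values)
    if not miss.any():
        return values, probes
    frac = miss.mean(axis=0)
    keep = frac <= 0.10
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropped %d probes missing in >10%% of samples", n_drop)
        values = values[:, keep]
        probes = probes[keep].reset_index(drop=True)
        miss = np.isnan(values)
    if miss.any():
        logger.info("imputed %d missing cells by chromosome median", int(miss.sum()))
        chroms = probes["chrom"].to_numpy()
        for c in np.unique(chroms):
            sel = chroms == c
            block = values[:, sel]
            med = np.nanmedian(block, axis=1, keepdims=True)
            block = np.where(np.isnan(block), med, block)
            values[:, sel] = block
    if np.isnan(values).any():
        raise InputError("sample with all values missing on a chromosome")
    return values, probes


def write_probe_matrix(matrix: LogRatioMatrix, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "ProbeID": matrix.probes["probe_id"],
            "Chromosome": matrix.probes["chrom"],
            "Start": matrix.probes["start_bp"],
            "End": matrix.probes["end_bp"],
        }
    )
    for i, s in enumerate(matrix.sample_ids):
        out[s] = matrix.values[i]
    out.to_csv(path, sep="\t", index=False)


def read_groups(path: str | Path) -> GroupAssignment:
    """Load a two-column (sample id, group label) assignment table."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("group file needs two columns: sample id, group")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    ga = GroupAssignment(mapping)
    logger.info(
        "groups: %s (%d) vs %s (%d)", ga.labels[0], ga.n_a, ga.labels[1], ga.n_b
    )
    return ga


def write_groups(groups: GroupAssignment, path: str | Path) -> None:
    pd.DataFrame(
        {"Sample": list(groups.mapping), "Group": list(groups.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


_REGION_COLS = ["Chromosome", "Start", "End", "NProbes"]


def read_region_matrix(path: str | Path) -> RegionSet:
    """Load a preprocessed region-level matrix (power-only mode).

    Columns: ``Chromosome``, ``Start``, ``End``, ``NProbes``, then one RWLR
    column per sample.
    """
    df = pd.read_csv(path, sep="\t")
    missing_cols = [c for c in _REGION_COLS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"region matrix missing columns: {missing_cols}")
    if len(df) == 0:
        raise InputError("no regions")
    sample_ids = [c for c in df.columns if c not in _REGION_COLS]
    if len(sample_ids) < 2:
        raise InputError("region matrix must contain at least 2 sample columns")
    regions = pd.DataFrame(
        {
            "chrom": df["Chromosome"].map(_parse_chrom).astype(int),
            "start_bp": df["Start"].astype(int),
            "end_bp": df["End"].astype(int),
            "n_probes": df["NProbes"].astype(int),
        }
    )
    rwlr = df[sample_ids].to_numpy(dtype=float)
    return RegionSet(regions, rwlr, sample_ids)


def write_region_matrix(regions: RegionSet, path: str | Path) -> None:
    out = pd.DataFrame(
        {
            "Chromosome": regions.regions["chrom"],
            "Start": regions.regions["start_bp"],
            "End": regions.regions["end_bp"],
            "NProbes": regions.regions["n_probes"],
        }
    )
    for j, s in enumerate(regions.sample_ids):
        out[s] = regions.rwlr[:, j]
    out.to_csv(path, sep="\t", index=False)


def read_cytobands(path: str | Path) -> pd.DataFrame:
    """Parse a UCSC-style cytoBand file.

    Input columns (no header): chrom, chromStart, chromEnd, name, gieStain
    with 0-based half-open coordinates; returns a DataFrame with 1-based
    closed ``start_bp``/``end_bp`` restricted to autosomes.
    """
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "chromStart", "chromEnd", "name", "gieStain"],
        dtype={"chrom": str, "name": str, "gieStain": str},
    )
    chroms = df["chrom"].map(_parse_chrom)
    df = df[chroms.notna()].copy()
    df["chrom"] = chroms[chroms.notna()].astype(int)
    out = pd.DataFrame(
        {
            "chrom": df["chrom"].to_numpy(),
            "start_bp": df["chromStart"].astype(int).to_numpy() + 1,
            "end_bp": df["chromEnd"].astype(int).to_numpy(),
            "name": df["name"].to_numpy(),
            "stain": df["gieStain"].to_numpy(),
        }
    )
    return out.sort_values(["chrom", "start_bp"]).reset_index(drop=True)


def write_run_summary(summary: dict, path: str | Path) -> None:
    """Write the machine-readable run summary (JSON)."""
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(summary, indent=2, default=_default) + "\n")
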