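"""Spike-in simulator for two-group aCGH experiments with known truth.

The simulator emulates the structure of tumour copy-number profiles in a
two-group comparison.  "Noise" consists of aberrant regions common to both
groups and of private aberrations in individual samples; "signal" consists
of regions specific to one group.  Aberration extents are whole numbers of
cytobands (1, 3 or 6 consecutive bands), a whole chromosome arm, or an
entire chromosome, with probabilities 10/30/30/20/10%.  Types are gain or
loss with equal probability, plus a 2% chance of amplification for
single-band events.  Carriers of a shared event are drawn Bernoulli(0.70);
each carrier's start and end probes are jittered by an integer uniform on
-10..10.  The baseline is i.i.d. Gaussian probe noise (optionally AR(1)
correlated) standing in for resampled clinical arrays.

Every introduced event is recorded in a ground-truth ledger
(:class:`SimTruth`) so that false-discovery and power claims made
downstream can be validated against known differential regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import GroupAssignment, InputError, LogRatioMatrix

SIZE_CLASSES = ("band1", "band3", "band6", "arm", "chrom")
SIZE_PROBS = (0.10, 0.30, 0.30, 0.20, 0.10)
AMP_PROB_SINGLE_BAND = 0.02


# ---------------------------------------------------------------------------
# genome model
# ---------------------------------------------------------------------------

@dataclass
class ChromosomeModel:
    chrom: int
    n_probes: int
    bands: list[tuple[int, int]]   # closed 0-based probe intervals, partition
    arm_boundary: int              # number of p-arm probes (first q probe idx)

    def arm_span(self, probe: int) -> tuple[int, int]:
        if probe < self.arm_boundary:
            return 0, self.arm_boundary - 1
        return self.arm_boundary, self.n_probes - 1

    def band_of(self, probe: int) -> int:
        for i, (s, e) in enumerate(self.bands):
            if s <= probe <= e:
                return i
        raise InputError(f"probe {probe} outside chromosome {self.chrom}")


@dataclass
class GenomeModel:
    """Probe layout and cytoband partition of a synthetic genome."""

    chromosomes: list[ChromosomeModel]
    probe_bp: int = 100_000        # constant probe footprint in bp

    def __post_init__(self) -> None:
        for cm in self.chromosomes:
            if len(cm.bands) < 12:
                raise InputError(
                    f"chromosome {cm.chrom} has {len(cm.bands)} cytobands; "
                    "need >= 12 so a six-band event fits either arm"
                )
            if not any(e + 1 == cm.arm_boundary for _, e in cm.bands):
                raise InputError(
                    f"arm boundary of chromosome {cm.chrom} not on a band edge"
                )

    @property
    def total_probes(self) -> int:
        return sum(c.n_probes for c in self.chromosomes)

    def probe_table(self) -> pd.DataFrame:
        """Probe annotation in the layout expected by LogRatioMatrix."""
        rows = []
        for cm in self.chromosomes:
            for i in range(cm.n_probes):
                rows.append(
                    (
                        f"chr{cm.chrom}_p{i:05d}",
                        cm.chrom,
                        i * self.probe_bp + 1,
                        (i + 1) * self.probe_bp,
                    )
                )
        return pd.DataFrame(rows, columns=["probe_id", "chrom", "start_bp", "end_bp"])

    def offsets(self) -> dict[int, int]:
        """Global probe-index offset of each chromosome."""
        out, off = {}, 0
        for cm in self.chromosomes:
            out[cm.chrom] = off
            off += cm.n_probes
        return out


def _partition(n: int, k: int) -> list[tuple[int, int]]:
    """Split 0..n-1 into k consecutive near-equal closed intervals."""
    edges = np.linspace(0, n, k + 1).round().astype(int)
    return [(int(edges[i]), int(edges[i + 1] - 1)) for i in range(k)]


def build_genome(
    n_chrom: int = 22,
    probes_per_chrom: int = 300,
    bands_per_arm: int = 6,
    probe_bp: int = 100_000,
) -> GenomeModel:
    """Deterministic synthetic genome: equal-size chromosomes, each split
    into two arms at the midpoint and each arm into ``bands_per_arm``
    near-equal cytobands.
    """
    if bands_per_arm < 6:
        raise InputError("bands_per_arm must be >= 6")
    if probes_per_chrom < 2 * bands_per_arm:
        raise InputError("probes_per_chrom must be >= 2 * bands_per_arm")
    chroms = []
    for c in range(1, n_chrom + 1):
        p_len = probes_per_chrom // 2
        p_bands = _partition(p_len, bands_per_arm)
        q_bands = [
            (s + p_len, e + p_len)
            for s, e in _partition(probes_per_chrom - p_len, bands_per_arm)
        ]
        chroms.append(
            ChromosomeModel(c, probes_per_chrom, p_bands + q_bands, p_len)
        )
    return GenomeModel(chroms, probe_bp)


def genome_from_cytobands(bands: pd.DataFrame, probe_bp: int = 100_000) -> GenomeModel:
    """Build a genome model from a parsed cytoBand table (see
    :func:`cnapower.io.read_cytobands`).

    Probes of ``probe_bp`` footprint tile each chromosome end to end; a
    band's probe span is the 1-based-closed bp interval converted to the
    probes whose start falls inside it.  The arm boundary is the first band
    whose name starts with "q".
    """
    chroms = []
    for c, grp in bands.groupby("chrom"):
        grp = grp.sort_values("start_bp")
        chrom_end = int(grp["end_bp"].max())
        n_probes = chrom_end // probe_bp
        spans = []
        arm_boundary = None
        for _, row in grp.iterrows():
            s = (int(row["start_bp"]) - 1) // probe_bp
            e = min((int(row["end_bp"]) - 1) // probe_bp, n_probes - 1)
            if spans and s <= spans[-1][1]:
                s = spans[-1][1] + 1
            if e < s:
                continue
            if str(row["name"]).startswith("q") and arm_boundary is None:
                arm_boundary = s
            spans.append((s, e))
        if arm_boundary is None:
            raise InputError(f"chromosome {c}: no q-arm band found")
        chroms.append(ChromosomeModel(int(c), spans[-1][1] + 1, spans, arm_boundary))
    return GenomeModel(chroms, probe_bp)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------

@dataclass
class RegionExtent:
    """Nominal extent of a drawn aberration (before per-carrier jitter)."""

    chrom: int
    start_probe: int     # 0-based, within chromosome, closed
    end_probe: int
    size_class: str      # one of SIZE_CLASSES
    kind: str            # gain / loss / amplification


@dataclass
class AberrationEvent:
    """A realized aberration: nominal span plus per-carrier jittered spans."""

    extent: RegionExtent
    amplitude: float
    carriers: list[int]
    realized: dict[int, tuple[int, int]]  # carrier -> (start, end) probes
    klass: str = "common"                 # common / private / groupA / groupB

    def total_shift(self) -> float:
        """Sum over carriers of amplitude x realized span length (probes)."""
        return sum(
            self.amplitude * (e - s + 1) for s, e in self.realized.values()
        )


@dataclass
class SimConfig:
    """Study-condition parameters of the simulator.

    Defaults reproduce the two-group design the simulations are built
    around: 15 samples per group, 30 shared events, 5 private events per
    sample, Bernoulli(0.70) carriers, and k group-specific events per group.
    """

    n_per_group: int = 15
    n_common: int = 30
    n_private_per_sample: int = 5
    n_group_specific: int = 0     # the "k" knob, 0..10
    carrier_p: float = 0.70
    size_probs: tuple[float, ...] = SIZE_PROBS
    amp_prob_single_band: float = AMP_PROB_SINGLE_BAND
    jitter_max: int = 10
    noise_sd: float = 0.15
    noise_rho: float = 0.0        # optional AR(1) probe correlation
    amp_gain: float = 0.58        # ~= log2(3/2)
    amp_loss: float = -1.0        # = log2(1/2)
    amp_amp: float = 2.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.size_probs) - 1.0) > 1e-9:
            raise InputError("size_probs must sum to 1")
        if not 0 < self.carrier_p <= 1:
            raise InputError("carrier_p must lie in (0, 1]")
        if self.jitter_max < 0:
            raise InputError("jitter_max must be >= 0")
        if self.n_per_group < 2:
            raise InputError("n_per_group must be >= 2")

    def amplitude_for(self, kind: str) -> float:
        return {"gain": self.amp_gain, "loss": self.amp_loss,
                "amplification": self.amp_amp}[kind]


@dataclass
class SimTruth:
    """Ground-truth ledger of every introduced aberration."""

    events: list[AberrationEvent] = field(default_factory=list)

    def counts_by_class(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.klass] = out.get(ev.klass, 0) + 1
        return out

    def differential_mask(self, genome: GenomeModel) -> np.ndarray:
        """Boolean per-probe (global index) mask of group-specific signal.

        A probe is differentially behaving iff some groupA/groupB event's
        nominal span covers it.
        """
        mask = np.zeros(genome.total_probes, dtype=bool)
        off = genome.offsets()
        for ev in self.events:
            if ev.klass in ("groupA", "groupB"):
                o = off[ev.extent.chrom]
                mask[o + ev.extent.start_probe: o + ev.extent.end_probe + 1] = True
        return mask

    def to_frame(self) -> pd.DataFrame:
        """One row per event per carrier, with nominal and realized spans."""
        rows = []
        for i, ev in enumerate(self.events):
            for carrier in sorted(ev.realized):
                s, e = ev.realized[carrier]
                rows.append(
                    (
                        i, ev.klass, ev.extent.kind, ev.extent.size_class,
                        ev.extent.chrom, ev.extent.start_probe,
                        ev.extent.end_probe, carrier, s, e, ev.amplitude,
                    )
                )
            if not ev.realized:   # zero-carrier events are still recorded
                rows.append(
                    (
                        i, ev.klass, ev.extent.kind, ev.extent.size_class,
                        ev.extent.chrom, ev.extent.start_probe,
                        ev.extent.end_probe, -1, -1, -1, ev.amplitude,
                    )
                )
        return pd.DataFrame(
            rows,
            columns=[
                "event", "class", "type", "size_class", "chrom",
                "nominal_start", "nominal_end", "carrier",
                "realized_start", "realized_end", "amplitude",
            ],
        )


# ---------------------------------------------------------------------------
# draws
# ---------------------------------------------------------------------------

def draw_region_extent(
    genome: GenomeModel,
    rng: np.random.Generator,
    size_probs: tuple[float, ...] = SIZE_PROBS,
    amp_prob: float = AMP_PROB_SINGLE_BAND,
) -> RegionExtent:
    """Draw one aberration extent and type.

    A random probe seeds the event; the extent is the cytoband containing
    it, three or six consecutive bands starting there (truncated at the
    chromosome end), the containing arm, or the whole chromosome.
    """
    sizes = np.array([c.n_probes for c in genome.chromosomes], dtype=float)
    ci = int(rng.choice(len(sizes), p=sizes / sizes.sum()))
    cm = genome.chromosomes[ci]
    probe = int(rng.integers(cm.n_probes))
    size_class = SIZE_CLASSES[int(rng.choice(len(SIZE_CLASSES), p=size_probs))]

    if size_class in ("band1", "band3", "band6"):
        n_bands = {"band1": 1, "band3": 3, "band6": 6}[size_class]
        b0 = cm.band_of(probe)
        b1 = min(b0 + n_bands - 1, len(cm.bands) - 1)
        start, end = cm.bands[b0][0], cm.bands[b1][1]
    elif size_class == "arm":
        start, end = cm.arm_span(probe)
    else:
        start, end = 0, cm.n_probes - 1

    if size_class == "band1":
        u = rng.random()
        if u < amp_prob:
            kind = "amplification"
        elif u < amp_prob + (1 - amp_prob) / 2:
            kind = "gain"
        else:
            kind = "loss"
    else:
        kind = "gain" if rng.random() < 0.5 else "loss"
    return RegionExtent(cm.chrom, start, end, size_class, kind)


def _jitter_span(
    start: int, end: int, n_probes: int, jitter_max: int, rng: np.random.Generator
) -> tuple[int, int]:
    """Independently shift both boundaries; redraw if the span inverts."""
    if jitter_max == 0:
        return start, end
    while True:
        s = int(np.clip(start + rng.integers(-jitter_max, jitter_max + 1), 0, n_probes - 1))
        e = int(np.clip(end + rng.integers(-jitter_max, jitter_max + 1), 0, n_probes - 1))
        if s <= e:
            return s, e


def apply_aberration(
    matrix: LogRatioMatrix,
    extent: RegionExtent,
    carriers: list[int],
    amplitude: float,
    jitter_max: int,
    rng: np.random.Generator,
    klass: str = "common",
) -> tuple[LogRatioMatrix, AberrationEvent]:
    """Add an aberration to a copy of ``matrix`` and return the realized event.

    Each carrier gets its own jittered span (boundaries shifted by integers
    uniform on -jitter_max..jitter_max, clamped to the chromosome); the
    amplitude is added to every probe in the carrier's realized span.  The
    input matrix is left untouched.
    """
    out = matrix.copy()
    ev = _apply_inplace(out, extent, carriers, amplitude, jitter_max, rng, klass)
    return out, ev


def _apply_inplace(
    matrix: LogRatioMatrix,
    extent: RegionExtent,
    carriers: list[int],
    amplitude: float,
    jitter_max: int,
    rng: np.random.Generator,
    klass: str,
) -> AberrationEvent:
    sl = matrix.chrom_slices()[extent.chrom]
    n_probes = sl.stop - sl.start
    realized: dict[int, tuple[int, int]] = {}
    for carrier in carriers:
        s, e = _jitter_span(
            extent.start_probe, extent.end_probe, n_probes, jitter_max, rng
        )
        matrix.values[carrier, sl.start + s: sl.start + e + 1] += amplitude
        realized[carrier] = (s, e)
    return AberrationEvent(extent, amplitude, list(carriers), realized, klass)


def draw_carriers(
    candidates: np.ndarray, carrier_p: float, rng: np.random.Generator
) -> list[int]:
    """Bernoulli carrier assignment over a candidate sample set.

    Zero carriers is a legal outcome and is kept (the event is recorded
    with no effect on the matrix).
    """
    keep = rng.random(len(candidates)) < carrier_p
    return [int(c) for c in candidates[keep]]


# ---------------------------------------------------------------------------
# experiment
# ---------------------------------------------------------------------------

def simulate_experiment(
    config: SimConfig,
    genome: GenomeModel | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[LogRatioMatrix, GroupAssignment, SimTruth]:
    """Generate a full two-group experiment with ground truth.

    Baseline probe noise is N(0, noise_sd^2) (AR(1) along the genome if
    noise_rho > 0).  On top of it: ``n_common`` shared events with
    Bernoulli(carrier_p) carriers over all samples, ``n_private_per_sample``
    events owned by each single sample, and ``n_group_specific`` events per
    group with Bernoulli(carrier_p) carriers within that group.
    """
    if genome is None:
        genome = build_genome()
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)

    n = config.n_per_group
    sample_ids = [f"A{i + 1:02d}" for i in range(n)] + [
        f"B{i + 1:02d}" for i in range(n)
    ]
    groups = GroupAssignment(
        {s: ("A" if s.startswith("A") else "B") for s in sample_ids}
    )

    noise = rng.normal(0.0, config.noise_sd, size=(2 * n, genome.total_probes))
    if config.noise_rho > 0:
        rho = config.noise_rho
        for j in range(1, noise.shape[1]):
            noise[:, j] = rho * noise[:, j - 1] + np.sqrt(1 - rho**2) * noise[:, j]
    matrix = LogRatioMatrix(genome.probe_table(), noise, sample_ids)

    all_idx = np.arange(2 * n)
    a_idx, b_idx = all_idx[:n], all_idx[n:]
    truth = SimTruth()

    def introduce(candidates: np.ndarray | list[int], klass: str,
                  bernoulli: bool) -> None:
        extent = draw_region_extent(
            genome, rng, config.size_probs, config.amp_prob_single_band
        )
        if bernoulli:
            carriers = draw_carriers(np.asarray(candidates), config.carrier_p, rng)
        else:
            carriers = list(candidates)
        ev = _apply_inplace(
            matrix, extent, carriers, config.amplitude_for(extent.kind),
            config.jitter_max, rng, klass,
        )
        truth.events.append(ev)

    for _ in range(config.n_common):
        introduce(all_idx, "common", bernoulli=True)
    for s in all_idx:
        for _ in range(config.n_private_per_sample):
            introduce([int(s)], "private", bernoulli=False)
    for _ in range(config.n_group_specific):
        introduce(a_idx, "groupA", bernoulli=True)
    for _ in range(config.n_group_specific):
        introduce(b_idx, "groupB", bernoulli=True)

    return matrix, groups, truth
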