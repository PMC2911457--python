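"""Spike-in simulator: genome construction, draws, truth accounting."""

import numpy as np
import pandas as pd
import pytest

from cnapower import (
    InputError,
    SimConfig,
    apply_aberration,
    build_genome,
    draw_carriers,
    draw_region_extent,
    genome_from_cytobands,
    simulate_experiment,
)
from cnapower.io import read_cytobands
from cnapower.simulate import SIZE_CLASSES, SIZE_PROBS


class TestBuildGenome:
    def test_even_partition(self):
        g = build_genome(22, 1000, 10)
        assert len(g.chromosomes) == 22
        for cm in g.chromosomes:
            assert len(cm.bands) == 20
            assert cm.arm_boundary == 500
            widths = {e - s + 1 for s, e in cm.bands}
            assert widths == {50}

    def test_single_chromosome(self):
        g = build_genome(1, 100, 6)
        cm = g.chromosomes[0]
        assert cm.arm_boundary == 50
        assert len(cm.bands) == 12
        # bands partition the probes
        covered = sorted(p for s, e in cm.bands for p in range(s, e + 1))
        assert covered == list(range(100))

    def test_rejects_degenerate(self):
        with pytest.raises(InputError):
            build_genome(1, 100, 5)
        with pytest.raises(InputError):
            build_genome(1, 10, 6)

    def test_from_cytobands(self, tmp_path):
        # 14 bands of 3 Mb each; with 1 Mb probes, band i covers probes
        # 3i..3i+2 (verified by hand for the first three rows)
        lines = []
        for i in range(14):
            arm = "p" if i < 7 else "q"
            lines.append(f"chr1\t{3_000_000 * i}\t{3_000_000 * (i + 1)}\t{arm}{i}\tgneg")
        f = tmp_path / "cyto.txt"
        f.write_text("\n".join(lines) + "\n")
        genome = genome_from_cytobands(read_cytobands(f), probe_bp=1_000_000)
        cm = genome.chromosomes[0]
        assert cm.bands[0] == (0, 2)
        assert cm.bands[1] == (3, 5)
        assert cm.bands[2] == (6, 8)
        assert cm.arm_boundary == 21          # first q band starts at probe 21
        assert cm.n_probes == 42


N_DRAWS = 20_000


@pytest.fixture(scope="module")
def draws(default_genome):
    rng = np.random.default_rng(5)
    return [draw_region_extent(default_genome, rng) for _ in range(N_DRAWS)]


class TestDrawRegionExtent:
    N = N_DRAWS

    def test_size_class_frequencies(self, draws):
        counts = pd.Series([d.size_class for d in draws]).value_counts()
        for cls, prob in zip(SIZE_CLASSES, SIZE_PROBS):
            se = np.sqrt(prob * (1 - prob) / self.N)
            assert abs(counts.get(cls, 0) / self.N - prob) < 3 * se, cls

    def test_amplification_only_single_band(self, draws):
        singles = [d for d in draws if d.size_class == "band1"]
        amps = sum(d.kind == "amplification" for d in singles)
        frac = amps / len(singles)
        se = np.sqrt(0.02 * 0.98 / len(singles))
        assert abs(frac - 0.02) < 3 * se
        assert all(
            d.kind in ("gain", "loss")
            for d in draws if d.size_class != "band1"
        )

    def test_multiband_gain_loss_balanced(self, draws):
        multi = [d for d in draws if d.size_class != "band1"]
        frac = sum(d.kind == "gain" for d in multi) / len(multi)
        se = np.sqrt(0.25 / len(multi))
        assert abs(frac - 0.5) < 3 * se

    def test_spans_are_whole_units(self, draws, default_genome):
        by_chrom = {c.chrom: c for c in default_genome.chromosomes}
        for d in draws[:2000]:
            cm = by_chrom[d.chrom]
            starts = {s for s, _ in cm.bands}
            ends = {e for _, e in cm.bands}
            assert d.start_probe in starts
            assert d.end_probe in ends
            if d.size_class == "chrom":
                assert (d.start_probe, d.end_probe) == (0, cm.n_probes - 1)
            if d.size_class == "arm":
                assert (d.start_probe, d.end_probe) in (
                    (0, cm.arm_boundary - 1),
                    (cm.arm_boundary, cm.n_probes - 1),
                )


class TestApplyAberration:
    def test_no_jitter_exact_span(self, small_genome, rng):
        from cnapower import LogRatioMatrix

        matrix = LogRatioMatrix(
            small_genome.probe_table(),
            np.zeros((3, small_genome.total_probes)),
            ["s0", "s1", "s2"],
        )
        extent = draw_region_extent(small_genome, rng)
        out, ev = apply_aberration(matrix, extent, [1], 1.0, 0, rng)
        assert np.all(matrix.values == 0), "input must stay untouched"
        sl = out.chrom_slices()[extent.chrom]
        span = slice(sl.start + extent.start_probe, sl.start + extent.end_probe + 1)
        assert np.all(out.values[1, span] == 1.0)
        assert out.values[1].sum() == extent.end_probe - extent.start_probe + 1
        assert np.all(out.values[[0, 2]] == 0)
        assert ev.realized[1] == (extent.start_probe, extent.end_probe)

    def test_zero_amplitude_recorded_but_no_effect(self, small_genome, rng):
        from cnapower import LogRatioMatrix

        matrix = LogRatioMatrix(
            small_genome.probe_table(),
            np.zeros((2, small_genome.total_probes)),
            ["s0", "s1"],
        )
        extent = draw_region_extent(small_genome, rng)
        out, ev = apply_aberration(matrix, extent, [0, 1], 0.0, 5, rng)
        assert np.all(out.values == 0)
        assert set(ev.realized) == {0, 1}

    def test_jitter_bounded_and_spread(self, default_genome):
        rng = np.random.default_rng(17)
        from cnapower import LogRatioMatrix

        matrix = LogRatioMatrix(
            default_genome.probe_table(),
            np.zeros((1, default_genome.total_probes)),
            ["s0"],
        )
        shifts = []
        for _ in range(4000):
            extent = draw_region_extent(default_genome, rng)
            cm = next(c for c in default_genome.chromosomes if c.chrom == extent.chrom)
            _, ev = apply_aberration(matrix, extent, [0], 0.0, 10, rng)
            s, e = ev.realized[0]
            # boundary shifts, ignoring clamped chromosome edges
            if extent.start_probe >= 10 and extent.end_probe <= cm.n_probes - 11:
                shifts += [s - extent.start_probe, e - extent.end_probe]
        shifts = np.array(shifts)
        assert shifts.min() >= -10 and shifts.max() <= 10
        # roughly uniform on -10..10: each value within 4 sd of 1/21
        counts = np.bincount(shifts + 10, minlength=21) / len(shifts)
        se = np.sqrt((1 / 21) * (20 / 21) / len(shifts))
        assert np.all(np.abs(counts - 1 / 21) < 4 * se)


class TestSimulateExperiment:
    def test_event_counts_by_class(self, small_genome):
        cfg = SimConfig(n_per_group=5, rng_seed=1)
        _, _, truth = simulate_experiment(cfg, small_genome)
        counts = truth.counts_by_class()
        assert counts["common"] == 30
        assert counts["private"] == 50          # 5 per sample x 10 samples
        assert "groupA" not in counts

    def test_group_specific_counts(self, small_genome):
        cfg = SimConfig(n_per_group=5, n_group_specific=10, rng_seed=1)
        _, _, truth = simulate_experiment(cfg, small_genome)
        counts = truth.counts_by_class()
        assert counts["groupA"] == 10
        assert counts["groupB"] == 10

    def test_carrier_fraction(self, small_genome):
        rng = np.random.default_rng(3)
        fracs = [
            len(draw_carriers(np.arange(15), 0.70, rng)) / 15
            for _ in range(4000)
        ]
        se = np.sqrt(0.7 * 0.3 / 15 / len(fracs))
        assert abs(np.mean(fracs) - 0.70) < 3 * se

    def test_conservation_noiseless(self, small_genome):
        cfg = SimConfig(n_per_group=4, noise_sd=0.0, rng_seed=7,
                        n_group_specific=3)
        matrix, _, truth = simulate_experiment(cfg, small_genome)
        total = sum(ev.total_shift() for ev in truth.events)
        assert matrix.values.sum() == pytest.approx(total, rel=1e-12)

    def test_reproducible(self, small_genome):
        cfg = SimConfig(n_per_group=4, rng_seed=11)
        m1, _, t1 = simulate_experiment(cfg, small_genome)
        m2, _, t2 = simulate_experiment(cfg, small_genome)
        np.testing.assert_array_equal(m1.values, m2.values)
        pd.testing.assert_frame_equal(t1.to_frame(), t2.to_frame())

    def test_private_events_single_owner(self, small_genome):
        cfg = SimConfig(n_per_group=4, rng_seed=5)
        _, _, truth = simulate_experiment(cfg, small_genome)
        owners = [ev.carriers for ev in truth.events if ev.klass == "private"]
        assert all(len(c) == 1 for c in owners)
        # each of the 8 samples owns exactly 5
        assert sorted(
            sum(c[0] == s for c in owners) for s in range(8)
        ) == [5] * 8

    def test_differential_mask_only_group_events(self, small_genome):
        cfg = SimConfig(n_per_group=4, rng_seed=5)
        _, _, truth = simulate_experiment(cfg, small_genome)
        assert not truth.differential_mask(small_genome).any()
        cfg2 = SimConfig(n_per_group=4, rng_seed=5, n_group_specific=2)
        _, _, truth2 = simulate_experiment(cfg2, small_genome)
        assert truth2.differential_mask(small_genome).any()


def test_carrier_counts_binomial(small_genome):
    """Carrier counts per common event follow Binomial(n, 0.7)."""
    from scipy import stats

    rng = np.random.default_rng(23)
    n = 15
    counts = np.array(
        [len(draw_carriers(np.arange(n), 0.70, rng)) for _ in range(10_000)]
    )
    observed = np.bincount(counts, minlength=n + 1)
    expected = stats.binom.pmf(np.arange(n + 1), n, 0.70) * len(counts)
    # pool sparse tail cells for a valid chi-square
    keep = expected > 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    chi2 += (observed[~keep].sum() - expected[~keep].sum()) ** 2 / expected[~keep].sum()
    dof = keep.sum()  # pooled cell adds one
    assert chi2 < stats.chi2.ppf(0.99, dof)
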