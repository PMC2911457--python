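# cnapower

Power and sample-size estimation for two-group array-CGH (aCGH) copy-number
experiments, from pilot data.

Comparative genomic hybridization arrays measure DNA copy number as per-probe
log2 ratios. When two groups of tumours are compared (say HPV-positive versus
HPV-negative), the scientific question at the planning stage is how many
arrays per group are needed to detect the truly differential chromosomal
regions at a controlled false discovery rate. `cnapower` answers it from a
pilot experiment: it estimates the biological diversity between the groups
and extrapolates the average power — the expected fraction of truly
differential regions detected — as a function of the per-group sample size,
with the FDR fixed (10% by default).

## Model

Probe-level log2 ratios are median-normalized, segmented per sample with
circular binary segmentation, called as loss/normal/gain/amplification by
fixed thresholds, and collapsed across samples into *regions* — runs of
probes sharing a copy-number signature in most samples. Each region is
summarised per sample by its median log ratio (region-wise log ratio, RWLR)
and tested with a Welch t statistic; two-sided p-values come from the
standard normal.

With γ the proportion of non-differential regions, the region p-values
follow the mixture

    F(t) = γ·t + (1 − γ)·G(t),

where G is the unknown p-value distribution of the differential regions.
Two estimators of G are computed for each candidate γ — a non-parametric
inversion Ĝ_γ(t) = (F̂(t) − γt)/(1 − γ) of the empirical CDF and a
parametric Ĝ_n assuming noncentralities θ ~ N(±a, b²) — and γ̂ minimizes
their sup-distance (the two drift apart as γ moves off its true value).
The effect-size density λ(θ) is then deconvolved from the t statistics.
For a balanced design of n per group, noncentralities scale by
s = √((n/2)/h₀) with h₀ = (1/n_A + 1/n_B)⁻¹ the pilot's effective size;
the adaptive Benjamini–Hochberg threshold is

    u* = sup{ u : γ̂u / (γ̂u + (1 − γ̂)·G_n(u)) ≤ α },

and the average power is Π(n) = G_n(u*). When no threshold satisfies the
bound the run ends in the *flat-line* failure state, which the diagnostics
(goodness-of-fit of the two G estimators, p-value density shape, RWLR
skewness/kurtosis) help interpret.

A spike-in simulator generates two-group experiments with known truth:
30 shared aberrations, 5 private aberrations per sample, and k
group-specific aberrations per group, with whole-cytoband/arm/chromosome
extents (10/30/30/20/10%), Bernoulli(0.70) carriers, and ±10-probe boundary
jitter per carrier.

## Worked example

```python
import numpy as np
from cnapower import (AnalysisConfig, SimConfig, build_genome,
                      simulate_experiment, run_pipeline)

genome = build_genome()                       # 22 chromosomes x 300 probes
matrix, groups, truth = simulate_experiment(
    SimConfig(n_group_specific=10, rng_seed=12354), genome)
report = run_pipeline(AnalysisConfig(rng_seed=12355), groups, matrix=matrix)

s = report.summary
print(f"regions={s['n_regions']} gamma_hat={s['gamma_hat']:.3f} "
      f"gof={s['gof']:.3f} grade={s['gof_grade']}")
curve = report.result.curve.table
for n in (15, 30, 60):
    print(f"n={n}: power={float(curve[curve.n == n].avg_power.iloc[0]):.3f}")
```

prints

```
regions=258 gamma_hat=0.500 gof=0.097 grade=satisfactory
n=15: power=0.438
n=30: power=0.678
n=60: power=0.889
```

The pilot of 15 + 15 arrays is expected to detect about 44% of the
differential regions at FDR 10%; doubling the experiment raises the
expectation to about 68%, and 60 per group to 89%. The low γ̂ reflects that, besides the 20
spiked group-specific regions, shared aberrations with random carriers
produce many weakly differential regions in this simulation.

The same analysis is available from the shell:

```
cnapower simulate --out-dir sim --k 10 --seed 12354
cnapower run --matrix sim/probe_matrix.tsv --groups sim/groups.tsv \
             --out-dir out --seed 12355
```

Users who prefer their own segmentation/calling stack can run
`cnapower power --regions regions.tsv --groups groups.tsv --out-dir out`
on a preprocessed region matrix (power-only mode).

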