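# daquant

Quantification toolkit for dopamine-system recordings: spike-train burst
analysis of putative ventral tegmental area (VTA) dopamine (DA) neurons,
surrogate-based permutation testing of group differences, fiber-photometry
ΔF/F z-score and AUC quantification, and dendritic spine / axonal varicosity
morphometry. It is aimed at systems-neuroscience labs that record DA-neuron
activity in vivo (e.g. in sham vs. vagotomized cohorts) and need the full
bespoke analysis chain as tested, reusable code rather than one-off scripts.

## What it computes

**Burst analysis.** In-vivo DA neurons are included when four criteria hold:
a triphasic action potential, total spike duration > 2.0 ms, start-to-trough
width > 1.1 ms, and a slow firing rate (> 1 and < 10 Hz). Bursts follow the
classic two-threshold rule: a burst opens at the first of two consecutive
spikes with an inter-spike interval (ISI) < 80 ms, continues while ISIs stay
≤ 160 ms, and closes at the first ISI > 160 ms. Each neuron is summarised by
its firing rate and

%SWB = 100 · (spikes within bursts) / (total spikes).

**Surrogate permutation test.** Per-neuron statistics are skewed, so group
means are compared nonparametrically. With cohorts *A* and *B*, the observed
difference is Δo = |mean(A) − mean(B)|. The two cohorts are pooled and the
values randomly reassigned to groups of the original sizes N times (default
N = 10,000), giving surrogate differences ΔS. The p estimate is the fraction
of surrogates with ΔS ≥ Δo; significance brackets are declared when the
exceedance count falls below 500 (\*), 100 (\*\*) or 10 (\*\*\*) out of
10,000, scaling proportionally with N. Distribution shape is compared with
the two-sample Kolmogorov–Smirnov statistic, and a Shapiro–Wilk gate
(all groups P > 0.05) selects parametric vs. nonparametric branches for
standard tests.

**Photometry.** Dual-excitation traces (465 nm signal, 405 nm isosbestic
reference) are corrected by an affine least-squares fit of the reference
onto the signal, r(t); ΔF/F = (F465 − r)/r. Traces are z-scored against a
baseline window, aligned into peri-event matrices, and quantified as the
area under the z-score curve in contiguous 5-s bins (left-Riemann, exactly
bin-additive).

**Morphometry.** Spines split into thin (< 350 nm 2D head diameter) and
mushroom (≥ 350 nm) classes; densities are reported per 10 µm of dendrite,
and varicosity counts are normalized to a 10-µm-side cube.

Every stage has a synthetic-data counterpart (`daquant.synth`) constructed
so that ground truth is exactly recoverable, which is how the pipeline is
validated end to end.

## Worked example

Two simulated cohorts of DA neurons (61 and 81 cells, the sham-like cohort
bursting slightly more), compared on %SWB:

```python
import numpy as np
from daquant import (BurstyTrainSpec, PermutationSpec, burst_stats,
                     gen_bursty_spike_train, ks_two_sample,
                     surrogate_permutation_test)

swb = {}
for gi, (label, p_burst, n) in enumerate([("sham", 0.21, 61), ("sdv", 0.19, 81)]):
    swb[label] = np.array([
        burst_stats(gen_bursty_spike_train(
            BurstyTrainSpec(p_burst=p_burst, duration_s=60.0, seed=1000 * gi + s))[0]
        ).swb_percent
        for s in range(n)
    ])

print(f"mean %SWB  sham: {swb['sham'].mean():.1f}   sdv: {swb['sdv'].mean():.1f}")
ks = ks_two_sample(swb["sham"], swb["sdv"])
print(f"KS distribution test: D = {ks.d_statistic:.3f}, p = {ks.p_value:.2e}")
res = surrogate_permutation_test(swb["sham"], swb["sdv"],
                                 PermutationSpec(n_surrogates=10_000, seed=0))
print(f"permutation test: observed delta = {res.observed_delta:.2f} points, "
      f"{res.exceedance_count}/{res.n_surrogates} surrogates >= observed, "
      f"p = {res.p_estimate:.4f} ({res.stars})")
```

Output:

```
mean %SWB  sham: 44.3   sdv: 40.1
KS distribution test: D = 0.301, p = 2.62e-03
permutation test: observed delta = 4.21 points, 1/10000 surrogates >= observed, p = 0.0001 (***)
```

The sham-like cohort fires 44.3% of its spikes within bursts vs. 40.1% in
the other cohort; only 1 of 10,000 label reshuffles reproduces a mean gap
of ≥ 4.21 points, so the difference is declared significant at the
strictest bracket.

## Command line

The `daquant` CLI orchestrates end-to-end runs from YAML configs:

```bash
daquant simulate        --config sim.yaml  --seed 1 --out data/
daquant ephys-compare   --config run.yaml  --seed 1 --out results/
daquant photometry-quant --config phot.yaml --seed 1 --out results/
daquant morpho-summarize --config morph.yaml          --out results/
```

Reports are deterministic JSON (config hash and seed embedded) plus CSV
tables; exit codes are 0 (success), 2 (validation failure), 3 (insufficient
data after the inclusion gates).

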