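# Methods

This note documents the models, defaults, and numerical choices behind
`daquant`, and what the synthetic-data validation does and does not show.

## Burst detection and %SWB

Bursts are detected with the two-threshold ISI scheme used for midbrain DA
neurons recorded in vivo: onset requires two consecutive spikes with an ISI
strictly below 80 ms; the burst then absorbs spikes while ISIs stay at or
below 160 ms and closes at the first ISI strictly above 160 ms (or at the
end of the train). The 80–160 ms band therefore *continues* a burst but can
never *open* one — the standard reading of the two-threshold scheme. A burst
has at least two spikes, bursts are disjoint, and scanning resumes after a
burst's last spike, so a closing spike cannot re-open a burst.

Boundary semantics matter at exactly 80 and 160 ms. Spike times are stored
in seconds but compared in integer microseconds (times rounded to the
nearest µs, thresholds converted exactly), which removes float-equality
ambiguity: an ISI of exactly 80 ms does not open a burst; an ISI of exactly
160 ms continues one.

%SWB = 100 × (spikes inside bursts) / (total spikes); an empty train has
firing rate 0 and %SWB 0 by definition. The DA inclusion gate (triphasic,
duration > 2.0 ms, start-to-trough > 1.1 ms, 1 < rate < 10 Hz, all strict)
is applied before any group statistic, and every exclusion is logged with
its violated criteria, since the gate materially changes n.

## Surrogate permutation test

Units of analysis are per-neuron values; spikes are never pooled across
neurons. The test pools the two cohorts, reassigns values without
replacement to groups of the original sizes, and counts surrogates whose
absolute mean difference reaches the observed one. Choices:

- **p estimate = count / N**, with no +1 correction — fidelity to the
  counting rule as stated. When count = 0 a warning notes that the true p is
  bounded above by 1/N, not zero.
- **Ties count as exceedances** (the comparison is ≥). Because a surrogate
  recomputes the means from a re-ordered pooled vector, an exact tie can be
  perturbed by one ulp; the comparison therefore uses
  `delta >= observed − 1e-12·max(1, observed)`.
- **Independent random assignments** are drawn (surrogates may repeat); the
  observed configuration is not added to the surrogate set.
- **Exhaustive mode** enumerates all C(n1+n2, n1) splits when that number is
  at most a configurable cap (default 10,000) and reports the exact p.
- **Star thresholds** are fractions 0.05/0.01/0.001 of N, declared when the
  count is strictly below the threshold; at N = 10,000 they are exactly
  500/100/10.
- Monte-Carlo surrogates are drawn in vectorized chunks (argsort of uniform
  matrices), which keeps 500 replicates × 2,000 surrogates at cohort sizes
  (61, 81) under a minute on one core.

The KS statistic and Shapiro–Wilk p-values are delegated to scipy
(`ks_2samp` with the exact method when both n ≤ 10, `shapiro`); only the
branch-selection contract (parametric iff all groups have P > 0.05) is
implemented here, and the D statistic — not its p — is the primary reported
quantity for distribution comparisons.

## Photometry

The offline correction fits the 405 nm reference onto the 465 nm signal
with an affine least-squares fit (slope + intercept) and defines
ΔF/F = (F465 − r)/r against the fitted reference r. The affine fit is
robust to channel-specific offsets, is invariant under common rescaling of
both channels, and reduces to ΔF/F ≡ 0 when the channels are identical. A
constant reference admits no fit and is rejected as unusable — except in
that degenerate identical-channel case.

z-scores use the mean and sample SD (ddof = 1) of a declared baseline
window, so the baseline's own z-score has mean 0 and SD 1 exactly under the
same estimator. Two baseline conventions are available:

- a fixed per-session window (`zscore_trace`), and
- per-event re-baselining against each peri-event row's pre-event span
  (`peri_event_matrix(..., rebaseline="pre")`, the default), which is the
  convention under which pre-event traces hover around zero.

Peri-event rows span event − pre to event + post with inclusive endpoints;
events whose window overruns a recording edge are dropped and logged, never
zero-padded (padding would fabricate baseline). Binned AUC uses left-Riemann
quadrature (each sample owns [t, t + dt)), which is exactly additive over
adjacent bins and matches per-bin AUC semantics; the O(dt) difference from
trapezoidal quadrature is negligible at 10–20 Hz effective rates. Bins start
at the analysis-window start; a trailing remainder shorter than one bin is
kept and flagged partial. The default bin width is 5 s.

## Morphometry

Thin vs. mushroom classification splits at a 350 nm 2D head diameter; the
boundary point itself is assigned mushroom — the split's wording leaves the
point mass undefined, and a fixed tie-break keeps results deterministic.
Spine densities are reported per 10 µm of dendrite (consistent with the
50–70 µm segments typically analyzed; lengths outside 10–200 µm trigger a
warning). Varicosity counts are normalized to a 10-µm-side cube
(count × 1000 / stack volume in µm³); stack dimensions quoted in nm in some
protocols are treated as µm, the only physically sensible reading.

## Synthetic data: what it emulates, and what it does not

- **Bursty trains** are renewal processes: each event is a burst of k spikes
  (fixed intra-burst ISI < 80 ms) with probability p, else a singlet;
  inter-event gaps are exponential left-truncated above 160 ms. The
  truncation guarantees generated bursts can never merge or split under the
  detector, so ground truth is exact rather than approximate, and the
  expected %SWB has the closed form 100·pk/(pk + 1 − p). Defaults (2
  events/s, k = 3, 50 ms intra-burst ISI, 200 ms gap floor, 300 s records)
  give firing rates and %SWB in the range typical of VTA DA neurons. Real
  trains have variable intra-burst ISIs, occasional 80–160 ms gaps between
  events, and rate nonstationarity; passing recovery tests shows detector
  correctness under the rule, not robustness to rule-ambiguous data.
- **Group samples** default to a lognormal (meanlog 3, sdlog 0.6), emulating
  the skewed per-neuron distributions that motivate the permutation test;
  the effect is a pure location shift of one group.
- **Photometry traces** use a mono-exponential bleach (the simplest model
  that exercises the correction stage), a difference-of-exponentials
  transient kernel normalized to unit peak (rise 0.3 s, decay 2 s — typical
  of genetically encoded DA sensors) with an analytic peak lag
  ln(τd/τr)·τrτd/(τd − τr) used as an oracle, white Gaussian per-channel
  noise, and a white shared motion component added to both channels. Real
  artifacts are low-frequency and wavelength-dependent; the simulation
  validates the arithmetic of correction, z-scoring and binning, not sensor
  physics.
- **Spine tables** are two-component Gaussian mixtures (thin 220 ± 35 nm,
  mushroom 580 ± 70 nm) with rejection sampling so that no draw crosses the
  350 nm boundary (components must keep ≥ 2 SD of clearance); the true class
  is then exactly the classified class, and recovery tests measure only
  binomial sampling error against the mixing proportion.

All generators draw from one explicit per-call seed (`numpy` Generator); no
global RNG state is touched, and equal spec + seed gives identical output.

## Pipeline reproducibility

Each stage derives its own seed from the run seed via a `SeedSequence` keyed
on a CRC32 of the stage name — stage-level reproducibility without seed
collisions. Every report embeds the config hash (SHA-256 of the canonical
config JSON, truncated) and the seed; JSON is written with sorted keys and
no timestamps, so reruns with the same config and seed are byte-identical.

## Validation problem sizes

The test suite and `scripts/acceptance.py` use: 1,000 random trains against
an independently written naive burst scanner plus 1,000 generated bursty
trains (exact label recovery); 200 realizations of 400 s for %SWB
calibration (±2 points of the closed form); 100 small datasets for
Monte-Carlo vs. exhaustive agreement (3 MC standard errors at N = 10,000);
500 null replicates at cohort sizes (61, 81) with 2,000 surrogates for the
type-I error (expected within [0.03, 0.07] at the 0.05 level); 200 seeded
traces at signal-to-noise 3 (kernel amplitude 0.06 ΔF/F vs. 0.02 per-channel
noise SD) for transient bin localization (≥ 95%); and 10,000 spines for
classification recovery (±2 points).

## Known limitations

- The burst detector assumes sorted, deduplicated spike times from upstream
  spike sorting; it does not handle overlapping units or artifacts.
- The affine isosbestic fit absorbs a small fraction of true transients into
  the fitted reference when transients occupy a large share of the record;
  with sparse events the bias is negligible.
- The photometry baseline convention is configuration, not ground truth:
  per-event pre-window z-scoring is the default, but session-level windows
  are supported and can change AUC magnitudes.
- Star brackets at small N are coarse (at N = 100 the \*\*\* bracket is
  empty below count 1); use N ≥ 1,000 in practice.
- Exhaustive enumeration is combinatorial; beyond the cap the Monte-Carlo
  path is used even when `exhaustive=True`.
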