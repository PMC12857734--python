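"""Two-sample machinery used for per-neuron statistics.

Per-neuron firing rate and %SWB distributions in vivo are strongly skewed,
so group means are compared with a surrogate permutation test: the two
cohorts are pooled, group labels are reassigned at random many times, and
the absolute mean difference of each surrogate split is compared with the
observed one.  Significance is declared from the exceedance count — with
10,000 surrogates the conventional brackets are counts below 500 (*), 100
(**), and 10 (***).  Distribution shape is compared separately with the
two-sample Kolmogorov–Smirnov statistic, and a Shapiro normality gate
selects the parametric or nonparametric branch for standard tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

__all__ = [
    "PermutationSpec",
    "PermutationResult",
    "KsResult",
    "surrogate_permutation_test",
    "significance_stars",
    "ks_two_sample",
    "normality_gate",
    "shapiro_pvalues",
]

# Significance fractions of the surrogate count: at N=10,000 these reproduce
# the 500/100/10 exceedance-count thresholds exactly.
STAR_FRACTIONS: tuple[tuple[float, str], ...] = (
    (0.001, "***"),
    (0.01, "**"),
    (0.05, "*"),
)

_MC_CHUNK = 2048


@dataclass(frozen=True)
class PermutationSpec:
    """Configuration of the surrogate permutation test."""

    n_surrogates: int = 10_000
    seed: int | None = None
    exhaustive: bool = False
    exhaustive_cap: int = 10_000

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.exhaustive_cap < 1:
            raise ValueError("exhaustive_cap must be >= 1")


@dataclass(frozen=True)
class PermutationResult:
    """Observed |mean difference|, surrogate exceedances, and star level."""

    observed_delta: float
    exceedance_count: int
    n_surrogates: int
    p_estimate: float
    stars: str
    seed: int | None = None
    method: str = "monte_carlo"

    def to_dict(self) -> dict:
        return {
            "observed_delta": self.observed_delta,
            "exceedance_count": self.exceedance_count,
            "n_surrogates": self.n_surrogates,
            "p_estimate": self.p_estimate,
            "stars": self.stars,
            "seed": self.seed,
            "method": self.method,
        }


@dataclass(frozen=True)
class KsResult:
    """Two-sample Kolmogorov–Smirnov statistic and p-value."""

    d_statistic: float
    p_value: float
    method: str = field(default="asymp")


def significance_stars(count: int, n: int) -> str:
    """Map a surrogate exceedance count to a star level.

    Significance is declared when ``count`` is strictly below the scaled
    threshold ``fraction * n``; the strictest attained level is returned,
    otherwise ``"ns"``.  At n=10,000 the thresholds are 500, 100 and 10.
    """
    if not 0 <= count <= n:
        raise ValueError("require 0 <= count <= n")
    for fraction, label in STAR_FRACTIONS:
        if count < fraction * n:
            return label
    return "ns"


def _validate_group(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 2:
        raise ValueError(f"group {name} needs at least 2 values")
    if not np.all(np.isfinite(x)):
        raise ValueError(f"group {name} contains non-finite values")
    return x


def surrogate_permutation_test(
    a: np.ndarray, b: np.ndarray, spec: PermutationSpec | None = None
) -> PermutationResult:
    """Surrogate-based permutation test of the absolute mean difference.

    The two samples are pooled and repeatedly split at random (without
    replacement) into groups of the original sizes; each surrogate yields
    Delta = |mean(A*) - mean(B*)| and the test counts surrogates with
    Delta >= Delta_observed (ties count as exceedances).  The p estimate is
    exceedance_count / n_surrogates, exactly as the counting rule is stated;
    when the count is zero the true p is bounded above by 1/N rather than
    zero, and a warning notes this.

    With ``spec.exhaustive`` and a feasible number of distinct splits
    (at most ``spec.exhaustive_cap``), all splits are enumerated instead.
    """
    if spec is None:
        spec = PermutationSpec()
    a = _validate_group(a, "a")
    b = _validate_group(b, "b")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    n = n1 + n2
    total = pooled.sum()

    observed = abs(a.mean() - b.mean())
    # Pooled re-orderings can move an exact tie by one ulp; the counting rule
    # includes ties, so compare against observed minus a relative epsilon.
    atol = 1e-12 * max(1.0, observed)

    n_distinct = math.comb(n, n1)
    if spec.exhaustive and n_distinct <= spec.exhaustive_cap:
        count = 0
        for idx in combinations(range(n), n1):
            sum_a = pooled[list(idx)].sum()
            delta = abs(sum_a / n1 - (total - sum_a) / n2)
            if delta >= observed - atol:
                count += 1
        n_sur = n_distinct
        method = "exhaustive"
    else:
        rng = np.random.default_rng(spec.seed)
        count = 0
        remaining = spec.n_surrogates
        while remaining > 0:
            m = min(_MC_CHUNK, remaining)
            order = np.argsort(rng.random((m, n)), axis=1)
            sums_a = pooled[order[:, :n1]].sum(axis=1)
            delta = np.abs(sums_a / n1 - (total - sums_a) / n2)
            count += int(np.count_nonzero(delta >= observed - atol))
            remaining -= m
        n_sur = spec.n_surrogates
        method = "monte_carlo"

    if count == 0:
        warnings.warn(
            "no surrogate reached the observed difference: the true p-value "
            f"is bounded by 1/{n_sur}, not zero",
            UserWarning,
            stacklevel=2,
        )
    return PermutationResult(
        observed_delta=float(observed),
        exceedance_count=count,
        n_surrogates=n_sur,
        p_estimate=count / n_sur,
        stars=significance_stars(count, n_sur),
        seed=spec.seed,
        method=method,
    )


def ks_two_sample(a: np.ndarray, b: np.ndarray) -> KsResult:
    """Two-sample Kolmogorov–Smirnov comparison of empirical distributions.

    The D statistic (max ECDF gap) is the primary quantity; the p-value is
    exact when both samples have at most 10 values, asymptotic otherwise.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    method = "exact" if (a.size <= 10 and b.size <= 10) else "asymp"
    res = sps.ks_2samp(a, b, method=method)
    return KsResult(float(res.statistic), float(res.pvalue), method)


def normality_gate(p_values, alpha: float = 0.05) -> str:
    """Choose the analysis branch from per-group Shapiro–Wilk p-values.

    Returns ``"parametric"`` iff every group has p > alpha (all groups pass
    the normality test), else ``"nonparametric"``.
    """
    p = list(p_values)
    if not p:
        raise ValueError("at least one group p-value is required")
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise ValueError("p-values must lie in [0, 1]")
    return "parametric" if all(v > alpha for v in p) else "nonparametric"


def shapiro_pvalues(*groups) -> list[float]:
    """Shapiro–Wilk p-value for each sample (convenience for the gate)."""
    return [float(sps.shapiro(np.asarray(g, dtype=float)).pvalue) for g in groups]
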