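"""Synthetic data with exact ground truth for every analysis stage.

Each generator draws all randomness from one explicit per-call seed and is
constructed so that downstream analysis recovers the generated truth exactly
(bursty trains whose bursts are exactly the detectable bursts, photometry
transients with an analytic peak time, spine-diameter mixtures that never
cross the classification boundary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spikes import SpikeTrain

__all__ = [
    "BurstyTrainSpec",
    "GroupSampleSpec",
    "PhotometrySimSpec",
    "gen_bursty_spike_train",
    "gen_group_samples",
    "gen_photometry_trace",
    "gen_spine_table",
    "expected_swb_percent",
    "kernel_peak_lag_s",
]


@dataclass(frozen=True)
class BurstyTrainSpec:
    """Renewal-process spike train mixing bursts and singlet events.

    Events (a burst of ``spikes_per_burst`` spikes or a single spike) occur
    with mean rate ``rate_events_hz``; inter-event gaps are exponential,
    left-truncated at ``min_inter_event_gap_ms``.  Because the truncation
    floor exceeds the 160 ms burst-termination threshold and the intra-burst
    ISI is below the 80 ms onset threshold, the detected bursts are exactly
    the generated ones.
    """

    rate_events_hz: float = 2.0
    p_burst: float = 0.3
    spikes_per_burst: int = 3
    intra_burst_isi_ms: float = 50.0
    min_inter_event_gap_ms: float = 200.0
    duration_s: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_burst <= 1.0:
            raise ValueError("p_burst must lie in [0, 1]")
        if self.intra_burst_isi_ms >= 80.0:
            raise ValueError("intra_burst_isi_ms must be < 80 ms")
        if self.min_inter_event_gap_ms <= 160.0:
            raise ValueError("min_inter_event_gap_ms must be > 160 ms")
        if self.spikes_per_burst < 2:
            raise ValueError("spikes_per_burst must be >= 2")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.rate_events_hz <= 0:
            raise ValueError("rate_events_hz must be positive")


def expected_swb_percent(p_burst: float, spikes_per_burst: int) -> float:
    """Closed-form expected %SWB: 100·p·k / (p·k + 1 − p)."""
    pk = p_burst * spikes_per_burst
    denom = pk + (1.0 - p_burst)
    return 100.0 * pk / denom if denom else 0.0


def gen_bursty_spike_train(
    spec: BurstyTrainSpec, neuron_id: str = "sim"
) -> tuple[SpikeTrain, pd.DataFrame]:
    """Generate a spike train with per-spike ground-truth burst labels.

    Returns the train and a table with one row per spike: columns
    ``spike_time_s``, ``in_burst`` (bool) and ``event_index``.
    """
    rng = np.random.default_rng(spec.seed)
    gap_floor_s = spec.min_inter_event_gap_ms / 1e3
    intra_s = spec.intra_burst_isi_ms / 1e3
    mean_extra = 1.0 / spec.rate_events_hz

    times: list[float] = []
    in_burst: list[bool] = []
    event_idx: list[int] = []
    t_last = 0.0
    event = 0
    while True:
        gap = gap_floor_s + rng.exponential(mean_extra)
        start = t_last + gap
        is_burst = rng.random() < spec.p_burst
        k = spec.spikes_per_burst if is_burst else 1
        spikes = start + intra_s * np.arange(k)
        if spikes[-1] > spec.duration_s:
            break
        times.extend(spikes.tolist())
        in_burst.extend([is_burst] * k)
        event_idx.extend([event] * k)
        t_last = spikes[-1]
        event += 1

    train = SpikeTrain(neuron_id, np.asarray(times), spec.duration_s)
    truth = pd.DataFrame(
        {
            "spike_time_s": times,
            "in_burst": in_burst,
            "event_index": event_idx,
        }
    )
    return train, truth


@dataclass(frozen=True)
class GroupSampleSpec:
    """Two cohorts of a per-neuron statistic from a skewed (or normal) family.

    Group B is shifted by ``shift`` relative to group A; ``shift=0`` is the
    exchangeable null.  ``params`` are the family's own parameters
    (lognormal: meanlog/sdlog; normal: mean/sd; beta: a/b plus scale).
    """

    n1: int
    n2: int
    family: str = "lognormal"
    shift: float = 0.0
    params: tuple[tuple[str, float], ...] = (("meanlog", 3.0), ("sdlog", 0.6))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.family not in ("lognormal", "beta", "normal"):
            raise ValueError(f"unknown family: {self.family!r}")
        p = dict(self.params)
        disp = {
            "lognormal": p.get("sdlog", 0.0),
            "normal": p.get("sd", 0.0),
            "beta": min(p.get("a", 0.0), p.get("b", 0.0)),
        }[self.family]
        if disp <= 0:
            raise ValueError("dispersion parameter must be positive")


def _draw_family(rng: np.random.Generator, family: str, params: dict, size: int):
    if family == "lognormal":
        return rng.lognormal(params["meanlog"], params["sdlog"], size)
    if family == "normal":
        return rng.normal(params["mean"], params["sd"], size)
    if family == "beta":
        scale = params.get("scale", 1.0)
        return scale * rng.beta(params["a"], params["b"], size)
    raise ValueError(f"unknown family: {family!r}")


def gen_group_samples(spec: GroupSampleSpec) -> tuple[np.ndarray, np.ndarray]:
    """Draw two statistic vectors; the effect is a location shift of group B."""
    rng = np.random.default_rng(spec.seed)
    p = dict(spec.params)
    a = _draw_family(rng, spec.family, p, spec.n1)
    b = _draw_family(rng, spec.family, p, spec.n2) + spec.shift
    return a, b


@dataclass(frozen=True)
class PhotometrySimSpec:
    """Dual-channel photometry simulation.

    The 465 nm channel carries sensor transients (difference-of-exponentials
    kernel, unit peak, amplitude in dF/F units) on a mono-exponentially
    bleaching baseline; the 405 nm reference carries the same baseline,
    shared motion artifact, and independent noise, but no transients.
    """

    duration_s: float = 120.0
    fs_hz: float = 20.0
    event_times_s: tuple[float, ...] = (30.0, 60.0, 90.0)
    amplitude: float = 0.05
    tau_rise_s: float = 0.3
    tau_decay_s: float = 2.0
    bleach_tau_s: float = 600.0
    noise_sd: float = 0.0
    motion_sd: float = 0.0
    f0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not self.tau_rise_s < self.tau_decay_s:
            raise ValueError("tau_rise_s must be < tau_decay_s")
        ev = np.asarray(self.event_times_s, dtype=float)
        if ev.size:
            if np.any(ev < 0) or np.any(ev > self.duration_s):
                raise ValueError("event times must lie in [0, duration_s]")
            if np.any(np.diff(ev) <= 0):
                raise ValueError("event times must be strictly increasing")


def kernel_peak_lag_s(tau_rise_s: float, tau_decay_s: float) -> float:
    """Analytic peak lag of the difference-of-exponentials kernel:
    ln(tau_d/tau_r)·tau_r·tau_d/(tau_d − tau_r)."""
    return (
        math.log(tau_decay_s / tau_rise_s)
        * tau_rise_s
        * tau_decay_s
        / (tau_decay_s - tau_rise_s)
    )


def _unit_peak_kernel(s: np.ndarray, tau_r: float, tau_d: float) -> np.ndarray:
    t_pk = kernel_peak_lag_s(tau_r, tau_d)
    peak = math.exp(-t_pk / tau_d) - math.exp(-t_pk / tau_r)
    out = np.zeros_like(s)
    pos = s >= 0
    out[pos] = (np.exp(-s[pos] / tau_d) - np.exp(-s[pos] / tau_r)) / peak
    return out


def gen_photometry_trace(spec: PhotometrySimSpec):
    """Simulate a dual-channel trace; returns (PhotometryTrace, event times)."""
    from .photometry import PhotometryTrace  # local import avoids a cycle

    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    bleach = spec.f0 * np.exp(-t / spec.bleach_tau_s)

    transient = np.zeros(n)
    for e in spec.event_times_s:
        transient += _unit_peak_kernel(t - e, spec.tau_rise_s, spec.tau_decay_s)

    motion = rng.normal(0.0, spec.motion_sd, n) if spec.motion_sd > 0 else 0.0
    noise465 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0
    noise405 = rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else 0.0

    f465 = bleach * (1.0 + spec.amplitude * transient) + motion + noise465
    f405 = bleach + motion + noise405
    trace = PhotometryTrace(time_s=t, f465=f465, f405=f405, fs_hz=spec.fs_hz)
    return trace, np.asarray(spec.event_times_s, dtype=float)


def gen_spine_table(
    n: int,
    p_mushroom: float,
    thin_mean_nm: float = 220.0,
    thin_sd_nm: float = 35.0,
    mushroom_mean_nm: float = 580.0,
    mushroom_sd_nm: float = 70.0,
    seed: int = 0,
    boundary_nm: float = 350.0,
    min_separation_sd: float = 2.0,
) -> pd.DataFrame:
    """Spine head-diameter mixture with exact class ground truth.

    Each component must keep ``min_separation_sd`` standard deviations of
    clearance from the 350 nm boundary, and draws that would cross it are
    rejected and redrawn, so the true class is always the downstream class.
    Returns columns spine_id, dendrite_id, head_diameter_nm, true_class.
    """
    if not 0.0 <= p_mushroom <= 1.0:
        raise ValueError("p_mushroom must lie in [0, 1]")
    if thin_mean_nm + min_separation_sd * thin_sd_nm > boundary_nm:
        raise ValueError("thin component straddles the classification boundary")
    if mushroom_mean_nm - min_separation_sd * mushroom_sd_nm < boundary_nm:
        raise ValueError("mushroom component straddles the classification boundary")
    rng = np.random.default_rng(seed)
    is_mushroom = rng.random(n) < p_mushroom

    diam = np.empty(n)
    for mask, mean, sd, lo, hi in (
        (~is_mushroom, thin_mean_nm, thin_sd_nm, 0.0, boundary_nm),
        (is_mushroom, mushroom_mean_nm, mushroom_sd_nm, boundary_nm, np.inf),
    ):
        m = int(mask.sum())
        if not m:
            continue
        draws = rng.normal(mean, sd, m)
        bad = (draws <= lo) | (draws >= hi)
        while np.any(bad):
            draws[bad] = rng.normal(mean, sd, int(bad.sum()))
            bad = (draws <= lo) | (draws >= hi)
        diam[mask] = draws

    return pd.DataFrame(
        {
            "spine_id": [f"s{i:06d}" for i in range(n)],
            "dendrite_id": "d0",
            "head_diameter_nm": diam,
            "true_class": np.where(is_mushroom, "mushroom", "thin"),
        }
    )
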