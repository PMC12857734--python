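"""Spike-train burst analysis for putative midbrain dopamine (DA) neurons.

Juxtacellular recordings of VTA DA neurons are screened with the classic
in-vivo inclusion criteria (triphasic waveform, long spike duration, wide
start-to-trough, slow 1-10 Hz firing) and then summarised per neuron by the
average firing rate and the percentage of spikes fired within bursts (%SWB).

Bursts follow the two-threshold (Grace-style) rule: a burst opens at the
first of two consecutive spikes separated by less than 80 ms, grows while
successive inter-spike intervals (ISIs) stay at or below 160 ms, and closes
at the first ISI above 160 ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "WaveformFeatures",
    "BurstParams",
    "Burst",
    "BurstStats",
    "classify_da_neuron",
    "detect_bursts",
    "burst_stats",
]


@dataclass(frozen=True)
class SpikeTrain:
    """Ordered spike times (seconds) for one neuron over a known duration."""

    neuron_id: str
    spike_times_s: np.ndarray
    duration_s: float

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times_s, dtype=float)
        object.__setattr__(self, "spike_times_s", times)
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if times.ndim != 1:
            raise ValueError("spike_times_s must be a 1-D vector")
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError("spike times must be strictly increasing")
            if times[0] < 0 or times[-1] > self.duration_s:
                raise ValueError("spike times must lie in [0, duration_s]")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)


@dataclass(frozen=True)
class WaveformFeatures:
    """Waveform and rate features used by the DA-neuron inclusion gate."""

    triphasic: bool
    duration_ms: float
    start_to_trough_ms: float
    mean_rate_hz: float

    def __post_init__(self) -> None:
        if self.duration_ms < 0 or self.start_to_trough_ms < 0:
            raise ValueError("waveform durations must be non-negative")
        if self.mean_rate_hz < 0:
            raise ValueError("mean_rate_hz must be non-negative")


@dataclass(frozen=True)
class BurstParams:
    """Two-threshold burst rule: onset ISI < 80 ms, continuation ISI <= 160 ms."""

    onset_isi_max_ms: float = 80.0
    continuation_isi_max_ms: float = 160.0

    def __post_init__(self) -> None:
        if not 0 < self.onset_isi_max_ms < self.continuation_isi_max_ms:
            raise ValueError(
                "require 0 < onset_isi_max_ms < continuation_isi_max_ms"
            )


@dataclass(frozen=True)
class Burst:
    """One detected burst: inclusive spike-index span within a train."""

    first_spike_index: int
    last_spike_index: int

    def __post_init__(self) -> None:
        if self.last_spike_index <= self.first_spike_index:
            raise ValueError("a burst needs at least two spikes")

    @property
    def n_spikes(self) -> int:
        return self.last_spike_index - self.first_spike_index + 1


@dataclass(frozen=True)
class BurstStats:
    """Per-neuron firing rate, detected bursts, and %SWB."""

    neuron_id: str
    firing_rate_hz: float
    bursts: tuple[Burst, ...]
    swb_percent: float
    n_spikes: int = field(default=0)

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)


# Inclusion criteria for putative DA neurons recorded in vivo:
# triphasic waveform, total duration > 2.0 ms, start-to-trough > 1.1 ms,
# and a slow firing rate strictly between 1 and 10 Hz.
_DURATION_MIN_MS = 2.0
_WIDTH_MIN_MS = 1.1
_RATE_LO_HZ = 1.0
_RATE_HI_HZ = 10.0


def classify_da_neuron(f: WaveformFeatures) -> tuple[bool, list[str]]:
    """Apply the four-part DA-neuron inclusion gate.

    Returns ``(accepted, reasons)`` where ``reasons`` lists every violated
    criterion (``triphasic``, ``duration``, ``width``, ``rate``); the list is
    empty iff the neuron is accepted.
    """
    reasons: list[str] = []
    if not f.triphasic:
        reasons.append("triphasic")
    if not f.duration_ms > _DURATION_MIN_MS:
        reasons.append("duration")
    if not f.start_to_trough_ms > _WIDTH_MIN_MS:
        reasons.append("width")
    if not _RATE_LO_HZ < f.mean_rate_hz < _RATE_HI_HZ:
        reasons.append("rate")
    return (not reasons, reasons)


def _times_to_us(times_s: np.ndarray) -> np.ndarray:
    # Integer-microsecond comparison removes float ambiguity exactly at the
    # 80/160 ms boundaries.
    return np.round(np.asarray(times_s, dtype=float) * 1e6).astype(np.int64)


def detect_bursts(train: SpikeTrain, params: BurstParams | None = None) -> list[Burst]:
    """Detect bursts with the two-threshold ISI rule.

    A burst opens at the first of two consecutive spikes with ISI strictly
    below ``onset_isi_max_ms``; spikes are appended while the next ISI is at
    most ``continuation_isi_max_ms``; the burst closes when the next ISI
    exceeds that bound or the train ends.  Scanning resumes after the burst's
    last spike, so bursts are disjoint and each spike belongs to at most one.
    """
    if params is None:
        params = BurstParams()
    times_us = _times_to_us(train.spike_times_s)
    onset_us = int(round(params.onset_isi_max_ms * 1e3))
    cont_us = int(round(params.continuation_isi_max_ms * 1e3))

    n = times_us.size
    if n < 2:
        return []
    isi = np.diff(times_us)
    bursts: list[Burst] = []
    i = 0
    while i < n - 1:
        if isi[i] < onset_us:
            j = i + 1
            while j < n - 1 and isi[j] <= cont_us:
                j += 1
            bursts.append(Burst(i, j))
            i = j + 1
        else:
            i += 1
    return bursts


def burst_stats(train: SpikeTrain, params: BurstParams | None = None) -> BurstStats:
    """Firing rate and %SWB (spikes within bursts / total spikes x 100)."""
    bursts = detect_bursts(train, params)
    n = train.n_spikes
    rate = n / train.duration_s
    in_burst = sum(b.n_spikes for b in bursts)
    swb = 100.0 * in_burst / n if n else 0.0
    return BurstStats(
        neuron_id=train.neuron_id,
        firing_rate_hz=rate,
        bursts=tuple(bursts),
        swb_percent=swb,
        n_spikes=n,
    )
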