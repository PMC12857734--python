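"""Fiber-photometry signal processing: dF/F, z-scores, peri-event AUC.

Dual-excitation recordings pair an activity-dependent 465 nm channel with an
activity-independent 405 nm (isosbestic) reference that shares bleaching and
motion artifacts.  The reference is fitted to the signal with an affine
least-squares fit; dF/F is the fractional deviation of the signal from that
fitted reference.  Traces are reported as z-scores of dF/F relative to a
declared baseline window, aligned into peri-event matrices, and quantified
as area under the z-score curve in contiguous 5-s bins.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "PhotometryTrace",
    "ProcessedTrace",
    "PeriEventMatrix",
    "BinnedAuc",
    "correct_and_dff",
    "zscore_trace",
    "process_trace",
    "peri_event_matrix",
    "binned_auc",
]


@dataclass(frozen=True)
class PhotometryTrace:
    """Uniformly sampled dual-channel fluorescence trace."""

    time_s: np.ndarray
    f465: np.ndarray
    f405: np.ndarray
    fs_hz: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.f465, dtype=float)
        r = np.asarray(self.f405, dtype=float)
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "f465", s)
        object.__setattr__(self, "f405", r)
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if not (t.size == s.size == r.size):
            raise ValueError("time and channel vectors must have equal length")
        if t.size >= 2:
            dt = np.diff(t)
            if np.any(dt <= 0):
                raise ValueError("time must be strictly increasing")
            if not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-6, atol=1e-9):
                raise ValueError("time grid must be uniform at fs_hz")

    @property
    def n_samples(self) -> int:
        return int(self.time_s.size)


@dataclass(frozen=True)
class ProcessedTrace:
    """Motion/bleach-corrected dF/F and its baseline z-score."""

    time_s: np.ndarray
    dff: np.ndarray
    zscore: np.ndarray
    baseline_window_s: tuple[float, float]
    fs_hz: float


@dataclass(frozen=True)
class PeriEventMatrix:
    """Event-aligned z-score rows; time 0 is event onset."""

    z: np.ndarray  # events x samples
    time_rel_s: np.ndarray
    window_s: tuple[float, float]
    event_times_s: np.ndarray
    dropped_event_times_s: np.ndarray
    fs_hz: float

    @property
    def n_events(self) -> int:
        return int(self.z.shape[0])


@dataclass(frozen=True)
class BinnedAuc:
    """Per-bin AUC of a z-score series (z·s), contiguous bins."""

    bin_edges_s: np.ndarray
    auc: np.ndarray
    last_bin_partial: bool = False


def correct_and_dff(trace: PhotometryTrace) -> np.ndarray:
    """Affine isosbestic correction: dF/F = (F465 − r) / r, r = fit of F405.

    The 405 nm reference is regressed onto the 465 nm signal (slope +
    intercept, least squares); dF/F is invariant under a common
    multiplicative rescaling of both channels.  A constant reference admits
    no fit and is rejected, unless the signal channel is identical to it
    (the fitted reference is then the signal itself and dF/F is zero).
    """
    if trace.n_samples < 2:
        raise ValueError("need at least 2 samples")
    x = trace.f405
    y = trace.f465
    if np.ptp(x) == 0.0:
        if np.array_equal(x, y):
            return np.zeros_like(y)
        raise ValueError("constant 405 nm reference: fit is degenerate")
    slope, intercept = np.polyfit(x, y, 1)
    r = slope * x + intercept
    if np.any(r == 0):
        raise ValueError("fitted reference crosses zero; dF/F undefined")
    return (y - r) / r


def zscore_trace(
    time_s: np.ndarray,
    dff: np.ndarray,
    baseline_window_s: tuple[float, float],
    fs_hz: float,
) -> ProcessedTrace:
    """z-score dF/F against the mean/SD of a declared baseline window.

    The sample SD (ddof=1) of the window is used; over the baseline window
    the resulting z-score has mean 0 and SD 1 by construction.
    """
    time_s = np.asarray(time_s, dtype=float)
    dff = np.asarray(dff, dtype=float)
    lo, hi = baseline_window_s
    if lo >= hi:
        raise ValueError("baseline window must have positive length")
    if lo < time_s[0] or hi > time_s[-1]:
        raise ValueError("baseline window outside the recording")
    mask = (time_s >= lo) & (time_s <= hi)
    if int(mask.sum()) < 10:
        raise ValueError("baseline window must contain at least 10 samples")
    base = dff[mask]
    sd = base.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance in the baseline window")
    z = (dff - base.mean()) / sd
    return ProcessedTrace(
        time_s=time_s,
        dff=dff,
        zscore=z,
        baseline_window_s=(float(lo), float(hi)),
        fs_hz=fs_hz,
    )


def process_trace(
    trace: PhotometryTrace, baseline_window_s: tuple[float, float]
) -> ProcessedTrace:
    """Convenience: isosbestic correction followed by baseline z-scoring."""
    return zscore_trace(
        trace.time_s, correct_and_dff(trace), baseline_window_s, trace.fs_hz
    )


def peri_event_matrix(
    p: ProcessedTrace,
    event_times_s,
    window_s: tuple[float, float],
    rebaseline: str | None = "pre",
) -> PeriEventMatrix:
    """Align the trace around event onsets into an events × samples matrix.

    Each row spans ``event − pre`` to ``event + post`` (inclusive endpoints).
    Events whose window overruns a recording edge are dropped and logged.
    With ``rebaseline="pre"`` (the default) each row is re-z-scored against
    its own pre-event span — the peri-event baseline convention under which
    pre-event traces hover around zero; ``rebaseline=None`` keeps the
    session-level z-score.
    """
    pre, post = window_s
    if pre <= 0 or post <= 0:
        raise ValueError("window (pre, post) must both be positive")
    events = np.asarray(event_times_s, dtype=float)
    if events.size and np.any(np.diff(events) < 0):
        raise ValueError("event times must be sorted")
    fs = p.fs_hz
    t0 = p.time_s[0]
    n = p.time_s.size
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))

    rows, kept, dropped = [], [], []
    for e in events:
        ie = int(round((e - t0) * fs))
        i0, i1 = ie - n_pre, ie + n_post
        if i0 < 0 or i1 >= n:
            dropped.append(e)
            logger.warning("event at %.3f s dropped: window overruns recording", e)
            continue
        row = p.zscore[i0 : i1 + 1]
        if rebaseline == "pre":
            base = p.dff[i0 : i0 + n_pre]
            sd = base.std(ddof=1)
            if sd == 0:
                raise ValueError(f"zero pre-event variance at event {e} s")
            row = (p.dff[i0 : i1 + 1] - base.mean()) / sd
        rows.append(row)
        kept.append(e)
    if not rows:
        raise ValueError("no events survive edge filtering")

    return PeriEventMatrix(
        z=np.vstack(rows),
        time_rel_s=np.arange(-n_pre, n_post + 1) / fs,
        window_s=(float(pre), float(post)),
        event_times_s=np.asarray(kept),
        dropped_event_times_s=np.asarray(dropped),
        fs_hz=fs,
    )


def binned_auc(
    z: np.ndarray, fs_hz: float, bin_s: float = 5.0, t_start_s: float = 0.0
) -> BinnedAuc:
    """AUC of a z-score series in contiguous ``bin_s``-second bins.

    Left-Riemann quadrature (each sample owns [t, t+dt)) makes the AUC
    exactly additive over adjacent bins.  If the series does not fill an
    integer number of bins, the trailing partial bin is kept and flagged.
    """
    z = np.asarray(z, dtype=float).ravel()
    if z.size == 0:
        raise ValueError("empty input")
    dt = 1.0 / fs_hz
    n_per = int(round(bin_s * fs_hz))
    if n_per < 1:
        raise ValueError("bin_s shorter than one sample")
    n_full, rem = divmod(z.size, n_per)
    aucs = [z[i * n_per : (i + 1) * n_per].sum() * dt for i in range(n_full)]
    edges = [t_start_s + i * bin_s for i in range(n_full + 1)]
    partial = rem > 0
    if partial:
        aucs.append(z[n_full * n_per :].sum() * dt)
        edges.append(t_start_s + n_full * bin_s + rem * dt)
    return BinnedAuc(
        bin_edges_s=np.asarray(edges),
        auc=np.asarray(aucs),
        last_bin_partial=partial,
    )
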