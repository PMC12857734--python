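import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def random_train_times(rng, max_spikes=120):
    """Random spike times on an exact 1-ms grid (no float boundary ambiguity)."""
    n = int(rng.integers(0, max_spikes))
    if n == 0:
        return np.array([])
    # ISIs from 1 ms to 1 s, integer ms; includes the 80/160 ms boundaries often
    isis_ms = rng.integers(1, 1000, n - 1) if n > 1 else np.array([], dtype=int)
    # force boundary-adjacent ISIs to appear regularly
    if isis_ms.size:
        boundary = rng.random(isis_ms.size) < 0.25
        isis_ms[boundary] = rng.choice([79, 80, 81, 159, 160, 161], boundary.sum())
    times_ms = np.concatenate([[0], np.cumsum(isis_ms)]) + int(rng.integers(0, 100))
    return times_ms / 1000.0


def reference_burst_spans(times_s, onset_ms=80.0, cont_ms=160.0):
    """Independent naive burst scanner used as the oracle.

    Walks the train spike by spike with an explicit in-burst flag, comparing
    ISIs in milliseconds (inputs are on an exact ms grid).
    """
    t_ms = [round(x * 1000) for x in np.asarray(times_s, dtype=float)]
    spans = []
    start = None
    k = 0
    while k < len(t_ms) - 1:
        isi = t_ms[k + 1] - t_ms[k]
        if start is None:
            if isi < onset_ms:
                start = k
        else:
            if isi > cont_ms:
                spans.append((start, k))
                start = None
        k += 1
    if start is not None:
        spans.append((start, len(t_ms) - 1))
    return spans
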