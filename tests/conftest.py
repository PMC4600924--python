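import numpy as np
import pytest

from doamon import EEGRecord


def sampen_bruteforce_counts(x, m, r):
    """O(N^2) pair-count oracle for sample entropy, by direct enumeration.

    Templates i = 0..N-m-1 (those that can be extended by one point);
    Chebyshev distance; self-matches excluded.  Returns (A, B).
    """
    x = np.asarray(x, dtype=float)
    T = np.lib.stride_tricks.sliding_window_view(x, m + 1)  # (N-m, m+1)
    d_m = np.abs(T[:, None, :m] - T[None, :, :m]).max(axis=-1)
    d_m1 = np.maximum(d_m, np.abs(T[:, None, m] - T[None, :, m]))
    iu = np.triu_indices(T.shape[0], k=1)
    b = int(np.count_nonzero(d_m[iu] <= r))
    a = int(np.count_nonzero(d_m1[iu] <= r))
    return a, b


def sampen_bruteforce(x, m, r):
    a, b = sampen_bruteforce_counts(x, m, r)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def short_eeg(rng):
    """A 4 s broadband record, long enough for small-window analyses."""
    return EEGRecord(rng.standard_normal(500), fs=125.0)
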