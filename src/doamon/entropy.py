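"""Sample entropy, coarse-graining, and multiscale entropy (MSE).

Sample entropy (Richman & Moorman) of a series ``x`` with embedding
dimension ``m`` and tolerance ``r`` is

    SampEn(m, r, N) = -ln( A / B )

where ``B`` counts pairs of distinct m-point templates whose Chebyshev
distance is at most ``r`` and ``A`` counts the pairs that still match when
extended by one point.  Self-matches are excluded.  The conventional
tolerance is ``r = 0.2 * SD(x)``.

MSE evaluates SampEn on coarse-grained copies of the series: at scale tau
consecutive blocks of tau samples are averaged, shortening the series to
floor(N/tau).  The tolerance stays fixed at 0.2x the *original* (scale-1)
SD, so the profile reflects the loss of fast structure, not the shrinking
variance.  Scale 1 is exactly SampEn.

For monitoring, entropies are computed in a 30 s sliding window (3750
samples at 125 Hz) advanced every 5 s, yielding a windows x scales matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .records import EEGRecord


@dataclass
class SampEnParams:
    """Embedding dimension and relative tolerance (fraction of series SD)."""

    m: int = 2
    r_rel: float = 0.2

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_rel <= 0:
            raise ValueError("r_rel must be positive")


DEFAULT_SCALES = tuple(range(1, 21))


@njit(cache=True)
def _match_counts(x, m, r):  # pragma: no cover - exercised via sampen
    """Pair counts (A, B) over distinct template pairs i < j."""
    n = x.shape[0]
    a = 0
    b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            match = True
            for k in range(m):
                if abs(x[i + k] - x[j + k]) > r:
                    match = False
                    break
            if match:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    return a, b


def match_counts(x: np.ndarray, m: int, r: float) -> tuple[int, int]:
    """(A, B): m+1- and m-template match-pair counts at absolute tolerance r."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    return tuple(int(v) for v in _match_counts(x, m, r))


def sampen(x, params: SampEnParams | None = None, *, m: int | None = None,
           r: float | None = None, relative: bool = True) -> float:
    """Sample entropy in nats; NaN when undefined.

    By default the tolerance is ``params.r_rel * SD(x)``; pass ``r`` with
    ``relative=False`` for an absolute tolerance.  Returns NaN (the
    undefined marker) for a zero-variance series or when no template pairs
    match.
    """
    params = params or SampEnParams()
    m = params.m if m is None else m
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < m + 2:
        raise ValueError(f"series must be 1-D with at least m+2={m + 2} points")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if r is None or relative:
        r_rel = params.r_rel if r is None else r
        sd = x.std()
        if sd == 0:
            return np.nan
        r_abs = r_rel * sd
    else:
        r_abs = float(r)
    a, b = match_counts(x, m, r_abs)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def coarse_grain(x, tau: int) -> np.ndarray:
    """Non-overlapping tau-sample averages; trailing remainder discarded."""
    x = np.asarray(x, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    if tau > x.size:
        raise ValueError(f"tau={tau} exceeds series length {x.size}")
    n = (x.size // tau) * tau
    return x[:n].reshape(-1, tau).mean(axis=1)


def mse_profile(x, scales=DEFAULT_SCALES, params: SampEnParams | None = None) -> np.ndarray:
    """SampEn of the coarse-grained series at each scale.

    The tolerance is fixed from the scale-1 SD of ``x`` and reused across
    scales.  Undefined entropies (zero SD, no matches, or a coarse-grained
    series too short to embed) are reported as NaN per scale without
    aborting the others.
    """
    params = params or SampEnParams()
    x = np.asarray(x, dtype=float)
    sd = x.std()
    out = np.full(len(scales), np.nan)
    if sd == 0:
        return out
    r_abs = params.r_rel * sd
    for i, tau in enumerate(scales):
        y = coarse_grain(x, int(tau))
        if y.size < params.m + 2:
            continue
        a, b = match_counts(y, params.m, r_abs)
        if a > 0 and b > 0:
            out[i] = -np.log(a / b)
    return out


@dataclass
class MSEMatrix:
    """Windows x scales grid of entropies from a sliding-window analysis."""

    values: np.ndarray                 # (n_windows, n_scales), NaN = undefined
    window_start_s: np.ndarray         # (n_windows,)
    scales: tuple = DEFAULT_SCALES
    params: SampEnParams = field(default_factory=SampEnParams)
    window_s: float = 30.0
    step_s: float = 5.0
    filtered: bool = False

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.window_start_s = np.asarray(self.window_start_s, dtype=float)
        sc = np.asarray(self.scales)
        if not (np.all(sc >= 1) and np.all(np.diff(sc) > 0)):
            raise ValueError("scales must be strictly increasing positive integers")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def window_end_s(self) -> np.ndarray:
        return self.window_start_s + self.window_s


def sliding_mse(x: EEGRecord, window_s: float = 30.0, step_s: float = 5.0,
                scales=DEFAULT_SCALES, params: SampEnParams | None = None,
                filtered: bool = False) -> MSEMatrix:
    """MSE profile of each sliding window (30 s window, 5 s hop by default).

    At 125 Hz the defaults give 3750-sample windows advanced by 625
    samples.  The tolerance is re-derived per window from that window's
    scale-1 SD.
    """
    params = params or SampEnParams()
    win = int(round(window_s * x.fs))
    hop = int(round(step_s * x.fs))
    if x.n < win:
        raise ValueError(
            f"record of {x.n} samples is shorter than one {win}-sample window")
    if hop < 1:
        raise ValueError("step_s too small for the sampling rate")
    starts = np.arange(0, x.n - win + 1, hop)
    values = np.empty((starts.size, len(scales)))
    for w, s0 in enumerate(starts):
        values[w] = mse_profile(x.samples[s0:s0 + win], scales, params)
    return MSEMatrix(values, x.t0 + starts / x.fs, tuple(int(s) for s in scales),
                     params, window_s, step_s, filtered)
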