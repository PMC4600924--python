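"""Multivariate empirical mode decomposition (MEMD) and IMF-based filtering.

EMD decomposes a signal into intrinsic mode functions (IMFs) ordered from
high to low characteristic frequency plus a residue; the signal is exactly
the sum of its IMFs and the residue.  The multivariate extension sifts all
channels jointly: the local mean is estimated by projecting the signal onto
a set of direction vectors spread over the unit hypersphere, interpolating
the signal through the extrema of each projection, and averaging the
resulting envelopes.  Joint sifting guarantees every channel yields the
same number of IMFs.

Single-channel EEG is handled in noise-assisted mode: independent white
noise is placed in extra channels, the multivariate decomposition is run,
and only the signal channel's IMFs are kept.  Unlike ensemble EMD this
injects no noise into the output while still counteracting mode mixing.

EOG artifacts live in the lowest-frequency IMFs of forehead EEG, so the
default denoising reconstruction keeps IMF2 + IMF3 — the band that retains
the EEG while dropping both the highest-frequency noise (IMF1) and the slow
blink transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import norm

from .records import EEGRecord


class SiftConvergenceError(RuntimeError):
    """Sifting failed to produce a valid IMF within the iteration budget."""

    def __init__(self, imf_index: int, iterations: int):
        super().__init__(
            f"sifting of IMF {imf_index} did not converge within "
            f"{iterations} iterations")
        self.imf_index = imf_index


@dataclass
class MEMDConfig:
    """Knobs of the decomposition.

    ``n_noise_channels``/``noise_sd_rel`` configure the noise-assisted
    single-channel mode; ``n_directions`` is the number of projection
    directions on the hypersphere; ``sift_stop`` the envelope-mean-to-signal
    amplitude ratio below which sifting of an IMF stops; ``max_imfs`` bounds
    runtime on long windows.
    """

    n_noise_channels: int = 2
    noise_sd_rel: float = 0.1
    n_directions: int = 64
    sift_stop: float = 0.075
    max_sift_iter: int = 100
    max_imfs: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_noise_channels < 1:
            raise ValueError("n_noise_channels must be >= 1")
        if self.n_directions < 4:
            raise ValueError("n_directions must be >= 4")


@dataclass
class IMFSet:
    """Ordered IMFs plus residue of one channel; their sum is the source."""

    imfs: np.ndarray          # (n_imfs, n_samples), high -> low frequency
    residue: np.ndarray       # (n_samples,)
    source_fs: float = 125.0
    config: MEMDConfig | None = None

    @property
    def n_imfs(self) -> int:
        return self.imfs.shape[0]

    def reconstruct_all(self) -> np.ndarray:
        return self.imfs.sum(axis=0) + self.residue


# ---------------------------------------------------------------------------
# extrema / zero-crossing utilities

def count_zero_crossings(x: np.ndarray) -> int:
    s = np.sign(x)
    s = s[s != 0]
    if s.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(s) != 0))


def _extrema_indices(x: np.ndarray):
    """Indices of strict local maxima and minima (plateau midpoints count once)."""
    d = np.diff(x)
    s = np.sign(d)
    # propagate the sign over flat segments so plateaus yield one extremum
    nz = s != 0
    if not nz.any():
        return np.empty(0, int), np.empty(0, int)
    idx = np.where(nz, np.arange(s.size), -1)
    idx = np.maximum.accumulate(idx)
    filled = np.where(idx >= 0, s[np.maximum(idx, 0)], 0)
    change = np.diff(filled)
    maxima = np.flatnonzero(change < 0) + 1
    minima = np.flatnonzero(change > 0) + 1
    return maxima, minima


def count_extrema(x: np.ndarray) -> int:
    mx, mn = _extrema_indices(x)
    return int(mx.size + mn.size)


def is_imf(x: np.ndarray) -> bool:
    """Extrema and zero-crossing counts differ by at most one."""
    return abs(count_extrema(x) - count_zero_crossings(x)) <= 1


# ---------------------------------------------------------------------------
# direction vectors

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29)


def _radical_inverse(i: int, base: int) -> float:
    f, r = 1.0, 0.0
    while i > 0:
        f /= base
        r += f * (i % base)
        i //= base
    return r


def hammersley_directions(n_dir: int, dim: int) -> np.ndarray:
    """Quasi-uniform unit vectors on the (dim-1)-sphere.

    A Hammersley point set on the unit cube is pushed through the Gaussian
    quantile per coordinate and normalised; the low-discrepancy structure
    survives the map well enough to spread projections over the sphere.
    """
    if dim - 1 > len(_PRIMES):
        raise ValueError("too many channels for the direction generator")
    pts = np.empty((n_dir, dim))
    for i in range(n_dir):
        pts[i, 0] = (i + 0.5) / n_dir
        for d in range(1, dim):
            pts[i, d] = _radical_inverse(i + 1, _PRIMES[d - 1])
    pts = np.clip(pts, 1e-6, 1 - 1e-6)
    vec = norm.ppf(pts)
    vec /= np.linalg.norm(vec, axis=1, keepdims=True)
    return vec


# ---------------------------------------------------------------------------
# sifting

def _mirror_extend(idx: np.ndarray, vals: np.ndarray, n: int, pad: int = 2):
    """Mirror boundary extrema about the record ends to anchor the splines."""
    t = idx.astype(float)
    t_parts = [t]
    v_parts = [vals]
    left_k = min(pad, t.size)
    lt = -t[:left_k][::-1]
    lv = vals[:left_k][::-1]
    keep = lt < t[0]
    if keep.any():
        t_parts.insert(0, lt[keep])
        v_parts.insert(0, lv[keep])
    right_k = min(pad, t.size)
    rt = 2 * (n - 1) - t[-right_k:][::-1]
    rv = vals[-right_k:][::-1]
    keep = rt > t[-1]
    if keep.any():
        t_parts.append(rt[keep])
        v_parts.append(rv[keep])
    return np.concatenate(t_parts), np.concatenate(v_parts, axis=0)


def _envelope_mean(h: np.ndarray, directions: np.ndarray):
    """Mean of directional envelopes; None if the signal is too featureless."""
    n, _ = h.shape
    t = np.arange(n)
    acc = np.zeros_like(h)
    used = 0
    for v in directions:
        proj = h @ v
        mx, _ = _extrema_indices(proj)
        if mx.size < 2:
            continue
        te, ve = _mirror_extend(mx, h[mx], n)
        acc += CubicSpline(te, ve, axis=0)(t)
        used += 1
    if used < max(4, directions.shape[0] // 4):
        return None
    return acc / used


def _univariate_mean(x: np.ndarray):
    """Classic EMD local mean: average of the channel's own extremal splines."""
    n = x.size
    mx, mn = _extrema_indices(x)
    if mx.size < 2 or mn.size < 2:
        return None
    te, ve = _mirror_extend(mx, x[mx], n)
    upper = CubicSpline(te, ve)(np.arange(n))
    te, ve = _mirror_extend(mn, x[mn], n)
    lower = CubicSpline(te, ve)(np.arange(n))
    return 0.5 * (upper + lower)


def _polish_channel(x: np.ndarray, config: MEMDConfig, imf_index: int) -> np.ndarray:
    """Univariate refinement sifts until the IMF acceptance criterion holds.

    The joint multivariate sift aligns modes across channels but its mean
    envelope (interpolated at projection extrema) cannot fully cancel each
    channel's own local mean, leaving riding waves; a few classic
    single-channel sifts remove them.
    """
    h = x
    for _ in range(config.max_sift_iter):
        m = _univariate_mean(h)
        if m is None:
            return h
        ratio = np.sqrt(np.mean(m ** 2)) / max(np.sqrt(np.mean(h ** 2)), 1e-300)
        if ratio < config.sift_stop and is_imf(h):
            return h
        h = h - m
    if is_imf(h):
        return h
    raise SiftConvergenceError(imf_index, config.max_sift_iter)


def _sift_one_imf(x: np.ndarray, directions: np.ndarray, config: MEMDConfig,
                  imf_index: int):
    """Extract one multivariate IMF from ``x`` (n_samples, n_channels).

    Returns None when ``x`` is already a residue (too few projection
    extrema to envelope).  Joint sifting runs until the envelope-mean
    amplitude ratio drops below ``config.sift_stop``; each channel is then
    polished univariately so the final component satisfies the per-channel
    extrema/zero-crossing criterion.
    """
    h = x.copy()
    m = _envelope_mean(h, directions)
    if m is None:
        return None
    for _ in range(config.max_sift_iter):
        h = h - m
        ratio = np.sqrt(np.mean(m ** 2)) / max(np.sqrt(np.mean(h ** 2)), 1e-300)
        if ratio < config.sift_stop:
            break
        m = _envelope_mean(h, directions)
        if m is None:
            break
    for c in range(h.shape[1]):
        h[:, c] = _polish_channel(h[:, c], config, imf_index)
    return h


def memd_decompose(channels: np.ndarray, config: MEMDConfig | None = None,
                   fs: float = 125.0) -> list[IMFSet]:
    """Joint decomposition of a multichannel signal.

    Parameters
    ----------
    channels : ndarray, shape (n_samples, n_channels)
        At least two channels of equal length >= 16.

    Returns
    -------
    list of IMFSet, one per channel, each with the same number of IMFs.
    The residue is the exact remainder, so IMFs + residue always reproduce
    the input to floating-point accuracy.
    """
    config = config or MEMDConfig()
    x = np.asarray(channels, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("channels must be 2-D with at least two columns")
    if x.shape[0] < 16:
        raise ValueError("need at least 16 samples")
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")

    directions = hammersley_directions(config.n_directions, x.shape[1])
    rem = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < config.max_imfs:
        imf = _sift_one_imf(rem, directions, config, imf_index=len(imfs) + 1)
        if imf is None:
            break
        if not all(is_imf(imf[:, c]) for c in range(imf.shape[1])):
            # too few extrema left to envelope: the remainder is residue
            break
        imfs.append(imf)
        rem = rem - imf
    stack = np.stack(imfs) if imfs else np.empty((0,) + x.shape)
    out = []
    for c in range(x.shape[1]):
        ch_imfs = stack[:, :, c]
        residue = x[:, c] - ch_imfs.sum(axis=0)
        out.append(IMFSet(ch_imfs, residue, source_fs=fs, config=config))
    return out


def na_memd_single(x: EEGRecord, config: MEMDConfig | None = None) -> IMFSet:
    """Noise-assisted single-channel MEMD.

    White-noise channels (``config.n_noise_channels``, SD
    ``config.noise_sd_rel`` x signal SD) are stacked next to the signal,
    the multivariate decomposition is run, and the signal channel's IMFSet
    is returned; the noise channels are discarded, so no noise enters the
    output.
    """
    config = config or MEMDConfig()
    if x.n < 16:
        raise ValueError("need at least 16 samples")
    rng = np.random.default_rng(config.seed)
    sd = x.samples.std()
    if sd == 0:
        sd = 1.0
    noise = config.noise_sd_rel * sd * rng.standard_normal(
        (x.n, config.n_noise_channels))
    stacked = np.column_stack([x.samples, noise])
    return memd_decompose(stacked, config, fs=x.fs)[0]


def reconstruct(imfset: IMFSet, p: int, q: int,
                include_residue: bool = False) -> np.ndarray:
    """Band selection: sum of IMFs p..q (1-based, inclusive)."""
    n = imfset.n_imfs
    if not 1 <= p <= q <= n:
        raise ValueError(f"need 1 <= p <= q <= {n}, got p={p}, q={q}")
    out = imfset.imfs[p - 1:q].sum(axis=0)
    if include_residue:
        out = out + imfset.residue
    return out


def band_stop(imfset: IMFSet, p: int, q: int) -> np.ndarray:
    """Band-stop selection: sum of IMFs 1..q plus p..N, requiring q < p."""
    n = imfset.n_imfs
    if not 1 <= q < p <= n:
        raise ValueError(
            f"band_stop needs 1 <= q < p <= {n}, got q={q}, p={p}; "
            "use reconstruct for a contiguous band")
    return reconstruct(imfset, 1, q) + reconstruct(imfset, p, n)


def eeg_filter(x: EEGRecord, config: MEMDConfig | None = None,
               imf_selection=(2, 3), include_residue: bool = False,
               return_imfs: bool = False):
    """Denoise EEG by keeping selected IMFs of the noise-assisted decomposition.

    The default IMF2 + IMF3 reconstruction removes both the fastest
    component and the slow high-amplitude EOG band.
    """
    selection = sorted(set(int(i) for i in imf_selection))
    if not selection or selection[0] < 1:
        raise ValueError("imf_selection must contain positive indices")
    imfset = na_memd_single(x, config)
    if imfset.n_imfs < selection[-1]:
        raise RuntimeError(
            f"decomposition produced {imfset.n_imfs} IMFs, fewer than the "
            f"requested IMF {selection[-1]}")
    out = imfset.imfs[[i - 1 for i in selection]].sum(axis=0)
    if include_residue:
        out = out + imfset.residue
    rec = EEGRecord(out, fs=x.fs, t0=x.t0, stage=x.stage,
                    label=f"{x.label} [IMF {'+'.join(map(str, selection))}]")
    return (rec, imfset) if return_imfs else rec


def mean_zero_crossing_rates(imfset: IMFSet) -> np.ndarray:
    """Zero-crossing rate (per sample) of each IMF; diagnostic for ordering."""
    n = imfset.imfs.shape[1]
    return np.array([count_zero_crossings(c) / n for c in imfset.imfs])
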