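"""Synthetic signal generators for exercising the monitoring pipeline.

Clinical recordings are not needed to test the method: these generators
emulate the features the pipeline is sensitive to —

* spectrally distinct awake vs. anesthesia EEG (awake EEG is broadband and
  irregular; EEG under stable anesthesia is dominated by slow waves),
* blink-like EOG artifacts: sparse, high-amplitude, low-frequency transients,
* mixing of clean EEG and artifact at a prescribed SNR,
* a smooth 0-100 consciousness curve sampled at 0.2 Hz
  (awake plateau -> induction descent -> surgical plateau -> recovery),
* EEG whose spectral content tracks such a curve, for end-to-end recovery
  studies.

All generators are deterministic given their seed.  Amplitudes are in
microvolts with a nominal 10 uV EEG standard deviation; entropy analysis is
amplitude-invariant so the scale is cosmetic.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .records import EEGRecord, GoldStandard

_EEG_SD_UV = 10.0


def generate_white_noise(n: int, sigma: float = 1.0, seed: int = 0,
                         fs: float = 125.0) -> EEGRecord:
    """I.i.d. Gaussian noise with mean 0 and standard deviation ``sigma``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    rng = np.random.default_rng(seed)
    return EEGRecord(sigma * rng.standard_normal(int(n)), fs=fs,
                     label=f"white noise sd={sigma}")


def _bandlimited(rng: np.random.Generator, n: int, fs: float,
                 btype: str, cutoff, order: int = 4) -> np.ndarray:
    """Unit-SD filtered Gaussian noise."""
    b, a = signal.butter(order, np.asarray(cutoff) / (fs / 2), btype=btype)
    x = signal.lfilter(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink(rng: np.random.Generator, n: int, fs: float,
          f_lo: float = 0.5, f_hi: float = 45.0) -> np.ndarray:
    """Unit-SD band-limited 1/f noise via FFT amplitude shaping."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, 1 / fs)
    shape = np.zeros_like(f)
    band = (f >= f_lo) & (f <= f_hi)
    shape[band] = 1.0 / np.sqrt(f[band])
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    if sd == 0:  # record too short to resolve the band
        x = rng.standard_normal(n)
        sd = x.std()
    return x / sd


def generate_synthetic_eeg(duration_s: float, fs: float = 125.0,
                           stage: str = "preoperation", seed: int = 0) -> EEGRecord:
    """Stage-dependent spectrally shaped Gaussian noise.

    ``preoperation`` (awake) gives 1/f-type broadband noise with an alpha
    accent — irregular and high-frequency-rich like desynchronised awake
    EEG; ``maintenance`` (anesthesia) gives slow-wave-dominated noise with
    at least 70% of its power below 8 Hz.  Both are zero-mean.
    """
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("duration_s * fs must be >= 2")
    rng = np.random.default_rng(seed)
    if stage == "preoperation":
        x = _pink(rng, n, fs)
        x = x + 0.4 * _bandlimited(rng, n, fs, "bandpass", [8.0, 12.0])
    elif stage == "maintenance":
        # delta/theta-dominated slow waves plus a weak fast component
        x = _bandlimited(rng, n, fs, "lowpass", 5.0)
        x = x + 0.25 * _bandlimited(rng, n, fs, "bandpass", [8.0, 30.0])
    else:
        raise ValueError(
            f"unknown stage {stage!r}; generators cover 'preoperation' and 'maintenance'")
    x = x - x.mean()
    x *= _EEG_SD_UV / x.std()
    return EEGRecord(x, fs=fs, stage=stage, label=f"synthetic {stage} EEG")


def generate_eog(duration_s: float, fs: float = 125.0,
                 blink_rate_hz: float = 0.25, seed: int = 0,
                 drift_rel: float = 0.3) -> EEGRecord:
    """Blink-like EOG artifact: Poisson-timed Gaussian bumps plus ocular drift.

    Each blink lasts 200-400 ms with amplitude 5-10x the nominal EEG SD.
    Between blinks the eye is not still: a continuous slow drift
    (< 1.5 Hz, amplitude ``drift_rel`` x the blink-train SD) rides under
    the transients, as in frontal-channel recordings from awake subjects.
    The combined energy is concentrated well below 4 Hz, which is what the
    IMF-based filter exploits.  A zero blink rate yields a silent record.
    """
    if blink_rate_hz < 0:
        raise ValueError("blink_rate_hz must be >= 0")
    n = int(round(duration_s * fs))
    x = np.zeros(max(n, 1))
    rng = np.random.default_rng(seed)
    if blink_rate_hz > 0:
        t = rng.exponential(1.0 / blink_rate_hz)
        times = []
        while t < duration_s:
            times.append(t)
            t += rng.exponential(1.0 / blink_rate_hz)
        grid = np.arange(n) / fs
        for tc in times:
            width_s = rng.uniform(0.2, 0.4)      # full blink duration
            amp = rng.uniform(5.0, 10.0) * _EEG_SD_UV
            sig = width_s / 6.0                  # +-3 sigma spans the blink
            x += amp * np.exp(-0.5 * ((grid - tc) / sig) ** 2)
        blink_sd = x.std()
        if drift_rel > 0 and blink_sd > 0 and n >= 16:
            x += drift_rel * blink_sd * _bandlimited(rng, n, fs, "lowpass", 1.5)
    return EEGRecord(x, fs=fs, label="synthetic EOG")


def mix_at_snr(clean: EEGRecord, artifact: EEGRecord, snr_db: float) -> EEGRecord:
    """Add a scaled artifact so that 10*log10(P_clean / P_artifact) = snr_db.

    Power is the mean squared amplitude over the whole record.
    """
    if clean.n != artifact.n or clean.fs != artifact.fs:
        raise ValueError("clean and artifact must share length and sampling rate")
    p_clean = np.mean(clean.samples ** 2)
    p_art = np.mean(artifact.samples ** 2)
    if p_art == 0:
        raise ValueError("artifact has zero power; cannot scale to a target SNR")
    gain = np.sqrt(p_clean / (p_art * 10.0 ** (snr_db / 10.0)))
    return EEGRecord(clean.samples + gain * artifact.samples, fs=clean.fs,
                     t0=clean.t0, stage=clean.stage,
                     label=f"{clean.label} + EOG @ {snr_db:g} dB")


def generate_gold_curve(duration_s: float, seed: int = 0,
                        fs: float = 0.2) -> GoldStandard:
    """Smooth synthetic consciousness curve: awake ~95, surgical plateau
    40-60, then recovery; sampled at 0.2 Hz, clipped to [0, 100]."""
    if duration_s < 10:
        raise ValueError("duration_s must be >= 10")
    rng = np.random.default_rng(seed)
    t = np.arange(int(np.floor(duration_s * fs))) / fs
    awake = rng.uniform(92.0, 98.0)
    plateau = rng.uniform(46.0, 54.0)
    wake = rng.uniform(88.0, 96.0)
    t1, w1 = 0.15 * duration_s, 0.04 * duration_s
    t2, w2 = 0.78 * duration_s, 0.05 * duration_s

    def sigm(z):
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))

    c = awake - (awake - plateau) * sigm((t - t1) / w1) \
        + (wake - plateau) * sigm((t - t2) / w2)
    # slow seeded drift, small enough to keep the plateau in band
    c += 1.5 * np.sin(2 * np.pi * t / (duration_s / rng.uniform(1.5, 3.0))
                      + rng.uniform(0, 2 * np.pi))
    return GoldStandard(np.clip(c, 0.0, 100.0), fs=fs, source="synthetic")


def generate_depth_modulated_eeg(gold: GoldStandard, fs: float = 125.0,
                                 seed: int = 0,
                                 sensor_noise_rel: float = 0.3) -> EEGRecord:
    """EEG whose spectrum interpolates awake <-> anesthesia along ``gold``.

    The record is a pointwise mixture ``w*awake + (1-w)*anesthesia`` with
    ``w = gold/100`` interpolated onto the sample grid, plus additive
    broadband sensor noise (``sensor_noise_rel`` x the EEG SD) standing in
    for the instrument and muscle noise every real recording carries.  The
    noise matters: it blurs the scale-1 entropy (which sees every fast
    fluctuation) far more than the larger scales, whose coarse-graining
    averages it out — the situation the multiscale index is designed for.
    Sliding-window MSE of the result carries a learnable relationship with
    the consciousness level, used by the end-to-end recovery study.
    """
    duration_s = gold.n / gold.fs
    awake = generate_synthetic_eeg(duration_s, fs, "preoperation", seed=seed)
    anes = generate_synthetic_eeg(duration_s, fs, "maintenance", seed=seed + 1)
    t = awake.times()
    w = np.interp(t, gold.times(), gold.values) / 100.0
    x = w * awake.samples + (1.0 - w) * anes.samples
    if sensor_noise_rel > 0:
        rng = np.random.default_rng(seed + 2)
        x = x + sensor_noise_rel * x.std() * rng.standard_normal(x.size)
    return EEGRecord(x, fs=fs, label="depth-modulated synthetic EEG")
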