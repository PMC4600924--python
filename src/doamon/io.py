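"""Readers and writers for the formats the pipeline touches.

EEG travels as two-column CSV (``time_s, amplitude_uV``) or EDF (read via
:mod:`mne` when installed); gold-standard series as two-column CSV
(``time_s, value``); MSE matrices as wide CSV (one column per scale) with a
JSON sidecar of the analysis parameters; models as JSON.  Expert-assessment
(EACL) curves from several raters are averaged pointwise into the gold
standard, and hand-drawn curves are resampled onto the uniform 0.2 Hz grid
by linear interpolation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .entropy import MSEMatrix, SampEnParams
from .model import ANNModel
from .records import EEGRecord, GoldStandard

_FLOAT_FMT = "%.10g"


# ---------------------------------------------------------------------------
# EEG

def write_eeg(record: EEGRecord, path) -> None:
    """CSV writer: columns time_s, amplitude_uV."""
    df = pd.DataFrame({"time_s": record.times(), "amplitude_uV": record.samples})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_eeg(path, fs: float | None = None, channel=None) -> EEGRecord:
    """Read EEG from CSV (time_s, amplitude_uV) or EDF.

    For CSV the sampling rate is taken from the time column (must be
    uniform) unless ``fs`` overrides it.  For EDF (requires ``mne``) a
    ``channel`` name or index must be given when the file holds several.
    """
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return _read_edf(path, channel)
    df = pd.read_csv(path)
    if not {"time_s", "amplitude_uV"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, amplitude_uV")
    t = df["time_s"].to_numpy(dtype=float)
    if fs is None:
        dt = np.diff(t)
        if t.size < 2:
            raise ValueError(f"{path}: need at least 2 samples to infer fs")
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9) or dt[0] <= 0:
            raise ValueError(f"{path}: non-uniform time column; pass fs explicitly")
        fs = 1.0 / dt[0]
    return EEGRecord(df["amplitude_uV"].to_numpy(dtype=float), fs=fs,
                     t0=float(t[0]) if t.size else 0.0, label=path.stem)


def _read_edf(path: Path, channel) -> EEGRecord:
    try:
        import mne
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading EDF requires the 'mne' package") from e
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    if channel is None:
        if len(names) != 1:
            raise ValueError(
                f"{path} holds {len(names)} channels {names}; pass channel=")
        channel = names[0]
    if isinstance(channel, int):
        channel = names[channel]
    data = raw.get_data(picks=[channel])[0] * 1e6  # volts -> microvolts
    return EEGRecord(data, fs=float(raw.info["sfreq"]), label=f"{path.stem}:{channel}")


# ---------------------------------------------------------------------------
# gold standard

def write_gold(gold: GoldStandard, path) -> None:
    df = pd.DataFrame({"time_s": gold.times(), "value": gold.values})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_gold(path, source: str = "BIS") -> GoldStandard:
    df = pd.read_csv(path)
    if not {"time_s", "value"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns time_s, value")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6):
        raise ValueError(f"{path}: gold standard must be uniformly sampled")
    return GoldStandard(df["value"].to_numpy(dtype=float), fs=1.0 / dt[0],
                        t0=float(t[0]), source=source)


def aggregate_eacl(raters) -> GoldStandard:
    """Pointwise mean of several raters' 0.2 Hz assessment curves.

    ``raters`` is a sequence of equal-length arrays or GoldStandard
    objects (one per anesthesiologist).
    """
    series = [r.values if isinstance(r, GoldStandard) else np.asarray(r, float)
              for r in raters]
    if not series:
        raise ValueError("need at least one rater")
    n = series[0].size
    if any(s.size != n for s in series):
        raise ValueError("rater curves must have equal length")
    t0 = raters[0].t0 if isinstance(raters[0], GoldStandard) else 0.0
    fs = raters[0].fs if isinstance(raters[0], GoldStandard) else 0.2
    return GoldStandard(np.mean(series, axis=0), fs=fs, t0=t0, source="EACL_mean")


def resample_gold(times, values, fs_out: float = 0.2) -> GoldStandard:
    """Linearly interpolate an irregular hand-drawn curve onto a uniform grid.

    The grid spans the curve at ``fs_out`` (0.2 Hz, the BIS export rate);
    values are clamped to [0, 100].
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points to resample")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    grid = t[0] + np.arange(int(np.floor((t[-1] - t[0]) * fs_out)) + 1) / fs_out
    out = np.clip(np.interp(grid, t, v), 0.0, 100.0)
    return GoldStandard(out, fs=fs_out, t0=float(t[0]), source="EACL_mean")


# ---------------------------------------------------------------------------
# MSE matrices

def write_mse(mse: MSEMatrix, path, tidy_path=None) -> None:
    """Wide CSV (scale_1..scale_N per window) plus a JSON parameter sidecar;
    optionally also a tidy CSV (window_start_s, scale, entropy)."""
    path = Path(path)
    cols = {"window_start_s": mse.window_start_s}
    for i, s in enumerate(mse.scales):
        cols[f"scale_{s}"] = mse.values[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=_FLOAT_FMT)
    sidecar = {
        "m": mse.params.m, "r_rel": mse.params.r_rel,
        "window_s": mse.window_s, "step_s": mse.step_s,
        "scales": list(mse.scales), "filtered": mse.filtered,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))
    if tidy_path is not None:
        rows = [(t, s, mse.values[w, i])
                for w, t in enumerate(mse.window_start_s)
                for i, s in enumerate(mse.scales)]
        pd.DataFrame(rows, columns=["window_start_s", "scale", "entropy"]) \
            .to_csv(tidy_path, index=False, float_format=_FLOAT_FMT)


def read_mse(path) -> MSEMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    scales = tuple(sidecar["scales"])
    values = df[[f"scale_{s}" for s in scales]].to_numpy(dtype=float)
    return MSEMatrix(values, df["window_start_s"].to_numpy(dtype=float),
                     scales, SampEnParams(sidecar["m"], sidecar["r_rel"]),
                     sidecar["window_s"], sidecar["step_s"], sidecar["filtered"])


# ---------------------------------------------------------------------------
# models and index series

def save_model(model: ANNModel, path) -> None:
    Path(path).write_text(model.to_json())


def load_model(path) -> ANNModel:
    return ANNModel.from_json(Path(path).read_text())


def write_index(times_s: np.ndarray, index: np.ndarray, path) -> None:
    pd.DataFrame({"time_s": times_s, "doa_index": index}) \
        .to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_index(path):
    df = pd.read_csv(path)
    return df["time_s"].to_numpy(dtype=float), df["doa_index"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# IMF sets

def write_imfset(imfset, path) -> None:
    """Multi-column CSV (imf1..imfN, residue) plus a JSON config sidecar."""
    path = Path(path)
    cols = {f"imf{i + 1}": imfset.imfs[i] for i in range(imfset.n_imfs)}
    cols["residue"] = imfset.residue
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    cfg = imfset.config
    sidecar = {"source_fs": imfset.source_fs}
    if cfg is not None:
        sidecar["config"] = {
            "n_noise_channels": cfg.n_noise_channels,
            "noise_sd_rel": cfg.noise_sd_rel,
            "n_directions": cfg.n_directions,
            "sift_stop": cfg.sift_stop,
            "max_sift_iter": cfg.max_sift_iter,
            "max_imfs": cfg.max_imfs,
            "seed": cfg.seed,
        }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_imfset(path):
    from .memd import IMFSet, MEMDConfig
    path = Path(path)
    df = pd.read_csv(path)
    imf_cols = [c for c in df.columns if c.startswith("imf")]
    imf_cols.sort(key=lambda c: int(c[3:]))
    sidecar = json.loads(path.with_suffix(".json").read_text())
    cfg = MEMDConfig(**sidecar["config"]) if "config" in sidecar else None
    return IMFSet(df[imf_cols].to_numpy(dtype=float).T,
                  df["residue"].to_numpy(dtype=float),
                  source_fs=sidecar.get("source_fs", 125.0), config=cfg)
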