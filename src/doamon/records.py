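"""Core data containers for EEG depth-of-anesthesia monitoring.

The pipeline passes three kinds of series around: raw EEG (`EEGRecord`,
typically 125 Hz single-channel forehead EEG in microvolts), a gold-standard
consciousness series (`GoldStandard`, a 0.2 Hz curve in [0, 100] such as a
BIS export or the mean of expert-drawn assessments), and an SNR grid used by
the artifact-sensitivity study.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Stage labels used in the studies: "preoperation" is the awake baseline
#: ("stage 1"), "maintenance" the period of stable surgical anesthesia
#: ("stage 3").
STAGES = ("preoperation", "induction", "maintenance", "recovery")


@dataclass
class EEGRecord:
    """A uniformly sampled single-channel EEG signal.

    Parameters
    ----------
    samples : ndarray
        Amplitude series in microvolts.
    fs : float
        Sampling rate in Hz (125 for the forehead-sensor recordings this
        package models).
    t0 : float
        Start time in seconds.
    label : str
        Free-text description.
    stage : str or None
        Optional anesthesia stage, one of :data:`STAGES`.
    """

    samples: np.ndarray
    fs: float = 125.0
    t0: float = 0.0
    label: str = ""
    stage: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.stage is not None and self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class GoldStandard:
    """A 0.2 Hz depth-of-anesthesia reference series in [0, 100].

    100 is fully awake, 0 is EEG silence; 40-60 is the band regarded as
    adequate surgical anesthesia.
    """

    values: np.ndarray
    fs: float = 0.2
    t0: float = 0.0
    source: str = "synthetic"  # "BIS", "EACL_mean" or "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-D array")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 100:
            raise ValueError("gold-standard values must lie in [0, 100]")

    @property
    def n(self) -> int:
        return self.values.size

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs


@dataclass
class SNRGrid:
    """Signal-to-artifact ratio grid in dB, enumerated start -> stop inclusive.

    The default grid (10 dB down to -20 dB in -1 dB steps) spans from mild
    contamination to artifact power 100x the EEG power.
    """

    start_db: float = 10.0
    stop_db: float = -20.0
    step_db: float = -1.0

    def __post_init__(self) -> None:
        if self.step_db == 0:
            raise ValueError("step_db must be nonzero")
        if (self.stop_db - self.start_db) * self.step_db < 0:
            raise ValueError("step_db must point from start_db toward stop_db")

    def levels(self) -> np.ndarray:
        """Grid values in dB, endpoints included."""
        n = int(np.floor((self.stop_db - self.start_db) / self.step_db + 1e-9)) + 1
        return self.start_db + self.step_db * np.arange(n)


@dataclass
class EvalReport:
    """Agreement between a predicted DOA index and the gold standard.

    ``corr`` is the Pearson correlation, ``r_squared`` its square (the
    coefficient of determination as reported by regression tooling),
    ``cv_pct`` the coefficient of variation (%) of per-case correlations
    when the report aggregates several recordings.
    """

    corr: float
    r_squared: float
    n: int
    cv_pct: float | None = None
    per_case_corr: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.corr) and not -1 - 1e-9 <= self.corr <= 1 + 1e-9:
            raise ValueError("correlation out of [-1, 1]")
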