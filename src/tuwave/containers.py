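"""Core data containers shared across the pipeline.

All waveforms are in millivolts, times in seconds, sampling rates in Hz.
Sample indices are 0-based; times are measured from the start of the beat
window unless a docstring says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

__all__ = [
    "EcgRecording",
    "AveragedBeat",
    "FiducialSet",
    "TuParameters",
    "PredictorVector",
    "PREDICTOR_NAMES",
]


@dataclass
class EcgRecording:
    """Multi-lead raw ECG waveform.

    Parameters
    ----------
    samples : ndarray, shape (n_leads, n_samples)
        Signal in mV.
    fs : float
        Sampling rate in Hz.
    lead_labels : list of str
        One label per lead (e.g. ``V2``).
    """

    samples: np.ndarray
    fs: float
    lead_labels: list[str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_leads, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.lead_labels) != self.samples.shape[0]:
            raise ValueError("one label per lead required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def lead(self, label: str) -> np.ndarray:
        """Return one lead by label."""
        try:
            idx = self.lead_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"lead {label!r} not in recording") from exc
        return self.samples[idx]


@dataclass
class AveragedBeat:
    """Signal-averaged beat: per-lead mean of aligned beats plus mean RR."""

    samples: np.ndarray
    fs: float
    lead_labels: list[str]
    mean_rr: float
    n_beats_used: int
    r_offset: int = 0  # sample index of the R peak inside the beat window

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be 2-D (n_leads, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.n_beats_used < 2:
            raise ValueError("n_beats_used must be >= 2")
        if len(self.lead_labels) != self.samples.shape[0]:
            raise ValueError("one label per lead required")

    @property
    def n_leads(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    def lead(self, label: str) -> np.ndarray:
        try:
            idx = self.lead_labels.index(label)
        except ValueError as exc:
            raise KeyError(f"lead {label!r} not in beat") from exc
        return self.samples[idx]


@dataclass
class FiducialSet:
    """TU-complex fiducial points on the analysis lead.

    Integer fields are sample indices into the beat window; ``t_end`` and
    ``u_end`` come from the tangent method and may fall between samples, so
    they are stored as times in seconds from the window start.
    """

    q_onset: int
    j_point: int
    t_peak: int
    bottom_b: int
    u_peak: int
    t_end: float
    u_end: float
    analysis_lead: str
    fs: float
    baseline: float = 0.0  # isoelectric level in mV

    def validate(self) -> None:
        """Raise if the fiducial ordering is anatomically impossible."""
        if not (self.q_onset < self.j_point < self.t_peak < self.bottom_b < self.u_peak):
            raise ValueError(
                "fiducial ordering violated: require "
                "q_onset < j_point < t_peak < bottom_b < u_peak, got "
                f"{self.q_onset}, {self.j_point}, {self.t_peak}, "
                f"{self.bottom_b}, {self.u_peak}"
            )
        if not self.t_peak / self.fs < self.t_end:
            raise ValueError("t_end must follow t_peak")
        if not self.u_peak / self.fs < self.u_end:
            raise ValueError("u_end must follow u_peak")

    def time_of(self, name: str) -> float:
        """Time (s, from window start) of any fiducial by field name."""
        value = getattr(self, name)
        if name in ("t_end", "u_end"):
            return float(value)
        return float(value) / self.fs

    def shifted(self, k: int) -> "FiducialSet":
        """Return a copy with every fiducial translated by k samples."""
        dt = k / self.fs
        return FiducialSet(
            q_onset=self.q_onset + k,
            j_point=self.j_point + k,
            t_peak=self.t_peak + k,
            bottom_b=self.bottom_b + k,
            u_peak=self.u_peak + k,
            t_end=self.t_end + dt,
            u_end=self.u_end + dt,
            analysis_lead=self.analysis_lead,
            fs=self.fs,
            baseline=self.baseline,
        )

    def to_dict(self) -> dict:
        return {
            "q_onset": int(self.q_onset),
            "j_point": int(self.j_point),
            "t_peak": int(self.t_peak),
            "bottom_b": int(self.bottom_b),
            "u_peak": int(self.u_peak),
            "t_end_s": float(self.t_end),
            "u_end_s": float(self.u_end),
            "analysis_lead": self.analysis_lead,
            "fs_hz": float(self.fs),
            "baseline_mv": float(self.baseline),
        }


# Field order follows the study's comparison table.
TABLE_PARAMETER_NAMES = [
    "hr", "qtc", "quc", "qtp", "qup", "teue", "tpup", "bup", "bue",
    "up_amp", "tp_amp", "ut_ratio", "pca_ratio",
]


@dataclass
class TuParameters:
    """Temporal/amplitude parameter vector for one subject.

    Intervals are RR-corrected seconds (Bazett: interval / sqrt(RR)) unless
    produced with correction disabled; amplitudes are mV relative to the
    isoelectric baseline.
    """

    hr: float          # bpm
    qtc: float         # Q onset -> T end
    quc: float         # Q onset -> U end
    qtp: float         # Q onset -> T peak
    qup: float         # Q onset -> U peak
    teue: float        # T end -> U end
    tpup: float        # T peak -> U peak
    bup: float         # bottom B -> U peak
    bue: float         # bottom B -> U end (U duration)
    tp_amp: float      # T peak amplitude, mV
    up_amp: float      # U peak amplitude, mV
    ut_ratio: float    # up_amp / tp_amp
    pca_ratio: float = float("nan")  # percent, second/first PC variance

    def validate(self) -> None:
        for name in ("qtc", "quc", "qtp", "qup", "teue", "tpup", "bup", "bue"):
            if getattr(self, name) <= 0:
                raise ValueError(f"interval {name} must be positive")
        if self.bue <= self.bup:
            raise ValueError("bue must exceed bup (U end after U peak)")
        if self.quc <= self.qtc:
            raise ValueError("quc must exceed qtc (U end after T end)")

    def as_dict(self) -> dict:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}


#: The 15 explanatory variables of the logistic-model layer. Times are
#: RR-corrected seconds from Q onset; the *y-suffixed entries are the
#: amplitudes (mV) read at the corresponding fiducial.
PREDICTOR_NAMES = [
    "tp", "tpy", "te", "b", "up", "upy", "ue", "uey",
    "uete", "jte", "bup", "bue", "upue", "tpup", "pca_ratio",
]


@dataclass
class PredictorVector:
    """The 15-entry predictor set used for best-subset logistic regression."""

    tp: float
    tpy: float
    te: float
    b: float
    up: float
    upy: float
    ue: float
    uey: float
    uete: float
    jte: float
    bup: float
    bue: float
    upue: float
    tpup: float
    pca_ratio: float

    def as_array(self) -> np.ndarray:
        arr = np.array([getattr(self, n) for n in PREDICTOR_NAMES], dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValueError("predictor vector contains non-finite entries")
        return arr

    def as_dict(self) -> dict:
        return {n: float(getattr(self, n)) for n in PREDICTOR_NAMES}

    def __len__(self) -> int:
        return len(PREDICTOR_NAMES)
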