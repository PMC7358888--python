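"""TU-complex parameters, the logistic predictor set, and the PCA ratio.

All temporal parameters are heart-rate corrected (Bazett, interval/sqrt(RR))
to match how the group comparison table is defined; amplitudes are read at
the fiducial sample relative to the isoelectric baseline.  The PCA ratio
summarizes inter-lead repolarization dyssynchrony: the ratio of the second
to the first principal-component variance of the J-point -> U-end segment,
in percent.
"""

from __future__ import annotations

import numpy as np

from .containers import (
    AveragedBeat,
    FiducialSet,
    PredictorVector,
    TuParameters,
)
from .delineate import rate_correct

__all__ = ["compute_parameters", "pca_ratio", "predictor_vector"]


def compute_parameters(
    fiducials: FiducialSet,
    beat: AveragedBeat,
    pca: float = float("nan"),
    correct: bool = True,
) -> TuParameters:
    """Compute the full temporal/amplitude parameter vector for one subject.

    Parameters
    ----------
    fiducials : FiducialSet
        Delineated on ``beat``'s analysis lead.
    beat : AveragedBeat
        Signal-averaged beat providing the waveform and mean RR.
    pca : float
        PCA ratio in percent (optional; NaN if not computed).
    correct : bool
        Apply Bazett correction (divide intervals by sqrt(RR)).  Disable
        to obtain raw intervals.

    Raises
    ------
    ValueError
        If the T-peak amplitude is non-positive (U/T undefined) or any
        interval is degenerate.
    """
    fiducials.validate()
    x = beat.lead(fiducials.analysis_lead)
    rr = beat.mean_rr
    f = fiducials.time_of

    def corr(interval: float) -> float:
        return rate_correct(interval, rr) if correct else interval

    q = f("q_onset")
    tp_amp = float(x[fiducials.t_peak] - fiducials.baseline)
    up_amp = float(x[fiducials.u_peak] - fiducials.baseline)
    if tp_amp <= 0:
        raise ValueError("non-positive T amplitude: U/T ratio undefined")

    params = TuParameters(
        hr=60.0 / rr,
        qtc=corr(f("t_end") - q),
        quc=corr(f("u_end") - q),
        qtp=corr(f("t_peak") - q),
        qup=corr(f("u_peak") - q),
        teue=corr(f("u_end") - f("t_end")),
        tpup=corr(f("u_peak") - f("t_peak")),
        bup=corr(f("u_peak") - f("bottom_b")),
        bue=corr(f("u_end") - f("bottom_b")),
        tp_amp=tp_amp,
        up_amp=up_amp,
        ut_ratio=up_amp / tp_amp,
        pca_ratio=pca,
    )
    params.validate()
    return params


def pca_ratio(
    beat: AveragedBeat,
    fiducials: FiducialSet,
    definition: str = "eigenvalue_ratio",
) -> float:
    """Inter-lead PCA dyssynchrony ratio of the TU segment, in percent.

    The segment from the J point to the U end is taken on every lead, the
    per-lead mean is removed, and the inter-lead covariance matrix is
    eigendecomposed; the ratio of the second-largest to largest eigenvalue
    (x100) measures how far the leads depart from a single shared
    repolarization waveform.  ``definition='singular_ratio'`` returns the
    singular-value ratio instead.

    Raises
    ------
    ValueError
        On an all-zero (rank-0) segment or fewer than 2 leads.
    """
    if beat.n_leads < 2:
        raise ValueError("PCA ratio requires at least 2 leads")
    lo = fiducials.j_point
    hi = int(round(fiducials.u_end * beat.fs))
    hi = min(hi, beat.n_samples)
    if hi - lo < 2:
        raise ValueError("TU segment too short for PCA")
    seg = beat.samples[:, lo:hi]
    seg = seg - seg.mean(axis=1, keepdims=True)
    cov = (seg @ seg.T) / (seg.shape[1] - 1)
    if not np.any(cov):
        raise ValueError("rank-0 (all-zero) TU segment")
    evals = np.linalg.eigvalsh(cov)[::-1]  # descending
    lam1, lam2 = float(evals[0]), float(max(evals[1], 0.0))
    if definition == "eigenvalue_ratio":
        return 100.0 * lam2 / lam1
    if definition == "singular_ratio":
        return 100.0 * np.sqrt(lam2 / lam1)
    raise ValueError(f"unknown PCA ratio definition {definition!r}")


def predictor_vector(
    fiducials: FiducialSet,
    beat: AveragedBeat,
    pca: float,
    correct: bool = True,
) -> PredictorVector:
    """The 15 U-wave-related explanatory variables for model selection.

    Times (tp, te, b, up, ue) are measured from Q onset and RR-corrected;
    the *y-suffixed entries are amplitudes (mV) at the T peak, U peak and
    U end; uete/jte/upue are the corresponding interval differences.
    """
    fiducials.validate()
    x = beat.lead(fiducials.analysis_lead)
    rr = beat.mean_rr
    f = fiducials.time_of

    def corr(interval: float) -> float:
        return rate_correct(interval, rr) if correct else interval

    q = f("q_onset")
    ue_idx = min(int(round(fiducials.u_end * beat.fs)), beat.n_samples - 1)
    return PredictorVector(
        tp=corr(f("t_peak") - q),
        tpy=float(x[fiducials.t_peak] - fiducials.baseline),
        te=corr(f("t_end") - q),
        b=corr(f("bottom_b") - q),
        up=corr(f("u_peak") - q),
        upy=float(x[fiducials.u_peak] - fiducials.baseline),
        ue=corr(f("u_end") - q),
        uey=float(x[ue_idx] - fiducials.baseline),
        uete=corr(f("u_end") - f("t_end")),
        jte=corr(f("t_end") - f("j_point")),
        bup=corr(f("u_peak") - f("bottom_b")),
        bue=corr(f("u_end") - f("bottom_b")),
        upue=corr(f("u_end") - f("u_peak")),
        tpup=corr(f("u_peak") - f("t_peak")),
        pca_ratio=pca,
    )
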