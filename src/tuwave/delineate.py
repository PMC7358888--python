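"""TU-complex delineation on the analysis lead.

Fiducials are located on raw, first- and second-derivative traces of the
signal-averaged beat: Q onset and J point by a combined amplitude/slope
return-to-baseline criterion around the QRS, T and U peaks by prominence
peak-picking on the TU segment, bottom B as the minimum of the bifid
complex between the peaks, and T/U ends by the tangent method — the
tangent at the wave's steepest down-slope extrapolated to the isoelectric
line.
"""

from __future__ import annotations

from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .containers import AveragedBeat, FiducialSet

__all__ = [
    "differentiate",
    "select_analysis_lead",
    "tangent_end",
    "locate_fiducials",
    "rate_correct",
]

#: U waves smaller than this (mV, relative to baseline) are treated as absent.
DEFAULT_AMPLITUDE_FLOOR = 0.010

# return-to-baseline criterion: within 1% of R amplitude AND local slope
# below 2% of the peak QRS slope
_AMP_FRACTION = 0.01
_SLOPE_FRACTION = 0.02


def differentiate(beat: AveragedBeat) -> tuple[np.ndarray, np.ndarray]:
    """First and second central-difference derivatives of every lead.

    Returns
    -------
    (d1, d2) : ndarrays, same shape as ``beat.samples``
        In mV/s and mV/s^2; endpoints use one-sided differences.
    """
    if beat.n_samples < 5:
        raise ValueError("beat too short to differentiate")
    dt = 1.0 / beat.fs
    d1 = np.gradient(beat.samples, dt, axis=1)
    d2 = np.gradient(d1, dt, axis=1)
    return d1, d2


def rate_correct(interval: float, rr: float) -> float:
    """Bazett heart-rate correction: interval / sqrt(RR)."""
    if rr <= 0:
        raise ValueError("rr must be positive")
    return interval / np.sqrt(rr)


def _smooth(x: np.ndarray, width_s: float, fs: float) -> np.ndarray:
    w = max(int(round(width_s * fs)) | 1, 3)
    return np.convolve(x, np.ones(w) / w, mode="same")


def tangent_end(
    x: np.ndarray,
    peak: int,
    search_window: int,
    fs: float,
    baseline: float = 0.0,
) -> float:
    """Tangent-method wave end (seconds from the start of ``x``).

    Anchors on the first substantial local minimum of the first derivative
    after ``peak`` (the wave's own steepest down-slope; shallow wiggles
    below 60% of the window's steepest slope are skipped) and returns the
    time where that tangent crosses the ``baseline`` level.  The crossing
    may fall between samples.

    Raises
    ------
    ValueError
        If no descending limb exists inside the window.
    """
    lo = peak + 1
    hi = min(peak + search_window, len(x) - 1)
    if hi <= lo + 2:
        raise ValueError("tangent search window too short")
    # work on the signed deflection so biphasic (negative) waves delineate
    # the same way; "descending" then always means returning to baseline
    sign = 1.0 if x[peak] >= baseline else -1.0
    y = sign * (np.asarray(x, dtype=float) - baseline)
    ys = _smooth(y, 0.010, fs)

    # truncate the window where the wave has returned to <8% of its peak:
    # beyond that there is no limb, only noise (or the next beat)
    level = 0.08 * ys[peak]
    below = np.flatnonzero(ys[lo:hi] < level)
    if below.size:
        hi = max(lo + 3, lo + int(below[0]))

    # anchor on the steepest down-slope of the (smoothed) limb
    d1 = _smooth(np.gradient(y, 1.0 / fs), 0.008, fs)
    seg = d1[lo:hi]
    if seg.min() >= 0:
        raise ValueError("no descending limb after peak (monotone segment)")
    anchor = lo + int(np.argmin(seg))
    # tangent slope and value by least squares over +/-14 ms around the
    # anchor: far less noise-sensitive than a pointwise derivative, and
    # nearly unbiased because the anchor is the wave's inflection point
    h = max(int(round(0.014 * fs)), 2)
    a0, a1 = max(anchor - h, 0), min(anchor + h + 1, len(y))
    tt = (np.arange(a0, a1) - anchor) / fs
    slope, value = np.polyfit(tt, y[a0:a1], 1)
    if slope >= 0 or value <= 0:
        raise ValueError("no descending limb after peak")
    return anchor / fs + value / (-slope)


def _qrs_bounds(
    x: np.ndarray,
    r: int,
    fs: float,
    baseline: float,
) -> tuple[int, int]:
    """Q onset and J point by the return-to-baseline criterion around R."""
    r_amp = abs(x[r] - baseline)
    if r_amp <= 0:
        raise ValueError("flat QRS")
    d1s = _smooth(np.gradient(x, 1.0 / fs), 0.007, fs)
    qrs_lo = max(r - int(0.15 * fs), 1)
    qrs_hi = min(r + int(0.15 * fs), len(x) - 1)
    max_slope = np.max(np.abs(d1s[qrs_lo:qrs_hi]))

    def quiet(i: int, relax: float) -> bool:
        return (abs(x[i] - baseline) < relax * _AMP_FRACTION * r_amp
                and abs(d1s[i]) < _SLOPE_FRACTION * max_slope)

    # the amplitude tolerance is relaxed progressively: at fast heart rates
    # the previous beat's U wave can keep the whole PQ stretch off baseline
    q_onset = None
    for relax in (1.0, 2.5, 5.0):
        for i in range(r - int(0.010 * fs), qrs_lo - 1, -1):
            if quiet(i, relax):
                q_onset = i
                break
        if q_onset is not None:
            break
    if q_onset is None:
        raise ValueError("QRS onset not found (no return to baseline before R)")

    j_point = None
    for relax in (1.0, 2.5, 5.0):
        for i in range(r + int(0.012 * fs), qrs_hi + 1):
            if quiet(i, relax):
                j_point = i
                break
        if j_point is not None:
            break
    if j_point is None:
        raise ValueError("QRS offset not found (no return to baseline after R)")
    return q_onset, j_point


def locate_fiducials(
    beat: AveragedBeat,
    lead: Optional[str] = None,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
) -> FiducialSet:
    """Delineate the full TU-complex fiducial set on one lead.

    Parameters
    ----------
    beat : AveragedBeat
        Signal-averaged (preferably denoised) beat.
    lead : str, optional
        Lead label; defaults to the larger-U of V2/V3 via
        :func:`select_analysis_lead`.
    amplitude_floor : float
        Minimum |U amplitude| (mV); below it the beat is declared to have
        no discernible U wave.

    Raises
    ------
    ValueError
        "no U wave detected" if the floor is not met, or on an ordering
        violation.
    """
    if lead is None:
        lead = select_analysis_lead(beat, amplitude_floor)
    x = beat.lead(lead)
    fs = beat.fs
    n = len(x)

    # R peak: the averaging stage pins R at r_offset; fall back to the
    # dominant deflection for beats without that metadata
    if 0 < beat.r_offset < n - 1:
        r = int(beat.r_offset)
    else:
        med = np.median(x)
        r = int(np.argmax(np.abs(x - med)))

    # provisional baseline from the quiet stretch just before the QRS (the
    # previous beat's U wave can intrude further out at fast heart rates),
    # refined to the 40 ms window ending at Q onset
    pre_lo, pre_hi = max(r - int(0.105 * fs), 0), max(r - int(0.045 * fs), 1)
    baseline0 = float(np.median(x[pre_lo:pre_hi]))
    q_onset, j_point = _qrs_bounds(x, r, fs, baseline0)
    bl_lo = max(q_onset - int(0.040 * fs), 0)
    baseline = float(np.mean(x[bl_lo:q_onset])) if q_onset > bl_lo else baseline0
    # second pass with the refined isoelectric level
    q_onset, j_point = _qrs_bounds(x, r, fs, baseline)
    bl_lo = max(q_onset - int(0.040 * fs), 0)
    if q_onset > bl_lo:
        baseline = float(np.mean(x[bl_lo:q_onset]))

    # TU search segment: from just after J to before the next beat's QRS
    seg_lo = j_point + int(0.010 * fs)
    seg_hi = min(n - 2, r + int((beat.mean_rr - 0.060) * fs))
    if seg_hi - seg_lo < int(0.05 * fs):
        raise ValueError("TU segment too short to delineate")
    # peaks and the bifid minimum are located on a lightly smoothed copy
    # (10 ms) so residual noise cannot shift them across flat tops/valleys
    xs = _smooth(x, 0.010, fs)
    seg = xs[seg_lo:seg_hi] - baseline

    prominence = max(0.005, 0.4 * amplitude_floor)
    pk_pos, _ = find_peaks(seg, prominence=prominence)
    if pk_pos.size == 0:
        raise ValueError("no T wave detected in the TU segment")
    # T peak: tallest peak in the first 55% of the TU segment (the T wave
    # always precedes the U wave, and shoulders stay below the peak)
    first = pk_pos[pk_pos <= 0.55 * (seg_hi - seg_lo)]
    t_peak = seg_lo + int(first[np.argmax(seg[first])] if first.size
                          else pk_pos[int(np.argmax(seg[pk_pos]))])

    # U peak: largest |amplitude| extremum after the T peak (either
    # polarity; biphasic U waves take the larger deflection)
    after = t_peak - seg_lo + int(0.020 * fs)
    cand_pos = pk_pos[pk_pos > after]
    pk_neg, _ = find_peaks(-seg, prominence=prominence)
    cand_neg = pk_neg[pk_neg > after]
    best, best_amp = None, 0.0
    for c in np.concatenate([cand_pos, cand_neg]):
        amp = abs(seg[int(c)])
        if amp > best_amp:
            best, best_amp = int(c), amp
    if best is None or best_amp < amplitude_floor:
        raise ValueError("no U wave detected")
    u_peak = seg_lo + best
    # relocalize the (often flat) U extremum on a more heavily smoothed
    # trace; 20 ms smoothing biases a broad peak by well under a sample
    xb = _smooth(x, 0.020, fs)
    sgn = 1.0 if seg[best] >= 0 else -1.0
    h = int(round(0.025 * fs))
    w_lo, w_hi = max(u_peak - h, seg_lo), min(u_peak + h + 1, seg_hi)
    u_peak = w_lo + int(np.argmax(sgn * xb[w_lo:w_hi]))

    # bifid minimum on the heavily smoothed trace (residual noise would
    # wander across a shallow valley on the raw one)
    bottom_b = t_peak + 1 + int(np.argmin(xb[t_peak + 1: u_peak]))

    # stop the T-tangent search clear of the bottom so a deep T-U
    # junction notch cannot masquerade as the T downslope
    t_end = tangent_end(x, t_peak,
                        max(bottom_b - t_peak - int(0.045 * fs), int(0.030 * fs)),
                        fs, baseline)
    u_win = min(int(0.25 * fs), n - 1 - u_peak)
    u_end = tangent_end(x, u_peak, u_win, fs, baseline)

    fid = FiducialSet(
        q_onset=q_onset,
        j_point=j_point,
        t_peak=t_peak,
        bottom_b=bottom_b,
        u_peak=u_peak,
        t_end=t_end,
        u_end=u_end,
        analysis_lead=lead,
        fs=fs,
        baseline=baseline,
    )
    fid.validate()
    return fid


def select_analysis_lead(
    beat: AveragedBeat,
    amplitude_floor: float = DEFAULT_AMPLITUDE_FLOOR,
) -> str:
    """Pick the analysis lead: whichever of V2/V3 shows the larger U wave.

    Ties break deterministically to V2.  A lead whose provisional
    delineation fails counts as having no U wave; if neither lead is
    present, this is an error.
    """
    candidates = [lab for lab in ("V2", "V3") if lab in beat.lead_labels]
    if not candidates:
        raise ValueError("lead labels must include V2 or V3")
    amps = {}
    for lab in candidates:
        try:
            fid = locate_fiducials(beat, lead=lab, amplitude_floor=amplitude_floor)
            amps[lab] = abs(beat.lead(lab)[fid.u_peak] - fid.baseline)
        except ValueError:
            amps[lab] = -np.inf
    if all(v == -np.inf for v in amps.values()):
        raise ValueError("no U wave detected on V2 or V3")
    # strict 'larger amplitude wins'; ties fall back to V2
    if len(candidates) == 2 and amps["V3"] > amps["V2"]:
        return "V3"
    return candidates[0]
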