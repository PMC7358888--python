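"""Beat detection, signal averaging and wavelet-threshold denoising.

The analysis operates on one signal-averaged beat per subject: QRS
complexes are detected by derivative-energy thresholding, the first ten
sinus beats are aligned by cross-correlation of the QRS and averaged per
lead, and the averaged beat is denoised by soft universal wavelet
thresholding before delineation and source separation.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy.signal import correlate

from .containers import AveragedBeat, EcgRecording
from .synthetic import BEAT_PRE, beat_window_post

__all__ = ["detect_beats", "average_beats", "wavelet_denoise"]


def detect_beats(recording: EcgRecording) -> np.ndarray:
    """Locate R peaks via derivative-energy thresholding.

    Derivative energy summed over all leads (the sharp QRS adds coherently
    on every channel, so it dominates even when a single lead is T-wave
    dominant) is smoothed with an 80 ms moving average; contiguous segments
    above 25% of the 98th-percentile energy are QRS candidates, and the R
    peak is the maximum of the summed squared deflection within each
    segment, refined on a lightly low-passed copy so sensor noise cannot
    shift the sharp peak.

    Returns
    -------
    ndarray of int
        Strictly increasing R-peak sample indices, one per QRS.

    Raises
    ------
    ValueError
        If fewer than two beats are found.
    """
    fs = recording.fs
    # second-derivative energy isolates the sharp QRS from even tall, steep
    # T waves; light pre-smoothing plus subtraction of the flat noise
    # background keeps sensor noise from dominating
    wp = max(int(round(0.0045 * fs)) | 1, 3)
    xs = np.apply_along_axis(
        lambda v: np.convolve(v, np.ones(wp) / wp, mode="same"), 1,
        recording.samples)
    d2 = np.gradient(np.gradient(xs, 1.0 / fs, axis=1), 1.0 / fs, axis=1)
    energy = (d2 ** 2).sum(axis=0)
    w = max(int(round(0.080 * fs)), 1)
    smoothed = np.convolve(energy, np.ones(w) / w, mode="same")
    smoothed = smoothed - np.median(smoothed)

    level = np.percentile(smoothed, 98)
    if level <= 0:
        raise ValueError("fewer than 2 beats detected (flat recording)")
    mask = smoothed > 0.20 * level

    med = np.median(recording.samples, axis=1, keepdims=True)
    deflect = ((recording.samples - med) ** 2).sum(axis=0)
    wr = max(int(round(0.0035 * fs)) | 1, 3)
    deflect = np.convolve(deflect, np.ones(wr) / wr, mode="same")

    # contiguous above-threshold runs, merging gaps below 120 ms (one QRS
    # can straddle a brief energy dip)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError("fewer than 2 beats detected (found 0)")
    gap = int(round(0.120 * fs))
    runs: list[tuple[int, int]] = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev > gap:
            runs.append((start, prev + 1))
            start = i
        prev = i
    runs.append((start, prev + 1))

    cand = [(a + int(np.argmax(deflect[a:b])), float(smoothed[a:b].max()))
            for a, b in runs]

    # periodicity filter: a residual T-wave candidate sits implausibly
    # close after its own QRS — drop the weaker of any close pair, or the
    # later one when their energies are comparable (T follows QRS)
    changed = True
    while changed and len(cand) > 2:
        changed = False
        times = np.array([c[0] for c in cand])
        rr_est = np.percentile(np.diff(times), 75)
        for k in range(len(cand) - 1):
            if cand[k + 1][0] - cand[k][0] < 0.5 * rr_est:
                e1, e2 = cand[k][1], cand[k + 1][1]
                drop = k + 1 if (e2 < 0.6 * e1 or e2 <= e1 * 1.67) else k
                del cand[drop]
                changed = True
                break

    peaks = [c[0] for c in cand]
    if len(peaks) < 2:
        raise ValueError(f"fewer than 2 beats detected (found {len(peaks)})")
    return np.asarray(peaks, dtype=int)


def average_beats(
    recording: EcgRecording,
    r_peaks: np.ndarray,
    n: int = 10,
) -> AveragedBeat:
    """Signal-average the first ``n`` beats.

    Each beat window spans R-300 ms to R+max(700, 780*RR) ms.  Beats are
    aligned to the first by cross-correlating a 120 ms QRS-centred window
    (shift constrained to +/-10 ms) and averaged per lead.

    Raises
    ------
    ValueError
        If fewer than ``n`` complete beats are available (no silent
        fallback to fewer beats).
    """
    r_peaks = np.asarray(r_peaks, dtype=int)
    if len(r_peaks) < n:
        raise ValueError(
            f"need {n} beats for averaging, only {len(r_peaks)} detected"
        )
    if n < 2:
        raise ValueError("averaging requires n >= 2")
    fs = recording.fs
    use = r_peaks[:n]
    mean_rr = float(np.mean(np.diff(use))) / fs

    pre = int(round(BEAT_PRE * fs))
    post = int(round(beat_window_post(mean_rr) * fs))
    max_shift = int(round(0.010 * fs))
    qrs_half = int(round(0.060 * fs))

    # require complete windows (with alignment slack) inside the recording
    for r in use:
        if r - pre - max_shift < 0 or r + post + max_shift > recording.n_samples:
            raise ValueError("incomplete beat window; record too short at the edges")

    ref_lead = int(np.argmax(recording.samples.max(axis=1)
                             - recording.samples.min(axis=1)))
    x = recording.samples[ref_lead]
    ref = x[use[0] - qrs_half: use[0] + qrs_half]

    acc = np.zeros((recording.n_leads, pre + post))
    for r in use:
        seg = x[r - qrs_half - max_shift: r + qrs_half + max_shift]
        cc = correlate(seg, ref, mode="valid")
        shift = int(np.argmax(cc)) - max_shift
        r_al = r + shift
        acc += recording.samples[:, r_al - pre: r_al + post]
    acc /= n

    return AveragedBeat(
        samples=acc,
        fs=fs,
        lead_labels=list(recording.lead_labels),
        mean_rr=mean_rr,
        n_beats_used=n,
        r_offset=pre,
    )


def wavelet_denoise(
    beat: AveragedBeat,
    wavelet: str = "sym8",
    level: int = 5,
) -> AveragedBeat:
    """Per-lead discrete wavelet denoising with the soft universal threshold.

    Each lead is decomposed to ``level`` scales, detail coefficients are
    soft-thresholded at sigma*sqrt(2 log N) with sigma estimated from the
    median absolute deviation of the finest details, and the lead is
    reconstructed.  Channels are never mixed; output length equals input
    length.
    """
    n = beat.n_samples
    if n < 2 ** level:
        raise ValueError(
            f"beat too short for level-{level} decomposition ({n} samples)"
        )
    out = np.empty_like(beat.samples)
    for k in range(beat.n_leads):
        x = beat.samples[k]
        coeffs = pywt.wavedec(x, wavelet, level=level)
        finest = coeffs[-1]
        sigma = np.median(np.abs(finest)) / 0.6745
        thr = sigma * np.sqrt(2.0 * np.log(n))
        if thr == 0.0:
            out[k] = x
            continue
        coeffs = [coeffs[0]] + [pywt.threshold(c, thr, mode="soft")
                                for c in coeffs[1:]]
        out[k] = pywt.waverec(coeffs, wavelet)[:n]
    return AveragedBeat(
        samples=out,
        fs=beat.fs,
        lead_labels=list(beat.lead_labels),
        mean_rr=beat.mean_rr,
        n_beats_used=beat.n_beats_used,
        r_offset=beat.r_offset,
    )
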