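"""Ground-truthed synthetic multi-lead ECG cohorts.

The generator emulates the statistical structure the downstream analysis
assumes: two cohorts (ATS1-like vs control) of multi-lead beat trains in
which the TU complex is a linear mixture of latent source waveforms.

* Controls carry ``n_t_sources`` T-window sources whose late tails also form
  the U deflection — the U wave is composed of the same sources as the
  T wave, so no U-specific component exists to be found.
* ATS1-like subjects carry the same T sources plus 1-2 additional sources
  supported (>=99% of energy) inside the U window [B, U end].

Temporal and amplitude parameters are drawn from truncated normal
distributions around the study's group means/SDs (RR-corrected seconds and
mV).  An iterative calibration of the analysis-lead composite pins the
realized fiducials (peaks, bottom B, tangent wave ends) to the drawn values,
and the stored ground truth is re-measured from the realized clean waveform
so that it is exact by construction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .containers import EcgRecording, FiducialSet, TuParameters

__all__ = [
    "CohortConfig",
    "SubjectTruth",
    "GROUP_TABLES",
    "DEFAULT_LEAD_LABELS",
    "sample_subject_params",
    "synth_beat",
    "generate_cohort",
]

#: Group summary statistics (mean, SD) of the independently drawn subject
#: parameters.  Intervals are RR-corrected seconds, amplitudes mV, HR bpm.
#: The remaining table quantities (QUp, QUc, TeUe, U/T) are derived:
#: qup = qtp + tpup;  quc = qup - bup + bue;  teue = quc - qtc.
GROUP_TABLES: dict[str, dict[str, tuple[float, float]]] = {
    "ATS1": {
        "hr": (62.8, 11.5),
        "qtc": (0.400, 0.031),
        "qtp": (0.289, 0.018),
        "tpup": (0.249, 0.019),
        "bup": (0.101, 0.013),
        "bue": (0.232, 0.018),
        "tp_amp": (0.456, 0.261),
        "up_amp": (0.166, 0.063),
    },
    "control": {
        "hr": (63.8, 7.5),
        "qtc": (0.388, 0.017),
        "qtp": (0.301, 0.020),
        "tpup": (0.196, 0.021),
        "bup": (0.063, 0.013),
        "bue": (0.165, 0.017),
        "tp_amp": (0.767, 0.326),
        "up_amp": (0.062, 0.033),
    },
}

#: 10-channel montage: precordial V1-V6 plus four auxiliary high-frequency
#: channels named by position-code convention.
DEFAULT_LEAD_LABELS = ["V1", "V2", "V3", "V4", "V5", "V6",
                       "4C6", "4C7", "4C8", "4C9"]

# Beat window geometry (seconds): window spans [R - PRE, R + post] where
# post adapts to the heart rate so the full TU complex (raw QU interval is
# the corrected QUc times sqrt(RR)) fits at bradycardic rates too.
BEAT_PRE = 0.300
BEAT_POST = 0.700


def beat_window_post(rr: float) -> float:
    """Post-R extent (s) of the beat window at mean RR interval ``rr``."""
    return max(BEAT_POST, 0.78 * rr)
# QRS support: Q onset and J point as fixed offsets from the R peak; the
# QRS bumps decay to <0.1% of R amplitude outside [q_onset, j_point].
Q_ONSET_FROM_R = -0.040
J_POINT_FROM_R = 0.045

# Amplitude floors (mV): a non-positive wave amplitude has no waveform
# interpretation, so sampling truncates at these in addition to +/-3 SD.
TP_AMP_FLOOR = 0.10
UP_AMP_FLOOR = 0.015
HR_FLOOR = 35.0


@dataclass
class CohortConfig:
    """Study-condition parameters for cohort synthesis."""

    n_per_group: int = 13
    n_leads: int = 10
    fs: float = 2000.0
    heart_rate_mean: Optional[float] = None  # None -> group-specific means
    n_t_sources: int = 4
    n_u_sources_ats: int = 2
    noise_sd: float = 0.010  # mV, white sensor noise on the raw recording
    seed: int = 0
    n_beats: int = 12
    rr_jitter: float = 0.02  # fractional SD of per-beat RR
    sd_scale: float = 1.0    # scales all group SDs (0 -> degenerate draws)
    include_qrs: bool = True
    lead_labels: Optional[list[str]] = None

    def validate(self) -> None:
        n_sources = self.n_t_sources + self.n_u_sources_ats + int(self.include_qrs)
        if self.n_leads < n_sources:
            raise ValueError(
                f"n_leads={self.n_leads} must be >= total source count {n_sources}"
            )
        if self.n_t_sources < 1:
            raise ValueError("need at least one T source")
        if self.n_u_sources_ats not in (0, 1, 2):
            raise ValueError("n_u_sources_ats must be 0, 1 or 2")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be positive")
        if self.n_beats < 2:
            raise ValueError("need at least two beats per record")

    def labels(self) -> list[str]:
        if self.lead_labels is not None:
            if len(self.lead_labels) != self.n_leads:
                raise ValueError("lead_labels length must equal n_leads")
            return list(self.lead_labels)
        return DEFAULT_LEAD_LABELS[: self.n_leads]


@dataclass
class SubjectTruth:
    """Ground truth for one simulated subject."""

    group: str
    rr: float
    analysis_lead: str
    true_fiducials: FiducialSet
    true_parameters: TuParameters
    sampled_parameters: TuParameters
    source_waveforms: np.ndarray      # (n_sources, beat_samples)
    source_names: list[str]
    mixing: np.ndarray                # (n_leads, n_sources)
    u_source_indices: list[int]
    fs: float
    r_indices: Optional[np.ndarray] = None   # R-peak samples in the recording
    noise: Optional[np.ndarray] = None       # injected sensor noise

    @property
    def beat_template(self) -> np.ndarray:
        """Clean multi-lead beat, ``mixing @ source_waveforms``."""
        return self.mixing @ self.source_waveforms


# ---------------------------------------------------------------------------
# parameter sampling


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float = -np.inf, hi: float = np.inf) -> float:
    """Rejection-sample N(mean, sd) truncated to [max(lo, mean-3sd), min(hi, mean+3sd)]."""
    if sd == 0:
        return mean
    a = max(lo, mean - 3 * sd)
    b = min(hi, mean + 3 * sd)
    for _ in range(10_000):
        x = rng.normal(mean, sd)
        if a <= x <= b:
            return x
    raise RuntimeError("truncated-normal sampling failed (bounds too tight)")


def sample_subject_params(
    group: str,
    rng: np.random.Generator,
    config: Optional[CohortConfig] = None,
    table: Optional[dict[str, tuple[float, float]]] = None,
) -> TuParameters:
    """Draw one subject's TU parameter vector for ``group``.

    Independent truncated-normal draws for HR, QTc, QTp, TpUp, BUp, BUe and
    the two amplitudes; QUp, QUc, TeUe and U/T are derived so the vector is
    internally consistent.  The physiological ordering
    Q onset < T peak < B < U peak < U end is enforced by resampling.
    """
    if group not in GROUP_TABLES:
        raise ValueError(f"unknown group {group!r}; expected one of {list(GROUP_TABLES)}")
    tab = dict(table if table is not None else GROUP_TABLES[group])
    cfg = config or CohortConfig()
    if cfg.heart_rate_mean is not None:
        tab["hr"] = (cfg.heart_rate_mean, tab["hr"][1])
    ss = cfg.sd_scale

    for _ in range(1000):
        hr = _trunc_normal(rng, tab["hr"][0], ss * tab["hr"][1], lo=HR_FLOOR)
        qtc = _trunc_normal(rng, tab["qtc"][0], ss * tab["qtc"][1])
        qtp = _trunc_normal(rng, tab["qtp"][0], ss * tab["qtp"][1])
        tpup = _trunc_normal(rng, tab["tpup"][0], ss * tab["tpup"][1])
        bup = _trunc_normal(rng, tab["bup"][0], ss * tab["bup"][1])
        bue = _trunc_normal(rng, tab["bue"][0], ss * tab["bue"][1])
        tp_amp = _trunc_normal(rng, tab["tp_amp"][0], ss * tab["tp_amp"][1],
                               lo=TP_AMP_FLOOR)
        up_amp = _trunc_normal(rng, tab["up_amp"][0], ss * tab["up_amp"][1],
                               lo=UP_AMP_FLOOR)
        # Ordering/geometry constraints: T end after T peak (finite tangent
        # slope), bottom B strictly between the peaks, U end after U peak.
        if not (qtc > qtp + 0.020):
            continue
        if not (tpup > bup + 0.010):
            continue
        if not (bue > bup + 0.020):
            continue
        qup = qtp + tpup
        quc = qup - bup + bue
        teue = quc - qtc
        if teue <= 0:
            continue
        return TuParameters(
            hr=hr, qtc=qtc, quc=quc, qtp=qtp, qup=qup, teue=teue,
            tpup=tpup, bup=bup, bue=bue, tp_amp=tp_amp, up_amp=up_amp,
            ut_ratio=up_amp / tp_amp,
        )
    raise RuntimeError(
        "could not draw an ordered parameter vector in 1000 attempts; "
        "group SDs are misconfigured"
    )


# ---------------------------------------------------------------------------
# waveform primitives


@dataclass
class _Bump:
    """Asymmetric smooth bump.

    The rising limb is Gaussian with width ``s_rise``.  The falling limb is
    either Gaussian (``fall='gauss'``) or a compactly supported cos^4 arch
    (``fall='cos4'``) that reaches exactly zero ``s_fall`` after the center.
    The compact family models the fast terminal decay of the T downslope: a
    Gaussian keeps ~13% of the peak at its tangent crossing, which would
    bury a small U wave under the T tail and destroy the bifid geometry.
    """

    mu: float
    s_rise: float
    s_fall: float
    amp: float
    fall: str = "gauss"

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.empty_like(t)
        rise = t < self.mu
        out[rise] = np.exp(-0.5 * ((t[rise] - self.mu) / self.s_rise) ** 2)
        x = (t[~rise] - self.mu) / self.s_fall
        if self.fall == "gauss":
            out[~rise] = np.exp(-0.5 * x ** 2)
        else:  # tapered gaussian: near-Gaussian through the steepest-slope
            # region, then decays faster -- real T downslopes hug the
            # baseline soon after the tangent point
            extra = np.maximum(x - 1.3, 0.0)
            out[~rise] = np.exp(-0.5 * x ** 2 * (1.0 + 0.6 * extra ** 2))
        return self.amp * out


def _eval(t: np.ndarray, bumps: list[_Bump]) -> np.ndarray:
    out = np.zeros_like(t)
    for b in bumps:
        out += b(t)
    return out


def _parabolic(y: np.ndarray, i: int) -> float:
    """Sub-sample refinement of a discrete extremum at index i."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    denom = y[i - 1] - 2 * y[i] + y[i + 1]
    if denom == 0:
        return float(i)
    # offset beyond one sample means the local quadratic model is invalid
    return i + float(np.clip(0.5 * (y[i - 1] - y[i + 1]) / denom, -1.0, 1.0))


def _argmax_time(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> tuple[float, float]:
    """(time, value) of the refined maximum of y on [lo, hi]."""
    m = (t >= lo) & (t <= hi)
    idx = np.flatnonzero(m)
    i = idx[np.argmax(y[idx])]
    fi = _parabolic(y, i)
    dt = t[1] - t[0]
    return t[0] + fi * dt, float(np.max(y[idx]))


def _argmin_time(t: np.ndarray, y: np.ndarray, lo: float, hi: float) -> float:
    m = (t >= lo) & (t <= hi)
    idx = np.flatnonzero(m)
    i = idx[np.argmin(y[idx])]
    fi = _parabolic(y, i)
    dt = t[1] - t[0]
    return t[0] + fi * dt


def _tangent_cross(t: np.ndarray, y: np.ndarray, d1: np.ndarray,
                   peak_t: float, hi: float, baseline: float = 0.0) -> float:
    """Tangent-method wave end on a composite.

    Delegates to the delineator's :func:`~tuwave.delineate.tangent_end`
    so that generator ground truth and pipeline measurement share one
    definition of the tangent (``d1`` is accepted for call-site symmetry
    but recomputed inside).
    """
    from .delineate import tangent_end
    fs = 1.0 / (t[1] - t[0])
    peak = int(round((peak_t - t[0]) * fs))
    win = int(round((hi - peak_t) * fs))
    if win <= 3:
        raise ValueError("empty tangent search window")
    return t[0] + tangent_end(y, peak, win, fs, baseline)


# ---------------------------------------------------------------------------
# beat synthesis


def _qrs_bumps(r_time: float, amp: float) -> list[_Bump]:
    return [
        _Bump(r_time - 0.018, 0.006, 0.006, -0.10 * amp),
        _Bump(r_time, 0.010, 0.009, amp),
        _Bump(r_time + 0.022, 0.006, 0.007, -0.18 * amp),
    ]


def _draw_mixing(rng: np.random.Generator, n_leads: int, n_sources: int) -> np.ndarray:
    """Generic full-column-rank mixing: seeded uniform entries, unit-norm columns."""
    a = rng.uniform(0.45, 1.0, size=(n_leads, n_sources))
    return a / np.linalg.norm(a, axis=0, keepdims=True)


def synth_beat(
    params: TuParameters,
    config: CohortConfig,
    rng: np.random.Generator,
    group: str = "ATS1",
    mixing: Optional[np.ndarray] = None,
) -> SubjectTruth:
    """Build one subject's source waveforms, mixing and ground truth.

    The analysis-lead composite is calibrated by a damped fixed-point
    iteration so that its measured fiducials (T/U peaks and amplitudes,
    bottom B, tangent T/U ends) match ``params``; ground truth is then
    re-measured from the realized clean waveform.
    """
    return _synth_subject(params, group, config, rng, mixing)


def _synth_subject(
    params: TuParameters,
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    mixing: Optional[np.ndarray] = None,
) -> SubjectTruth:
    config.validate()
    fs = config.fs
    labels = config.labels()
    rr = 60.0 / params.hr
    s = np.sqrt(rr)

    n_u = config.n_u_sources_ats if group == "ATS1" else 0
    n_t = config.n_t_sources
    n_sources = n_t + n_u + int(config.include_qrs)
    if n_sources > config.n_leads:
        raise ValueError("requested source count exceeds n_leads")

    # window clock: 0 at window start, R at BEAT_PRE
    r_time = BEAT_PRE
    # Q onset on the criterion the delineator uses (return-to-baseline
    # around the QRS); scale-invariant, so computed on the unit QRS shape
    if config.include_qrs:
        from .delineate import _qrs_bounds
        _tq = np.arange(int(round((r_time + 0.2) * fs))) / fs
        _xq = _eval(_tq, _qrs_bumps(r_time, 1.0))
        _qi, _ji = _qrs_bounds(_xq, int(round(r_time * fs)), fs, 0.0)
        q0 = _qi / fs
    else:
        q0 = r_time + Q_ONSET_FROM_R
        _qi = int(round(q0 * fs))
        _ji = int(round((r_time + J_POINT_FROM_R) * fs))
    n_win = int(round((BEAT_PRE + beat_window_post(rr)) * fs))
    t = np.arange(n_win) / fs

    # raw (uncorrected) fiducial targets on the window clock
    tp = q0 + params.qtp * s
    te = q0 + params.qtc * s
    up = q0 + params.qup * s
    b = up - params.bup * s
    ue = q0 + params.quc * s

    if mixing is None:
        A = _draw_mixing(rng, config.n_leads, n_sources)
    else:
        A = np.asarray(mixing, dtype=float)
        if A.shape != (config.n_leads, n_sources):
            raise ValueError(f"mixing must have shape {(config.n_leads, n_sources)}")
    if np.linalg.matrix_rank(A) < n_sources:
        raise ValueError("mixing matrix must have full column rank")
    custom_mix = mixing is not None

    # source layout: [qrs?] + t sources (main last) + u sources
    i_qrs = 0 if config.include_qrs else None
    t_idx = list(range(int(config.include_qrs), int(config.include_qrs) + n_t))
    i_main = t_idx[-1]
    u_idx = list(range(t_idx[-1] + 1, t_idx[-1] + 1 + n_u))

    # without planted U sources, the U deflection is embedded as a late
    # tail shared between the last two T sources
    if n_u > 0 or n_t == 1:
        tail_shares = {i_main: 1.0}
    else:
        tail_shares = {t_idx[-2]: 0.45, i_main: 0.55}

    # choose which of V2/V3 the calibration (and thus the analysis) targets
    v2_i = labels.index("V2") if "V2" in labels else None
    v3_i = labels.index("V3") if "V3" in labels else None
    if v2_i is None and v3_i is None:
        raise ValueError("lead labels must include V2 or V3")

    def _u_coeff(row: int) -> float:
        if group == "ATS1" and n_u > 0:
            return float(np.sum(A[row, u_idx]))
        return float(sum(share * A[row, j] for j, share in tail_shares.items()))

    if v2_i is not None and v3_i is not None and mixing is None:
        # make the randomly chosen analysis lead the one that carries the
        # larger U projection by swapping the two precordial rows if needed
        lead_i = int(rng.choice([v2_i, v3_i]))
        other = v3_i if lead_i == v2_i else v2_i
        if _u_coeff(other) > _u_coeff(lead_i):
            A[[lead_i, other], :] = A[[other, lead_i], :]
    else:
        lead_i = v2_i if v2_i is not None else v3_i
    analysis_lead = labels[lead_i]

    if mixing is None:
        # route the component *structure* away from the analysis lead: the
        # secondary T sources (and the second U source) take their smallest
        # column entry on V2/V3, so the analysis lead shows a smooth
        # single-peaked T wave while the other leads carry the substructure.
        # Amplitudes below are in analysis-lead units, so a small entry
        # means a large source waveform, keeping every component salient.
        # the analysis lead must carry the dominant U projection so lead
        # selection is unambiguous: give it the largest entry of the main
        # U channel (U1 for ATS1-like subjects, the main T source -- which
        # carries most of the embedded U tail -- for controls)
        # ... and the main T deflection is likewise prominent there (the
        # analysis lead is chosen for its large waves)
        dom_cols = [i_main] + ([u_idx[0]] if n_u > 0 else [])
        for dom_col in dom_cols:
            k_max = int(np.argmax(A[:, dom_col]))
            if k_max != lead_i:
                A[[lead_i, k_max], dom_col] = A[[k_max, lead_i], dom_col]

        prec = [lead_i] + ([other] if (v2_i is not None and v3_i is not None)
                           else [])
        if n_u == 2:
            # the second U component projects mainly onto the auxiliary
            # channels: damp its precordial entries so its source waveform
            # can carry substantial energy without distorting the analysis
            # lead's U morphology
            A[prec, u_idx[1]] *= 0.12
            A[:, u_idx[1]] /= np.linalg.norm(A[:, u_idx[1]])

        restructure = list(t_idx[:-1])
        for col in restructure:
            vals = np.sort(A[:, col])
            rest = iter(np.delete(np.sort(A[:, col]), range(len(prec))))
            new_col = np.empty_like(A[:, col])
            taken = set(prec)
            for rank, row in enumerate(prec):
                new_col[row] = vals[rank]
            for row in range(A.shape[0]):
                if row not in taken:
                    new_col[row] = next(rest)
            A[:, col] = new_col


    # ---- bump construction (source-space amplitudes) ----
    def _coeff(value: float) -> float:
        # a user-supplied mixing may zero the analysis-lead entry; fall back
        # to source units in that case
        return value if abs(value) > 1e-9 else 1.0

    if config.include_qrs:
        qrs_amp = 1.1 if custom_mix else 1.1 / _coeff(A[lead_i, i_qrs])
        qrs = _qrs_bumps(r_time, qrs_amp)
    else:
        qrs = []

    # Gaussian falling limb: tangent crossing sits 2*s_fall past the center.
    # The T cluster is self-similar in the T half-width (te - tp).  The
    # secondary sources are deliberately diverse (staggered monophasic and
    # biphasic lobed shapes, all sums of asymmetric Gaussian bumps): four
    # near-identical bumps would be statistically inseparable, whereas the
    # study's premise is a T wave composed of four identifiable components.
    half = te - tp
    main = _Bump(tp, max(0.036 * s, 0.32 * half), max(half / 2, 0.012),
                 0.62 * params.tp_amp, fall="taper")
    n_sec = n_t - 1
    # per-source lobe templates: (offset/half, s_rise/half, s_fall/half or
    # None meaning 'tied to the main falling width', amp/tp_amp)
    # all secondary structure sits well before the T peak so the post-peak
    # downslope (hence the tangent T end) belongs to the main source alone
    _sec_templates = [
        [(-1.05, 0.14, 0.14, +0.26)],
        [(-0.70, 0.14, 0.14, +0.22)],
        [(-0.38, 0.14, 0.14, +0.20)],
        [(-0.85, 0.11, 0.11, +0.17)],
        [(-0.52, 0.11, 0.11, +0.16)],
    ]
    # amplitudes are fixed in *analysis-lead* units (divided by the source's
    # own mixing coefficient), so the composite's geometry on the analysis
    # lead does not depend on the mixing draw
    t_bumps: list[_Bump] = []
    t_bump_src: list[int] = []   # which T source (0..n_t-1) each bump belongs to
    tied: list[int] = []         # bump indices whose fall width tracks the main
    # the tiles live on the T upstroke, so their span is limited by the
    # distance to Q onset (an extreme wide-T draw must not put T-source
    # material before the QRS)
    span = min(half, 0.5 * max(tp - q0 - 0.02, 0.04))
    for s_i in range(n_sec):
        a_v = 1.0 if custom_mix else _coeff(A[lead_i, t_idx[s_i]])
        for off, s_r_f, s_f_f, amp_f in _sec_templates[s_i % len(_sec_templates)]:
            sf = 0.60 * main.s_fall if s_f_f is None else max(s_f_f * span, 0.010)
            t_bumps.append(_Bump(tp + off * span, max(s_r_f * span, 0.010),
                                 sf, amp_f * params.tp_amp / a_v))
            t_bump_src.append(s_i)
            if s_f_f is None:
                tied.append(len(t_bumps) - 1)
    if not custom_mix:
        main.amp = main.amp / _coeff(A[lead_i, i_main])
    t_bumps.append(main)
    t_bump_src.append(n_sec)
    # terminal-repolarization notch at B: carves the bifid minimum when the
    # T downslope and U upslope alone cannot place it (depth calibrated,
    # zero unless needed)
    dip = _Bump(b, 0.012, 0.012, 0.0)

    # U1: the main U deflection (planted source for ATS1, or the shared
    # late-tail shape embedded in the T sources for controls)
    sig_r0 = max((up - b) / 2.1, 0.008)
    sig_f0 = max((ue - up) / 2, 0.010)
    u1_coeff = (1.0 if custom_mix else
                _coeff(A[lead_i, u_idx[0]] if n_u > 0 else _u_coeff(lead_i)))
    u_bumps = [_Bump(up, sig_r0, sig_f0, params.up_amp / u1_coeff)]

    # U2 (second planted U source): a biphasic lobed waveform confined to
    # [B, U end] — temporally near-orthogonal to U1 so the pair spans two
    # identifiable dimensions; its amplitude is set after U1 calibration
    w_u = ue - b
    if n_u == 2:
        # a smooth early-U hump confined to the rising half of the U wave,
        # so the falling limb (which defines the tangent U end) stays U1's
        u2_bumps = [
            _Bump(b + 0.35 * (up - b), 0.10 * (up - b), 0.16 * (up - b), 1.0),
        ]
    else:
        u2_bumps = []
    u2_scale = 0.0

    if custom_mix:
        # a caller-provided mixing may leave the analysis lead without some
        # sources; calibrate an equal-weight virtual composite instead (the
        # analysis-lead morphology guarantee only holds for drawn mixings)
        t_coeffs = [1.0 for _ in t_bump_src]
        u_coeffs = [1.0]
        u2_coeff = 1.0 if n_u == 2 else 0.0
    else:
        t_coeffs = [A[lead_i, t_idx[si]] for si in t_bump_src]
        if n_u > 0:
            u_coeffs = [A[lead_i, u_idx[0]]]
            u2_coeff = A[lead_i, u_idx[1]] if n_u == 2 else 0.0
        else:
            u_coeffs = [_u_coeff(lead_i)]
            u2_coeff = 0.0

    # ---- fixed-point calibration on the analysis-lead composite ----
    # Knobs: joint T shift/scale + main falling width (targets: T peak
    # position/amplitude, tangent T end) and joint U shift/scale plus the
    # U rising/falling widths (targets: bottom B, U peak position/amplitude,
    # tangent U end).  Measurement windows are centred on the *target*
    # locations so a bad intermediate state cannot collapse the search.
    lam_t, lam_u, d_t, d_u = 1.0, 1.0, 0.0, 0.0
    # planted U sources must keep >=99% of their energy inside [B, U end];
    # a rise width of (Up-B)/1.75 leaves <1% outside. Embedded control
    # tails carry no such constraint.
    rise_div = 1.75 if n_u > 0 else 1.2
    sig_r_bounds = (0.008, max((up - b) / rise_div, 0.009))

    def t_wave(tt: np.ndarray) -> np.ndarray:
        c = np.zeros_like(tt)
        for coef, bump in zip(t_coeffs, t_bumps):
            bb = _Bump(bump.mu + d_t, bump.s_rise, bump.s_fall,
                       lam_t * bump.amp, fall=bump.fall)
            c += coef * bb(tt)
        return c

    def u_wave_eval(tt: np.ndarray) -> np.ndarray:
        c = np.zeros_like(tt)
        for coef, bump in zip(u_coeffs, u_bumps):
            bb = _Bump(bump.mu + d_u, bump.s_rise, bump.s_fall, lam_u * bump.amp)
            c += coef * bb(tt)
        if u2_scale != 0.0:
            c = c + u2_coeff * u2_scale * _eval(tt, u2_bumps)
        return c

    damp = 0.7
    dt_grid = 1.0 / fs

    def _measure_t(c, d1):
        tp_hat, tp_amp_hat = _argmax_time(t, c, tp - 0.06, tp + 0.06)
        te_hat = _tangent_cross(t, c, d1, tp_hat, max(b - 0.045, tp_hat + 0.03))
        return tp_hat, tp_amp_hat, te_hat

    def _update_t(tp_hat, tp_amp_hat, te_hat):
        nonlocal d_t, lam_t
        d_t = float(np.clip(d_t + damp * (tp - tp_hat),
                            d_t0 - 0.012, d_t0 + 0.012))
        lam_t *= float(np.clip(params.tp_amp / max(tp_amp_hat, 1e-9), 0.5, 2.0))
        # the tangent crossing moves ~2x per unit falling-width change
        main.s_fall = float(np.clip(main.s_fall + damp * 0.45 * (te - te_hat),
                                    max(0.008, 0.25 * half), 0.15))
        for i in tied:
            t_bumps[i].s_fall = 0.60 * main.s_fall

    def _measure_u(c, d1):
        # U-peak and bottom locations are defined on the 20 ms-smoothed
        # trace (matching the delineator); amplitude reads the raw trace
        from .delineate import _smooth
        cs = _smooth(c, 0.020, fs)
        up_hat, _ = _argmax_time(t, cs, up - 0.035, up + 0.06)
        up_amp_hat = float(np.interp(up_hat, t, c))
        b_hat = _argmin_time(t, cs, tp + 0.015, up - 0.008)
        ue_hat = _tangent_cross(t, c, d1, up_hat, min(ue + 0.10, t[-1]))
        return up_hat, up_amp_hat, b_hat, ue_hat

    def _update_u(up_hat, up_amp_hat, b_hat, ue_hat):
        nonlocal d_u, lam_u
        d_u = float(np.clip(d_u + damp * (up - up_hat), -0.06, 0.06))
        t_at_up = float(t_wave(np.array([up_hat]))[0])
        u_part = up_amp_hat - t_at_up
        if u_part > 1e-6 and params.up_amp - t_at_up > 1e-6:
            lam_u *= float(np.clip((params.up_amp - t_at_up) / u_part, 0.5, 2.0))
        f_step = damp * 0.45 * (ue - ue_hat)
        # the composite minimum moves ~2x (opposite sign) per unit
        # rising-width change, hence the small gain
        r_step = damp * 0.35 * (b_hat - b)
        pinned = True
        for ub in u_bumps:
            ub.s_fall = float(np.clip(ub.s_fall + f_step, 0.010, 0.12))
            new_r = float(np.clip(ub.s_rise + r_step, *sig_r_bounds))
            if abs(new_r - ub.s_rise) > 1e-6:
                pinned = False
            ub.s_rise = new_r
        if pinned and abs(b_hat - b) > 0.3e-3:
            # rising width exhausted: deepen the notch at B; it pins the
            # minimum there whether the free minimum sits late (steep T
            # tail) or wanders early (flat T-U gap). Once active, its
            # center tracks out any residual offset of the minimum.
            dip.amp = float(np.clip(dip.amp - damp * 8.0 * abs(b_hat - b),
                                    -1.5 * params.up_amp, 0.0))
        if dip.amp < 0.0:
            dip.mu = float(np.clip(dip.mu - damp * (b_hat - b),
                                   b - 0.02, b + 0.02))

    # initialize the T shift so the cluster's free peak starts on target
    c0 = _eval(t, qrs) + t_wave(t)
    tp0, _ = _argmax_time(t, c0, tp - 0.10, tp + 0.06)
    d_t = d_t0 = float(np.clip(tp - tp0, -0.08, 0.08))

    # Stage A: T wave alone (the U contribution under the T peak is
    # negligible by construction, but its rising limb does perturb the
    # T tangent, so stage C below refines on the full composite).
    for _ in range(25):
        c = _eval(t, qrs) + t_wave(t)
        d1 = np.gradient(c, dt_grid)
        tp_hat, tp_amp_hat, te_hat = _measure_t(c, d1)
        if (abs(tp - tp_hat) < 0.2e-3 and abs(te - te_hat) < 0.2e-3
                and abs(params.tp_amp - tp_amp_hat) < 2e-3 * params.tp_amp):
            break
        _update_t(tp_hat, tp_amp_hat, te_hat)

    # Stage B: add the U wave, T frozen.
    for _ in range(30):
        c = _eval(t, qrs) + t_wave(t) + u_wave_eval(t) + dip(t)
        d1 = np.gradient(c, dt_grid)
        up_hat, up_amp_hat, b_hat, ue_hat = _measure_u(c, d1)
        if (abs(up - up_hat) < 0.2e-3 and abs(b - b_hat) < 0.3e-3
                and abs(ue - ue_hat) < 0.2e-3
                and abs(params.up_amp - up_amp_hat) < 2e-3 * params.up_amp):
            break
        _update_u(up_hat, up_amp_hat, b_hat, ue_hat)

    # size the second U source for energy parity with U1 (capped so its
    # wiggle on the analysis lead stays well below the U peak)
    if u2_bumps:
        u1_src = lam_u * _eval(t, u_bumps)
        u2_shape = _eval(t, u2_bumps)
        e1 = float(np.sum(u1_src ** 2))
        e2 = float(np.sum(u2_shape ** 2))
        if e2 > 0:
            u2_scale = np.sqrt(0.5 * e1 / e2)
            peak2 = float(np.abs(u2_shape).max())
            if u2_coeff > 0 and peak2 > 0:
                # keep the analysis-lead composite unimodal in the U window:
                # the hump may only fill the headroom under the U peak at
                # its own center
                mu2 = u2_bumps[0].mu
                v1 = float(np.interp(mu2, t, _eval(t, qrs) + t_wave(t)
                                     + u_wave_eval(t) + dip(t)))
                headroom = max(0.75 * params.up_amp - v1, 0.08 * params.up_amp)
                u2_scale = min(u2_scale, headroom / (u2_coeff * peak2))

    # Stage C: joint refinement on the full composite.
    converged = False
    for _ in range(40):
        c = _eval(t, qrs) + t_wave(t) + u_wave_eval(t) + dip(t)
        d1 = np.gradient(c, dt_grid)
        tp_hat, tp_amp_hat, te_hat = _measure_t(c, d1)
        up_hat, up_amp_hat, b_hat, ue_hat = _measure_u(c, d1)
        if (max(abs(tp - tp_hat), abs(up - up_hat)) < 0.5e-3
                and abs(b - b_hat) < 1.0e-3
                and max(abs(te - te_hat), abs(ue - ue_hat)) < 1.0e-3
                and abs(params.tp_amp - tp_amp_hat) < 1e-2 * params.tp_amp
                and abs(params.up_amp - up_amp_hat) < 1e-2 * params.up_amp):
            converged = True
            break
        _update_t(tp_hat, tp_amp_hat, te_hat)
        _update_u(up_hat, up_amp_hat, b_hat, ue_hat)

    if not converged:
        # the drawn vector is geometrically infeasible for a bifid TU
        # complex (e.g. tall T with a tiny, early U); caller redraws
        raise ValueError("infeasible TU geometry: calibration did not converge")
    # the bottom must not undershoot the baseline by more than a fraction
    # of the U amplitude: a notch deeper than the U wave itself would be
    # the dominant "U" deflection under the biphasic-U reading
    if float(np.interp(b, t, c)) < -0.30 * params.up_amp:
        raise ValueError("infeasible TU geometry: notch deeper than the U wave")

    # ---- assemble final source waveforms ----
    u_wave = np.zeros(n_win)
    for bump in u_bumps:
        bb = _Bump(bump.mu + d_u, bump.s_rise, bump.s_fall, lam_u * bump.amp)
        u_wave_i = bb(t)
        u_wave += u_wave_i

    sources = np.zeros((n_sources, n_win))
    names: list[str] = []
    if config.include_qrs:
        sources[i_qrs] = _eval(t, qrs)
        names.append("qrs")
    for k in range(n_t):
        names.append(f"t{k + 1}")
    for bump, s_i in zip(t_bumps, t_bump_src):
        bb = _Bump(bump.mu + d_t, bump.s_rise, bump.s_fall, lam_t * bump.amp,
                   fall=bump.fall)
        sources[t_idx[s_i]] += bb(t)
    if dip.amp != 0.0:
        # notch amplitude was calibrated in analysis-lead units
        sources[i_main] = sources[i_main] + dip(t) / (
            1.0 if custom_mix else _coeff(A[lead_i, i_main]))
    if n_u > 0:
        sources[u_idx[0]] = u_wave
        names.append("u1")
        if n_u == 2:
            sources[u_idx[1]] = u2_scale * _eval(t, u2_bumps)
            names.append("u2")
    else:
        for j, share in tail_shares.items():
            sources[j] = sources[j] + share * u_wave

    template = A @ sources
    lead = sources.sum(axis=0) if custom_mix else template[lead_i]
    d1 = np.gradient(lead, 1.0 / fs)

    # ---- measure realized ground truth from the clean composite ----
    q_idx, j_idx = int(_qi), int(_ji)
    from .delineate import _smooth as _dsmooth
    lead_s = _dsmooth(lead, 0.020, fs)
    tp_t, tp_amp_true = _argmax_time(t, lead, tp - 0.06, tp + 0.06)
    up_t, _ = _argmax_time(t, lead_s, up - 0.035, up + 0.06)
    up_amp_true = float(np.interp(up_t, t, lead))
    b_t = _argmin_time(t, lead_s, tp + 0.015, up - 0.008)
    te_true = _tangent_cross(t, lead, d1, tp_t, max(b_t - 0.045, tp_t + 0.03))
    ue_true = _tangent_cross(t, lead, d1, up_t, min(ue + 0.10, t[-1]))

    fid = FiducialSet(
        q_onset=q_idx,
        j_point=j_idx,
        t_peak=int(round(tp_t * fs)),
        bottom_b=int(round(b_t * fs)),
        u_peak=int(round(up_t * fs)),
        t_end=te_true,
        u_end=ue_true,
        analysis_lead=analysis_lead,
        fs=fs,
        baseline=0.0,
    )
    fid.validate()

    q_t = q_idx / fs
    true_params = TuParameters(
        hr=params.hr,
        qtc=(te_true - q_t) / s,
        quc=(ue_true - q_t) / s,
        qtp=(tp_t - q_t) / s,
        qup=(up_t - q_t) / s,
        teue=(ue_true - te_true) / s,
        tpup=(up_t - tp_t) / s,
        bup=(up_t - b_t) / s,
        bue=(ue_true - b_t) / s,
        tp_amp=tp_amp_true,
        up_amp=up_amp_true,
        ut_ratio=up_amp_true / tp_amp_true,
    )
    true_params.validate()

    return SubjectTruth(
        group=group,
        rr=rr,
        analysis_lead=analysis_lead,
        true_fiducials=fid,
        true_parameters=true_params,
        sampled_parameters=params,
        source_waveforms=sources,
        source_names=names,
        mixing=A,
        u_source_indices=u_idx if n_u > 0 else [],
        fs=fs,
    )


def simulate_subject(
    group: str,
    config: CohortConfig,
    rng: np.random.Generator,
    params: Optional[TuParameters] = None,
) -> SubjectTruth:
    """Draw parameters (unless given) and synthesize one subject's beat.

    Retries the whole draw a few times in the rare case a drawn vector does
    not yield a valid bifid TU geometry after calibration.
    """
    last_err: Exception | None = None
    for _ in range(25):
        p = params if params is not None else sample_subject_params(group, rng, config)
        try:
            return _synth_subject(p, group, config, rng)
        except (ValueError, RuntimeError) as err:
            last_err = err
            if params is not None:
                raise
    raise RuntimeError(f"subject synthesis failed repeatedly: {last_err}")


def _beat_train(
    truth: SubjectTruth,
    config: CohortConfig,
    rng: np.random.Generator,
) -> EcgRecording:
    """Place the subject's beat template on a jittered RR grid plus noise."""
    fs = config.fs
    template = truth.beat_template
    n_win = template.shape[1]
    jit = np.array([
        _trunc_normal(rng, 1.0, config.rr_jitter) for _ in range(config.n_beats - 1)
    ])
    rr_series = truth.rr * jit
    r_times = np.concatenate([[0.35 + BEAT_PRE], 0.35 + BEAT_PRE + np.cumsum(rr_series)])
    n_samples = int(np.ceil((r_times[-1] + beat_window_post(truth.rr) + 0.05) * fs))
    clean = np.zeros((config.n_leads, n_samples))
    r_indices = np.round(r_times * fs).astype(int)
    for r in r_indices:
        start = r - int(round(BEAT_PRE * fs))
        stop = start + n_win
        lo, hi = max(start, 0), min(stop, n_samples)
        clean[:, lo:hi] += template[:, lo - start: n_win - (stop - hi)]
    noise = rng.normal(0.0, config.noise_sd, size=clean.shape) if config.noise_sd > 0 \
        else np.zeros_like(clean)
    truth.r_indices = r_indices
    truth.noise = noise
    return EcgRecording(samples=clean + noise, fs=fs, lead_labels=config.labels())


def generate_cohort(config: CohortConfig) -> list[tuple[EcgRecording, SubjectTruth]]:
    """Generate the two seeded cohorts: ``n_per_group`` recordings per group.

    Deterministic given ``config.seed``: running twice yields byte-identical
    output.  Controls come first, then ATS1-like subjects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    out: list[tuple[EcgRecording, SubjectTruth]] = []
    for group in ("control", "ATS1"):
        for _ in range(config.n_per_group):
            truth = simulate_subject(group, config, rng)
            rec = _beat_train(truth, config, rng)
            out.append((rec, truth))
    return out
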