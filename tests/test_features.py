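"""Parameter vector, predictor set and the PCA dyssynchrony ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tuwave.containers import AveragedBeat, FiducialSet, PREDICTOR_NAMES
from tuwave.features import compute_parameters, pca_ratio, predictor_vector
from tuwave.synthetic import CohortConfig, simulate_subject

FS = 2000.0


def _fid(**kw):
    base = dict(q_onset=520, j_point=690, t_peak=1100, bottom_b=1320,
                u_peak=1500, t_end=0.73, u_end=0.84, analysis_lead="V2",
                fs=FS, baseline=0.0)
    base.update(kw)
    return FiducialSet(**base)


def _beat_for(fid, rr=1.0, n_leads=1):
    n = int(round(fid.u_end * FS)) + 400
    t = np.arange(n) / FS
    x = (0.5 * np.exp(-0.5 * ((t - fid.t_peak / FS) / 0.05) ** 2)
         + 0.15 * np.exp(-0.5 * ((t - fid.u_peak / FS) / 0.04) ** 2)
         + 1.0 * np.exp(-0.5 * ((t - 0.3) / 0.01) ** 2))
    samples = np.tile(x, (n_leads, 1))
    labels = ["V2"] + [f"L{i}" for i in range(1, n_leads)]
    return AveragedBeat(samples=samples, fs=FS, lead_labels=labels,
                        mean_rr=rr, n_beats_used=10)


def test_bue_is_the_b_to_u_end_difference_at_unit_rr():
    """B at 0.400 s and U end at 0.632 s give BUe = 0.232 s when RR = 1."""
    fid = _fid(q_onset=200, j_point=370, t_peak=600, bottom_b=800,
               u_peak=1000, t_end=0.38, u_end=0.632)
    beat = _beat_for(fid, rr=1.0)
    p = compute_parameters(fid, beat)
    assert p.bue == pytest.approx(0.632 - 0.400, abs=1e-9)
    assert p.bup == pytest.approx((1000 - 800) / FS, abs=1e-9)


def test_degenerate_zero_length_interval_rejected():
    fid = _fid(u_end=1500 / FS)  # U end at the U peak
    with pytest.raises(ValueError):
        fid.validate()


def test_bazett_correction_scales_intervals_by_inverse_sqrt_rr():
    fid = _fid()
    p1 = compute_parameters(fid, _beat_for(fid, rr=1.0))
    p2 = compute_parameters(fid, _beat_for(fid, rr=0.25))
    for name in ("qtc", "quc", "qtp", "qup", "teue", "tpup", "bup", "bue"):
        assert getattr(p2, name) == pytest.approx(2 * getattr(p1, name))
    # amplitudes are not rate corrected
    assert p2.tp_amp == pytest.approx(p1.tp_amp)


def test_pca_ratio_rank_one_segment_is_zero(one_beat):
    """All leads proportional to one waveform -> second eigenvalue 0."""
    beat, fid, _ = one_beat
    wave = beat.lead(fid.analysis_lead)
    rank1 = AveragedBeat(
        samples=np.outer([1.0, 0.5, -0.7, 0.2], wave),
        fs=beat.fs, lead_labels=["V2", "V3", "V4", "V5"],
        mean_rr=beat.mean_rr, n_beats_used=10)
    assert pca_ratio(rank1, fid) == pytest.approx(0.0, abs=1e-8)


def test_pca_ratio_four_to_one_variance_pair_is_25_percent():
    """Two orthogonal inter-lead components with variances 4 and 1."""
    n = 3000
    t = np.arange(n) / FS
    c1 = np.sin(2 * np.pi * 3 * t)
    c2 = np.cos(2 * np.pi * 7 * t)
    # orthonormal lead loadings, component variances 4:1
    load1 = np.array([0.5, 0.5, 0.5, 0.5]) * 2.0
    load2 = np.array([0.5, -0.5, 0.5, -0.5]) * 1.0
    samples = np.outer(load1, c1) + np.outer(load2, c2)
    beat = AveragedBeat(samples=samples, fs=FS,
                        lead_labels=["V2", "V3", "V4", "V5"],
                        mean_rr=1.0, n_beats_used=10)
    fid = _fid(j_point=10, u_end=(n - 2) / FS)
    assert pca_ratio(beat, fid) == pytest.approx(25.0, abs=0.5)
    assert pca_ratio(beat, fid, definition="singular_ratio") == pytest.approx(50.0, abs=0.5)


def test_pca_ratio_invariances(one_beat):
    """Bounded in [0, 100]; invariant to lead order and global scaling."""
    beat, fid, _ = one_beat
    r = pca_ratio(beat, fid)
    assert 0.0 <= r <= 100.0
    perm = np.random.default_rng(0).permutation(beat.n_leads)
    permuted = AveragedBeat(samples=beat.samples[perm] * 3.7, fs=beat.fs,
                            lead_labels=[beat.lead_labels[i] for i in perm],
                            mean_rr=beat.mean_rr, n_beats_used=10)
    assert pca_ratio(permuted, fid) == pytest.approx(r, rel=1e-9)


def test_pca_ratio_rank_zero_segment_rejected():
    beat = AveragedBeat(samples=np.zeros((4, 2000)), fs=FS,
                        lead_labels=["V2", "V3", "V4", "V5"],
                        mean_rr=1.0, n_beats_used=10)
    with pytest.raises(ValueError, match="rank-0"):
        pca_ratio(beat, _fid(j_point=10, u_end=0.9))


def test_predictor_vector_length_and_consistency(one_beat):
    beat, fid, _ = one_beat
    pca = pca_ratio(beat, fid)
    pv = predictor_vector(fid, beat, pca=pca)
    assert len(pv) == 15
    arr = pv.as_array()
    assert arr.shape == (15,) and np.all(np.isfinite(arr))
    p = compute_parameters(fid, beat, pca=pca)
    # shared quantities agree between the two feature surfaces
    assert pv.bue == pytest.approx(p.bue)
    assert pv.bup == pytest.approx(p.bup)
    assert pv.tpup == pytest.approx(p.tpup)
    assert pv.uete == pytest.approx(p.teue)
    assert pv.pca_ratio == pytest.approx(p.pca_ratio)


def test_predictor_times_invariant_to_beat_translation():
    fid = _fid()
    beat = _beat_for(fid, n_leads=2)
    k = 60
    rolled = AveragedBeat(samples=np.roll(beat.samples, k, axis=1),
                          fs=beat.fs, lead_labels=beat.lead_labels,
                          mean_rr=beat.mean_rr, n_beats_used=10)
    a = predictor_vector(fid, beat, pca=10.0)
    b = predictor_vector(fid.shifted(k), rolled, pca=10.0)
    for name in PREDICTOR_NAMES:
        assert getattr(b, name) == pytest.approx(getattr(a, name), abs=1e-6), name


def test_simulated_control_ut_ratio_is_small_and_below_ats():
    """Controls show U/T amplitude ratios near the configured 0.0895 level
    (the feasibility-rejection step inflates the smallest U draws), well
    separated from the ATS1-like group."""
    rng = np.random.default_rng(9)
    cfg = CohortConfig()
    ctrl = [simulate_subject("control", cfg, rng).true_parameters.ut_ratio
            for _ in range(60)]
    ats = [simulate_subject("ATS1", cfg, rng).true_parameters.ut_ratio
           for _ in range(60)]
    assert 0.05 < np.mean(ctrl) < 0.20
    assert np.mean(ats) > 2 * np.mean(ctrl)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(rr=st.floats(0.4, 2.0), x=st.floats(0.05, 1.0))
def test_correction_scaling_property(rr, x):
    from tuwave.delineate import rate_correct
    assert rate_correct(x, rr) == pytest.approx(x / np.sqrt(rr))


def test_pca_ratio_direction_ats_exceeds_control():
    """Inter-lead dyssynchrony is larger for ATS1-like subjects than for
    controls (direction of the group effect)."""
    import warnings
    warnings.filterwarnings("ignore", message="FastICA")
    from tuwave.preprocess import average_beats, detect_beats, wavelet_denoise
    from tuwave.delineate import locate_fiducials
    from tuwave.synthetic import generate_cohort

    vals = {"ATS1": [], "control": []}
    for rec, truth in generate_cohort(CohortConfig(n_per_group=8, seed=21)):
        beat = wavelet_denoise(average_beats(rec, detect_beats(rec)))
        try:
            fid = locate_fiducials(beat)
        except ValueError:
            continue
        vals[truth.group].append(pca_ratio(beat, fid))
    assert len(vals["ATS1"]) >= 6 and len(vals["control"]) >= 6
    assert np.mean(vals["ATS1"]) > np.mean(vals["control"])
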