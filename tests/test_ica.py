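"""Repeated-run ICA: separation, stability selection, i-ICA, counting."""

import numpy as np
import pytest

from tuwave.containers import AveragedBeat, FiducialSet
from tuwave.ica import (
    IcaDecomposition,
    IcaRunConfig,
    classify_ics,
    decompose_beat,
    inverse_project,
    run_ica_once,
    select_best_model,
)

FS = 2000.0


def _beat_from(samples, labels=None):
    labels = labels or [f"L{i}" for i in range(samples.shape[0])]
    return AveragedBeat(samples=samples, fs=FS, lead_labels=labels,
                        mean_rr=1.0, n_beats_used=10)


def _sparse_sources(rng, k=2, n=3000):
    """Disjoint sparse bump trains: strongly non-Gaussian, independent.

    Each source's bumps live in its own time slice, so the sources are
    temporally disjoint (sample correlation ~0)."""
    t = np.arange(n) / FS
    s = np.zeros((k, n))
    width = n / FS / k
    for i in range(k):
        centers = rng.uniform(i * width + 0.05, (i + 1) * width - 0.05, size=5)
        for c in centers:
            s[i] += rng.uniform(0.5, 1.5) * np.exp(-0.5 * ((t - c) / 0.01) ** 2)
        s[i] -= s[i].mean()
    return s


def _match_corr(s_true, s_est):
    """Best |corr| match per true source."""
    out = []
    for i in range(s_true.shape[0]):
        cs = [abs(np.corrcoef(s_true[i], s_est[j])[0, 1])
              for j in range(s_est.shape[0])]
        out.append(max(cs))
    return out


@pytest.mark.parametrize("backend", ["fastica", "radical"])
def test_two_source_recovery(backend):
    """A random 2x2 mixture of non-Gaussian sources is unmixed to |corr|>0.95."""
    rng = np.random.default_rng(0)
    s = _sparse_sources(rng)
    a = rng.uniform(0.3, 1.0, (2, 2))
    beat = _beat_from(a @ s)
    cfg = IcaRunConfig(n_runs=2, additive_noise_sd=0.0)
    sources, mixing = run_ica_once(beat, cfg, run_seed=1, backend=backend)
    assert min(_match_corr(s, sources)) > 0.95
    # exact reconstruction: the unmixing is square and applied to the data
    np.testing.assert_allclose(mixing @ sources,
                               beat.samples - beat.samples.mean(axis=1, keepdims=True),
                               atol=1e-8)


def test_identity_mixture_gives_permutation_mixing():
    """When the leads already are the sources, the mixing estimate is a
    (signed, scaled) permutation matrix."""
    rng = np.random.default_rng(1)
    s = _sparse_sources(rng)
    beat = _beat_from(s.copy())
    cfg = IcaRunConfig(n_runs=2, additive_noise_sd=0.0)
    _, mixing = run_ica_once(beat, cfg, run_seed=2)
    for col in range(2):
        entries = np.abs(mixing[:, col])
        assert entries.max() > 10 * np.sort(entries)[-2] or np.sort(entries)[-2] < 1e-6


def test_rank_deficient_input_rejected():
    rng = np.random.default_rng(2)
    s = _sparse_sources(rng, k=1)
    beat = _beat_from(np.vstack([s[0], 2 * s[0]]))
    with pytest.raises(ValueError, match="rank-deficient"):
        run_ica_once(beat, IcaRunConfig(n_runs=2), run_seed=0)


def test_best_model_identical_runs_have_unit_stability():
    rng = np.random.default_rng(3)
    s = _sparse_sources(rng, k=3)
    a = rng.uniform(0.3, 1.0, (3, 3))
    beat = _beat_from(a @ s)
    run = run_ica_once(beat, IcaRunConfig(n_runs=2, additive_noise_sd=0.0), 5)
    dec = select_best_model([run, run, run], beat, IcaRunConfig(n_runs=3))
    np.testing.assert_allclose(dec.stability, 1.0, atol=1e-9)


def test_best_model_permutation_invariant():
    """A permuted, sign-flipped copy of a run clusters perfectly."""
    rng = np.random.default_rng(4)
    s = _sparse_sources(rng, k=3)
    a = rng.uniform(0.3, 1.0, (3, 3))
    beat = _beat_from(a @ s)
    s1, m1 = run_ica_once(beat, IcaRunConfig(n_runs=2, additive_noise_sd=0.0), 5)
    perm = [2, 0, 1]
    s2 = -s1[perm]
    m2 = -m1[:, perm]
    dec = select_best_model([(s1, m1), (s2, m2)], beat, IcaRunConfig(n_runs=2))
    np.testing.assert_allclose(dec.stability, 1.0, atol=1e-9)


def test_gaussian_sources_are_flagged_unstable():
    """Pure Gaussian sources are not identifiable: repeated runs disagree
    and the stability index shows it."""
    rng = np.random.default_rng(5)
    x = rng.normal(size=(4, 3000))
    beat = _beat_from(x)
    cfg = IcaRunConfig(n_runs=6, additive_noise_sd=0.02, seed=0)
    runs = [run_ica_once(beat, cfg, run_seed=i) for i in range(6)]
    dec = select_best_model(runs, beat, cfg)
    assert np.mean(dec.stability) < 0.9


def test_inverse_projection_contract(one_beat):
    """Full subset reconstructs the beat (minus the mean), the empty subset
    is zero, and out-of-range indices raise."""
    beat, fid, _ = one_beat
    dec = decompose_beat(beat, fid, IcaRunConfig(n_runs=4, seed=0))
    full = inverse_project(dec, range(dec.n_ics))
    centred = beat.samples - beat.samples.mean(axis=1, keepdims=True)
    np.testing.assert_allclose(full, centred, atol=1e-6)
    np.testing.assert_allclose(dec.reconstruct(), beat.samples, atol=1e-6)
    assert not inverse_project(dec, []).any()
    with pytest.raises(IndexError):
        inverse_project(dec, [dec.n_ics])


def test_planted_u_sources_project_into_u_window(one_beat):
    """The inverse projection of the planted U sources keeps >=90% of its
    energy inside [B, U end] on every lead."""
    beat, fid, truth = one_beat
    dec = IcaDecomposition(
        sources=truth.source_waveforms.copy(),
        mixing=truth.mixing.copy(),
        mean=np.zeros(truth.mixing.shape[0]),
        fs=truth.fs,
        lead_labels=list(beat.lead_labels),
    )
    p = inverse_project(dec, truth.u_source_indices)
    lo, hi = fid.bottom_b, int(round(fid.u_end * truth.fs))
    total = np.sum(p ** 2, axis=1)
    inside = np.sum(p[:, lo:hi] ** 2, axis=1)
    active = total > 1e-12
    assert np.all(inside[active] >= 0.90 * total[active])


def _toy_decomposition(fid):
    """Hand-built decomposition with known window energies."""
    n = int(round(fid.u_end * FS)) + 200
    t = np.arange(n) / FS
    b_t, ue_t = fid.bottom_b / FS, fid.u_end
    j_t = fid.j_point / FS
    u_only = np.exp(-0.5 * ((t - (b_t + ue_t) / 2) / 0.02) ** 2)
    u_only[: fid.bottom_b] = 0.0          # exactly zero before B
    t_only = np.exp(-0.5 * ((t - (j_t + b_t) / 2) / 0.03) ** 2)
    t_only[fid.bottom_b:] = 0.0
    # 60% T / 40% U energy split, at the same energy scale as the pure
    # sources so the straddler stays salient in the T window
    scale = np.linalg.norm(t_only)
    mixed = (np.sqrt(0.6) * t_only / np.linalg.norm(t_only)
             + np.sqrt(0.4) * u_only / np.linalg.norm(u_only)) * scale
    sources = np.vstack([t_only, u_only, mixed])
    mixing = np.eye(3)
    return IcaDecomposition(sources=sources, mixing=mixing,
                            mean=np.zeros(3), fs=FS,
                            lead_labels=["V2", "V3", "V4"])


def test_classification_rules():
    """Zero-before-B implies U-specific; a 60/40 straddler with a large
    T-energy share is a T-IC."""
    fid = FiducialSet(q_onset=100, j_point=200, t_peak=400, bottom_b=700,
                      u_peak=900, t_end=0.33, u_end=0.55,
                      analysis_lead="V2", fs=FS)
    dec = classify_ics(_toy_decomposition(fid), fid, IcaRunConfig())
    assert dec.labels[1] == "U-specific"
    assert dec.labels[0] == "T-IC"
    assert dec.labels[2] == "T-IC"       # 60% T, salient in the T window
    assert dec.n_u_specific_ics == 1
    assert dec.n_t_ics == 2


def test_counts_invariant_under_permutation_and_sign():
    fid = FiducialSet(q_onset=100, j_point=200, t_peak=400, bottom_b=700,
                      u_peak=900, t_end=0.33, u_end=0.55,
                      analysis_lead="V2", fs=FS)
    dec = _toy_decomposition(fid)
    ref = classify_ics(dec, fid, IcaRunConfig())
    perm = [2, 0, 1]
    flipped = IcaDecomposition(
        sources=-dec.sources[perm], mixing=-dec.mixing[:, perm],
        mean=dec.mean, fs=dec.fs, lead_labels=dec.lead_labels)
    out = classify_ics(flipped, fid, IcaRunConfig())
    assert out.n_t_ics == ref.n_t_ics
    assert out.n_u_specific_ics == ref.n_u_specific_ics
    assert sorted(out.labels) == sorted(ref.labels)


def test_single_planted_u_source_counts_one():
    """With one planted U source per ATS1-like subject the modal U-specific
    count is 1 (and controls remain at 0 elsewhere in the suite)."""
    import warnings
    from collections import Counter
    warnings.filterwarnings("ignore", message="FastICA")
    from tuwave.delineate import locate_fiducials
    from tuwave.preprocess import average_beats, detect_beats, wavelet_denoise
    from tuwave.synthetic import CohortConfig, generate_cohort

    counts = Counter()
    cohort = generate_cohort(CohortConfig(n_per_group=6, seed=17,
                                          n_u_sources_ats=1))
    for rec, truth in cohort:
        if truth.group != "ATS1":
            continue
        beat = wavelet_denoise(average_beats(rec, detect_beats(rec)))
        try:
            fid = locate_fiducials(beat)
        except ValueError:
            continue
        dec = decompose_beat(beat, fid, IcaRunConfig(n_runs=10, seed=2))
        counts[dec.n_u_specific_ics] += 1
    assert sum(counts.values()) >= 4
    assert counts.most_common(1)[0][0] == 1, counts
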