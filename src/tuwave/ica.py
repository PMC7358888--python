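"""Repeated-run ICA of the TU complex with inverse projection.

The decomposition follows a four-step scheme: (1) the averaged beat is
wavelet-denoised upstream; (2) ICA is run many times, each time on a copy
of the data perturbed with a small amount of additive random noise — a
robustification that exposes unstable components; (3) the runs are matched
component-by-component and the most self-consistent run is kept, with a
per-component stability index; (4) chosen components are projected back
through the mixing matrix onto the original leads (inverse ICA) to show
what each contributes to the surface ECG, which is what the T-window /
U-window classification and the component counts are computed from.

The default rotation is FastICA's negentropy-based fixed point
(scikit-learn); an order-statistics (spacings-entropy, RADICAL-style)
backend is available for cross-checking on small problems.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import FastICA

from .containers import AveragedBeat, FiducialSet

__all__ = [
    "IcaRunConfig",
    "IcaDecomposition",
    "run_ica_once",
    "select_best_model",
    "inverse_project",
    "classify_ics",
    "decompose_beat",
]

#: an IC participates in a wave when it carries at least this fraction of
#: that wave's window energy (summed over ICs); judged per window because
#: the U wave carries an order of magnitude less energy than the T wave,
#: so U components would never clear a threshold set against the whole
#: TU complex
RELEVANCE_FRACTION = 0.05


@dataclass
class IcaRunConfig:
    """Settings for the repeated-run decomposition."""

    n_runs: int = 50
    additive_noise_sd: float = 0.02   # fraction of per-lead signal SD
    seed: int = 0
    energy_fraction_threshold: float = 0.90

    def validate(self) -> None:
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not (0.5 < self.energy_fraction_threshold <= 1.0):
            raise ValueError("energy_fraction_threshold must be in (0.5, 1]")
        if self.additive_noise_sd < 0:
            raise ValueError("additive_noise_sd must be non-negative")


@dataclass
class IcaDecomposition:
    """Sources, mixing and (after classification) per-IC labels/counts.

    ``mixing @ sources + mean`` reconstructs the decomposed beat exactly
    (the unmixing matrix is square and full rank).
    """

    sources: np.ndarray               # (n_ics, n_samples), unit variance
    mixing: np.ndarray                # (n_leads, n_ics)
    mean: np.ndarray                  # (n_leads,) per-lead offset
    fs: float
    lead_labels: list[str]
    stability: Optional[np.ndarray] = None     # per-IC in [0, 1]
    labels: Optional[list[str]] = None         # 'T-IC' | 'U-specific' | 'other'
    n_t_ics: Optional[int] = None
    n_u_specific_ics: Optional[int] = None

    @property
    def n_ics(self) -> int:
        return self.sources.shape[0]

    @property
    def n_leads(self) -> int:
        return self.mixing.shape[0]

    def reconstruct(self) -> np.ndarray:
        """The decomposed (denoised) beat: mixing @ sources + mean."""
        return self.mixing @ self.sources + self.mean[:, None]


def _normalize(sources: np.ndarray, mixing: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unit-variance sources; signs fixed so the largest extremum is positive."""
    sources = sources.copy()
    mixing = mixing.copy()
    for i in range(sources.shape[0]):
        sd = sources[i].std()
        if sd > 0:
            sources[i] /= sd
            mixing[:, i] *= sd
        if abs(sources[i].min()) > abs(sources[i].max()):
            sources[i] *= -1.0
            mixing[:, i] *= -1.0
    return sources, mixing


def _spacings_entropy(x: np.ndarray) -> float:
    """Vasicek m-spacings estimate of the differential entropy."""
    n = len(x)
    m = max(int(np.sqrt(n)), 1)
    xs = np.sort(x)
    gaps = xs[m:] - xs[:-m]
    gaps = np.maximum(gaps, 1e-12)
    return float(np.mean(np.log(n / (2.0 * m) * gaps)))


def _radical_rotation(z: np.ndarray, rng: np.random.Generator,
                      n_angles: int = 60, sweeps: int = 2) -> np.ndarray:
    """Order-statistics ICA on whitened data via pairwise Jacobi rotations.

    For every pair of components the rotation angle minimizing the sum of
    spacings-entropy marginals is chosen from ``n_angles`` candidates on
    [0, pi/2); a few sweeps over all pairs suffice after whitening.
    Returns the orthogonal unmixing rotation.
    """
    k = z.shape[0]
    w = np.eye(k)
    y = z.copy()
    angles = np.linspace(0.0, np.pi / 2, n_angles, endpoint=False)
    for _ in range(sweeps):
        for a in range(k - 1):
            for b in range(a + 1, k):
                best_h, best_theta = np.inf, 0.0
                for theta in angles:
                    c, s = np.cos(theta), np.sin(theta)
                    ya = c * y[a] + s * y[b]
                    yb = -s * y[a] + c * y[b]
                    h = _spacings_entropy(ya) + _spacings_entropy(yb)
                    if h < best_h:
                        best_h, best_theta = h, theta
                c, s = np.cos(best_theta), np.sin(best_theta)
                rot = np.eye(k)
                rot[a, a] = rot[b, b] = c
                rot[a, b] = s
                rot[b, a] = -s
                y = rot @ y
                w = rot @ w
    return w


def run_ica_once(
    beat: AveragedBeat,
    config: IcaRunConfig,
    run_seed: int,
    backend: str = "fastica",
) -> tuple[np.ndarray, np.ndarray]:
    """One ICA decomposition with additive-noise robustification.

    The unmixing is *fit* on a copy of the centred data perturbed by white
    noise (``additive_noise_sd`` x per-lead SD) and then applied to the
    unperturbed data, so ``mixing @ sources`` reconstructs the input
    exactly while the estimate itself is exposed to the perturbation.

    Returns
    -------
    (sources, mixing) : unit-variance sources (n_ics x n_samples) and the
    corresponding mixing matrix (n_leads x n_ics).
    """
    config.validate()
    x = beat.samples
    if x.shape[0] < 2:
        raise ValueError("ICA requires at least 2 leads")
    mean = x.mean(axis=1)
    xc = x - mean[:, None]
    sv = np.linalg.svd(xc, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        raise ValueError("rank-deficient input (collinear leads)")

    rng = np.random.default_rng(run_seed)
    noise = rng.normal(0.0, 1.0, size=xc.shape) * (
        config.additive_noise_sd * xc.std(axis=1, keepdims=True))
    x_fit = xc + noise

    if backend == "fastica":
        ica = FastICA(
            n_components=x.shape[0],
            whiten="unit-variance",
            max_iter=1000,
            tol=1e-5,
            random_state=int(rng.integers(2 ** 31 - 1)),
        )
        ica.fit(x_fit.T)
        w_full = ica.components_          # (n_ics, n_leads), includes whitening
    elif backend == "radical":
        # whiten x_fit, then rotate by spacings-entropy minimization
        cov = np.cov(x_fit)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.maximum(evals, 1e-12)
        whiten = (evecs / np.sqrt(evals)).T   # (k, n_leads)
        z = whiten @ x_fit
        rot = _radical_rotation(z, rng)
        w_full = rot @ whiten
    else:
        raise ValueError(f"unknown ICA backend {backend!r}")

    sources = w_full @ xc
    mixing = np.linalg.pinv(w_full)
    return _normalize(sources, mixing)


def select_best_model(
    runs: Sequence[tuple[np.ndarray, np.ndarray]],
    beat: AveragedBeat,
    config: IcaRunConfig,
) -> IcaDecomposition:
    """Match components across repeated runs and keep the best run.

    Components are clustered by absolute correlation: each run's ICs are
    assigned (Hungarian matching) to the first run's, defining one cluster
    per component slot.  A cluster's stability is the mean pairwise |corr|
    of its members; the returned model is the run whose members agree best
    with the rest, with the cluster stabilities attached per IC.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs to select a best model")
    r_n = len(runs)
    k = runs[0][0].shape[0]
    n = runs[0][0].shape[1]

    def std_rows(s: np.ndarray) -> np.ndarray:
        c = s - s.mean(axis=1, keepdims=True)
        norm = np.linalg.norm(c, axis=1, keepdims=True)
        if np.any(norm == 0):
            raise ValueError("all-zero source; cannot cluster runs")
        return c / norm

    z0 = std_rows(runs[0][0])
    # members[r] = row-permuted standardized sources of run r aligned to run 0
    members = np.empty((r_n, k, n))
    members[0] = z0
    perms = [np.arange(k)]
    for r in range(1, r_n):
        zr = std_rows(runs[r][0])
        c = np.abs(z0 @ zr.T)
        row, col = linear_sum_assignment(-c)
        perm = np.empty(k, dtype=int)
        perm[row] = col
        members[r] = zr[perm]
        perms.append(perm)

    # pairwise |corr| within each cluster
    run_scores = np.zeros(r_n)
    cluster_stability = np.zeros(k)
    for c_i in range(k):
        m = members[:, c_i, :]               # (r_n, n)
        cc = np.abs(m @ m.T)
        off_sum = cc.sum(axis=1) - np.diag(cc)
        member_score = off_sum / (r_n - 1)
        run_scores += member_score
        cluster_stability[c_i] = (cc.sum() - np.trace(cc)) / (r_n * (r_n - 1))
    run_scores /= k

    best = int(np.argmax(run_scores))
    sources, mixing = runs[best]
    # align the best run's ICs to the cluster slots so stability lines up
    perm = perms[best]
    inv = np.empty(k, dtype=int)
    inv[np.arange(k)] = perm
    sources = sources[perm]
    mixing = mixing[:, perm]
    return IcaDecomposition(
        sources=sources,
        mixing=mixing,
        mean=beat.samples.mean(axis=1),
        fs=beat.fs,
        lead_labels=list(beat.lead_labels),
        stability=cluster_stability,
    )


def inverse_project(
    decomposition: IcaDecomposition,
    ic_subset: Sequence[int],
) -> np.ndarray:
    """Contribution of a subset of ICs on the original leads (i-ICA).

    Returns ``mixing[:, subset] @ sources[subset]``; the empty subset gives
    all-zero waveforms and the full set reconstructs the decomposed beat up
    to the per-lead mean offset.
    """
    subset = np.asarray(list(ic_subset), dtype=int)
    if subset.size == 0:
        return np.zeros((decomposition.n_leads, decomposition.sources.shape[1]))
    if subset.min() < 0 or subset.max() >= decomposition.n_ics:
        raise IndexError(f"IC index out of range (have {decomposition.n_ics})")
    return decomposition.mixing[:, subset] @ decomposition.sources[subset]


def classify_ics(
    decomposition: IcaDecomposition,
    fiducials: FiducialSet,
    config: IcaRunConfig,
) -> IcaDecomposition:
    """Label every IC as T-IC, U-specific or other, and count them.

    For each IC the inverse projection's energy (averaged over leads) is
    split between the T window [J point, B] and the U window [B, U end].
    An IC is *U-specific* when at least ``energy_fraction_threshold`` of
    its TU energy falls in the U window — it contributes (essentially)
    nothing to the T wave.  It is a *T-IC* when the same holds for the T
    window, or when it carries at least 10% of the total T-window energy.
    Counts consider only ICs that are salient in the wave they are
    attributed to: >=5% of that window's energy summed over ICs (the U
    wave carries far less energy than the T wave, so salience is judged
    per window); this excludes QRS and noise components.
    """
    fid = fiducials
    t_lo, t_hi = fid.j_point, fid.bottom_b
    u_lo = fid.bottom_b
    u_hi = min(int(round(fid.u_end * decomposition.fs)),
               decomposition.sources.shape[1])
    if not (t_lo < t_hi <= u_hi):
        raise ValueError("inconsistent T/U windows from fiducials")

    k = decomposition.n_ics
    e_t = np.zeros(k)
    e_u = np.zeros(k)
    for i in range(k):
        p = inverse_project(decomposition, [i])
        e_t[i] = np.mean(np.sum(p[:, t_lo:t_hi] ** 2, axis=1))
        e_u[i] = np.mean(np.sum(p[:, u_lo:u_hi] ** 2, axis=1))
    tu = e_t + e_u
    if tu.sum() <= 0:
        raise ValueError("no TU-window energy in any component")
    t_share = e_t / max(e_t.sum(), 1e-300)
    u_share = e_u / max(e_u.sum(), 1e-300)

    thr = config.energy_fraction_threshold
    labels = []
    for i in range(k):
        if u_share[i] >= RELEVANCE_FRACTION and e_u[i] / tu[i] >= thr:
            labels.append("U-specific")
        elif t_share[i] >= RELEVANCE_FRACTION and e_t[i] / tu[i] >= 0.5:
            # salient in the T window and majority-T: a component that
            # "comprises the T wave" even when its tail also shapes the U
            labels.append("T-IC")
        else:
            labels.append("other")

    decomposition.labels = labels
    decomposition.n_t_ics = labels.count("T-IC")
    decomposition.n_u_specific_ics = labels.count("U-specific")
    return decomposition


def decompose_beat(
    beat: AveragedBeat,
    fiducials: FiducialSet,
    config: Optional[IcaRunConfig] = None,
    backend: str = "fastica",
) -> IcaDecomposition:
    """Full repeated-run decomposition of one denoised beat.

    Runs ICA ``config.n_runs`` times with per-run seeds spawned from
    ``config.seed``, selects the most stable run, and classifies/counts
    the T-ICs and U-specific ICs using the delineated windows.
    """
    config = config or IcaRunConfig()
    config.validate()
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_runs)
    runs = [run_ica_once(beat, config, int(s) % (2 ** 31 - 1), backend=backend)
            for s in seeds]
    dec = select_best_model(runs, beat, config)
    return classify_ics(dec, fiducials, config)
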