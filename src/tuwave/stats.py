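"""Group comparisons, best-subset logistic regression and ROC analysis.

The group layer reproduces the study's statistics three ways: Welch tests
computed directly from summary statistics (mean, SD, n per group), an
exhaustive best-subset logistic regression scored by AIC with a
separation-safe convergence rule, and ROC analysis with Youden-index
cutoffs.

Under complete separation the logistic likelihood tends to 1 and the
coefficients diverge; the reproducible quantity is then the AIC limit
2*(number of parameters), which the fit reports together with a
``separated`` flag instead of the meaningless coefficient values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "LogisticModelFit",
    "RocResult",
    "welch_t_summary",
    "welch_t",
    "fit_logistic",
    "best_subset_logistic",
    "roc_analysis",
]


@dataclass
class GroupSummary:
    """Summary statistics of one variable in two groups."""

    mean1: float
    sd1: float
    n1: int
    mean2: float
    sd2: float
    n2: int

    def validate(self) -> None:
        if self.sd1 < 0 or self.sd2 < 0:
            raise ValueError("standard deviations must be non-negative")
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs at least 2 observations")


@dataclass
class LogisticModelFit:
    """Result of one maximum-likelihood logistic fit."""

    predictor_subset: tuple[str, ...]
    coefficients: np.ndarray          # intercept first
    log_likelihood: float
    aic: float
    separated: bool
    n_iter: int = 0
    converged: bool = True

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


@dataclass
class RocResult:
    """ROC summary for one candidate marker."""

    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def sensitivity_counts(self) -> str:
        return f"{self.tp}/{self.tp + self.fn}"

    @property
    def specificity_counts(self) -> str:
        return f"{self.tn}/{self.tn + self.fp}"


def welch_t_summary(s: GroupSummary, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided t test from group summaries.

    Welch's unequal-variance form by default; ``equal_var=True`` gives the
    classical pooled test.

    Returns
    -------
    (t, df, p) : test statistic, degrees of freedom, two-sided p value.
    """
    s.validate()
    if s.sd1 == 0 and s.sd2 == 0:
        raise ValueError("both group SDs are zero; t test undefined")
    d = s.mean1 - s.mean2
    if equal_var:
        sp2 = (((s.n1 - 1) * s.sd1 ** 2 + (s.n2 - 1) * s.sd2 ** 2)
               / (s.n1 + s.n2 - 2))
        se = np.sqrt(sp2 * (1 / s.n1 + 1 / s.n2))
        df = float(s.n1 + s.n2 - 2)
    else:
        v1, v2 = s.sd1 ** 2 / s.n1, s.sd2 ** 2 / s.n2
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (s.n1 - 1) + v2 ** 2 / (s.n2 - 1))
    t = d / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def welch_t(x1: np.ndarray, x2: np.ndarray, equal_var: bool = False) -> tuple[float, float, float]:
    """Two-sided t test from raw samples (consistent with the summary form)."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return welch_t_summary(GroupSummary(
        mean1=float(x1.mean()), sd1=float(x1.std(ddof=1)), n1=len(x1),
        mean2=float(x2.mean()), sd2=float(x2.std(ddof=1)), n2=len(x2),
    ), equal_var=equal_var)


# deviance below this is taken as a perfectly fitted (separated) model
_SEPARATION_DEVIANCE = 1e-6
_MAX_IRLS_ITER = 100


def fit_logistic(
    x: np.ndarray,
    y: np.ndarray,
    names: Optional[Sequence[str]] = None,
) -> LogisticModelFit:
    """Maximum-likelihood logistic regression by IRLS with separation guard.

    Parameters
    ----------
    x : ndarray (n, k)
        Predictor matrix (no intercept column; one is added).  ``k`` may be
        0 for the intercept-only model.
    y : ndarray (n,)
        Binary labels in {0, 1}; both classes must be present.

    Notes
    -----
    Iteratively reweighted least squares, capped at 100 iterations.  If the
    deviance falls below 1e-6 the classes are completely separated: the
    likelihood approaches 1, the coefficients are non-identifiable, and the
    fit reports ``separated=True`` with AIC at its limit 2*(k+1).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.shape[0] == 1 and x.shape[1] > 1 and x.size == len(y):
        x = x.T
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if x.size == 0:
        x = np.empty((n, 0))
    if x.shape[0] != n:
        raise ValueError("x and y lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("y must contain both classes")
    k = x.shape[1]
    if k > 0:
        constant = np.all(x == x[0, :], axis=0)
        if np.any(constant):
            raise ValueError("constant predictor column: slope unidentifiable")

    design = np.column_stack([np.ones(n), x])
    beta = np.zeros(k + 1)
    converged = False
    it = 0
    for it in range(1, _MAX_IRLS_ITER + 1):
        eta = design @ beta
        p = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        w = p * (1 - p)
        z = eta + (y - p) / w
        wd = design * w[:, None]
        try:
            beta_new = np.linalg.solve(design.T @ wd + 1e-10 * np.eye(k + 1),
                                       design.T @ (w * z))
        except np.linalg.LinAlgError:
            break
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if step < 1e-8:
            converged = True
            break

    eta = design @ beta
    p = np.clip(1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35))), 1e-15, 1 - 1e-15)
    loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
    deviance = -2.0 * loglik
    # complete separation: the deviance collapses, or the coefficients
    # diverge while every observation is already on its own side
    all_correct = bool(np.all((p > 0.5) == (y > 0.5)))
    separated = (deviance < _SEPARATION_DEVIANCE
                 or (np.max(np.abs(beta)) > 50 and all_correct
                     and deviance < 1e-3))
    if separated:
        # likelihood tends to 1 and the coefficients are non-identifiable;
        # report the limiting values as the reproducible quantities
        loglik = 0.0
    aic = 2.0 * (k + 1) - 2.0 * loglik
    subset = tuple(names) if names is not None else tuple(f"x{i}" for i in range(k))
    return LogisticModelFit(
        predictor_subset=subset,
        coefficients=beta,
        log_likelihood=loglik,
        aic=float(aic),
        separated=bool(separated),
        n_iter=it,
        converged=converged or separated,
    )


def best_subset_logistic(
    x: np.ndarray,
    y: np.ndarray,
    names: Sequence[str],
) -> tuple[LogisticModelFit, int]:
    """Exhaustive best-subset logistic regression scored by AIC.

    Fits the intercept-only model and every non-empty predictor subset
    (2^k - 1 fits) and returns the minimum-AIC model.  Ties break to the
    smaller subset, then lexicographically on predictor names.  Subsets
    whose fit fails outright are skipped.

    Returns
    -------
    (best_fit, n_subset_fits) : the winning model and the number of
    non-empty subsets actually fitted (the exhaustiveness audit counter).
    """
    x = np.asarray(x, dtype=float)
    names = list(names)
    if x.shape[1] != len(names):
        raise ValueError("one name per predictor column required")
    if x.shape[1] > 20:
        raise ValueError("exhaustive enumeration limited to 20 predictors")

    best = fit_logistic(np.empty((len(y), 0)), y, names=())
    n_fits = 0
    for r in range(1, len(names) + 1):
        for combo in combinations(range(len(names)), r):
            try:
                fit = fit_logistic(x[:, combo], y,
                                   names=[names[i] for i in combo])
            except (ValueError, np.linalg.LinAlgError):
                continue
            n_fits += 1
            key = (round(fit.aic, 9), len(fit.predictor_subset), fit.predictor_subset)
            best_key = (round(best.aic, 9), len(best.predictor_subset), best.predictor_subset)
            if key < best_key:
                best = fit
    return best, n_fits


def roc_analysis(
    values: np.ndarray,
    labels: np.ndarray,
    direction: str = "greater",
) -> RocResult:
    """ROC curve summary with the Youden-index optimal cutoff.

    AUC is the rank statistic (probability that a random positive exceeds a
    random negative, ties counted 1/2).  The cutoff maximizes Youden's
    J = sensitivity + specificity - 1 over thresholds halfway between
    consecutive distinct values; ties at the maximum J break toward the
    larger specificity.  ``direction='greater'`` classifies values at or
    above the cutoff as positive.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    pos = values[labels]
    neg = values[~labels]
    if direction == "less":
        res = roc_analysis(-values, labels, direction="greater")
        return RocResult(auc=res.auc, cutoff=-res.cutoff,
                         sensitivity=res.sensitivity, specificity=res.specificity,
                         tp=res.tp, fn=res.fn, tn=res.tn, fp=res.fp)
    if direction != "greater":
        raise ValueError("direction must be 'greater' or 'less'")

    # Mann-Whitney formulation of the AUC
    u = 0.0
    for v in pos:
        u += np.sum(v > neg) + 0.5 * np.sum(v == neg)
    auc = u / (len(pos) * len(neg))

    uniq = np.unique(values)
    candidates = np.concatenate([
        [uniq[0] - 1.0], (uniq[:-1] + uniq[1:]) / 2.0, [uniq[-1] + 1.0]])
    best = None
    for c in candidates:
        tp = int(np.sum(pos >= c))
        fn = len(pos) - tp
        tn = int(np.sum(neg < c))
        fp = len(neg) - tn
        sens = tp / len(pos)
        spec = tn / len(neg)
        j = sens + spec - 1.0
        key = (j, spec)
        if best is None or key > best[0]:
            best = (key, c, tp, fn, tn, fp, sens, spec)
    _, cutoff, tp, fn, tn, fp, sens, spec = best
    return RocResult(auc=float(auc), cutoff=float(cutoff),
                     sensitivity=sens, specificity=spec,
                     tp=tp, fn=fn, tn=tn, fp=fp)
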