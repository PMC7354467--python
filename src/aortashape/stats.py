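"""Statistics on shape modes: correlations, group tests, risk models, clusters.

Mode scores ("shape vectors") are correlated with morphometric and
biomechanical descriptors by Pearson's R with two-sided t-distribution
p-values (raw p at alpha 0.05 by default; Benjamini-Hochberg behind a
flag, with the choice always recorded in the output).  Group comparisons
use Mann-Whitney (exact for small tie-free samples, tie-corrected normal
approximation otherwise) and Pearson chi-square.

The surgery-risk model is a maximum-likelihood logistic regression on the
shape modes retained at 90% cumulative variance, compared in-sample
against a diameter-only baseline via ROC curves and AUC.  The AUC is
computed by trapezoid over the threshold-swept ROC and is asserted at run
time to equal the rank-sum statistic (probability that a random positive
outranks a random negative, ties half-counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps
from scipy.special import expit

from .atlas import ShapeAtlas, modes_for_variance
from .errors import DegenerateInputError

ALPHA = 0.05
#: sample size at or below which Mann-Whitney uses the exact distribution
EXACT_MW_MAX_N = 20
#: ridge applied only when separation is detected in the logistic fit
SEPARATION_RIDGE = 1e-6


@dataclass
class CorrelationResult:
    mode: int
    descriptor: str
    r: float
    p: float
    n: int
    undefined: bool = False


@dataclass
class RiskModelResult:
    predictor: str                   # "modes_90" or "diameter"
    coefficients: np.ndarray         # on the original predictor scale
    intercept: float
    probabilities: np.ndarray
    auc: float
    roc_fpr: np.ndarray = field(repr=False)
    roc_tpr: np.ndarray = field(repr=False)
    n_predictors: int = 0
    ridge_active: bool = False
    converged: bool = True
    gradient_norm: float = np.nan


@dataclass
class ClusterResult:
    labels: np.ndarray
    k: int
    silhouette: float
    degenerate: bool = False


def correlate_modes(
    scores: np.ndarray,
    descriptors: pd.DataFrame,
    modes: Sequence[int] | None = None,
    subset: np.ndarray | None = None,
) -> pd.DataFrame:
    """Pearson R and two-sided p per (mode, descriptor) pair.

    ``scores`` is subjects x modes (row order matching ``descriptors``);
    missing descriptor values are removed pairwise.  Zero-variance pairs
    are flagged undefined rather than propagating NaN silently.  No
    multiple-testing correction is applied here; see
    :func:`benjamini_hochberg` to adjust downstream.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if subset is not None:
        scores = scores[np.asarray(subset)]
        descriptors = descriptors.loc[np.asarray(subset)]
    mode_list = list(modes) if modes is not None else list(range(1, scores.shape[1] + 1))
    results = []
    for m in mode_list:
        x_full = scores[:, m - 1]
        for name in descriptors.columns:
            y_full = pd.to_numeric(descriptors[name], errors="coerce").to_numpy()
            keep = np.isfinite(x_full) & np.isfinite(y_full)
            x, y = x_full[keep], y_full[keep]
            n = int(keep.sum())
            if n < 3:
                raise DegenerateInputError(
                    f"mode {m} vs {name}: only {n} complete pairs; need >= 3"
                )
            if np.std(x) == 0 or np.std(y) == 0:
                results.append(CorrelationResult(m, name, np.nan, np.nan, n, undefined=True))
                continue
            r, p = sps.pearsonr(x, y)
            results.append(CorrelationResult(m, name, float(r), float(p), n))
    return pd.DataFrame([r.__dict__ for r in results])


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(p_values, dtype=np.float64)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def compare_groups(a, b=None, kind: str = "mann_whitney", yates: bool = False):
    """Two-group comparison: ``mann_whitney`` on values, ``chi_square`` on counts.

    Mann-Whitney: exact null distribution when both groups have <= 20
    observations and no ties; tie-corrected normal approximation otherwise.
    Chi-square: Pearson statistic without Yates correction unless requested.
    Returns (statistic, p).
    """
    if kind == "mann_whitney":
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if a.size == 0 or b.size == 0:
            raise DegenerateInputError("both groups must be non-empty")
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        exact = max(a.size, b.size) <= EXACT_MW_MAX_N and not has_ties
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="exact" if exact else "asymptotic",
            use_continuity=False,
        )
        return float(res.statistic), float(min(res.pvalue, 1.0))
    if kind == "chi_square":
        table = np.asarray(a, dtype=np.float64)
        if np.any(table < 1):
            raise ValueError("chi-square requires counts >= 1 per cell")
        stat, p, _, _ = sps.chi2_contingency(table, correction=yates)
        return float(stat), float(p)
    raise ValueError(f"unknown test kind {kind!r}")


# ---------------------------------------------------------------------------
# Logistic risk model and ROC
# ---------------------------------------------------------------------------

def _logistic_nll(beta, X1, y, ridge):
    eta = X1 @ beta
    # log(1 + exp(eta)) - y*eta, numerically stable
    nll = np.sum(np.logaddexp(0.0, eta) - y * eta) + 0.5 * ridge * np.sum(beta[1:] ** 2)
    p = expit(eta)
    grad = X1.T @ (p - y)
    grad[1:] += ridge * beta[1:]
    return nll, grad


def _fit_logistic(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    X1 = np.column_stack([np.ones(len(y)), X])
    res = optimize.minimize(
        _logistic_nll,
        np.zeros(X1.shape[1]),
        args=(X1, y.astype(np.float64), ridge),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
    )
    return res.x, res


def fit_risk_model(
    labels: np.ndarray,
    atlas: ShapeAtlas | None = None,
    scores: np.ndarray | None = None,
    diameter: np.ndarray | None = None,
    predictor: str = "modes_90",
    variance_threshold: float = 0.90,
) -> RiskModelResult:
    """Logistic surgery-risk model and its in-sample ROC/AUC.

    ``predictor="modes_90"`` uses the mode scores retained at
    ``variance_threshold`` cumulative variance (from ``atlas``, or a
    pre-sliced ``scores`` matrix); ``predictor="diameter"`` is the
    diameter-only baseline.  The fit is unpenalized maximum likelihood;
    when complete separation blows the coefficients up, a ridge of 1e-6 is
    applied and ``ridge_active`` reported.  In-sample probabilities feed a
    threshold-swept ROC; the trapezoidal AUC is asserted against the
    rank-sum oracle.
    """
    y = np.asarray(labels).astype(bool)
    if y.sum() < 2 or (~y).sum() < 2:
        raise DegenerateInputError("need >= 2 subjects in each outcome class")
    if predictor == "modes_90":
        if scores is not None:
            X = np.asarray(scores, dtype=np.float64)
        elif atlas is not None:
            k = modes_for_variance(atlas, variance_threshold)
            X = atlas.scores[:, :k]
        else:
            raise ValueError("modes_90 predictor needs an atlas or a scores matrix")
    elif predictor == "diameter":
        if diameter is None:
            raise ValueError("diameter predictor needs the diameter array")
        X = np.asarray(diameter, dtype=np.float64).reshape(-1, 1)
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    if not np.isfinite(X).all():
        raise ValueError("predictor matrix contains non-finite values")

    # standardize internally for conditioning; coefficients mapped back
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Z = (X - mu) / sd

    beta, res = _fit_logistic(Z, y, ridge=0.0)
    ridge_active = False
    if not res.success or np.abs(beta[1:]).max() > 30.0:
        beta, res = _fit_logistic(Z, y, ridge=SEPARATION_RIDGE)
        ridge_active = True
    eta = beta[0] + Z @ beta[1:]
    prob = expit(eta)
    fpr, tpr, _, auc = roc_curve(prob, y)
    auc_rank = rank_auc(prob, y)
    assert abs(auc - auc_rank) < 1e-10, f"trapezoid AUC {auc} != rank-sum AUC {auc_rank}"

    coef = beta[1:] / sd
    intercept = float(beta[0] - np.sum(beta[1:] * mu / sd))
    return RiskModelResult(
        predictor=predictor,
        coefficients=coef,
        intercept=intercept,
        probabilities=prob,
        auc=auc,
        roc_fpr=fpr,
        roc_tpr=tpr,
        n_predictors=X.shape[1],
        ridge_active=ridge_active,
        converged=bool(res.success),
        gradient_norm=float(np.linalg.norm(res.jac)),
    )


def roc_curve(probabilities: np.ndarray, labels: np.ndarray):
    """ROC points at every distinct threshold, plus (0,0) and (1,1).

    Returns ``(fpr, tpr, thresholds, auc)`` with the trapezoidal AUC.
    Both classes must be present.  The AUC is invariant to any strictly
    monotone transform of the probabilities.
    """
    prob = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC needs both classes present")
    order = np.argsort(-prob, kind="stable")
    p_sorted, y_sorted = prob[order], y[order]
    distinct = np.nonzero(np.diff(p_sorted))[0]
    cut = np.concatenate([distinct, [len(prob) - 1]])
    tp = np.cumsum(y_sorted)[cut]
    fp = np.cumsum(~y_sorted)[cut]
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    thresholds = np.concatenate([[np.inf], p_sorted[cut]])
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, thresholds, auc


def rank_auc(probabilities: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the rank-sum statistic: P(score_pos > score_neg) + 0.5 P(tie)."""
    prob = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("AUC needs both classes present")
    ranks = sps.rankdata(prob)
    u = ranks[y].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def cluster_scores(
    scores: np.ndarray,
    k: int | str = "auto",
    seed: int = 0,
    n_modes: int = 2,
    n_init: int = 10,
    k_range: tuple[int, int] = (2, 6),
) -> ClusterResult:
    """K-means on the first two mode scores (the Mode 1 x Mode 2 plane).

    ``k="auto"`` picks the silhouette-maximizing k in ``k_range``.
    ``k == n`` is permitted but reported as degenerate (silhouette
    undefined when every point is its own cluster).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    X = np.asarray(scores, dtype=np.float64)[:, :n_modes]
    n = len(X)

    def _fit(kk: int):
        km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X)
        if 2 <= kk <= n - 1:
            return km.labels_, float(silhouette_score(X, km.labels_)), False
        return km.labels_, np.nan, True

    if k == "auto":
        best = None
        for kk in range(k_range[0], min(k_range[1], n - 1) + 1):
            labels, sil, _ = _fit(kk)
            if best is None or sil > best[1]:
                best = (labels, sil, kk)
        labels, sil, kk = best
        return ClusterResult(labels, kk, sil)
    k = int(k)
    if k < 2 or k > n:
        raise ValueError(f"k must be in 2..{n}, got {k}")
    labels, sil, degenerate = _fit(k)
    return ClusterResult(labels, k, sil, degenerate=degenerate)


def group_mode_summary(
    scores: np.ndarray,
    groups: Sequence[str],
    control_label: str = "control",
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-group mean/SD of one mode's scores plus Mann-Whitney vs control.

    ``scores`` is the (n,) score vector of a single mode.  Each non-control
    group is tested against the control group; ``significant`` marks
    p < alpha (the control row has no test).
    """
    scores = np.asarray(scores, dtype=np.float64)
    groups = np.asarray(groups)
    if control_label not in groups:
        raise ValueError(f"control group {control_label!r} missing from groups")
    control = scores[groups == control_label]
    rows = []
    for g in pd.unique(groups):
        vals = scores[groups == g]
        if g == control_label:
            stat = p = np.nan
        else:
            stat, p = compare_groups(vals, control, kind="mann_whitney")
        rows.append(
            {
                "group": g,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan,
                "p_vs_control": p,
                "significant": bool(p < alpha) if np.isfinite(p) else False,
            }
        )
    return pd.DataFrame(rows)
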