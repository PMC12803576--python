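"""Outcome-association pipeline for LVAD reverse remodelling.

Classifies the myocardial response after left-ventricular-assist-device
implantation (functional: absolute LVEF increase >= 10 percentage points;
structural: relative LVEDd reduction >= 15%), stages reverse remodelling with
a configurable Utah-Inova-style rule, and provides the statistical plumbing
the analysis uses: Pearson correlation with Fisher-z confidence intervals,
ROC/AUC with a seeded percentile bootstrap, normality-gated two-group
comparison, standardized-beta multiple regression, and PCA of the metabolic
feature table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LVEF_RESPONSE_THRESHOLD",
    "LVEDD_RESPONSE_THRESHOLD",
    "DEFAULT_STAGING_RULE",
    "classify_response",
    "utah_inova_stage",
    "correlate",
    "roc_auc",
    "group_compare",
    "standardized_beta_regression",
    "pca_features",
]

#: inclusive thresholds, matching the printed ">=" definitions
LVEF_RESPONSE_THRESHOLD = 10.0  # percentage points, absolute increase
LVEDD_RESPONSE_THRESHOLD = 0.15  # relative reduction (pre - post)/pre

#: three-tier staging rule on the absolute LVEF change.  The published
#: staging criteria are not reprinted here; this default is a documented,
#: explicitly configurable stand-in ordered non-responder < partial
#: responder < responder.
DEFAULT_STAGING_RULE = {"responder": 10.0, "partial responder": 5.0, "non-responder": -np.inf}

STAGE_ORDER = ["non-responder", "partial responder", "responder"]


def classify_response(
    outcomes: pd.DataFrame,
    lvef_threshold: float = LVEF_RESPONSE_THRESHOLD,
    lvedd_threshold: float = LVEDD_RESPONSE_THRESHOLD,
) -> pd.DataFrame:
    """Endpoint labels per patient; thresholds are inclusive (>=).

    Rows with missing pre/post values get missing labels (never silently
    dropped).  ``lvedd_rel_change`` is (pre - post)/pre.
    """
    out = outcomes.copy()
    if (out["lvedd_pre"].fillna(1.0) <= 0).any():
        raise ValueError("invalid record: lvedd_pre must be positive")
    out["delta_lvef_abs"] = out["lvef_post"] - out["lvef_pre"]
    out["lvedd_rel_change"] = (out["lvedd_pre"] - out["lvedd_post"]) / out["lvedd_pre"]
    func = pd.array(out["delta_lvef_abs"] >= lvef_threshold, dtype="boolean")
    func[out["delta_lvef_abs"].isna().to_numpy()] = pd.NA
    out["functional_responder"] = func
    unload = pd.array(out["lvedd_rel_change"] >= lvedd_threshold, dtype="boolean")
    unload[out["lvedd_rel_change"].isna().to_numpy()] = pd.NA
    out["optimal_unloading"] = unload
    return out


def utah_inova_stage(
    outcomes: pd.DataFrame, staging_rule: dict[str, float] | None = None
) -> pd.Series:
    """Ordered categorical reverse-remodelling stage per patient.

    ``staging_rule`` maps stage name to the minimum absolute LVEF change;
    stages are assigned by the highest threshold met.  Swapping the rule
    changes labels only, never any metabolic readout.
    """
    rule = DEFAULT_STAGING_RULE if staging_rule is None else staging_rule
    unknown = set(rule) - set(STAGE_ORDER)
    if unknown:
        raise ValueError(f"unknown stages in rule: {sorted(unknown)}")
    d = outcomes["lvef_post"] - outcomes["lvef_pre"]
    ordered = sorted(rule.items(), key=lambda kv: -kv[1])
    labels = []
    for v in d:
        if pd.isna(v):
            labels.append(pd.NA)
            continue
        for stage, thr in ordered:
            if v >= thr:
                labels.append(stage)
                break
    return pd.Series(
        pd.Categorical(labels, categories=STAGE_ORDER, ordered=True),
        index=outcomes.index,
        name="utah_inova_stage",
    )


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int


def correlate(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson correlation with a Fisher-z confidence interval."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 finite pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0:
        lo = hi = r
    else:
        z = np.arctanh(r)
        se = 1.0 / math_sqrt(n - 3)
        zcrit = stats.norm.ppf(1 - alpha / 2)
        lo, hi = np.tanh(z - zcrit * se), np.tanh(z + zcrit * se)
    return CorrelationResult(float(r), float(lo), float(hi), float(p), n)


def math_sqrt(v):  # tiny indirection to keep numpy scalars out of dataclass fields
    return float(np.sqrt(v))


@dataclass(frozen=True)
class RocResult:
    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int


def roc_auc(score, labels, n_boot: int = 2000, seed: int = 0) -> RocResult:
    """AUC by the rank (trapezoid, tie-averaged) method with a seeded
    percentile-bootstrap 95% confidence interval."""
    from sklearn.metrics import roc_auc_score

    score = np.asarray(score, dtype=float)
    labels = np.asarray(labels).astype(bool)
    mask = np.isfinite(score)
    score, labels = score[mask], labels[mask]
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = float(roc_auc_score(labels, score))
    rng = np.random.default_rng(seed)
    boots = []
    idx = np.arange(len(score))
    for _ in range(n_boot):
        b = rng.choice(idx, size=len(idx), replace=True)
        if labels[b].all() or not labels[b].any():
            continue
        boots.append(roc_auc_score(labels[b], score[b]))
    lo, hi = (np.percentile(boots, [2.5, 97.5]) if boots else (np.nan, np.nan))
    return RocResult(auc, float(lo), float(hi), n_pos, n_neg)


@dataclass(frozen=True)
class GroupCompareResult:
    test: str  # 't' | 'mannwhitney'
    statistic: float
    p_value: float
    normal: bool


def group_compare(values, groups, alpha_normality: float = 0.05) -> GroupCompareResult:
    """Two-group comparison: two-tailed unpaired t-test when both groups pass
    a Kolmogorov-Smirnov normality check, Mann-Whitney U otherwise."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = pd.unique(groups)
    if len(names) != 2:
        raise ValueError("exactly two groups required")
    a = values[groups == names[0]]
    b = values[groups == names[1]]
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 finite values")

    def _ks_normal(v):
        if np.std(v, ddof=1) == 0:
            return False
        z = (v - v.mean()) / np.std(v, ddof=1)
        return stats.kstest(z, "norm").pvalue > alpha_normality

    normal = _ks_normal(a) and _ks_normal(b)
    if normal:
        res = stats.ttest_ind(a, b)
        return GroupCompareResult("t", float(res.statistic), float(res.pvalue), True)
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    return GroupCompareResult("mannwhitney", float(res.statistic), float(res.pvalue), False)


def standardized_beta_regression(features: pd.DataFrame, response) -> pd.DataFrame:
    """Multiple linear regression on z-scored predictors and response,
    reporting standardized beta coefficients as absolute numbers (plus their
    signed values and p-values)."""
    X = features.astype(float)
    y = np.asarray(response, dtype=float)
    keep = X.columns[X.std() > 0]
    if len(keep) == 0:
        raise ValueError("degenerate design: no varying predictors")
    Xz = (X[keep] - X[keep].mean()) / X[keep].std(ddof=1)
    if np.std(y, ddof=1) == 0:
        raise ValueError("degenerate response")
    yz = (y - y.mean()) / np.std(y, ddof=1)
    A = np.column_stack([np.ones(len(yz)), Xz.to_numpy()])
    if np.linalg.matrix_rank(A) < A.shape[1]:
        raise ValueError("design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(A, yz, rcond=None)
    resid = yz - A @ beta
    dof = len(yz) - A.shape[1]
    if dof > 0:
        sigma2 = resid @ resid / dof
        cov = sigma2 * np.linalg.inv(A.T @ A)
        se = np.sqrt(np.diag(cov))
        tvals = beta / se
        pvals = 2 * stats.t.sf(np.abs(tvals), dof)
    else:
        pvals = np.full(A.shape[1], np.nan)
    return pd.DataFrame(
        {"beta": beta[1:], "abs_beta": np.abs(beta[1:]), "p_value": pvals[1:]},
        index=keep,
    ).sort_values("abs_beta", ascending=False)


def pca_features(features: pd.DataFrame, n_components: int = 2):
    """PCA of a (z-scored) metabolic feature table; returns the score matrix
    and the explained-variance ratios."""
    from sklearn.decomposition import PCA

    X = features.select_dtypes(include=[np.number]).astype(float)
    X = X.loc[:, X.std() > 0]
    X = X.fillna(X.mean())
    Xz = (X - X.mean()) / X.std(ddof=1)
    pca = PCA(n_components=min(n_components, Xz.shape[1]), random_state=0)
    scores = pca.fit_transform(Xz.to_numpy())
    cols = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return pd.DataFrame(scores, index=features.index, columns=cols), pca.explained_variance_ratio_
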