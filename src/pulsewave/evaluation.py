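"""Diagnostic-accuracy statistics.

ROC AUC is the Mann–Whitney statistic (ties counted 1/2) with DeLong's
nonparametric variance for confidence intervals and paired AUC tests;
binomial proportions (sensitivity, specificity, predictive values) get
exact Clopper–Pearson intervals.  Also provided: the LVEDP
threshold-sweep AUC matrix, age/gender propensity matching (greedy
1:1 nearest neighbour without replacement on a logistic propensity
score), and per-subgroup ROC reports.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "RocResult", "TwoByTwo",
    "roc_auc", "delong_test", "delong_test_unpaired",
    "clopper_pearson", "two_by_two", "threshold_sweep",
    "propensity_match", "standardized_mean_difference", "subgroup_report",
]


# ---------------------------------------------------------------------------
# DeLong machinery
# ---------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")

def _delong_components(scores: np.ndarray, labels: np.ndarray):
    """AUC plus the per-subject structural components V10 (positives) and
    V01 (negatives) from DeLong, DeLong & Clarke-Pearson (1988)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise InsufficientDataError("both classes must be present")
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - r_pos) / n
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    return auc, v10, v01

def _delong_variance(v10: np.ndarray, v01: np.ndarray) -> float:
    m, n = v10.size, v01.size
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


@dataclass
class RocResult:
    auc: float
    ci95: tuple
    n_pos: int
    n_neg: int
    curve: list          # [(fpr, tpr), ...], monotone non-decreasing
    se: float = 0.0


@dataclass
class TwoByTwo:
    tp: int
    fp: int
    tn: int
    fn: int
    sens: float
    spec: float
    ppv: float
    npv: float
    sens_ci95: tuple
    spec_ci95: tuple
    ppv_ci95: tuple
    npv_ci95: tuple


def _roc_curve(scores: np.ndarray, labels: np.ndarray):
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    m = float((labels == 1).sum())
    n = float((labels == 0).sum())
    tps = np.cumsum(y == 1)
    fps = np.cumsum(y == 0)
    # collapse ties: keep the last point of each distinct score
    keep = np.r_[s[1:] != s[:-1], True]
    tpr = np.r_[0.0, tps[keep] / m]
    fpr = np.r_[0.0, fps[keep] / n]
    return list(zip(fpr.tolist(), tpr.tolist()))


def roc_auc(scores, labels, level: float = 0.95) -> RocResult:
    """Mann–Whitney AUC (ties 1/2) with a DeLong CI truncated to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    auc, v10, v01 = _delong_components(scores, labels)
    se = float(np.sqrt(_delong_variance(v10, v01)))
    z = stats.norm.ppf(0.5 + level / 2.0)
    lo, hi = max(0.0, auc - z * se), min(1.0, auc + z * se)
    return RocResult(auc=float(auc), ci95=(lo, hi),
                     n_pos=int((labels == 1).sum()), n_neg=int((labels == 0).sum()),
                     curve=_roc_curve(scores, labels), se=se)


def delong_test(scores_a, scores_b, labels) -> float:
    """Two-sided p for the paired AUC difference (same subjects)."""
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ConfigurationError("paired score vectors must have equal length")
    auc_a, v10a, v01a = _delong_components(a, labels)
    auc_b, v10b, v01b = _delong_components(b, labels)
    m, n = v10a.size, v01a.size
    diff = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(np.vstack([v10a, v10b]))
        s01 = np.cov(np.vstack([v01a, v01b]))
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = 0.0
    if var <= 0:
        return 1.0 if abs(diff) < 1e-12 else 0.0
    z = diff / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def delong_test_unpaired(res_a: RocResult, res_b: RocResult) -> float:
    """Two-sided z-test for AUCs from independent groups, DeLong SEs."""
    var = res_a.se ** 2 + res_b.se ** 2
    if var <= 0:
        return 1.0 if abs(res_a.auc - res_b.auc) < 1e-12 else 0.0
    z = (res_a.auc - res_b.auc) / np.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# binomial intervals / contingency statistics
# ---------------------------------------------------------------------------

def clopper_pearson(successes: int, n: int, level: float = 0.95) -> tuple:
    """Exact binomial (beta-quantile) interval; lo=0 at k=0, hi=1 at k=n."""
    if n <= 0:
        raise ConfigurationError("n must be positive")
    if not (0 <= successes <= n):
        raise ConfigurationError("successes must be within [0, n]")
    alpha = 1.0 - level
    k = successes
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def two_by_two(scores, labels, threshold: float, level: float = 0.95) -> TwoByTwo:
    """Contingency statistics at ``score >= threshold`` with CP intervals."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    frac = lambda a, b: a / b if b > 0 else np.nan
    ci = lambda a, b: clopper_pearson(a, b, level) if b > 0 else (np.nan, np.nan)
    return TwoByTwo(
        tp=tp, fp=fp, tn=tn, fn=fn,
        sens=frac(tp, tp + fn), spec=frac(tn, tn + fp),
        ppv=frac(tp, tp + fp), npv=frac(tn, tn + fn),
        sens_ci95=ci(tp, tp + fn), spec_ci95=ci(tn, tn + fp),
        ppv_ci95=ci(tp, tp + fp), npv_ci95=ci(tn, tn + fn))


def sensitivity_operating_threshold(scores, labels, target_sens: float = 0.82) -> float:
    """Largest threshold whose sensitivity is >= target (development-side
    choice of the binary operating point)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = np.sort(scores[labels == 1])[::-1]
    if pos.size == 0:
        raise InsufficientDataError("no positive subjects")
    k = int(np.ceil(target_sens * pos.size))
    k = min(max(k, 1), pos.size)
    return float(pos[k - 1])


# ---------------------------------------------------------------------------
# threshold sweep / matching / subgroups
# ---------------------------------------------------------------------------

def threshold_sweep(scores, lvedp, elevated_defs, nonelevated_defs) -> pd.DataFrame:
    """AUC matrix over (elevated_def, nonelevated_def) pairs.

    Cell (i, j) restricts to subjects with lvedp >= elevated_defs[i] or
    lvedp <= nonelevated_defs[j]; infeasible cells (overlapping
    definitions or an empty class) are NaN.
    """
    scores = np.asarray(scores, dtype=float)
    lvedp = np.asarray(lvedp, dtype=float)
    mat = np.full((len(elevated_defs), len(nonelevated_defs)), np.nan)
    for i, ed in enumerate(elevated_defs):
        for j, nd in enumerate(nonelevated_defs):
            if nd >= ed:
                continue
            pos = lvedp >= ed
            neg = lvedp <= nd
            if pos.sum() == 0 or neg.sum() == 0:
                continue
            sel = pos | neg
            mat[i, j] = roc_auc(scores[sel], pos[sel].astype(int)).auc
    return pd.DataFrame(mat, index=pd.Index(elevated_defs, name="elevated_def"),
                        columns=pd.Index(nonelevated_defs, name="nonelevated_def"))


def _propensity_scores(subjects: pd.DataFrame, treat: np.ndarray,
                       covariates) -> np.ndarray:
    X = pd.get_dummies(subjects[list(covariates)], drop_first=True) \
        .to_numpy(dtype=float)
    lr = LogisticRegression(max_iter=1000)
    lr.fit(X, treat.astype(int))
    return lr.predict_proba(X)[:, 1]


def propensity_match(subjects: pd.DataFrame, treat_col: str = "stratum",
                     treat_value: str = "elevated",
                     covariates=("age", "gender"), seed: int = 0,
                     caliper: float | None = None) -> pd.DataFrame:
    """1:1 greedy nearest-neighbour matching without replacement on a
    logistic propensity score; treated order randomized by ``seed``.
    Returns a DataFrame (treated_id, control_id, distance)."""
    treat = (subjects[treat_col] == treat_value).to_numpy()
    if treat.sum() == 0 or (~treat).sum() == 0:
        raise InsufficientDataError("both groups must be non-empty")
    ps = _propensity_scores(subjects, treat, covariates)
    ids = subjects.index.to_numpy()
    t_idx = np.flatnonzero(treat)
    c_idx = np.flatnonzero(~treat)
    rng = np.random.default_rng(seed)
    order = rng.permutation(t_idx)
    available = dict(zip(c_idx, ps[c_idx]))
    pairs = []
    for ti in order:
        if not available:
            break
        cand = np.array(list(available.keys()))
        d = np.abs(np.array([available[c] for c in cand]) - ps[ti])
        k = int(np.argmin(d))
        if caliper is not None and d[k] > caliper:
            continue
        pairs.append((ids[ti], ids[cand[k]], float(d[k])))
        del available[cand[k]]
    return pd.DataFrame(pairs, columns=["treated_id", "control_id", "distance"])


def standardized_mean_difference(subjects: pd.DataFrame, pairs: pd.DataFrame,
                                 covariate: str) -> float:
    """Post-match SMD of a covariate (categoricals are one-hot reduced)."""
    a = subjects.loc[pairs["treated_id"], covariate]
    b = subjects.loc[pairs["control_id"], covariate]
    if a.dtype == object or str(a.dtype) == "category":
        lev = sorted(subjects[covariate].unique())[-1]
        a = (a == lev).astype(float)
        b = (b == lev).astype(float)
    pooled = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
    if pooled == 0:
        return 0.0
    return float(abs(a.mean() - b.mean()) / pooled)


def subgroup_report(scores, labels, subjects: pd.DataFrame,
                    grouping: str) -> dict:
    """Per-level RocResult (or None when one class is absent); when
    exactly two levels are evaluable, also an unpaired DeLong p-value
    under key ``"delong_p"``."""
    if grouping not in subjects.columns:
        raise ConfigurationError(f"no column {grouping!r} in subjects")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    report: dict = {"levels": {}}
    for level_value, sub in subjects.groupby(grouping, observed=True):
        pos = subjects.index.get_indexer(sub.index)
        ls = labels[pos]
        if len(np.unique(ls)) < 2:
            report["levels"][level_value] = None
            continue
        report["levels"][level_value] = roc_auc(scores[pos], ls)
    evaluable = [r for r in report["levels"].values() if r is not None]
    if len(evaluable) == 2:
        report["delong_p"] = delong_test_unpaired(*evaluable)
    return report
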