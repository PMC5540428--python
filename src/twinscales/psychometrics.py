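"""Classical scale statistics.

Sum scores, Cronbach's alpha, polytomous Loevinger scalability coefficients
with Mokken classification, two-way consistency intraclass correlation for
test-retest reliability, winsorisation, zero-score proportions, and a
kinship-aware linear mixed model for group (sex) differences in scores.

The Loevinger coefficients use the comonotone (sorted-marginals) upper
bound for the inter-item covariance, the standard polytomous Mokken
normalisation: H_ij = Cov(X_i, X_j) / Cov_max(X_i, X_j) where Cov_max is
attained when both items are maximally dependent given their marginals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import gaussian_mixed_gls

logger = logging.getLogger(__name__)


def sum_scores(responses: pd.DataFrame, scale_items) -> pd.Series:
    cols = [f"item_{j}" for j in scale_items]
    s = responses[cols].sum(axis=1, skipna=False)
    return pd.Series(s.to_numpy(), index=pd.Index(responses["person_id"], name="person_id"),
                     name="sum_score")


def zero_score_proportion(responses: pd.DataFrame, scale_items) -> float:
    s = sum_scores(responses, scale_items).dropna()
    return float((s == 0).mean())


def cronbach_alpha(responses: pd.DataFrame, scale_items) -> float:
    """alpha = k/(k-1) * (1 - sum var(X_i) / var(sum X_i)), complete cases."""
    cols = [f"item_{j}" for j in scale_items]
    X = responses[cols].dropna().to_numpy(dtype=float)
    k = X.shape[1]
    if k < 2 or X.shape[0] < 2:
        raise ValueError("alpha needs >= 2 items and >= 2 complete respondents")
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ZeroDivisionError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1 - X.var(axis=0, ddof=1).sum() / total_var))


def _covmax(x: np.ndarray, y: np.ndarray) -> float:
    """Covariance of the comonotone coupling of the two marginals."""
    xs, ys = np.sort(x), np.sort(y)
    n = len(x)
    return float(xs @ ys / n - xs.mean() * ys.mean())


@dataclass
class ScalabilityReport:
    alpha: float
    hij: pd.DataFrame
    hi: pd.Series
    h: float
    n_hij_negative: int
    min_hi: float
    items_hi_below_030: list
    mokken_class: str


def loevinger_h(responses: pd.DataFrame, scale_items) -> ScalabilityReport:
    """Pairwise/item/scale Loevinger coefficients and Mokken classification.

    Mokken classes require all H_ij > 0; the class label (weak/medium/
    strong) follows the 0.3/0.4/0.5 cutoffs on min H_i.
    """
    cols = [f"item_{j}" for j in scale_items]
    X = responses[cols].dropna().to_numpy(dtype=float)
    items = list(scale_items)
    k = len(items)
    if k < 2:
        raise ValueError("scalability needs >= 2 items")
    keep = [i for i in range(k) if X[:, i].std() > 0]
    dropped = [items[i] for i in range(k) if i not in keep]
    if dropped:
        logger.warning("constant item(s) %s excluded from scalability", dropped)
    X = X[:, keep]
    items = [items[i] for i in keep]
    k = len(items)

    cov = np.cov(X, rowvar=False, ddof=0)
    cmax = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            cmax[i, j] = cmax[j, i] = _covmax(X[:, i], X[:, j])
    with np.errstate(divide="ignore", invalid="ignore"):
        hij = np.where(cmax != 0, cov / np.where(cmax == 0, np.nan, cmax), np.nan)
    np.fill_diagonal(hij, np.nan)
    off = ~np.eye(k, dtype=bool)
    hi = np.array([cov[i, off[i]].sum() / cmax[i, off[i]].sum() for i in range(k)])
    h = float(cov[np.triu(off)].sum() / cmax[np.triu(off)].sum())

    n_neg = int(np.nansum(hij[np.triu(off)] < 0))
    min_hi = float(np.min(hi))
    if n_neg > 0 or np.nanmin(hij) < 0 or min_hi < 0.3:
        mokken = "none"
    elif min_hi < 0.4:
        mokken = "weak"
    elif min_hi < 0.5:
        mokken = "medium"
    else:
        mokken = "strong"
    return ScalabilityReport(
        alpha=cronbach_alpha(responses, scale_items),
        hij=pd.DataFrame(hij, index=items, columns=items),
        hi=pd.Series(hi, index=items, name="Hi"),
        h=h, n_hij_negative=n_neg, min_hi=min_hi,
        items_hi_below_030=[items[i] for i in range(k) if hi[i] < 0.3],
        mokken_class=mokken)


def icc_consistency(test: np.ndarray, retest: np.ndarray,
                    alpha: float = 0.05) -> tuple[float, float, float]:
    """Two-way consistency ICC, single rater — ICC(C,1) — with F-based CI.

    From the two-way ANOVA without interaction (k = 2 occasions):
    ICC = (MS_rows - MS_err) / (MS_rows + (k-1) MS_err).  Consistency
    ignores systematic occasion shifts, so adding a constant to the retest
    leaves the estimate unchanged.
    """
    x = np.column_stack([np.asarray(test, float), np.asarray(retest, float)])
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if n < 3:
        raise ValueError("ICC needs at least 3 complete pairs")
    grand = x.mean()
    ms_rows = k * np.sum((x.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((x.mean(axis=0) - grand) ** 2) / (k - 1)
    ss_tot = np.sum((x - grand) ** 2)
    df_e = (n - 1) * (k - 1)
    ms_err = (ss_tot - (n - 1) * ms_rows - (k - 1) * ms_cols) / df_e
    if ms_err <= 0:  # perfectly consistent ratings
        return 1.0, 1.0, 1.0
    icc = (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)

    f_obs = ms_rows / ms_err
    fl = f_obs / stats.f.ppf(1 - alpha / 2, n - 1, df_e)
    fu = f_obs * stats.f.ppf(1 - alpha / 2, df_e, n - 1)
    lo = (fl - 1) / (fl + k - 1)
    hi = (fu - 1) / (fu + k - 1)
    return float(icc), float(lo), float(hi)


def winsorise(scores, z: float = 3.0) -> np.ndarray:
    """Clip to mean +/- z standard deviations (moments from the input)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("winsorisation needs >= 2 values")
    m, s = x.mean(), x.std(ddof=1)
    return np.clip(x, m - z * s, m + z * s)


def sex_difference_test(scores: pd.Series, pedigree: pd.DataFrame,
                        relatedness_blocks) -> tuple[float, float]:
    """Kinship-aware fixed-effect test of a sex difference in scores.

    Fits score ~ 1 + sex with random effect u ~ N(0, sg^2 * K) by ML and
    returns (estimate for female - male, Wald-t p-value).
    """
    df = pedigree.merge(scores.rename("score"), left_on="person_id", right_index=True).dropna(
        subset=["score"])
    if df["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")
    y = df["score"].to_numpy(float)
    X = np.column_stack([np.ones(len(df)), (df["sex"] == "F").to_numpy(float)])
    fit = gaussian_mixed_gls(y, X, df["family_id"].to_numpy(), relatedness_blocks)
    est = fit.beta[1]
    t = est / fit.se[1]
    dof = len(df) - X.shape[1]
    p = 2 * stats.t.sf(abs(t), dof)
    return float(est), float(p)
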