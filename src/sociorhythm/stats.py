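"""Statistical procedures for the badge analyses.

CES-D scoring and reliability, the one-tailed paired t-test for the
body-rhythm rise, the four headline Pearson correlations between
engagement and depression (self x self, self x partner, partner x self,
partner x partner), partner-number control curves with per-organization
bootstrap bands, tertile-group correlations, bootstrap regression
bands, and moment diagnostics.

Conventions: correlations are two-tailed; only the paired t-test for
the rise is one-tailed.  Kurtosis is reported non-excess (a normal
distribution scores 3).  No multiple-testing correction is applied by
default; ``adjust_bh`` offers Benjamini-Hochberg columns for users who
want them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

#: 1-based indices of the CES-D items phrased positively (reverse-scored).
POSITIVE_ITEMS = (4, 8, 12, 16)
N_ITEMS = 20

CORRELATION_NAMES = (
    "self_pe__self_ds",
    "self_pe__partner_ds",
    "partner_pe__self_ds",
    "partner_pe__partner_ds",
)
_CORRELATION_COLUMNS = {
    "self_pe__self_ds": ("mean_pe_self", "ds_self"),
    "self_pe__partner_ds": ("mean_pe_self", "mean_ds_partner"),
    "partner_pe__self_ds": ("mean_pe_partner", "ds_self"),
    "partner_pe__partner_ds": ("mean_pe_partner", "mean_ds_partner"),
}


# ---------------------------------------------------------------- CES-D

def score_cesd(items: pd.DataFrame,
               positive_items: Sequence[int] = POSITIVE_ITEMS) -> pd.DataFrame:
    """Score 20-item CES-D responses (0-3 each) into totals 0-60.

    ``items`` has one row per person (index = person_id) and 20 columns
    in instrument order.  The positively phrased items (1-based indices)
    are reverse-scored (3 - raw) before summing.  Rows with missing or
    out-of-range values are dropped with a warning.
    """
    if items.shape[1] != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} items, got {items.shape[1]}")
    arr = items.to_numpy(dtype=float)
    valid = np.all(np.isfinite(arr), axis=1) & np.all((arr >= 0) & (arr <= 3), axis=1)
    if not valid.all():
        logger.warning("dropping %d persons with invalid CES-D responses",
                       int((~valid).sum()))
    scored = arr.copy()
    for pos in positive_items:
        scored[:, pos - 1] = 3 - scored[:, pos - 1]
    out = pd.DataFrame(scored[valid], index=items.index[valid],
                       columns=items.columns)
    out["total"] = out.iloc[:, :N_ITEMS].sum(axis=1).astype(int)
    return out


def cronbach_alpha(item_matrix: np.ndarray | pd.DataFrame) -> float:
    """Cronbach's alpha: (k/(k-1)) * (1 - sum(item vars)/var(total)).

    Items must already be scored in a consistent direction.  Variances
    use the n-1 denominator.
    """
    x = np.asarray(item_matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 respondents and >= 2 items")
    k = x.shape[1]
    var_total = x.sum(axis=1).var(ddof=1)
    if var_total == 0:
        raise ValueError("zero total-score variance; alpha undefined")
    return float(k / (k - 1) * (1 - x.var(axis=0, ddof=1).sum() / var_total))


# ------------------------------------------------------------- t-test

def paired_t_one_tailed(during: np.ndarray, baseline: np.ndarray
                        ) -> tuple[float, int, float]:
    """One-tailed paired t (alternative: during > baseline) -> (t, df, p)."""
    during = np.asarray(during, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if during.shape != baseline.shape or during.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diff = during - baseline
    n = diff.size
    if diff.std(ddof=1) == 0:
        warnings.warn("zero variance of paired differences; p degenerate")
        if diff.mean() > 0:
            return float("inf"), n - 1, 0.0
        if diff.mean() < 0:
            return float("-inf"), n - 1, 1.0
        return 0.0, n - 1, 0.5
    res = sps.ttest_rel(during, baseline, alternative="greater")
    return float(res.statistic), n - 1, float(res.pvalue)


# --------------------------------------------------------- correlations

@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    rho: float | None = None
    rho_p: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def defined(self) -> bool:
        return np.isfinite(self.r)


def correlate(x: np.ndarray, y: np.ndarray, spearman: bool = False
              ) -> CorrelationResult:
    """Pearson r with two-tailed p; optional Spearman duplicate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 3 or x.std() == 0 or y.std() == 0:
        return CorrelationResult(r=float("nan"), p=float("nan"), n=n)
    pr = sps.pearsonr(x, y)
    res = CorrelationResult(r=float(pr.statistic), p=float(pr.pvalue), n=n)
    if spearman:
        sr = sps.spearmanr(x, y)
        res.rho = float(sr.statistic)
        res.rho_p = float(sr.pvalue)
    return res


def four_correlations(employee_features: pd.DataFrame, spearman: bool = False
                      ) -> dict[str, CorrelationResult]:
    """The four engagement x depression correlations across employees."""
    out = {}
    for name, (xcol, ycol) in _CORRELATION_COLUMNS.items():
        out[name] = correlate(employee_features[xcol].to_numpy(),
                              employee_features[ycol].to_numpy(),
                              spearman=spearman)
    return out


def group_correlations(employee_features: pd.DataFrame,
                       grouping: pd.DataFrame,
                       min_group_n: int = 4,
                       spearman: bool = False,
                       ) -> dict[str, dict[str, CorrelationResult]]:
    """The four correlations within each key-partner tertile group."""
    merged = employee_features.merge(grouping[["person_id", "group"]],
                                     on="person_id", how="inner")
    out: dict[str, dict[str, CorrelationResult]] = {}
    for group, sub in merged.groupby("group"):
        if len(sub) < min_group_n:
            out[str(group)] = {name: CorrelationResult(float("nan"), float("nan"), len(sub))
                               for name in CORRELATION_NAMES}
            continue
        out[str(group)] = four_correlations(sub, spearman=spearman)
    return out


def _rowwise_pearson(xs: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Pearson r along axis 1 of two (B, n) arrays; NaN where degenerate."""
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, (xc * yc).sum(axis=1) / denom, np.nan)


# ------------------------------------------ partner-number control

def partner_control_curves(feats_or_ego: pd.DataFrame,
                           org: Mapping[int, int],
                           n_range: Sequence[int],
                           n_resamples: int = 1000,
                           level: float = 0.95,
                           seed: int | None = None,
                           min_org_n: int = 4,
                           org_bootstrap: str = "within",
                           ) -> pd.DataFrame:
    """Correlations after restricting to each employee's top-N partners.

    For each N: employee features are recomputed over episodes with the
    employee's N most frequent partners, then the four correlations are
    taken pooled across all employees and per organization.  The
    across-organization mean carries a bootstrap confidence band:
    ``org_bootstrap='within'`` resamples employees within each
    organization and averages the per-organization coefficients (data
    rows are what is resampled); ``'orglevel'`` resamples the
    organization-level coefficients instead.
    """
    from .features import restrict_to_top_partners, employee_features

    if org_bootstrap not in ("within", "orglevel"):
        raise ValueError("org_bootstrap must be 'within' or 'orglevel'")
    rng = np.random.default_rng(seed)
    alpha = (1 - level) / 2
    rows = []
    for n_partners in n_range:
        ego = restrict_to_top_partners(feats_or_ego, n_partners)
        emp = employee_features(ego, org)
        pooled = four_correlations(emp)
        by_org = []
        for org_id, sub in emp.groupby("org_id"):
            if len(sub) < min_org_n:
                logger.warning("organization %s has n=%d < %d; skipped",
                               org_id, len(sub), min_org_n)
                continue
            by_org.append(sub)
        org_rs = {name: [] for name in CORRELATION_NAMES}
        boot_rs = {name: np.zeros((n_resamples, len(by_org))) for name in CORRELATION_NAMES}
        for k, sub in enumerate(by_org):
            cols = {c: sub[c].to_numpy(dtype=float)
                    for c in ("mean_pe_self", "mean_pe_partner",
                              "ds_self", "mean_ds_partner")}
            idx = rng.integers(0, len(sub), size=(n_resamples, len(sub)))
            for name in CORRELATION_NAMES:
                xcol, ycol = _CORRELATION_COLUMNS[name]
                org_rs[name].append(correlate(cols[xcol], cols[ycol]).r)
                if org_bootstrap == "within":
                    boot_rs[name][:, k] = _rowwise_pearson(cols[xcol][idx],
                                                           cols[ycol][idx])
        for name in CORRELATION_NAMES:
            rs = np.asarray(org_rs[name])
            rs = rs[np.isfinite(rs)]
            mean_r = float(rs.mean()) if rs.size else float("nan")
            if rs.size:
                if org_bootstrap == "orglevel":
                    picks = rng.integers(0, rs.size, size=(n_resamples, rs.size))
                    boots = rs[picks].mean(axis=1)
                else:
                    with np.errstate(invalid="ignore"):
                        boots = np.nanmean(boot_rs[name], axis=1)
                boots = boots[np.isfinite(boots)]
                ci_low, ci_high = (np.quantile(boots, [alpha, 1 - alpha])
                                   if boots.size else (np.nan, np.nan))
            else:
                ci_low = ci_high = float("nan")
            rows.append((n_partners, name, pooled[name].r, pooled[name].p,
                         pooled[name].n, mean_r, float(ci_low), float(ci_high)))
    return pd.DataFrame(rows, columns=["n_partners", "correlation", "r_pooled",
                                       "p_pooled", "n", "org_mean_r",
                                       "ci_low", "ci_high"])


# ---------------------------------------------------------- bootstrap

def bootstrap_regression_band(x: np.ndarray, y: np.ndarray,
                              n_resamples: int = 1000,
                              level: float = 0.95,
                              seed: int | None = None,
                              grid: np.ndarray | None = None,
                              max_redraws: int = 100,
                              ) -> pd.DataFrame:
    """Percentile band of least-squares fits over bootstrap resamples.

    Rows are resampled with replacement at the original size; each
    resample is fit by least squares and evaluated on ``grid`` (default:
    50 points spanning the observed x).  Degenerate resamples with zero
    x variance are redrawn (count logged).  Returns a frame with columns
    x, y_low, y_high, y_fit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired x, y with n >= 3")
    rng = np.random.default_rng(seed)
    if grid is None:
        grid = np.linspace(x.min(), x.max(), 50)
    n = x.size
    idx = rng.integers(0, n, size=(n_resamples, n))
    xs, ys = x[idx], y[idx]
    redraws = 0
    degenerate = xs.std(axis=1) == 0
    while degenerate.any() and redraws < max_redraws:
        k = int(degenerate.sum())
        idx_new = rng.integers(0, n, size=(k, n))
        xs[degenerate], ys[degenerate] = x[idx_new], y[idx_new]
        redraws += k
        degenerate = xs.std(axis=1) == 0
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    xm = xs.mean(axis=1, keepdims=True)
    ym = ys.mean(axis=1, keepdims=True)
    sxx = ((xs - xm) ** 2).sum(axis=1)
    sxy = ((xs - xm) * (ys - ym)).sum(axis=1)
    slope = sxy / sxx
    intercept = ym[:, 0] - slope * xm[:, 0]
    pred = intercept[:, None] + slope[:, None] * grid[None, :]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(pred, [alpha, 1 - alpha], axis=0)
    fit = np.polyfit(x, y, 1)
    return pd.DataFrame({"x": grid, "y_low": lo, "y_high": hi,
                         "y_fit": fit[1] + fit[0] * grid})


# -------------------------------------------------------- diagnostics

def distribution_report(values: np.ndarray) -> dict[str, float]:
    """Moments of a distribution; kurtosis is non-excess (normal = 3)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 4:
        raise ValueError("need n >= 4 for moment diagnostics")
    return {
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)),
        "median": float(np.median(v)),
        "skewness": float(sps.skew(v)),
        "kurtosis": float(sps.kurtosis(v, fisher=False)),
    }


def adjust_bh(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional output column)."""
    from statsmodels.stats.multitest import multipletests
    return multipletests(list(pvalues), method="fdr_bh")[1]
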