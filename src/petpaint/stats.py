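"""Robustness analytics: relative difference, inter-setting CV, ICC, rank tests.

The analysis design is a 3 (lesion) × 8 (imaging setting) × 2 (discretization)
grid of 46-index feature vectors:

* **Relative difference** of each index against an arbitrary reference
  setting (default D), in percent.
* **Inter-setting CV** per (index, lesion, discretization): sample standard
  deviation over mean across the eight settings, ×100; categories low (<10%),
  moderate (10–25%), high (>25%). The full design yields 46 × 3 × 2 = 276 CVs.
* **ICC**, two-way mixed-effects, absolute agreement, single measurement:
  lesions are rows (targets, n), settings are columns (raters, k);
  ICC = (MS_R − MS_E) / (MS_R + (k−1) MS_E + (k/n)(MS_C − MS_E)). Categories
  excellent (>0.9), good (0.75–0.9], moderate (0.5–0.75], poor (≤0.5).
* **Wilcoxon rank-sum** between lesion pairs over the eight per-setting
  values, exact enumeration with mid-rank ties for small samples, with
  Benjamini–Hochberg FDR correction across each discretization's family.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .registry import FEATURE_NAMES

CV_LOW, CV_MODERATE = 10.0, 25.0
ICC_EXCELLENT, ICC_GOOD, ICC_MODERATE = 0.9, 0.75, 0.5


class StatsError(ValueError):
    pass


def relative_difference(x_i: float, x_ref: float) -> float:
    """(x_i − x_ref) / x_ref × 100, in percent; NaN (with warning) if x_ref = 0."""
    if x_ref == 0:
        warnings.warn("relative difference undefined for zero reference; "
                      "reported as NaN", stacklevel=2)
        return float("nan")
    return (x_i - x_ref) / x_ref * 100.0


def cv_category(cv_pct: float) -> str:
    if np.isnan(cv_pct):
        return "undefined"
    if cv_pct < CV_LOW:
        return "low"
    if cv_pct <= CV_MODERATE:
        return "moderate"
    return "high"


def inter_setting_cv(values: np.ndarray, ddof: int = 1) -> tuple[float, str]:
    """Sample STD over mean × 100 across imaging settings, with its category."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    if mean == 0:
        warnings.warn("zero mean: CV undefined, reported as NaN", stacklevel=2)
        return float("nan"), "undefined"
    cv = float(np.std(v, ddof=ddof) / abs(mean) * 100.0)
    return cv, cv_category(cv)


def icc_category(icc_value: float) -> str:
    if np.isnan(icc_value):
        return "undefined"
    if icc_value > ICC_EXCELLENT:
        return "excellent"
    if icc_value > ICC_GOOD:
        return "good"
    if icc_value > ICC_MODERATE:
        return "moderate"
    return "poor"


def icc(values: np.ndarray) -> tuple[float, str]:
    """Two-way mixed, absolute-agreement, single-measurement ICC.

    ``values`` is an (n targets × k raters) matrix — here lesions × settings.
    Mean squares come from the two-way ANOVA decomposition without
    replication; negative ICCs are reported as-is.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise StatsError("ICC needs an n>=2 by k>=2 matrix")
    n, k = m.shape
    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if abs(denom) < 1e-300 or ss_total == 0:
        warnings.warn("degenerate ICC (zero total variance); reported as NaN",
                      stacklevel=2)
        return float("nan"), "undefined"
    value = float((ms_r - ms_e) / denom)
    return value, icc_category(value)


def _rank_sum_with_ties(combined: np.ndarray, idx_a: tuple[int, ...]) -> float:
    ranks = sps.rankdata(combined)  # mid-ranks
    return float(ranks[list(idx_a)].sum())


def wilcoxon_rank_sum(sample_a, sample_b, method: str = "auto") -> float:
    """Two-sided rank-sum (Mann–Whitney) p-value between two independent samples.

    For groups of up to 10 observations the exact permutation distribution of
    the rank sum is enumerated (mid-ranks for ties); larger samples use the
    normal approximation with tie correction.
    """
    a = np.asarray(sample_a, dtype=float).ravel()
    b = np.asarray(sample_b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise StatsError("both samples must be non-empty")
    exact = method == "exact" or (method == "auto" and max(a.size, b.size) <= 10)
    if not exact:
        return float(sps.ranksums(a, b).pvalue)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    observed = float(ranks[: a.size].sum())
    expected = a.size * (combined.size + 1) / 2.0
    dev = abs(observed - expected)
    count = 0
    total = 0
    for idx in itertools.combinations(range(combined.size), a.size):
        w = float(ranks[list(idx)].sum())
        if abs(w - expected) >= dev - 1e-12:
            count += 1
        total += 1
    return count / total


def wilcoxon_signed_rank(sample_a, sample_b) -> float:
    """Paired signed-rank alternative (two-sided), via scipy."""
    return float(sps.wilcoxon(sample_a, sample_b).pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# --- report assembly ----------------------------------------------------------

@dataclass
class RobustnessReport:
    """All robustness tables for one full experiment."""

    rd_table: pd.DataFrame  # rows: feature; cols: (lesion, discretization, setting)
    cv_table: pd.DataFrame  # rows: feature; cols: (lesion, discretization); % values
    cv_categories: pd.DataFrame
    icc_table: pd.DataFrame  # rows: feature; cols: discretization
    icc_categories: pd.DataFrame
    pvalue_table: pd.DataFrame  # tidy: feature, pair, discretization, p, p_adj
    reference_setting: str = "D"

    def cv_cell_count(self) -> int:
        return int(self.cv_table.notna().size)


def feature_table_to_report(table: pd.DataFrame, reference_setting: str = "D",
                            alpha: float = 0.05) -> RobustnessReport:
    """Build the robustness report from a tidy feature table.

    ``table`` needs columns ``lesion``, ``setting``, ``discretization`` plus
    the 46 feature columns (one row per design cell, native resampling).
    Missing design cells are tolerated: affected entries become NaN.
    """
    features = [c for c in table.columns if c in FEATURE_NAMES]
    lesions = sorted(table["lesion"].unique())
    settings = sorted(table["setting"].unique())
    discs = sorted(table["discretization"].unique())

    def cell(lesion, setting, disc):
        rows = table[(table.lesion == lesion) & (table.setting == setting)
                     & (table.discretization == disc)]
        return rows.iloc[0] if len(rows) else None

    # RD: per feature × (lesion, disc, non-reference setting)
    rd_cols, rd_data = [], []
    cv_cols, cv_data, cv_cat = [], [], []
    for lesion in lesions:
        for disc in discs:
            series = {s: cell(lesion, s, disc) for s in settings}
            ref = series.get(reference_setting)
            for s in settings:
                if s == reference_setting:
                    continue
                rd_cols.append((lesion, disc, s))
                row = series[s]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rd_data.append([
                        relative_difference(row[f], ref[f])
                        if row is not None and ref is not None else np.nan
                        for f in features
                    ])
            cv_cols.append((lesion, disc))
            vals_by_feature = []
            cats = []
            for f in features:
                vals = np.array([series[s][f] for s in settings if series[s] is not None])
                if len(vals) < 2:
                    vals_by_feature.append(np.nan)
                    cats.append("undefined")
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    cv, cat = inter_setting_cv(vals)
                vals_by_feature.append(cv)
                cats.append(cat)
            cv_data.append(vals_by_feature)
            cv_cat.append(cats)

    rd_names = ["lesion", "discretization", "setting"]
    if rd_cols:
        rd_table = pd.DataFrame(
            np.array(rd_data).T, index=features,
            columns=pd.MultiIndex.from_tuples(rd_cols, names=rd_names))
    else:  # degenerate design: only the reference setting present
        rd_table = pd.DataFrame(
            index=features,
            columns=pd.MultiIndex.from_arrays([[], [], []], names=rd_names),
            dtype=float)
    cv_table = pd.DataFrame(np.array(cv_data).T, index=features,
                            columns=pd.MultiIndex.from_tuples(
                                cv_cols, names=["lesion", "discretization"]))
    cv_categories = pd.DataFrame(np.array(cv_cat).T, index=features,
                                 columns=cv_table.columns)

    # ICC: per feature × discretization over the lesions × settings matrix
    icc_vals, icc_cats = {}, {}
    for disc in discs:
        vcol, ccol = [], []
        for f in features:
            m = np.array([[cell(lesion, s, disc)[f] if cell(lesion, s, disc) is not None
                           else np.nan for s in settings] for lesion in lesions])
            if np.any(np.isnan(m)) or m.shape[0] < 2:
                vcol.append(np.nan)
                ccol.append("undefined")
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                v, c = icc(m)
            vcol.append(v)
            ccol.append(c)
        icc_vals[disc] = vcol
        icc_cats[disc] = ccol
    icc_table = pd.DataFrame(icc_vals, index=features)
    icc_categories = pd.DataFrame(icc_cats, index=features)

    # Wilcoxon rank-sum per lesion pair × feature, BH-adjusted per discretization
    recs = []
    for disc in discs:
        pvals, keys = [], []
        for la, lb in itertools.combinations(lesions, 2):
            for f in features:
                va = np.array([cell(la, s, disc)[f] for s in settings
                               if cell(la, s, disc) is not None])
                vb = np.array([cell(lb, s, disc)[f] for s in settings
                               if cell(lb, s, disc) is not None])
                if len(va) == 0 or len(vb) == 0 or np.any(np.isnan(va)) or np.any(np.isnan(vb)):
                    continue
                pvals.append(wilcoxon_rank_sum(va, vb))
                keys.append((f, f"{la}-{lb}"))
        adj = bh_fdr(pvals) if pvals else np.array([])
        for (f, pair), p, pa in zip(keys, pvals, adj):
            recs.append(dict(feature=f, pair=pair, discretization=disc,
                             p=p, p_adj=pa, significant=pa < alpha))
    pvalue_table = pd.DataFrame(recs)

    return RobustnessReport(rd_table=rd_table, cv_table=cv_table,
                            cv_categories=cv_categories, icc_table=icc_table,
                            icc_categories=icc_categories, pvalue_table=pvalue_table,
                            reference_setting=reference_setting)
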