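"""Statistical battery: ANOVAs on gene age, bootstrapped group means, bin summaries.

Age enters every ANOVA as a single continuous covariate (df = 1): genes are
dated on an integer depth scale and the response is regressed on that scale
directly. The two-way analysis uses a sequential (type-I) decomposition —
age fitted first, then the categorical factor (functional category or
duplication status), main effects only. Group means are compared with a
percentile bootstrap resampled at the smallest group's size, so differences
in group sizes cannot masquerade as differences in means.

ANOVAs run on raw counts; the log10 transform is applied only in the
plot-oriented bin summaries.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .binning import AgeBinning

logger = logging.getLogger(__name__)

ANOVA_COLUMNS = ["df", "sum_sq", "mean_sq", "F", "PR(>F)"]


@dataclass
class AnovaTable:
    """Factor rows plus a residual row; ``note`` flags degenerate cases."""

    table: pd.DataFrame  # index: factor names + "Residual"; columns ANOVA_COLUMNS
    note: str | None = None

    @property
    def p(self) -> pd.Series:
        return self.table["PR(>F)"].drop("Residual")

    @property
    def F(self) -> pd.Series:
        return self.table["F"].drop("Residual")


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains NaN")
    return arr


def anova_one_way(response: Sequence[float], age: Sequence[float]) -> AnovaTable:
    """One-way ANOVA of a pleiotropy score on continuous gene age.

    Equivalent to simple linear regression: the age row carries the
    regression sum of squares on 1 df; F is tested against F(1, n-2).
    """
    y = _as_float_array(response, "response")
    x = _as_float_array(age, "age")
    if y.size != x.size:
        raise ValueError("response and age differ in length")
    if y.size < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size < 2:
        raise ValueError("age must take at least 2 distinct values")

    note = None
    if np.ptp(y) == 0:
        note = "constant response: F undefined"
        logger.warning(note)
        table = pd.DataFrame(
            [[1, 0.0, 0.0, np.nan, np.nan],
             [y.size - 2, 0.0, 0.0, np.nan, np.nan]],
            index=["Age", "Residual"], columns=ANOVA_COLUMNS,
        )
        return AnovaTable(table=table, note=note)

    fit = sm.OLS(y, sm.add_constant(x)).fit()
    ss_age = float(fit.ess)
    ss_res = float(fit.ssr)
    df_res = y.size - 2
    ms_age = ss_age
    ms_res = ss_res / df_res
    # residual SS at rounding-noise level relative to the total is a perfect fit
    if ss_res <= 1e-12 * max(ss_age + ss_res, 1.0):
        note = "perfect fit: residual SS is zero"
        logger.warning(note)
        f_stat, p = np.inf, 0.0
    else:
        f_stat = ms_age / ms_res
        p = float(sps.f.sf(f_stat, 1, df_res))
    table = pd.DataFrame(
        [[1, ss_age, ms_age, f_stat, p],
         [df_res, ss_res, ms_res, np.nan, np.nan]],
        index=["Age", "Residual"], columns=ANOVA_COLUMNS,
    )
    return AnovaTable(table=table, note=note)


def _dummy_matrix(factor: np.ndarray) -> tuple[np.ndarray, list[str]]:
    """Treatment-coded dummies, first level (sorted order) as reference."""
    levels = sorted(pd.unique(factor).tolist())
    cols = [(factor == lev).astype(float) for lev in levels[1:]]
    mat = np.column_stack(cols) if cols else np.empty((factor.size, 0))
    return mat, levels


def anova_two_way_sequential(
    response: Sequence[float],
    age: Sequence[float],
    factor: Sequence,
    factor_name: str = "Factor",
) -> AnovaTable:
    """Sequential (type-I) two-way ANOVA: age first, then a categorical factor.

    Main effects only. Sums of squares come from the drop in residual SS
    across the nested fits intercept → +age → +factor; the residual row is
    from the full main-effects fit.
    """
    y = _as_float_array(response, "response")
    x = _as_float_array(age, "age")
    fac = np.asarray(factor)
    if not (y.size == x.size == fac.size):
        raise ValueError("response, age and factor differ in length")
    dummies, levels = _dummy_matrix(fac)
    if len(levels) < 2:
        raise ValueError("factor needs at least 2 levels")

    intercept = np.ones((y.size, 1))
    design_age = np.column_stack([intercept, x])
    design_full = np.column_stack([design_age, dummies])
    rank = np.linalg.matrix_rank(design_full)
    if rank < design_full.shape[1]:
        # identify an aliased factor level by dropping dummy columns
        for j, lev in enumerate(levels[1:]):
            reduced = np.delete(design_full, 2 + j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(f"rank-deficient design: factor level {lev!r} is aliased")
        raise ValueError("rank-deficient design")

    ssr0 = float(np.sum((y - y.mean()) ** 2))
    fit_age = sm.OLS(y, design_age).fit()
    fit_full = sm.OLS(y, design_full).fit()
    ss_age = ssr0 - float(fit_age.ssr)
    ss_factor = float(fit_age.ssr) - float(fit_full.ssr)
    ss_res = float(fit_full.ssr)
    df_factor = len(levels) - 1
    df_res = y.size - design_full.shape[1]
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = ss_res / df_res
    rows = []
    for name, ss, df in [("Age", ss_age, 1), (factor_name, ss_factor, df_factor)]:
        ms = ss / df
        if ms_res == 0.0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = ms / ms_res
            p = float(sps.f.sf(f_stat, df, df_res))
        rows.append([df, ss, ms, f_stat, p])
    rows.append([df_res, ss_res, ms_res, np.nan, np.nan])
    table = pd.DataFrame(rows, index=["Age", factor_name, "Residual"], columns=ANOVA_COLUMNS)
    note = "perfect fit: residual SS is zero" if ms_res == 0.0 else None
    if note:
        logger.warning(note)
    return AnovaTable(table=table, note=note)


@dataclass
class BootstrapCi:
    group: str
    mean: float
    ci_low: float
    ci_high: float
    resample_size: int
    n_resamples: int
    seed: int | None
    degenerate: bool = False


def bootstrap_group_means(
    groups: Mapping[str, Sequence[float]],
    B: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[list[BootstrapCi], pd.DataFrame]:
    """Percentile-bootstrap means with CIs, resampled at the smallest group size.

    Each of ``B`` resamples draws ``m = min group size`` observations with
    replacement from a group; the CI is the percentile interval of the ``B``
    resample means. Returns the per-group results and a pairwise
    CI-disjointness table.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    for g, a in arrays.items():
        if a.size == 0:
            raise ValueError(f"group {g!r} is empty")
    if B < 100:
        warnings.warn(f"B={B} resamples is very small; CIs will be unstable", stacklevel=2)
    m = min(a.size for a in arrays.values())
    if m == 1:
        logger.warning("smallest group has a single observation; CIs are degenerate")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    results: list[BootstrapCi] = []
    for g in sorted(arrays):
        a = arrays[g]
        idx = rng.integers(0, a.size, size=(B, m))
        means = a[idx].mean(axis=1)
        lo, hi = np.quantile(means, [alpha, 1.0 - alpha])
        results.append(BootstrapCi(
            group=g, mean=float(means.mean()), ci_low=float(lo), ci_high=float(hi),
            resample_size=m, n_resamples=B, seed=seed, degenerate=(m == 1),
        ))
    pairs = []
    for i, r1 in enumerate(results):
        for r2 in results[i + 1:]:
            disjoint = r1.ci_high < r2.ci_low or r2.ci_high < r1.ci_low
            pairs.append((r1.group, r2.group, disjoint))
    disjointness = pd.DataFrame(pairs, columns=["group_a", "group_b", "disjoint"])
    return results, disjointness


def bootstrap_table(results: list[BootstrapCi]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.group, r.mean, r.ci_low, r.ci_high, r.resample_size, r.n_resamples) for r in results],
        columns=["group", "mean", "ci_low", "ci_high", "resample_size", "n_resamples"],
    )


def summarize_bins(
    scores: Mapping[str, float | int | None],
    binning: AgeBinning,
    score_name: str = "bp_count",
) -> pd.DataFrame:
    """Per-bin summary feeding the violin plots.

    Genes with missing or zero scores are excluded from the log10 summaries
    (log10 of 0 is undefined; missing means no data) but remain counted in
    ``n_total``. Bins with no plottable gene are omitted with a log entry.
    """
    rows = []
    for b in binning.bins:
        genes = [g for g, i in binning.gene_to_bin.items() if i == b.index]
        raw = [scores[g] for g in genes if g in scores and scores[g] is not None]
        plot = np.array([v for v in raw if v > 0], dtype=float)
        if plot.size == 0:
            logger.warning("bin %d (%s) has no positive %s; omitted from plot summary",
                           b.index, b.label, score_name)
            continue
        logv = np.log10(plot)
        rows.append({
            "bin_index": b.index,
            "bin_label": b.label,
            "n_total": len(genes),
            "n_plot": int(plot.size),
            "mean_raw": float(np.mean(raw)) if raw else np.nan,
            "median_raw": float(np.median(raw)) if raw else np.nan,
            "mean_log10": float(logv.mean()),
            "median_log10": float(np.median(logv)),
        })
    return pd.DataFrame(rows, columns=[
        "bin_index", "bin_label", "n_total", "n_plot",
        "mean_raw", "median_raw", "mean_log10", "median_log10",
    ])
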