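"""Profiling statistics: log + Pareto scaling, PCA, group comparisons and
top-N ranking.

Transform defaults mirror common metabolomics-platform behavior: missing
values and zeros are imputed as half the compound's minimum positive
value, logs are base 10, and Pareto scaling divides centered columns by
the square root of the unbiased standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .msio import PeakTable, warn_and_log

__all__ = [
    "ScaledMatrix",
    "log_pareto",
    "pca_scores",
    "group_compare",
    "top_changed",
]


@dataclass
class ScaledMatrix:
    """Log + Pareto scaled matrix with the parameters to invert it."""

    values: pd.DataFrame
    log_means: pd.Series
    log_sds: pd.Series
    log_base: float = 10.0

    def inverse_logged(self) -> pd.DataFrame:
        """Recover the imputed logged matrix from the scaled one."""
        return self.values * np.sqrt(self.log_sds) + self.log_means


def _impute_half_min(df: pd.DataFrame) -> pd.DataFrame:
    """Replace NaN/0 with half the column's minimum positive value."""
    out = df.replace(0, np.nan).copy()
    for col in out.columns:
        vals = out[col]
        if vals.isna().all():
            continue
        fill = vals[vals > 0].min() / 2.0
        out[col] = vals.fillna(fill)
    return out


def log_pareto(table: PeakTable | pd.DataFrame,
               log_base: float = 10.0) -> ScaledMatrix:
    """Impute, log-transform and Pareto scale a peak table.

    Zeros and missing values are imputed as half the compound's minimum
    positive value; compounds with no positive value at all are dropped
    with a warning; constant compounds scale to all-zero columns.
    """
    df = table.areas if isinstance(table, PeakTable) else table
    empty = [c for c in df.columns
             if df[c].replace(0, np.nan).isna().all()]
    if empty:
        warn_and_log(f"compounds with no positive values dropped: {empty}")
        df = df.drop(columns=empty)
    if df.shape[1] == 0:
        raise ValueError("no compounds left after dropping empty columns")
    imputed = _impute_half_min(df)
    logged = np.log(imputed) / np.log(log_base)
    means = logged.mean(axis=0)
    sds = logged.std(axis=0, ddof=1)
    constant = sds[sds == 0].index.tolist()
    if constant:
        warn_and_log(f"constant compounds scale to zero columns: {constant}")
    scaled = logged.sub(means, axis=1)
    nonzero = sds > 0
    scaled.loc[:, nonzero] = scaled.loc[:, nonzero].div(
        np.sqrt(sds[nonzero]), axis=1
    )
    scaled.loc[:, ~nonzero] = 0.0
    return ScaledMatrix(values=scaled, log_means=means, log_sds=sds,
                        log_base=log_base)


def pca_scores(
    m: ScaledMatrix | pd.DataFrame, k: int
) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA via SVD of the column-centered matrix.

    Returns (scores, loadings, explained-variance fractions). The sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    df = m.values if isinstance(m, ScaledMatrix) else m
    n, p = df.shape
    if k > min(n - 1, p) or k < 1:
        raise ValueError(f"k={k} out of range for a {n}x{p} matrix")
    x = df.to_numpy(dtype=float)
    x = x - x.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    for comp in range(k):
        pivot = np.argmax(np.abs(vt[comp]))
        if vt[comp, pivot] < 0:
            vt[comp] *= -1
            u[:, comp] *= -1
    scores = u[:, :k] * s[:k]
    evr = (s ** 2) / float(np.sum(s ** 2))
    return (
        pd.DataFrame(scores, index=df.index,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        pd.DataFrame(vt[:k].T, index=df.columns,
                     columns=[f"PC{i + 1}" for i in range(k)]),
        evr[:k],
    )


def group_compare(
    table: PeakTable | pd.DataFrame,
    labels: pd.Series | dict,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Two-group Welch test per compound with BH correction.

    The test runs on logged values (zeros/missing excluded); the log2
    fold change is computed on unlogged group means. Compounds with fewer
    than two values in either group are skipped and flagged.
    """
    df = table.areas if isinstance(table, PeakTable) else table
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, found {groups}")
    ga = labels.index[labels == groups[0]]
    gb = labels.index[labels == groups[1]]
    rows = []
    for cid in df.columns:
        a = df.loc[ga, cid].replace(0, np.nan).dropna()
        b = df.loc[gb, cid].replace(0, np.nan).dropna()
        if len(a) < 2 or len(b) < 2:
            rows.append({"compound_id": cid, "log2fc": np.nan,
                         "p": np.nan, "tested": False})
            continue
        la = np.log(a.to_numpy()) / np.log(log_base)
        lb = np.log(b.to_numpy()) / np.log(log_base)
        stat = sps.ttest_ind(la, lb, equal_var=False)
        log2fc = float(np.log2(a.mean() / b.mean()))
        rows.append({"compound_id": cid, "log2fc": log2fc,
                     "p": float(stat.pvalue), "tested": True})
    out = pd.DataFrame(rows).set_index("compound_id")
    skipped = out.index[~out["tested"]].tolist()
    if skipped:
        warn_and_log(f"compounds skipped in group comparison: {skipped}")
    out["q"] = np.nan
    tested = out["tested"]
    if tested.any():
        out.loc[tested, "q"] = multipletests(
            out.loc[tested, "p"], method="fdr_bh"
        )[1]
    out.attrs["groups"] = groups
    return out


def _anova_p(df: pd.DataFrame, labels: pd.Series, cid: str,
             log_base: float) -> tuple[float, float, bool]:
    arrays = []
    means = []
    for g in sorted(labels.unique()):
        vals = df.loc[labels.index[labels == g], cid]
        vals = vals.replace(0, np.nan).dropna()
        if len(vals) < 2:
            return np.nan, np.nan, False
        arrays.append(np.log(vals.to_numpy()) / np.log(log_base))
        means.append(vals.mean())
    p = float(sps.f_oneway(*arrays).pvalue)
    spread = float(np.log2(max(means) / min(means)))
    return p, spread, True


def top_changed(
    table: PeakTable | pd.DataFrame,
    labels: pd.Series | dict,
    n: int = 25,
    log_base: float = 10.0,
) -> pd.DataFrame:
    """Rank compounds by group difference; top-n returned.

    Two groups: Welch p from :func:`group_compare`; more groups: one-way
    ANOVA on logged values, with the log2 max/min group-mean spread as
    the effect size. Ties break by |log2fc| descending, then compound id.
    """
    df = table.areas if isinstance(table, PeakTable) else table
    labels = pd.Series(labels)
    groups = sorted(labels.unique())
    if len(groups) == 2:
        res = group_compare(table, labels, log_base=log_base)
    else:
        rows = []
        for cid in df.columns:
            p, fc, tested = _anova_p(df, labels, cid, log_base)
            rows.append({"compound_id": cid, "log2fc": fc, "p": p,
                         "tested": tested})
        res = pd.DataFrame(rows).set_index("compound_id")
        tested = res["tested"]
        res["q"] = np.nan
        if tested.any():
            res.loc[tested, "q"] = multipletests(
                res.loc[tested, "p"], method="fdr_bh"
            )[1]
    res = res[res["tested"]].copy()
    res["_absfc"] = -res["log2fc"].abs()
    res = res.sort_values(["p", "_absfc", "compound_id"],
                          kind="mergesort").drop(columns="_absfc")
    res["rank"] = np.arange(1, len(res) + 1)
    return res.head(n)
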