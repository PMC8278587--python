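"""Descriptive cohort statistics and IHC associations.

Group comparisons of cohort characteristics use Pearson's chi-square for
categorical variables (no continuity correction; subjects with a missing
level are excluded before testing) and one-way ANOVA for continuous ones.
Immunohistochemistry readouts — CD45 H-score (0-300) as an immune marker and
Ki67 percent-positive as a proliferation marker — are compared across groups
by Wilcoxon rank-sum (average ranks, normal approximation with tie
correction) and related to per-sample mutational burden (classical AAF
filtering + prioritization) by Spearman correlation.

The module also carries the published cohort's printed characteristic
tables (control / ER- / ER+ columns) for reference analyses.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prioritize import prioritize
from .qc import FILTER_STRATEGIES, apply_aaf_filter, filter_technical

__all__ = [
    "TABLE1_HISTOLOGY",
    "TABLE1_ATROPHY",
    "TABLE1_AGE",
    "pearson_chi_square",
    "one_way_anova",
    "sample_mutational_burden",
    "ihc_associations",
]

_T1_COLS = ["control", "ER_neg", "ER_pos"]

#: published cohort characteristics: histologic impression by group
TABLE1_HISTOLOGY = pd.DataFrame(
    [[25, 14, 19], [16, 19, 14], [1, 3, 9]],
    index=["non_proliferative", "proliferative_no_atypia", "atypical_hyperplasia"],
    columns=_T1_COLS,
)

#: published cohort characteristics: lobular atrophy by group (missing excluded)
TABLE1_ATROPHY = pd.DataFrame(
    [[9, 13, 6], [16, 13, 23], [15, 7, 10]],
    index=["none", "partial", "complete"],
    columns=_T1_COLS,
)

#: published cohort characteristics: age category at biopsy by group
TABLE1_AGE = pd.DataFrame(
    [[11, 11, 7], [19, 14, 16], [12, 11, 19]],
    index=["<45", "45-55", ">55"],
    columns=_T1_COLS,
)


def pearson_chi_square(table: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    Statistic sum (O-E)^2/E with E = row*col/total, df (r-1)(c-1), no
    continuity correction.  Zero rows/columns are an error; drop
    missing-category rows before calling.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or np.any(O < 0):
        raise ValueError("table must be a 2-D array of non-negative counts")
    if np.any(O.sum(axis=0) == 0) or np.any(O.sum(axis=1) == 0):
        raise ValueError("table has an all-zero row or column")
    stat, p, df, _ = stats.chi2_contingency(O, correction=False)
    return float(stat), int(df), float(p)


def one_way_anova(
    values: Sequence[float], groups: Sequence
) -> tuple[float, int, int, float]:
    """Classic one-way ANOVA F test; returns (F, df1, df2, p)."""
    v = np.asarray(values, dtype=float)
    g = np.asarray(groups)
    ok = ~pd.isna(v) & ~pd.isna(g)
    v, g = v[ok], g[ok]
    levels = pd.unique(g)
    arrays = [v[g == lev] for lev in levels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups each with >= 2 observations")
    F, p = stats.f_oneway(*arrays)
    df1 = len(arrays) - 1
    df2 = len(v) - len(arrays)
    return float(F), df1, df2, float(p)


def sample_mutational_burden(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    strategy: str = "classical",
    prioritized: bool = True,
) -> pd.Series:
    """Per-sample count of variants surviving a filter strategy.

    Applies the named AAF strategy to technically clean calls and, by
    default, the prioritization rules (population-common, control-common and
    low-impact sites removed, using the cohort's control samples).  Samples
    without surviving calls count 0.
    """
    if strategy not in FILTER_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    clean = apply_aaf_filter(filter_technical(variants), strategy)
    if prioritized:
        controls = samples.loc[samples["group"] == "control", "sample_id"]
        clean, _ = prioritize(clean, list(controls))
    counts = clean.groupby("sample_id").size()
    return counts.reindex(samples["sample_id"], fill_value=0).rename("burden")


def ihc_associations(
    samples: pd.DataFrame,
    burdens: pd.Series,
    marker: str = "cd45_hscore",
) -> pd.DataFrame:
    """Wilcoxon and Spearman report for an IHC marker.

    Rows: ``wilcoxon_cases_vs_controls`` (marker compared between pooled
    cases and controls; rank-sum with average ranks, asymptotic normal with
    tie correction) and ``spearman_burden_<scope>`` (marker vs mutational
    burden overall and within each group).  Constant marker or burden makes
    the corresponding value missing.
    """
    df = samples[["sample_id", "group", marker]].copy()
    df["burden"] = burdens.reindex(df["sample_id"]).to_numpy()
    df = df.dropna(subset=[marker])
    rows = []
    cases = df.loc[df["group"] != "control", marker].to_numpy(dtype=float)
    controls = df.loc[df["group"] == "control", marker].to_numpy(dtype=float)
    if len(cases) >= 3 and len(controls) >= 3:
        pooled = np.concatenate([cases, controls])
        if np.all(pooled == pooled[0]):
            w_p = np.nan
        else:
            w_p = float(
                stats.mannwhitneyu(cases, controls, alternative="two-sided",
                                   method="asymptotic", use_continuity=False).pvalue
            )
    else:
        w_p = np.nan
    rows.append({"analysis": "wilcoxon_cases_vs_controls", "n": len(df),
                 "estimate": np.nan, "p_value": w_p})

    def _spearman(sub: pd.DataFrame) -> tuple[float, float]:
        if len(sub) < 3:
            return np.nan, np.nan
        if sub[marker].nunique() < 2 or sub["burden"].nunique() < 2:
            return np.nan, np.nan
        r, p = stats.spearmanr(sub[marker], sub["burden"])
        return float(r), float(p)

    r, p = _spearman(df)
    rows.append({"analysis": "spearman_burden_overall", "n": len(df),
                 "estimate": r, "p_value": p})
    for grp, sub in df.groupby("group", observed=True):
        r, p = _spearman(sub)
        rows.append({"analysis": f"spearman_burden_{grp}", "n": len(sub),
                     "estimate": r, "p_value": p})
    return pd.DataFrame(rows)
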