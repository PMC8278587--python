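"""Consensus counting across the 12 combinations and label-permutation
empirical significance.

Two global statistics summarize the 12-way association table:

* S1 — the number of genes nominally significant (p < 0.05) in at least 4
  of the 12 filter x method combinations (two-sided permutation test);
* S2 — the number of genes with p < 0.05 and odds ratio < 1 (protective,
  i.e. more mutation in controls) under the FDR-weighted logistic
  regression with classical filtering (one-sided, enrichment).

The permutation scheme shuffles the assignment of genomic profiles to
subjects while each subject keeps their own (group label, covariates) tuple,
so the covariate/group relationship is preserved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    METHODS,
    _contrast_samples,
    build_covariates,
    compute_weights,
    logistic_burden_test,
    run_all_combinations,
)
from .qc import FILTER_STRATEGIES, apply_aaf_filter, filter_technical
from .variants import HIGH_IMPACT_CLASSES

__all__ = [
    "consensus_count",
    "bonferroni_threshold",
    "empirical_p",
    "permutation_test",
    "PermutationResult",
]

_SITE = ["chrom", "pos", "ref", "alt"]


def empirical_p(
    observed: float,
    null_values: np.ndarray,
    sided: str = "one_sided",
    plus_one: bool = True,
) -> float:
    """Permutation empirical p-value.

    One-sided (enrichment): (1 + #{null >= obs}) / (1 + n) with the plus-one
    correction (raw #/n without).  Two-sided on the discrete null: twice the
    smaller tail probability, capped at 1.
    """
    null_values = np.asarray(null_values, dtype=float)
    n = null_values.size
    add = 1 if plus_one else 0
    denom = n + add
    p_hi = (add + np.sum(null_values >= observed)) / denom
    if sided == "one_sided":
        return float(p_hi)
    if sided == "two_sided":
        p_lo = (add + np.sum(null_values <= observed)) / denom
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))
    raise ValueError(f"unknown sidedness {sided!r}")


def consensus_count(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_methods: int = 4,
) -> pd.DataFrame:
    """Per-gene consensus over the 12 combinations.

    ``n_nominal`` counts combinations with p strictly below ``alpha``
    (untestable combinations count as non-significant); ``protective`` marks
    genes with p < alpha and OR < 1 under weighted logistic regression with
    classical filtering; ``consensus`` flags n_nominal >= ``min_methods``.
    """
    key = ["gene", "strategy", "method"]
    if results.duplicated(subset=key).any():
        dup = results[results.duplicated(subset=key, keep=False)]
        raise ValueError(
            f"duplicate (gene, strategy, method) rows: "
            f"{dup[key].drop_duplicates().head().to_dict('records')}"
        )
    sig = results["p_value"] < alpha
    tab = (
        results.assign(sig=sig.fillna(False))
        .groupby("gene", observed=True)["sig"]
        .sum()
        .rename("n_nominal")
        .astype(int)
        .reset_index()
    )
    wl = results[
        (results["method"] == "logistic_weighted")
        & (results["strategy"] == "classical")
    ].set_index("gene")
    prot = (
        (wl["p_value"] < alpha) & (wl["odds_ratio"] < 1)
    ).reindex(tab["gene"]).fillna(False).to_numpy()
    tab["protective"] = prot
    tab["consensus"] = tab["n_nominal"] >= min_methods
    return tab


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Family-wise threshold alpha / n_genes (0.05 / 93 ~ 0.00054)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


@dataclass
class PermutationResult:
    statistic: str
    observed: float
    null_values: np.ndarray
    p_value: float
    n_perm: int
    seed: int
    sided: str


def _statistic_from_results(results: pd.DataFrame, statistic: str,
                            min_methods: int) -> float:
    tab = consensus_count(results, min_methods=min_methods)
    if statistic == "s1":
        return float((tab["n_nominal"] >= min_methods).sum())
    return float(tab["protective"].sum())


def permutation_test(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    statistic: str = "s1",
    n_perm: int = 100,
    seed: int = 0,
    contrast: str = "all_cases_vs_control",
    fdr_table: Optional[pd.DataFrame] = None,
    min_methods: int = 4,
    plus_one: bool = True,
    strategies: Sequence[str] = FILTER_STRATEGIES,
) -> PermutationResult:
    """Label-permutation empirical p-value for a consensus statistic.

    For each permutation the genomic profiles are reassigned to subjects (a
    permutation of sample ids applied to the variant table), the association
    chain is re-run and the statistic recomputed.  S2 depends only on the
    weighted-logistic/classical combination, so only that combination is
    recomputed per permutation; S1 recomputes all 12.

    Empirical p uses the plus-one estimator (1 + #extreme)/(1 + n_perm) by
    default (``plus_one=False`` gives the raw #extreme/n_perm); S1 is
    two-sided (double the smaller tail, capped at 1), S2 one-sided
    enrichment.
    """
    statistic = statistic.lower()
    if statistic not in ("s1", "s2"):
        raise ValueError("statistic must be 's1' or 's2'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    rng = np.random.default_rng(seed)
    ids = np.array(sorted(samples["sample_id"].unique()))

    if statistic == "s2":
        run_s2 = _s2_count_factory(variants, samples, contrast, fdr_table)
        observed = run_s2(None)
        null_vals = np.empty(n_perm)
        for b in range(n_perm):
            mapping = dict(zip(ids, rng.permutation(ids)))
            null_vals[b] = run_s2(mapping)
        sided = "one_sided"
    else:

        def _run(var_table: pd.DataFrame) -> float:
            res = run_all_combinations(
                var_table, samples, contrast=contrast, fdr_table=fdr_table,
                strategies=strategies, methods=METHODS,
            )
            return _statistic_from_results(res, "s1", min_methods)

        observed = _run(variants)
        null_vals = np.empty(n_perm)
        for b in range(n_perm):
            mapping = dict(zip(ids, rng.permutation(ids)))
            shuffled = variants.assign(
                sample_id=variants["sample_id"].map(mapping)
            )
            null_vals[b] = _run(shuffled)
        sided = "two_sided"

    p = empirical_p(observed, null_vals, sided=sided, plus_one=plus_one)
    return PermutationResult(
        statistic=statistic, observed=observed, null_values=null_vals,
        p_value=float(p), n_perm=n_perm, seed=seed, sided=sided,
    )


def _s2_count_factory(variants, samples, contrast, fdr_table):
    """Precompute the classical-filter AAF matrix and site annotations so the
    S2 statistic (weighted logistic / classical, protective count) can be
    recomputed per permutation as pure matrix work.  A permutation enters as
    a profile-to-subject mapping; ``None`` means the observed assignment."""
    if fdr_table is None:
        raise ValueError("weighted methods require an FDR table")
    all_ids = np.array(sorted(samples["sample_id"].unique()))
    sub = _contrast_samples(samples, contrast)
    y = (sub["group"] != "control").to_numpy(dtype=float)
    cov = build_covariates(sub)[0].to_numpy(dtype=float)
    filt = apply_aaf_filter(filter_technical(variants), "classical")
    piv = filt.pivot_table(index="sample_id", columns=_SITE, values="aaf",
                           aggfunc="max")
    piv = piv.reindex(index=all_ids).fillna(0.0)
    A = piv.to_numpy(dtype=float)
    site_info = (
        filt.groupby(_SITE, observed=True)
        .agg(gene=("gene", "first"), category=("category", "first"),
             population_af=("population_af", "first"),
             impact=("impact", "first"))
        .reindex(piv.columns)
    )
    w = compute_weights(site_info.reset_index(), fdr_table,
                        "fdr_downweighted", "logistic").to_numpy(dtype=float)
    rule_a = site_info["population_af"].gt(0.005).fillna(False).to_numpy()
    imp = site_info["impact"]
    rule_c = (~imp.isin(HIGH_IMPACT_CLASSES) & imp.notna()).to_numpy()
    invariant_removed = rule_a | rule_c
    pos = {s: i for i, s in enumerate(all_ids)}
    sub_rows = np.array([pos[s] for s in sub["sample_id"]])
    ctrl_mask = (sub["group"] == "control").to_numpy()
    genes = site_info["gene"].to_numpy()
    gene_idx = {
        g: np.flatnonzero(genes == g)
        for g in pd.unique(genes[pd.notna(genes)])
    }

    def run(mapping) -> float:
        if mapping is None:
            Ap = A
        else:
            inv = np.empty(len(all_ids), dtype=int)
            for i, old in enumerate(all_ids):
                inv[pos[mapping[old]]] = i
            Ap = A[inv]
        Asub = Ap[sub_rows]
        ctrl_mean = Asub[ctrl_mask].mean(axis=0)
        removed = invariant_removed | (ctrl_mean > 0.05)
        count = 0
        for idx in gene_idx.values():
            act = idx[~removed[idx]]
            if act.size == 0:
                continue
            out = logistic_burden_test(Asub[:, act] @ w[act], y, cov)
            if (out["p_value"] < 0.05) and (out["odds_ratio"] < 1):
                count += 1
        return float(count)

    return run
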