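"""Gene-level burden association under 12 filter x method combinations.

Each gene is tested four ways against a case/control contrast:

* ``logistic`` — logistic regression of case status on the per-sample sum of
  variant allele fractions across the gene's retained variants (continuous
  burden), adjusted for covariates; reports the per-unit-burden odds ratio
  with Wald interval and p-value.
* ``logistic_weighted`` — the same with each variant's AAF contribution
  multiplied by (1 - FDR) of its substitution category, so categories with a
  high FFPE false discovery rate (C>T above all) are down-weighted.
* ``skat_o`` — omnibus variance-component/burden score test on the binary
  presence matrix, with the rare-variant convention Beta(1, 25)-density
  weights evaluated at each variant's cohort alternate-allele frequency.
* ``skat_o_weighted`` — SKAT-O with the Beta weight additionally multiplied
  by (1 - FDR) of the category.

Crossed with the liberal / classical / strict AAF filtering strategies this
yields the 12 combinations reported per gene and contrast.

Covariates: epithelial percentage, histologic impression indicators, age,
biopsy year (linear term centered at 1992, post-1992 indicator and their
interaction — an FFPE processing change motivates the breakpoint), and SNP
call rate.  Aliased columns are dropped to full rank and logged.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prioritize import prioritize
from .qc import FILTER_STRATEGIES, apply_aaf_filter, filter_technical
from .skato import DEFAULT_RHO_GRID, LogisticNullModel, fit_null_logistic, skat_o

__all__ = [
    "CONTRASTS",
    "METHODS",
    "compute_weights",
    "gene_burden",
    "build_covariates",
    "logistic_burden_test",
    "skat_o_test",
    "run_all_combinations",
]

CONTRASTS = ("all_cases_vs_control", "er_pos_vs_control", "er_neg_vs_control")
METHODS = ("skat_o", "skat_o_weighted", "logistic", "logistic_weighted")

_SITE = ["chrom", "pos", "ref", "alt"]


def compute_weights(
    variant_sites: pd.DataFrame,
    fdr_table: Optional[pd.DataFrame],
    scheme: str = "default",
    test: str = "logistic",
) -> pd.Series:
    """Per-variant weights for one test family.

    ``variant_sites`` needs a ``category`` column (NaN for indels) and, for
    the SKAT family, a ``cohort_af`` column holding the variant's observed
    alternate-allele frequency in the analysis samples.  Base weight is 1 for
    the logistic burden and the Beta(1, 25) density at ``cohort_af`` for
    SKAT-O.  Under ``fdr_downweighted`` the base weight is multiplied by
    (1 - FDR) of the variant's category; indels (no category) keep factor 1.
    """
    if scheme not in ("default", "fdr_downweighted"):
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    if test not in ("logistic", "skat"):
        raise ValueError(f"unknown test family {test!r}")
    if test == "logistic":
        base = np.ones(len(variant_sites))
    else:
        f = variant_sites["cohort_af"].to_numpy(dtype=float)
        base = stats.beta.pdf(np.clip(f, 0.0, 1.0), 1.0, 25.0)
    if scheme == "fdr_downweighted":
        if fdr_table is None:
            raise ValueError("fdr_downweighted weighting requires an FDR table")
        fdr_map = fdr_table.set_index("category")["fdr"]
        factors = np.ones(len(variant_sites))
        for i, cat in enumerate(variant_sites["category"]):
            if cat is None or (isinstance(cat, float) and np.isnan(cat)):
                continue  # indel: category factor 1
            if cat not in fdr_map.index or np.isnan(fdr_map[cat]):
                raise ValueError(f"no FDR estimate for category {cat!r}")
            factors[i] = 1.0 - float(fdr_map[cat])
        base = base * factors
    return pd.Series(base, index=variant_sites.index, name="weight")


def gene_burden(
    variants: pd.DataFrame,
    sample_ids: Sequence[str],
    gene: str,
    weights: Optional[pd.Series] = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample continuous burden and binary presence matrix for one gene.

    Burden B_i = sum_v w_v * AAF_iv over the gene's retained variants;
    presence G_iv = 1 iff sample i carries variant v.  Samples without calls
    get zero rows.
    """
    sub = variants[variants["gene"] == gene]
    aaf = sub.pivot_table(index="sample_id", columns=_SITE, values="aaf",
                          aggfunc="max")
    aaf = aaf.reindex(index=list(sample_ids), fill_value=0.0).fillna(0.0)
    if weights is None:
        w = np.ones(aaf.shape[1])
    else:
        w = weights.reindex(aaf.columns).to_numpy(dtype=float)
    burden = pd.Series(aaf.to_numpy() @ w, index=aaf.index, name="burden")
    presence = (aaf > 0).astype(int)
    return burden, presence


def build_covariates(samples: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Covariate design matrix (without intercept) and the dropped columns.

    Biopsy year enters as year-1992, a post-1992 indicator and their
    interaction; histology as indicator columns against the
    non-proliferative baseline.  Collinear columns are removed back-to-front
    until the design (with intercept) has full column rank.
    """
    X = pd.DataFrame(index=samples.index)
    X["epithelial_pct"] = samples["epithelial_pct"].astype(float)
    for level in ("proliferative_no_atypia", "atypical_hyperplasia"):
        X[f"histology_{level}"] = (samples["histology"] == level).astype(float)
    X["age"] = samples["age"].astype(float)
    year_c = samples["biopsy_year"].astype(float) - 1992.0
    post = (samples["biopsy_year"].astype(float) > 1992.0).astype(float)
    X["year_c"] = year_c
    X["post1992"] = post
    X["year_c_x_post1992"] = year_c * post
    X["snp_call_rate"] = samples["snp_call_rate"].astype(float)
    dropped: list[str] = []
    n = len(X)
    cols = list(X.columns)
    while cols:
        M = np.column_stack([np.ones(n)] + [X[c].to_numpy() for c in cols])
        if np.linalg.matrix_rank(M) == M.shape[1]:
            break
        # drop the last column whose removal restores rank
        for c in reversed(cols):
            rest = [k for k in cols if k != c]
            M2 = np.column_stack([np.ones(n)] + [X[k].to_numpy() for k in rest])
            if np.linalg.matrix_rank(M2) == np.linalg.matrix_rank(M):
                dropped.append(c)
                cols = rest
                break
        else:  # pragma: no cover - cannot happen
            break
    if dropped:
        warnings.warn(f"dropped aliased covariate columns: {dropped}", stacklevel=2)
    return X[cols], dropped


def _loglik(Xs: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = np.clip(Xs @ beta, -35, 35)
    return float(np.sum(y * eta - np.log1p(np.exp(eta))))


def _irls_logistic(X: np.ndarray, y: np.ndarray, max_iter: int = 100,
                   tol: float = 1e-10) -> tuple[np.ndarray, np.ndarray, bool]:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares; returns (beta, standard errors, converged).

    Columns are standardized internally (near-constant covariates such as a
    SNP call rate hugging 1.0 otherwise wreck the Newton system) and the
    update is damped by step-halving on the log-likelihood; coefficients and
    standard errors are mapped back to the original scale.  Convergence is
    declared on log-likelihood stabilization, so a separating nuisance
    direction that drifts while the likelihood has flattened does not mark
    the whole fit failed — callers judge the coefficient of interest.
    """
    n, p = X.shape
    sd = X.std(axis=0)
    constant = sd < 1e-12
    sd_eff = np.where(constant, 1.0, sd)
    mean_eff = np.where(constant, 0.0, X.mean(axis=0))
    Xs = (X - mean_eff) / sd_eff
    beta = np.zeros(p)
    beta[0] = np.log(max(y.mean(), 1e-6) / max(1 - y.mean(), 1e-6))
    converged = False
    ll = _loglik(Xs, y, beta)
    for _ in range(max_iter):
        eta = np.clip(Xs @ beta, -35, 35)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = np.maximum(mu * (1 - mu), 1e-12)
        H = (Xs.T * w) @ Xs + 1e-10 * np.eye(p)
        try:
            delta = np.linalg.solve(H, Xs.T @ (y - mu))
        except np.linalg.LinAlgError:
            return beta / sd_eff, np.full(p, np.nan), False
        step = 1.0
        for _half in range(15):
            cand = beta + step * delta
            ll_new = _loglik(Xs, y, cand)
            if ll_new >= ll - 1e-12:
                break
            step *= 0.5
        beta = cand
        if ll_new - ll < tol * (1 + abs(ll_new)):
            converged = True
            break
        ll = ll_new
    eta = np.clip(Xs @ beta, -35, 35)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = np.maximum(mu * (1 - mu), 1e-12)
    try:
        cov = np.linalg.inv((Xs.T * w) @ Xs + 1e-10 * np.eye(p))
        se_s = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return beta / sd_eff, np.full(p, np.nan), False
    return beta / sd_eff, se_s / sd_eff, converged


def logistic_burden_test(
    burden: np.ndarray,
    case_indicator: np.ndarray,
    covariates: Optional[np.ndarray] = None,
) -> dict:
    """Logistic regression of case status on a continuous gene burden.

    Maximum-likelihood fit by iteratively reweighted least squares; reports
    the per-unit-burden odds ratio exp(beta), Wald 95% CI and Wald p.
    Constant burden is untestable; separation or non-convergence is flagged
    and leaves p/OR missing.
    """
    b = np.asarray(burden, dtype=float)
    y = np.asarray(case_indicator, dtype=float)
    out = {
        "p_value": np.nan, "odds_ratio": np.nan, "or_ci_low": np.nan,
        "or_ci_high": np.nan, "converged": False, "testable": True,
    }
    if np.all(b == b[0]):
        out["testable"] = False
        return out
    if y.sum() == 0 or y.sum() == len(y):
        out["testable"] = False
        return out
    n = len(y)
    cols = [np.ones(n), b]
    if covariates is not None and np.size(covariates):
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        cols.extend(cov.T)
    X = np.column_stack(cols)
    beta_hat, se_hat, converged = _irls_logistic(X, y)
    beta, se = beta_hat[1], se_hat[1]
    if (not converged) or (not np.isfinite(se)) or se > 50 or abs(beta) > 25:
        return out  # separation / non-convergence
    z = 1.959963984540054  # Phi^{-1}(0.975)
    out.update(
        p_value=float(2 * stats.norm.sf(abs(beta / se))),
        odds_ratio=float(np.exp(beta)),
        or_ci_low=float(np.exp(beta - z * se)),
        or_ci_high=float(np.exp(beta + z * se)),
        converged=True,
    )
    return out


def skat_o_test(
    presence: np.ndarray,
    null: LogisticNullModel,
    weights: Optional[np.ndarray] = None,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
) -> dict:
    """SKAT-O on a binary presence matrix against a fitted null model."""
    res = skat_o(presence, null, weights=weights, rho_grid=rho_grid)
    return {
        "p_value": res.p_value,
        "odds_ratio": np.nan,
        "or_ci_low": np.nan,
        "or_ci_high": np.nan,
        "converged": res.method != "untestable",
        "testable": res.method != "untestable",
    }


def _contrast_samples(samples: pd.DataFrame, contrast: str) -> pd.DataFrame:
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; use one of {CONTRASTS}")
    groups = {
        "all_cases_vs_control": ("control", "ER_pos", "ER_neg"),
        "er_pos_vs_control": ("control", "ER_pos"),
        "er_neg_vs_control": ("control", "ER_neg"),
    }[contrast]
    sub = samples[samples["group"].isin(groups)].copy()
    sub = sub.sort_values("sample_id")  # deterministic replicate selection
    if "replicate_set" in sub.columns:
        primary = sub["replicate_set"].isna() | ~sub.duplicated("replicate_set")
        sub = sub[primary]
    return sub.reset_index(drop=True)


def run_all_combinations(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    contrast: str = "all_cases_vs_control",
    fdr_table: Optional[pd.DataFrame] = None,
    strategies: Sequence[str] = FILTER_STRATEGIES,
    methods: Sequence[str] = METHODS,
    rho_grid: Sequence[float] = DEFAULT_RHO_GRID,
    genes: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Run the filter -> prioritize -> test chain for every combination.

    Returns one row per gene x strategy x method with the association
    outcome; genes emptied by a filter get flagged untestable rows so the
    12-way bookkeeping stays complete.
    """
    sub_samples = _contrast_samples(samples, contrast)
    ids = list(sub_samples["sample_id"])
    y = (sub_samples["group"] != "control").to_numpy(dtype=float)
    control_ids = list(sub_samples.loc[sub_samples["group"] == "control", "sample_id"])
    cov_df, _ = build_covariates(sub_samples)
    cov = cov_df.to_numpy(dtype=float)
    null = fit_null_logistic(y, cov)

    base = filter_technical(variants[variants["sample_id"].isin(ids)])
    if genes is None:
        genes = sorted(g for g in base["gene"].dropna().unique())
    n = len(ids)
    needs_fdr = any("weighted" in m for m in methods)
    if needs_fdr and fdr_table is None:
        raise ValueError("weighted methods require an FDR table")

    rows = []
    for strategy in strategies:
        filtered = apply_aaf_filter(base, strategy)
        retained, _ledger = prioritize(filtered, control_ids)
        site_info = (
            retained.groupby(_SITE, observed=True)
            .agg(gene=("gene", "first"), category=("category", "first"),
                 aaf_sum=("aaf", "sum"))
            .reset_index()
        )
        site_info["cohort_af"] = site_info["aaf_sum"] / n
        # one samples x sites AAF matrix per strategy; genes slice columns
        piv = retained.pivot_table(index="sample_id", columns=_SITE,
                                   values="aaf", aggfunc="max")
        piv = piv.reindex(index=ids).fillna(0.0)
        site_info = site_info.set_index(_SITE).reindex(piv.columns).reset_index()
        A = piv.to_numpy(dtype=float)
        col_idx = {
            g: np.flatnonzero((site_info["gene"] == g).to_numpy())
            for g in site_info["gene"].unique()
        }
        weights_by = {
            (scheme, fam): compute_weights(site_info, fdr_table, scheme, fam)
            .to_numpy(dtype=float)
            for scheme in ("default", "fdr_downweighted")
            for fam in ("logistic", "skat")
            if scheme == "default" or needs_fdr
        }
        for gene in genes:
            idx = col_idx.get(gene, np.array([], dtype=int))
            m = len(idx)
            if m == 0:
                for method in methods:
                    rows.append(
                        dict(contrast=contrast, gene=gene, strategy=strategy,
                             method=method, p_value=np.nan, odds_ratio=np.nan,
                             or_ci_low=np.nan, or_ci_high=np.nan, n_variants=0,
                             converged=False, testable=False)
                    )
                continue
            Ag = A[:, idx]
            Gm = (Ag > 0).astype(float)
            for method in methods:
                scheme = "fdr_downweighted" if "weighted" in method else "default"
                fam = "skat" if method.startswith("skat") else "logistic"
                w = weights_by[(scheme, fam)][idx]
                if fam == "logistic":
                    out = logistic_burden_test(Ag @ w, y, cov)
                else:
                    out = skat_o_test(Gm, null, w, rho_grid)
                rows.append(
                    dict(contrast=contrast, gene=gene, strategy=strategy,
                         method=method, n_variants=m, **out)
                )
    cols = ["contrast", "gene", "strategy", "method", "p_value", "odds_ratio",
            "or_ci_low", "or_ci_high", "n_variants", "converged", "testable"]
    return pd.DataFrame(rows)[cols]
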