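"""Sample- and variant-level quality control for FFPE variant calls.

Covers the pipeline's QC chain: removal of technically flagged calls,
AAF-bin genotype calling, sample acceptance (molecular-tag coverage and SNP
call rate), replicate-identity checks by rank correlation over known SNPs,
estimation of per-category false discovery rates from paired FFPE/fresh-frozen
samples, the three nested AAF filtering strategies (liberal / classical /
strict), and concordance of cohort allele frequencies with population allele
frequencies.

FFPE fixation deaminates cytosine, producing artifactual C>T calls at low
alternate-allele fraction; the classical and strict strategies therefore
impose a higher AAF floor on C>T substitutions or on everything,
respectively.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MUTATION_CATEGORIES

__all__ = [
    "FILTER_STRATEGIES",
    "filter_technical",
    "call_genotype",
    "call_genotypes",
    "sample_qc",
    "replicate_identity",
    "estimate_fdr",
    "apply_aaf_filter",
    "population_af_concordance",
]

FILTER_STRATEGIES = ("liberal", "classical", "strict")

#: genotype bins on AAF, endpoints inclusive
_GT_BINS = {"hom_ref": (0.0, 0.2), "het": (0.4, 0.6), "hom_alt": (0.8, 1.0)}


def filter_technical(variants: pd.DataFrame) -> pd.DataFrame:
    """Drop every call carrying one or more upstream technical failure flags
    (strand bias, low complexity region, low base quality, shallow
    molecular-tag coverage)."""
    flags = variants["technical_flags"].fillna("")
    keep = flags.astype(str).str.strip().isin(["", "."])
    return variants.loc[keep].reset_index(drop=True)


def call_genotype(aaf: float) -> str:
    """Genotype from AAF bins: [0,0.2] hom_ref, [0.4,0.6] het, [0.8,1] hom_alt,
    anything between the bins is a no-call."""
    if not 0.0 <= aaf <= 1.0:
        raise ValueError(f"aaf {aaf} outside [0, 1]")
    for gt, (lo, hi) in _GT_BINS.items():
        if lo <= aaf <= hi:
            return gt
    return "no_call"


def call_genotypes(aaf: np.ndarray) -> np.ndarray:
    """Vectorized :func:`call_genotype`."""
    aaf = np.asarray(aaf, dtype=float)
    if np.any((aaf < 0) | (aaf > 1)):
        raise ValueError("aaf outside [0, 1]")
    out = np.full(aaf.shape, "no_call", dtype=object)
    for gt, (lo, hi) in _GT_BINS.items():
        out[(aaf >= lo) & (aaf <= hi)] = gt
    return out


def _snp_aaf_matrix(
    samples: pd.DataFrame,
    variants: pd.DataFrame,
    known_snp_positions: pd.DataFrame,
) -> pd.DataFrame:
    """Samples x known-SNP AAF matrix; absent calls are AAF 0."""
    key_cols = ["chrom", "pos", "ref", "alt"]
    snp_index = pd.MultiIndex.from_frame(known_snp_positions[key_cols])
    vkey = pd.MultiIndex.from_frame(variants[key_cols])
    sub = variants.loc[vkey.isin(snp_index)]
    mat = sub.pivot_table(
        index="sample_id", columns=key_cols, values="aaf", aggfunc="max"
    )
    mat = mat.reindex(index=samples["sample_id"], fill_value=0.0)
    # SNP sites never observed anywhere still count as hom_ref in every sample
    mat = mat.reindex(columns=snp_index, fill_value=0.0)
    return mat.fillna(0.0)


def sample_qc(
    samples: pd.DataFrame,
    known_snp_positions: pd.DataFrame,
    variants: pd.DataFrame,
    min_umt_coverage: float = 20.0,
    min_call_rate: float = 0.80,
) -> pd.DataFrame:
    """Per-sample pass/fail with reasons.

    A sample fails when its mean unique-molecular-tag coverage is below
    ``min_umt_coverage`` (default 20x) or its SNP genotyping call rate —
    the fraction of known SNP positions whose AAF falls in one of the three
    genotype bins — is below ``min_call_rate`` (default 80%).
    Returns the sample sheet with ``snp_call_rate``, ``qc_pass`` and
    ``qc_reasons`` columns.
    """
    out = samples.copy().reset_index(drop=True)
    if len(known_snp_positions):
        mat = _snp_aaf_matrix(out, variants, known_snp_positions)
        rates = []
        for sid in out["sample_id"]:
            gts = call_genotypes(mat.loc[sid].to_numpy())
            rates.append(float(np.mean(gts != "no_call")))
        out["snp_call_rate"] = rates
    else:
        out["snp_call_rate"] = np.nan
    reasons = []
    passes = []
    for _, row in out.iterrows():
        why = []
        if not row["mean_umt_coverage"] >= min_umt_coverage:
            why.append(f"mean_umt_coverage<{min_umt_coverage:g}")
        rate = row["snp_call_rate"]
        if np.isnan(rate):
            why.append("snp_call_rate_missing")
        elif rate < min_call_rate:
            why.append(f"snp_call_rate<{min_call_rate:g}")
        reasons.append(";".join(why))
        passes.append(not why)
    out["qc_pass"] = passes
    out["qc_reasons"] = reasons
    return out


def replicate_identity(
    aaf_matrix: pd.DataFrame,
    threshold: float = 0.85,
    fold_maf: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman correlation of known-SNP AAFs across samples.

    Two profiles are called same-source when their rank correlation exceeds
    ``threshold`` (default 0.85, the margin that separates technical
    replicates from unrelated subjects).  Ties get average ranks.  With
    ``fold_maf`` the allele fractions are folded to min(aaf, 1-aaf) first.
    A constant profile has no defined correlation: its verdicts are missing.

    Returns ``(correlation_matrix, verdicts)`` where verdicts has one row per
    unordered sample pair with columns ``sample_a, sample_b, correlation,
    same_source``.
    """
    if aaf_matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    if aaf_matrix.shape[1] == 0:
        raise ValueError("empty shared SNP set")
    X = aaf_matrix.to_numpy(dtype=float)
    if fold_maf:
        X = np.minimum(X, 1.0 - X)
    constant = X.std(axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} sample(s) have constant AAF profiles; "
            "their correlations are undefined",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore"):
        corr, _ = stats.spearmanr(X, axis=1)
    if np.ndim(corr) == 0:  # scipy collapses the 2-sample case to a scalar
        corr = np.array([[1.0, float(corr)], [float(corr), 1.0]])
    corr[constant, :] = np.nan
    corr[:, constant] = np.nan
    np.fill_diagonal(corr, 1.0)
    ids = list(aaf_matrix.index)
    cmat = pd.DataFrame(corr, index=ids, columns=ids)
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r = cmat.iloc[i, j]
            rows.append(
                {
                    "sample_a": ids[i],
                    "sample_b": ids[j],
                    "correlation": r,
                    "same_source": bool(r > threshold) if np.isfinite(r) else None,
                }
            )
    return cmat, pd.DataFrame(rows)


def estimate_fdr(
    ffpe_variants: pd.DataFrame,
    frozen_variants: pd.DataFrame,
    pair_key: str = "pair_id",
    aaf_bins: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-category FFPE false discovery rate from paired FFPE/frozen calls.

    For each of the seven substitution categories (optionally further split
    into AAF bins), FDR = (# FFPE calls absent from the paired frozen
    sample) / (# FFPE calls), matching calls on
    (pair, chrom, pos, ref, alt).  Indels are ignored.  Cells with zero FFPE
    calls get a missing FDR.

    Returns a DataFrame with columns ``category`` (+ ``aaf_bin``),
    ``n_ffpe_calls``, ``n_ffpe_only_calls``, ``fdr``.
    """
    for df, name in ((ffpe_variants, "ffpe"), (frozen_variants, "frozen")):
        if pair_key not in df.columns:
            raise ValueError(f"{name} variants lack pairing column {pair_key!r}")
    key_cols = [pair_key, "chrom", "pos", "ref", "alt"]
    ffpe = ffpe_variants.dropna(subset=["category"]).copy()
    frozen_keys = set(map(tuple, frozen_variants[key_cols].itertuples(index=False)))
    ffpe_keys = list(map(tuple, ffpe[key_cols].itertuples(index=False)))
    ffpe["ffpe_only"] = [k not in frozen_keys for k in ffpe_keys]
    group_cols = ["category"]
    if aaf_bins is not None:
        edges = np.asarray(aaf_bins, dtype=float)
        ffpe["aaf_bin"] = pd.cut(ffpe["aaf"], edges, include_lowest=True)
        group_cols.append("aaf_bin")
    ffpe["category"] = pd.Categorical(ffpe["category"],
                                      categories=MUTATION_CATEGORIES)
    agg = (
        ffpe.groupby(group_cols, observed=False)["ffpe_only"]
        .agg(n_ffpe_calls="size", n_ffpe_only_calls="sum")
        .reset_index()
    )
    agg["n_ffpe_calls"] = agg["n_ffpe_calls"].astype(int)
    agg["n_ffpe_only_calls"] = agg["n_ffpe_only_calls"].astype(int)
    with np.errstate(invalid="ignore"):
        agg["fdr"] = np.where(
            agg["n_ffpe_calls"] > 0,
            agg["n_ffpe_only_calls"] / agg["n_ffpe_calls"],
            np.nan,
        )
    return agg


def apply_aaf_filter(variants: pd.DataFrame, strategy: str) -> pd.DataFrame:
    """Apply one of the three AAF filtering strategies.

    liberal
        remove calls with AAF < 0.05.
    classical
        remove C>T calls (both plain and at-CpG) lacking an rsID when
        AAF < 0.1; remove all other calls when AAF < 0.05.
    strict
        remove all calls with AAF < 0.1.

    Thresholds are exclusive (strictly ``<``), so the three survivor sets
    are nested: strict is a subset of classical is a subset of liberal.
    """
    if strategy not in FILTER_STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; use one of {FILTER_STRATEGIES}")
    aaf = variants["aaf"].to_numpy(dtype=float)
    if strategy == "liberal":
        keep = aaf >= 0.05
    elif strategy == "strict":
        keep = aaf >= 0.1
    else:
        is_ct = variants["category"].isin(["C>T", "C>T_at_CpG"]).to_numpy()
        has_rsid = (
            variants["rsid"].notna() & (variants["rsid"].astype(str) != "")
        ).to_numpy()
        ct_rule = is_ct & ~has_rsid
        keep = np.where(ct_rule, aaf >= 0.1, aaf >= 0.05)
    return variants.loc[keep].reset_index(drop=True)


def population_af_concordance(
    variants: pd.DataFrame,
    samples: pd.DataFrame,
    by_category: bool = False,
    method: str = "spearman",
) -> pd.DataFrame:
    """Correlation between cohort allele frequency and population AF.

    For every rsID-annotated site with a population allele frequency, the
    cohort frequency is the allele count implied by the AAF-bin genotypes of
    the passing samples (het = 1, hom_alt = 2; a sample without a call is
    hom_ref) over 2N chromosomes.  Returns a one-row DataFrame (plus one row
    per category under ``by_category``) with ``n_sites`` and ``correlation``;
    fewer than 3 shared sites give a missing value.
    """
    if method not in ("spearman", "pearson"):
        raise ValueError(f"unknown correlation method {method!r}")
    n = len(samples)
    sub = variants[
        variants["rsid"].notna()
        & (variants["rsid"].astype(str) != "")
        & variants["population_af"].notna()
        & variants["sample_id"].isin(samples["sample_id"])
    ].copy()
    dosage = {"hom_ref": 0, "het": 1, "hom_alt": 2, "no_call": 0}
    sub["dose"] = [dosage[g] for g in call_genotypes(sub["aaf"].to_numpy())]
    site_cols = ["chrom", "pos", "ref", "alt"]
    agg = (
        sub.groupby(site_cols, observed=True)
        .agg(dose=("dose", "sum"), population_af=("population_af", "first"),
             category=("category", "first"))
        .reset_index()
    )
    agg["cohort_af"] = agg["dose"] / (2.0 * n)

    def _corr(df: pd.DataFrame) -> float:
        if len(df) < 3:
            return np.nan
        if df["cohort_af"].nunique() < 2 or df["population_af"].nunique() < 2:
            return np.nan
        fn = stats.spearmanr if method == "spearman" else stats.pearsonr
        return float(fn(df["cohort_af"], df["population_af"])[0])

    rows = [{"category": "all", "n_sites": len(agg), "correlation": _corr(agg)}]
    if by_category:
        for cat, g in agg.groupby("category", observed=True):
            rows.append(
                {"category": cat, "n_sites": len(g), "correlation": _corr(g)}
            )
    return pd.DataFrame(rows)
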