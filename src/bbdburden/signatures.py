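"""De-novo mutational signature extraction from per-sample mutation spectra.

A mutation spectrum is a samples x categories count matrix, at either the
seven-category substitution resolution used throughout the pipeline
(C>A, C>G, C>T, C>T at CpG, T>A, T>C, T>G) or the 96-class trinucleotide
resolution.  Signatures are extracted by non-negative matrix factorization
minimizing the generalized Kullback-Leibler divergence with multiplicative
updates, stabilized by random restarts and consensus clustering of the
pooled per-restart signatures; exposures are refit against the consensus
signatures by non-negative least squares.  Extracted signatures are compared
to a reference catalog (e.g. COSMIC profiles supplied as a TSV) by cosine
similarity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import nnls

from .variants import MUTATION_CATEGORIES, revcomp

__all__ = [
    "spectrum_table",
    "cosine_similarity",
    "nmf_extract",
    "SignatureSet",
    "rank_scan",
    "compare_to_catalog",
    "associate_exposures",
    "TRINUCLEOTIDE_96",
]


def _tri96_classes() -> list[str]:
    classes = []
    for sub in ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G"):
        ref = sub[0]
        for left in "ACGT":
            for right in "ACGT":
                classes.append(f"{left}[{sub}]{right}")
    return classes


TRINUCLEOTIDE_96 = tuple(_tri96_classes())


def _tri96_label(ref: str, alt: str, context: str) -> str:
    if ref in "AG":
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    return f"{context[0]}[{ref}>{alt}]{context[2]}"


def spectrum_table(variants: pd.DataFrame, scheme: str = "seven_category") -> pd.DataFrame:
    """Per-sample mutation-category count matrix.

    Uses classified SNVs only; samples present in the table but without any
    classified SNV get a zero row.  ``scheme`` is ``seven_category`` or
    ``trinucleotide_96`` (the latter requires a trinucleotide context on
    every SNV).
    """
    if scheme not in ("seven_category", "trinucleotide_96"):
        raise ValueError(f"unknown scheme {scheme!r}")
    samples = list(pd.unique(variants["sample_id"]))
    snvs = variants[variants["category"].notna()].copy()
    if scheme == "seven_category":
        labels = snvs["category"]
        columns = list(MUTATION_CATEGORIES)
    else:
        bad = snvs["context"].isna() | (snvs["context"].astype(str).str.len() != 3)
        if bad.any():
            offenders = snvs.loc[bad, ["chrom", "pos", "ref", "alt"]]
            raise ValueError(
                "missing trinucleotide context for SNVs: "
                f"{offenders.head().to_dict('records')}"
            )
        labels = [
            _tri96_label(r, a, c)
            for r, a, c in zip(snvs["ref"], snvs["alt"], snvs["context"])
        ]
        columns = list(TRINUCLEOTIDE_96)
    counts = (
        pd.crosstab(snvs["sample_id"], pd.Series(labels, index=snvs.index))
        .reindex(index=samples, columns=columns, fill_value=0)
        .astype(int)
    )
    counts.index.name = "sample_id"
    return counts


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative vectors; NaN if either
    is the zero vector."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


@dataclass
class SignatureSet:
    """Consensus signatures with exposures and diagnostics.

    ``signatures``: categories x K, column-stochastic.  ``exposures``:
    samples x K non-negative loadings from the NNLS refit.  ``stability``:
    mean cosine of clustered per-restart signatures to their consensus
    centroid.  ``objective``: KL objective trajectory of the best restart
    (non-increasing).  ``reconstruction_error``: Frobenius residual of the
    refit relative to the spectrum norm.
    """

    signatures: pd.DataFrame
    exposures: pd.DataFrame
    stability: np.ndarray
    objective: np.ndarray
    reconstruction_error: float


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    mask = V > 0
    div = np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()
    return float(div)


def _nmf_mu_kl(V: np.ndarray, k: int, rng: np.random.Generator,
               max_iter: int, tol: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Multiplicative-update NMF for generalized KL divergence.

    Factorizes V (C x S) as W (C x k) @ H (k x S); the objective is
    non-increasing under the updates.  Returns (W, H, objective trajectory).
    """
    C, S = V.shape
    scale = V.mean()
    W = rng.uniform(0.5, 1.5, (C, k)) * np.sqrt(scale / k)
    H = rng.uniform(0.5, 1.5, (k, S)) * np.sqrt(scale / k)
    eps = 1e-12
    obj = []
    prev = np.inf
    for it in range(max_iter):
        WH = W @ H + eps
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], eps)
        WH = W @ H + eps
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], eps)
        cur = _kl_divergence(V, W @ H + eps)
        obj.append(cur)
        if prev - cur < tol * max(abs(prev), 1.0):
            break
        prev = cur
    # normalize signatures to column-stochastic, pushing scale into H
    colsum = np.maximum(W.sum(axis=0), eps)
    W = W / colsum
    H = H * colsum[:, None]
    return W, H, np.asarray(obj)


def nmf_extract(
    spectrum: pd.DataFrame,
    k: int,
    n_restarts: int = 30,
    max_iter: int = 2000,
    tol: float = 1e-9,
    seed: int = 0,
) -> SignatureSet:
    """Extract ``k`` consensus signatures from a spectrum by restarted NMF.

    ``n_restarts`` random initializations are run; the pooled per-restart
    signatures are clustered (average-linkage on cosine distance, cut at k),
    each cluster's renormalized centroid becomes a consensus signature whose
    stability is the mean cosine of members to the centroid, and exposures
    are refit per sample by non-negative least squares.
    """
    V = spectrum.to_numpy(dtype=float).T  # categories x samples
    categories = list(spectrum.columns)
    sample_ids = list(spectrum.index)
    if k < 1:
        raise ValueError("k must be >= 1")
    nonzero_rows = int(np.sum(V.sum(axis=0) > 0))
    if V.sum() == 0:
        raise ValueError("all-zero spectrum")
    if k > min(V.shape[0], nonzero_rows):
        raise ValueError(
            f"k={k} exceeds the rank bound min({V.shape[0]} categories, "
            f"{nonzero_rows} non-zero samples)"
        )
    rng = np.random.default_rng(seed)
    pool = []
    best_obj: Optional[np.ndarray] = None
    best_final = np.inf
    for _ in range(n_restarts):
        W, H, obj = _nmf_mu_kl(V, k, rng, max_iter, tol)
        pool.append(W)
        if obj[-1] < best_final:
            best_final = obj[-1]
            best_obj = obj
    P = np.hstack(pool)  # categories x (n_restarts*k)
    if k == 1 or P.shape[1] == 1:
        labels = np.ones(P.shape[1], dtype=int)
    else:
        norms = np.linalg.norm(P, axis=0)
        U = P / np.maximum(norms, 1e-12)
        d = 1.0 - np.clip(U.T @ U, -1.0, 1.0)
        iu = np.triu_indices(P.shape[1], 1)
        labels = fcluster(linkage(d[iu], method="average"), t=k,
                          criterion="maxclust")
    sigs = np.zeros((V.shape[0], k))
    stability = np.zeros(k)
    for ci in range(1, k + 1):
        members = P[:, labels == ci]
        if members.shape[1] == 0:
            continue
        centroid = members.mean(axis=1)
        centroid = centroid / max(centroid.sum(), 1e-12)
        sigs[:, ci - 1] = centroid
        stability[ci - 1] = float(
            np.mean([cosine_similarity(members[:, j], centroid)
                     for j in range(members.shape[1])])
        )
    order = np.argsort(-sigs.max(axis=0) * stability)  # stable-first labelling
    sigs, stability = sigs[:, order], stability[order]
    sig_names = [f"signature_{chr(ord('A') + i)}" for i in range(k)]
    exposures = np.zeros((V.shape[1], k))
    for s in range(V.shape[1]):
        exposures[s], _ = nnls(sigs, V[:, s])
    resid = np.linalg.norm(V - sigs @ exposures.T)
    rel_err = float(resid / max(np.linalg.norm(V), 1e-12))
    return SignatureSet(
        signatures=pd.DataFrame(sigs, index=categories, columns=sig_names),
        exposures=pd.DataFrame(exposures, index=sample_ids, columns=sig_names),
        stability=stability,
        objective=best_obj if best_obj is not None else np.array([]),
        reconstruction_error=rel_err,
    )


def rank_scan(
    spectrum: pd.DataFrame,
    ks: Union[range, list],
    n_restarts: int = 10,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Stability and reconstruction error across candidate ranks.

    Guides the choice of k: stable consensus (mean within-cluster cosine
    near 1) with a clear drop in reconstruction error marks a supported
    rank; beyond it stability degrades.
    """
    rows = []
    for k in ks:
        res = nmf_extract(spectrum, k, n_restarts=n_restarts, seed=seed,
                          **kwargs)
        rows.append(
            {
                "k": k,
                "mean_stability": float(res.stability.mean()),
                "min_stability": float(res.stability.min()),
                "reconstruction_error": res.reconstruction_error,
            }
        )
    return pd.DataFrame(rows)


def compare_to_catalog(
    signatures: pd.DataFrame, catalog: pd.DataFrame
) -> pd.DataFrame:
    """K x R cosine-similarity matrix between extracted signatures and a
    reference catalog (categories x profiles, matched on the index)."""
    shared = signatures.index.intersection(catalog.index)
    if len(shared) < 2:
        raise ValueError("signatures and catalog share fewer than 2 categories")
    S = signatures.loc[shared]
    C = catalog.loc[shared]
    out = pd.DataFrame(index=S.columns, columns=C.columns, dtype=float)
    for sc in S.columns:
        for cc in C.columns:
            out.loc[sc, cc] = cosine_similarity(S[sc].to_numpy(), C[cc].to_numpy())
    return out


def associate_exposures(
    exposures: Union[pd.Series, np.ndarray],
    sample_attribute: Union[pd.Series, np.ndarray],
    test: str = "wilcoxon_rank_sum",
) -> float:
    """Rank-based test of one signature's exposures across attribute levels.

    ``wilcoxon_rank_sum`` (two levels; normal approximation with average
    ranks and tie correction) or ``kruskal_wallis`` (>= 2 levels).  Levels
    with fewer than 2 samples give a missing p with a warning.
    """
    import warnings

    x = np.asarray(exposures, dtype=float)
    g = np.asarray(sample_attribute)
    levels = pd.unique(g[~pd.isna(g)])
    groups = [x[g == lev] for lev in levels]
    if any(len(grp) < 2 for grp in groups) or len(groups) < 2:
        warnings.warn("attribute level with < 2 samples; p-value missing",
                      stacklevel=2)
        return float("nan")
    if test == "wilcoxon_rank_sum":
        if len(groups) != 2:
            raise ValueError("wilcoxon_rank_sum requires exactly 2 levels")
        if np.all(x == x[0]):
            return 1.0
        res = stats.mannwhitneyu(groups[0], groups[1], alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        return float(res.pvalue)
    if test == "kruskal_wallis":
        if np.all(x == x[0]):
            return 1.0
        return float(stats.kruskal(*groups).pvalue)
    raise ValueError(f"unknown test {test!r}")
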