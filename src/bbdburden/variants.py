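"""Shared data model for sample-level variant calls.

The pipeline's atomic observation is one (sample, site, alt allele) call,
carried as a row of a pandas DataFrame with the columns in
:data:`VARIANT_COLUMNS`.  Single-nucleotide variants are additionally labelled
with one of seven pyrimidine-strand mutation categories
(C>A, C>G, C>T, C>T_at_CpG, T>A, T>C, T>G), the resolution at which FFPE
deamination artifacts concentrate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "MUTATION_CATEGORIES",
    "SNV_BASES",
    "VARIANT_COLUMNS",
    "TECHNICAL_FLAGS",
    "IMPACT_CLASSES",
    "HIGH_IMPACT_CLASSES",
    "SampleRecord",
    "classify_mutation",
    "revcomp",
    "is_snv",
    "molecular_diversity",
    "classify_variant_table",
    "validate_variants",
]

#: the seven substitution categories, pyrimidine-strand normalized
MUTATION_CATEGORIES = ("C>A", "C>G", "C>T", "C>T_at_CpG", "T>A", "T>C", "T>G")

SNV_BASES = frozenset("ACGT")

#: upstream variant-caller failure flags consumed as pass/fail annotations
TECHNICAL_FLAGS = frozenset(
    {"strand_bias", "low_complexity", "low_base_quality", "shallow_mt_coverage"}
)

#: controlled functional-impact vocabulary; everything but low_impact is
#: treated as medium/high impact during prioritization
IMPACT_CLASSES = (
    "essential_splice",
    "stop_gain",
    "frameshift",
    "nonsynonymous",
    "inframe_indel",
    "start_codon",
    "stop_loss",
    "exon_end",
    "low_impact",
)
HIGH_IMPACT_CLASSES = frozenset(IMPACT_CLASSES) - {"low_impact"}

#: canonical column order of a variant table
VARIANT_COLUMNS = [
    "sample_id",
    "chrom",
    "pos",
    "ref",
    "alt",
    "aaf",
    "umt_depth",
    "rsid",
    "gene",
    "impact",
    "population_af",
    "context",
    "technical_flags",
    "category",
]

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMPLEMENT)[::-1]


def is_snv(ref: str, alt: str) -> bool:
    """True when both alleles are single A/C/G/T bases."""
    return len(ref) == 1 and len(alt) == 1 and ref in SNV_BASES and alt in SNV_BASES


def classify_mutation(ref: str, alt: str, context: str) -> str:
    """Label an SNV with one of the seven substitution categories.

    Purine-reference substitutions are reverse-complemented onto the
    pyrimidine strand first; a (strand-normalized) C>T whose 3' neighbour is
    G becomes ``C>T_at_CpG``.

    Parameters
    ----------
    ref, alt:
        Single reference/alternate bases, ``ref != alt``.
    context:
        Trinucleotide reference context centered on the variant position;
        its middle base must equal ``ref``.
    """
    if not is_snv(ref, alt):
        raise ValueError(f"not an SNV: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if len(context) != 3 or any(b not in SNV_BASES for b in context):
        raise ValueError(f"invalid trinucleotide context {context!r}")
    if context[1] != ref:
        raise ValueError(f"context middle base {context[1]!r} != ref {ref!r}")
    if ref in "AG":  # normalize to the pyrimidine strand
        ref, alt, context = revcomp(ref), revcomp(alt), revcomp(context)
    if ref == "C" and alt == "T" and context[2] == "G":
        return "C>T_at_CpG"
    return f"{ref}>{alt}"


def molecular_diversity(mt_coverage: float, raw_coverage: float) -> float:
    """Molecular diversity score: 100 x MT-coverage / raw coverage.

    Quantifies what fraction of raw sequencing depth survives collapsing PCR
    duplicates by unique molecular tag.  Returns NaN when raw coverage is 0.
    """
    if raw_coverage is None or raw_coverage == 0 or np.isnan(raw_coverage):
        return float("nan")
    return 100.0 * mt_coverage / raw_coverage


def classify_variant_table(variants: pd.DataFrame) -> pd.DataFrame:
    """Fill the ``category`` column for every SNV row (NaN for indels)."""
    out = variants.copy()
    cats: list[Optional[str]] = []
    for ref, alt, ctx in zip(out["ref"], out["alt"], out["context"]):
        if is_snv(str(ref), str(alt)) and isinstance(ctx, str) and len(ctx) == 3:
            cats.append(classify_mutation(str(ref), str(alt), ctx))
        else:
            cats.append(None)
    out["category"] = cats
    return out


def validate_variants(variants: pd.DataFrame) -> None:
    """Raise ValueError if a variant table violates the model invariants."""
    missing = [c for c in VARIANT_COLUMNS if c not in variants.columns]
    if missing:
        raise ValueError(f"variant table missing columns: {missing}")
    aaf = variants["aaf"].to_numpy(dtype=float)
    if np.any((aaf < 0) | (aaf > 1)):
        raise ValueError("aaf outside [0, 1]")
    if np.any(variants["umt_depth"].to_numpy(dtype=float) < 0):
        raise ValueError("negative umt_depth")
    pop = variants["population_af"].to_numpy(dtype=float)
    ok = np.isnan(pop) | ((pop >= 0) & (pop <= 1))
    if not np.all(ok):
        raise ValueError("population_af outside [0, 1]")


@dataclass
class SampleRecord:
    """One subject: group label, covariates, QC metrics and IHC readouts.

    ``group`` is ``control``, ``ER_pos`` or ``ER_neg``; histology one of
    ``non_proliferative``, ``proliferative_no_atypia``,
    ``atypical_hyperplasia``.  CD45 is an immunohistochemistry H-score on the
    0-300 scale; Ki67 a percent of positive nuclei.
    """

    sample_id: str
    group: str
    age: float
    histology: str
    epithelial_pct: float
    biopsy_year: int
    atrophy: Optional[str] = None
    mean_umt_coverage: float = float("nan")
    mean_raw_coverage: float = float("nan")
    snp_call_rate: float = float("nan")
    replicate_set: Optional[str] = None
    cd45_hscore: Optional[float] = None
    ki67_pct: Optional[float] = None

    @property
    def molecular_diversity(self) -> float:
        return molecular_diversity(self.mean_umt_coverage, self.mean_raw_coverage)


def samples_to_frame(samples: Iterable[SampleRecord]) -> pd.DataFrame:
    """Tabulate SampleRecords as a sample sheet DataFrame."""
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "group": s.group,
                "age": s.age,
                "histology": s.histology,
                "atrophy": s.atrophy,
                "epithelial_pct": s.epithelial_pct,
                "biopsy_year": s.biopsy_year,
                "mean_umt_coverage": s.mean_umt_coverage,
                "mean_raw_coverage": s.mean_raw_coverage,
                "molecular_diversity": s.molecular_diversity,
                "snp_call_rate": s.snp_call_rate,
                "replicate_set": s.replicate_set,
                "cd45_hscore": s.cd45_hscore,
                "ki67_pct": s.ki67_pct,
            }
        )
    return pd.DataFrame(rows)
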