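"""Synthetic cohorts with the statistical structure of FFPE panel sequencing.

The generator emulates, at the variant-call level, a three-group benign
breast disease cohort sequenced with a molecular-tag panel: common germline
SNPs drawn from Hardy-Weinberg at their population allele frequencies with
genotype-consistent AAF noise, rare germline variants, somatic mutations at
recurrent per-gene sites (optionally with planted group-dependent rate
effects), and FFPE deamination artifacts concentrated in C>T categories at
low alternate-allele fraction.  Technical replicates share germline
genotypes and somatic variants but redraw artifacts and noise.  Paired
FFPE/fresh-frozen sets and signature-mixture spectra are generated for the
FDR-estimation and signature-extraction stages.  Every generated call
carries a ground-truth origin label.

Group-size defaults (42 controls / 42 future ER+ / 36 future ER-), the
93-gene panel size and the covariate margins follow the published cohort.
No read-level process is simulated: the unit is the variant call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .qc import sample_qc
from .variants import MUTATION_CATEGORIES, VARIANT_COLUMNS, classify_variant_table, revcomp

__all__ = [
    "EffectSpec",
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_paired_ffpe_frozen",
    "generate_signature_cohort",
]

_HIGH_IMPACTS = np.array(
    ["nonsynonymous", "stop_gain", "frameshift", "essential_splice",
     "inframe_indel", "start_codon", "stop_loss", "exon_end"]
)
_HIGH_IMPACT_P = np.array([0.70, 0.08, 0.06, 0.05, 0.04, 0.02, 0.02, 0.03])

# covariate margins per group, from the published cohort characteristics
_AGE_BINS = [(35, 44), (45, 55), (56, 69)]
_AGE_P = {
    "control": (11, 19, 12),
    "ER_neg": (11, 14, 11),
    "ER_pos": (7, 16, 19),
}
_HIST_LEVELS = ("non_proliferative", "proliferative_no_atypia", "atypical_hyperplasia")
_HIST_P = {
    "control": (25, 16, 1),
    "ER_neg": (14, 19, 3),
    "ER_pos": (19, 14, 9),
}
_ATROPHY_LEVELS = (None, "none", "partial", "complete")
_ATROPHY_P = {
    "control": (2, 9, 16, 15),
    "ER_neg": (3, 13, 13, 7),
    "ER_pos": (3, 6, 23, 10),
}
_YEAR_MEAN = {"control": 1986, "ER_neg": 1987, "ER_pos": 1988}


@dataclass
class EffectSpec:
    """A planted gene-level effect: the named group's somatic carrier rate is
    multiplied by ``rate_multiplier`` in ``gene``."""

    gene: str
    group: str
    rate_multiplier: float


@dataclass
class SimulationConfig:
    n_control: int = 42
    n_er_pos: int = 42
    n_er_neg: int = 36
    n_genes: int = 93
    n_germline_snps: int = 150
    common_af_range: tuple[float, float] = (0.05, 0.5)
    n_rare_germline_per_gene: int = 2
    rare_af_range: tuple[float, float] = (1e-4, 0.004)
    # mean artifact calls per sample per substitution category
    artifact_rate_by_category: dict = field(
        default_factory=lambda: {
            "C>A": 1.0, "C>G": 1.0, "C>T": 12.0, "C>T_at_CpG": 6.0,
            "T>A": 1.0, "T>C": 1.0, "T>G": 1.0,
        }
    )
    artifact_aaf_beta: tuple[float, float] = (1.5, 4.0)  # rescaled to (0, 0.2)
    artifact_sites_per_unit_rate: float = 25.0
    het_aaf_sd: float = 0.03
    hom_aaf_sd: float = 0.015
    ref_aaf_sd: float = 0.01
    # measurement noise redrawn per technical replicate; the rest of the
    # AAF deviation is a property of the DNA aliquot and shared
    replicate_aaf_sd: float = 0.003
    somatic_sites_per_gene: int = 6
    somatic_rate: float = 0.05  # per sample per candidate site
    somatic_aaf_range: tuple[float, float] = (0.08, 0.3)
    effect_genes: list = field(default_factory=list)
    purine_strand_prob: float = 0.3
    technical_flag_rate: float = 0.02
    n_replicate_sets: int = 4
    replicates_per_set: int = 2
    mean_umt: float = 600.0
    umt_sd: float = 100.0
    molecular_diversity_mean: float = 6.0
    molecular_diversity_sd: float = 1.5
    cd45_base: float = 35.0
    cd45_sd: float = 12.0
    cd45_burden_coef: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_control, self.n_er_pos, self.n_er_neg) < 1:
            raise ValueError("group sizes must be >= 1")
        genes = {f"GENE{i + 1:03d}" for i in range(self.n_genes)}
        for eff in self.effect_genes:
            e = eff if isinstance(eff, EffectSpec) else EffectSpec(*eff)
            if e.gene not in genes:
                raise ValueError(f"effect gene {e.gene!r} not in the gene list")
            if e.group not in ("control", "ER_pos", "ER_neg"):
                raise ValueError(f"unknown effect group {e.group!r}")
            if e.rate_multiplier < 0:
                raise ValueError("rate multipliers must be >= 0")
        for cat, rate in self.artifact_rate_by_category.items():
            if cat not in MUTATION_CATEGORIES:
                raise ValueError(f"unknown mutation category {cat!r}")
            if rate < 0:
                raise ValueError("artifact rates must be >= 0")


@dataclass
class GroundTruth:
    """Origin labels and planted parameters for one generated dataset."""

    variant_origin: pd.DataFrame  # sample_id + site + origin
    effect_genes: list
    snp_positions: pd.DataFrame  # known common SNP sites (QC panel)
    artifact_fraction_by_category: Optional[dict] = None
    signature_exposures: Optional[pd.DataFrame] = None


_BASES = np.array(list("ACGT"))


def _context_for(ref: str, alt: str, rng: np.random.Generator) -> str:
    """Random trinucleotide context consistent with the pyrimidine-strand
    category of ref>alt."""
    left = rng.choice(_BASES)
    if ref == "C" and alt == "T":
        right = rng.choice(list("ACT"))  # avoid CpG unless asked
    else:
        right = rng.choice(_BASES)
    return f"{left}{ref}{right}"


def _site_from_category(cat: str, rng: np.random.Generator, purine_p: float):
    """(ref, alt, context) realizing a category, possibly on the purine strand."""
    if cat == "C>T_at_CpG":
        ref, alt = "C", "T"
        ctx = f"{rng.choice(_BASES)}CG"
    else:
        ref, alt = cat.split(">")
        ctx = _context_for(ref, alt, rng)
    if rng.random() < purine_p:
        ref, alt, ctx = revcomp(ref), revcomp(alt), revcomp(ctx)
    return ref, alt, ctx


def _random_substitution(rng: np.random.Generator):
    ref = rng.choice(_BASES)
    alt = rng.choice([b for b in "ACGT" if b != ref])
    left, right = rng.choice(_BASES), rng.choice(_BASES)
    return ref, alt, f"{left}{ref}{right}"


def _round6(x: np.ndarray) -> np.ndarray:
    return np.round(np.clip(x, 0.0, 1.0), 6)


def _draw_covariates(group: str, rng: np.random.Generator) -> dict:
    age_p = np.asarray(_AGE_P[group], dtype=float)
    bin_i = rng.choice(3, p=age_p / age_p.sum())
    lo, hi = _AGE_BINS[bin_i]
    hist_p = np.asarray(_HIST_P[group], dtype=float)
    atro_p = np.asarray(_ATROPHY_P[group], dtype=float)
    return {
        "age": float(rng.integers(lo, hi + 1)),
        "histology": _HIST_LEVELS[rng.choice(3, p=hist_p / hist_p.sum())],
        "atrophy": _ATROPHY_LEVELS[rng.choice(4, p=atro_p / atro_p.sum())],
        "epithelial_pct": float(np.round(rng.uniform(5, 40), 1)),
        "biopsy_year": int(np.clip(round(rng.normal(_YEAR_MEAN[group], 8)), 1969, 2001)),
    }


def _build_sites(config: SimulationConfig, rng: np.random.Generator):
    """Site catalogs: known SNPs, rare germline, somatic, artifact sites."""
    genes = [f"GENE{i + 1:03d}" for i in range(config.n_genes)]
    rows_snp, rows_rare, rows_som, rows_art = [], [], [], []
    for j in range(config.n_germline_snps):
        gene = genes[j % len(genes)]
        ref, alt, ctx = _random_substitution(rng)
        rows_snp.append(
            dict(chrom="1", pos=(j % len(genes) + 1) * 1_000_000 + 1_000 + j,
                 ref=ref, alt=alt, context=ctx, gene=gene,
                 rsid=f"rs{100000 + j}",
                 population_af=float(np.round(rng.uniform(*config.common_af_range), 4)),
                 impact=("low_impact" if rng.random() < 0.8 else "nonsynonymous"))
        )
    counter = 0
    for gi, gene in enumerate(genes):
        base = (gi + 1) * 1_000_000
        for k in range(config.n_rare_germline_per_gene):
            ref, alt, ctx = _random_substitution(rng)
            rows_rare.append(
                dict(chrom="1", pos=base + 5_000 + k, ref=ref, alt=alt,
                     context=ctx, gene=gene,
                     rsid=(f"rs{900000 + counter}" if rng.random() < 0.5 else None),
                     population_af=float(rng.uniform(*config.rare_af_range)),
                     impact=str(rng.choice(_HIGH_IMPACTS, p=_HIGH_IMPACT_P)))
            )
            counter += 1
        for k in range(config.somatic_sites_per_gene):
            ref, alt, ctx = _random_substitution(rng)
            rows_som.append(
                dict(chrom="1", pos=base + 10_000 + k, ref=ref, alt=alt,
                     context=ctx, gene=gene, rsid=None, population_af=np.nan,
                     impact=str(rng.choice(_HIGH_IMPACTS, p=_HIGH_IMPACT_P)))
            )
    ai = 0
    for cat, rate in config.artifact_rate_by_category.items():
        n_sites = max(1, int(round(rate * config.artifact_sites_per_unit_rate)))
        per_site_rate = rate / n_sites
        for _ in range(n_sites):
            gi = int(rng.integers(len(genes)))
            ref, alt, ctx = _site_from_category(cat, rng, config.purine_strand_prob)
            rows_art.append(
                dict(chrom="1", pos=(gi + 1) * 1_000_000 + 20_000 + ai,
                     ref=ref, alt=alt, context=ctx, gene=genes[gi], rsid=None,
                     population_af=np.nan,
                     impact=str(rng.choice(_HIGH_IMPACTS, p=_HIGH_IMPACT_P))
                     if rng.random() < 0.85 else "low_impact",
                     carrier_rate=per_site_rate)
            )
            ai += 1
    return (pd.DataFrame(rows_snp), pd.DataFrame(rows_rare),
            pd.DataFrame(rows_som), pd.DataFrame(rows_art))


def _hwe_genotypes(af: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """n x len(af) genotype dosage (0/1/2) from Hardy-Weinberg."""
    u = rng.random((n, af.size))
    p_hom_ref = (1 - af) ** 2
    p_het = 2 * af * (1 - af)
    return (u >= p_hom_ref).astype(int) + (u >= p_hom_ref + p_het).astype(int)


def _germline_aaf(gt: np.ndarray, config: SimulationConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Genotype-consistent AAF: noise around 0 / 0.5 / 1."""
    noise_ref = np.abs(rng.normal(0, config.ref_aaf_sd, gt.shape))
    noise_het = rng.normal(0.5, config.het_aaf_sd, gt.shape)
    noise_hom = 1 - np.abs(rng.normal(0, config.hom_aaf_sd, gt.shape))
    return np.select([gt == 0, gt == 1], [noise_ref, noise_het], noise_hom)


def generate_cohort(
    config: Optional[SimulationConfig] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (sample sheet, variant table, ground truth) for one cohort.

    Deterministic given the seed.  The sample sheet includes technical
    replicate rows (shared ``replicate_set``) and a computed SNP call rate;
    the variant table is analysis-ready (category classified, technical
    flags mostly empty).
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    groups = (["control"] * config.n_control + ["ER_pos"] * config.n_er_pos
              + ["ER_neg"] * config.n_er_neg)
    n = len(groups)
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    snp_sites, rare_sites, som_sites, art_sites = _build_sites(config, rng)

    effects = [e if isinstance(e, EffectSpec) else EffectSpec(*e)
               for e in config.effect_genes]
    eff_map: dict[tuple[str, str], float] = {}
    for e in effects:
        eff_map[(e.gene, e.group)] = eff_map.get((e.gene, e.group), 1.0) * e.rate_multiplier

    site_cols = ["chrom", "pos", "ref", "alt", "rsid", "gene", "impact",
                 "population_af", "context"]

    def _emit(site_row, sid, aaf, origin, depth, flag=""):
        rec = {c: site_row[c] for c in site_cols}
        rec.update(sample_id=sid, aaf=aaf, umt_depth=depth,
                   technical_flags=flag, origin=origin)
        return rec

    # shared germline state so replicates can reuse it
    snp_af = snp_sites["population_af"].to_numpy()
    snp_gt = _hwe_genotypes(snp_af, n, rng)
    rare_af = rare_sites["population_af"].to_numpy()
    rare_gt = _hwe_genotypes(rare_af, n, rng)
    som_rate = np.full((n, len(som_sites)), config.somatic_rate)
    som_genes = som_sites["gene"].to_numpy()
    for si, grp in enumerate(groups):
        for j, gene in enumerate(som_genes):
            mult = eff_map.get((gene, grp))
            if mult is not None:
                som_rate[si, j] = min(1.0, config.somatic_rate * mult)
    som_carrier = rng.random(som_rate.shape) < som_rate
    som_aaf_val = rng.uniform(*config.somatic_aaf_range, som_rate.shape)

    mean_umt = np.maximum(rng.normal(config.mean_umt, config.umt_sd, n), 50.0)
    diversity = np.clip(
        rng.normal(config.molecular_diversity_mean,
                   config.molecular_diversity_sd, n), 2.0, 30.0)

    art_rate = art_sites["carrier_rate"].to_numpy() if len(art_sites) else np.array([])
    snp_recs = snp_sites.to_dict("records")
    rare_recs = rare_sites.to_dict("records")
    som_recs = som_sites.to_dict("records")
    art_recs = art_sites.to_dict("records")
    flag_pool = ["strand_bias", "low_complexity", "low_base_quality",
                 "shallow_mt_coverage"]

    # base germline AAF (genotype noise shared by replicates of a sample)
    snp_aaf_base = _germline_aaf(snp_gt, config, rng)
    rare_aaf_base = _germline_aaf(rare_gt, config, rng)

    def _sample_calls(si: int, sid: str, redraw_rng: np.random.Generator) -> list[dict]:
        depth = int(round(mean_umt[si]))
        rows = []
        aafs = _round6(
            snp_aaf_base[si]
            + redraw_rng.normal(0, config.replicate_aaf_sd, snp_aaf_base.shape[1])
        )
        for j, site in enumerate(snp_recs):
            rows.append(_emit(site, sid, float(aafs[j]), "germline", depth))
        rare_aafs = _round6(
            rare_aaf_base[si]
            + redraw_rng.normal(0, config.replicate_aaf_sd, rare_aaf_base.shape[1])
        )
        for j, site in enumerate(rare_recs):
            if rare_gt[si, j] > 0:
                rows.append(_emit(site, sid, float(rare_aafs[j]), "germline", depth))
        for j, site in enumerate(som_recs):
            if som_carrier[si, j]:
                rows.append(_emit(site, sid,
                                  float(np.round(som_aaf_val[si, j], 6)),
                                  "somatic_true", depth))
        if art_recs:
            hit = np.flatnonzero(redraw_rng.random(len(art_recs)) < art_rate)
            a, b = config.artifact_aaf_beta
            aaf_art = 0.2 * redraw_rng.beta(a, b, hit.size)
            flagged = redraw_rng.random(hit.size) < config.technical_flag_rate
            for k, j in enumerate(hit):
                flag = str(redraw_rng.choice(flag_pool)) if flagged[k] else ""
                rows.append(_emit(art_recs[j], sid,
                                  float(np.round(aaf_art[k], 6)),
                                  "ffpe_artifact", depth, flag))
        return rows

    all_rows: list[dict] = []
    sheet_rows: list[dict] = []
    for si, (sid, grp) in enumerate(zip(sample_ids, groups)):
        all_rows.extend(_sample_calls(si, sid, rng))
        cov = _draw_covariates(grp, rng)
        n_som = int(som_carrier[si].sum())
        cd45 = max(0.0, rng.normal(config.cd45_base, config.cd45_sd)
                   + config.cd45_burden_coef * n_som)
        sheet_rows.append(
            dict(sample_id=sid, group=grp, **cov,
                 mean_umt_coverage=float(np.round(mean_umt[si], 1)),
                 mean_raw_coverage=float(np.round(mean_umt[si] * 100 / diversity[si], 1)),
                 molecular_diversity=float(np.round(diversity[si], 2)),
                 replicate_set=None,
                 cd45_hscore=float(np.round(min(cd45, 300.0), 1)),
                 ki67_pct=float(np.round(abs(rng.normal(1.0, 1.0)), 2)))
        )

    # technical replicates: same germline genotypes and somatic calls,
    # artifacts and AAF noise redrawn
    for r in range(config.n_replicate_sets):
        si = r % n
        src = sheet_rows[si]
        src["replicate_set"] = f"repset{r + 1}"
        for k in range(1, config.replicates_per_set):
            rep_id = f"{sample_ids[si]}_rep{k}"
            all_rows.extend(_sample_calls(si, rep_id, rng))
            rep_row = dict(src)
            rep_row.update(sample_id=rep_id, replicate_set=f"repset{r + 1}")
            sheet_rows.append(rep_row)

    variants = pd.DataFrame(all_rows)
    variants = classify_variant_table(variants)
    origin = variants[["sample_id", "chrom", "pos", "ref", "alt", "origin"]].copy()
    variants = variants[VARIANT_COLUMNS]
    sheet = pd.DataFrame(sheet_rows)
    sheet = sample_qc(sheet, snp_sites[["chrom", "pos", "ref", "alt"]], variants)
    truth = GroundTruth(
        variant_origin=origin,
        effect_genes=effects,
        snp_positions=snp_sites[["chrom", "pos", "ref", "alt", "rsid",
                                 "population_af"]].copy(),
    )
    return sheet, variants, truth


def generate_paired_ffpe_frozen(
    n_pairs: int = 4,
    calls_per_category: Union[int, dict] = 600,
    artifact_fraction_by_category: Optional[dict] = None,
    seed: int = 0,
    purine_strand_prob: float = 0.3,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Paired FFPE / fresh-frozen call sets with planted artifact fractions.

    The frozen member of each pair carries only the true calls; the FFPE
    member carries the true calls plus artifacts, so the per-category FFPE
    false discovery rate equals the planted artifact fraction in
    expectation.  Defaults plant the C>T-dominated pattern typical of
    formalin fixation (0.6 for C>T, 0.25 for C>T at CpG, 0.1 elsewhere).
    """
    rng = np.random.default_rng(seed)
    if artifact_fraction_by_category is None:
        artifact_fraction_by_category = {
            c: (0.6 if c == "C>T" else 0.25 if c == "C>T_at_CpG" else 0.1)
            for c in MUTATION_CATEGORIES
        }
    ffpe_rows, frozen_rows = [], []
    realized = {}
    pos = 1_000
    for ci, cat in enumerate(MUTATION_CATEGORIES):
        n_calls = (calls_per_category if isinstance(calls_per_category, int)
                   else calls_per_category.get(cat, 0))
        frac = artifact_fraction_by_category.get(cat, 0.0)
        is_art = rng.random(n_calls) < frac
        realized[cat] = float(np.mean(is_art)) if n_calls else np.nan
        for j in range(n_calls):
            pair = f"P{1 + int(rng.integers(n_pairs))}"
            ref, alt, ctx = _site_from_category(cat, rng, purine_strand_prob)
            pos += 1
            base = dict(chrom="1", pos=pos, ref=ref, alt=alt, context=ctx,
                        gene=f"GENE{1 + (pos % 93):03d}", rsid=None,
                        population_af=np.nan, impact="nonsynonymous",
                        umt_depth=500, technical_flags="", pair_id=pair)
            if is_art[j]:
                aaf = float(np.round(0.2 * rng.beta(1.5, 4.0), 6))
                ffpe_rows.append(dict(base, sample_id=f"{pair}_FFPE", aaf=aaf,
                                      origin="ffpe_artifact"))
            else:
                aaf = float(np.round(rng.uniform(0.2, 0.9), 6))
                ffpe_rows.append(dict(base, sample_id=f"{pair}_FFPE", aaf=aaf,
                                      origin="somatic_true"))
                frozen_rows.append(dict(base, sample_id=f"{pair}_FROZEN",
                                        aaf=aaf, origin="somatic_true"))
    cols = VARIANT_COLUMNS + ["pair_id", "origin"]
    ffpe = classify_variant_table(pd.DataFrame(ffpe_rows))[cols]
    frozen = classify_variant_table(pd.DataFrame(frozen_rows))[cols]
    origin = pd.concat([ffpe, frozen])[
        ["sample_id", "chrom", "pos", "ref", "alt", "origin"]
    ].reset_index(drop=True)
    truth = GroundTruth(
        variant_origin=origin, effect_genes=[],
        snp_positions=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        artifact_fraction_by_category={
            "planted": dict(artifact_fraction_by_category), "realized": realized
        },
    )
    return ffpe, frozen, truth


def generate_signature_cohort(
    signature_profiles: Union[pd.DataFrame, np.ndarray],
    exposures: Union[pd.DataFrame, np.ndarray],
    n_mutations_per_sample: Union[int, Sequence[int]] = 500,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-sample category-count spectra from known signature mixtures.

    Each sample's counts are multinomial draws from its exposure-weighted
    mixture of column-stochastic signature profiles.
    """
    rng = np.random.default_rng(seed)
    if isinstance(signature_profiles, pd.DataFrame):
        categories = list(signature_profiles.index)
        P = signature_profiles.to_numpy(dtype=float)
    else:
        P = np.asarray(signature_profiles, dtype=float)
        categories = list(MUTATION_CATEGORIES[: P.shape[0]]) if P.shape[0] <= 7 \
            else [f"cat{i}" for i in range(P.shape[0])]
    E = (exposures.to_numpy(dtype=float) if isinstance(exposures, pd.DataFrame)
         else np.asarray(exposures, dtype=float))
    if E.ndim != 2 or P.ndim != 2 or E.shape[1] != P.shape[1]:
        raise ValueError("exposures must be samples x K matching profile columns")
    if np.any(P < 0) or not np.allclose(P.sum(axis=0), 1.0, atol=1e-8):
        raise ValueError("signature profiles must be column-stochastic")
    if np.any(E < 0):
        raise ValueError("exposures must be non-negative")
    n_samples = E.shape[0]
    n_mut = (np.full(n_samples, n_mutations_per_sample, dtype=int)
             if np.isscalar(n_mutations_per_sample)
             else np.asarray(n_mutations_per_sample, dtype=int))
    counts = np.zeros((n_samples, P.shape[0]), dtype=int)
    for i in range(n_samples):
        mix = P @ E[i]
        total = mix.sum()
        if total <= 0:
            continue
        counts[i] = rng.multinomial(n_mut[i], mix / total)
    spectrum = pd.DataFrame(
        counts, index=[f"S{i + 1:03d}" for i in range(n_samples)],
        columns=categories)
    Edf = pd.DataFrame(E, index=spectrum.index,
                       columns=[f"sig{k + 1}" for k in range(E.shape[1])])
    truth = GroundTruth(
        variant_origin=pd.DataFrame(
            columns=["sample_id", "chrom", "pos", "ref", "alt", "origin"]),
        effect_genes=[],
        snp_positions=pd.DataFrame(columns=["chrom", "pos", "ref", "alt"]),
        signature_exposures=Edf,
    )
    return spectrum, truth
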