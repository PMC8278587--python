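"""QC chain: genotype bins, sample acceptance, replicate identity, FDR
estimation, AAF filter strategies and population-AF concordance."""

import numpy as np
import pandas as pd
import pytest

import bbdburden as bb
from bbdburden.qc import (
    apply_aaf_filter,
    call_genotype,
    estimate_fdr,
    filter_technical,
    population_af_concordance,
    replicate_identity,
    sample_qc,
)
from bbdburden.variants import classify_variant_table


# --------------------------------------------------------------------------
# genotype calling


@pytest.mark.parametrize(
    "aaf,expected",
    [
        (0.50, "het"),
        (0.30, "no_call"),
        (1.00, "hom_alt"),
        (0.0, "hom_ref"),
        (0.2, "hom_ref"),   # bin endpoints inclusive
        (0.4, "het"),
        (0.6, "het"),
        (0.8, "hom_alt"),
        (0.21, "no_call"),
        (0.79, "no_call"),
    ],
)
def test_call_genotype_bins(aaf, expected):
    assert call_genotype(aaf) == expected


def test_call_genotype_rejects_out_of_range():
    with pytest.raises(ValueError):
        call_genotype(1.2)


# --------------------------------------------------------------------------
# technical flags


def test_filter_technical_counts(toy_variants):
    flagged = toy_variants.copy()
    flagged.loc[flagged.index[:3], "technical_flags"] = "strand_bias"
    out = filter_technical(flagged)
    assert len(out) == len(flagged) - 3
    assert filter_technical(toy_variants).shape[0] == len(toy_variants)


# --------------------------------------------------------------------------
# sample acceptance


def test_sample_qc_rules():
    snps = pd.DataFrame(
        {"chrom": "1", "pos": [10, 20, 30, 40, 50],
         "ref": list("ACGTA"), "alt": list("CATAG")}
    )
    samples = pd.DataFrame(
        {
            "sample_id": ["low_cov", "low_rate", "good"],
            "mean_umt_coverage": [19.5, 100.0, 100.0],
        }
    )
    rows = []
    # low_cov and good have callable genotypes everywhere; low_rate sits
    # between bins at 4 of 5 SNPs (call rate 0.2 < 0.8)
    for sid, aafs in [
        ("low_cov", [0.0, 0.5, 1.0, 0.5, 0.0]),
        ("low_rate", [0.3, 0.3, 0.25, 0.7, 0.5]),
        ("good", [0.0, 0.5, 1.0, 1.0, 0.0]),
    ]:
        for (pos, ref, alt), aaf in zip(zip(snps.pos, snps.ref, snps.alt), aafs):
            rows.append(dict(sample_id=sid, chrom="1", pos=pos, ref=ref,
                             alt=alt, aaf=aaf))
    variants = pd.DataFrame(rows)
    out = sample_qc(samples, snps, variants)
    res = out.set_index("sample_id")
    assert not res.loc["low_cov", "qc_pass"]
    assert "mean_umt_coverage" in res.loc["low_cov", "qc_reasons"]
    assert not res.loc["low_rate", "qc_pass"]
    assert "snp_call_rate" in res.loc["low_rate", "qc_reasons"]
    assert res.loc["good", "qc_pass"]
    assert res.loc["low_rate", "snp_call_rate"] == pytest.approx(0.2)


# --------------------------------------------------------------------------
# replicate identity


def test_replicate_identity_extremes():
    x = np.array([0.0, 0.1, 0.5, 0.52, 0.9, 1.0])
    mat = pd.DataFrame(
        [x, x, x[::-1]], index=["a", "a2", "rev"],
    )
    cmat, verdicts = replicate_identity(mat)
    v = verdicts.set_index(["sample_a", "sample_b"])
    assert cmat.loc["a", "a2"] == pytest.approx(1.0)
    assert v.loc[("a", "a2"), "same_source"]
    assert cmat.loc["a", "rev"] == pytest.approx(-1.0)
    assert not v.loc[("a", "rev"), "same_source"]


def test_replicate_identity_constant_profile_missing():
    mat = pd.DataFrame([[0.5, 0.5, 0.5], [0.1, 0.5, 0.9]], index=["c", "v"])
    with pytest.warns(UserWarning, match="constant"):
        _, verdicts = replicate_identity(mat)
    assert verdicts["same_source"].iloc[0] is None


def test_synthetic_replicates_separate_from_unrelated(small_cohort):
    """Replicate pairs share germline genotypes -> rank correlation near 1;
    unrelated pairs sit well below the 0.85 decision threshold."""
    _, sheet, variants, truth = small_cohort
    snps = truth.snp_positions[["chrom", "pos", "ref", "alt"]]
    from bbdburden.qc import _snp_aaf_matrix

    mat = _snp_aaf_matrix(sheet, variants, snps)
    cmat, verdicts = replicate_identity(mat)
    reps = sheet.dropna(subset=["replicate_set"]).groupby("replicate_set")
    rep_pairs = set()
    for _, grp in reps:
        ids = sorted(grp["sample_id"])
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                rep_pairs.add((ids[i], ids[j]))
    assert rep_pairs
    for a, b in rep_pairs:
        assert cmat.loc[a, b] > 0.85
    unrelated = verdicts[
        ~verdicts.apply(
            lambda r: (r.sample_a, r.sample_b) in rep_pairs
            or (r.sample_b, r.sample_a) in rep_pairs,
            axis=1,
        )
    ]
    assert (unrelated["correlation"] < 0.85).all()


# --------------------------------------------------------------------------
# FFPE FDR estimation


def _paired_fixture():
    rows_ffpe, rows_frozen = [], []
    for i in range(10):
        base = dict(chrom="1", pos=100 + i, ref="C", alt="T", context="ACA",
                    gene="G1", rsid=None, impact="nonsynonymous",
                    population_af=np.nan, umt_depth=100, technical_flags="",
                    aaf=0.3, pair_id="P1")
        rows_ffpe.append(dict(base, sample_id="P1_F"))
        if i >= 3:  # 3 of 10 are FFPE-only
            rows_frozen.append(dict(base, sample_id="P1_Z"))
    ffpe = classify_variant_table(pd.DataFrame(rows_ffpe))
    frozen = classify_variant_table(pd.DataFrame(rows_frozen))
    return ffpe, frozen


def test_estimate_fdr_direct_ratio():
    ffpe, frozen = _paired_fixture()
    tab = estimate_fdr(ffpe, frozen).set_index("category")
    assert tab.loc["C>T", "fdr"] == pytest.approx(0.30)
    assert tab.loc["C>T", "n_ffpe_calls"] == 10
    # categories absent from the FFPE set are missing, not zero
    assert np.isnan(tab.loc["T>A", "fdr"])


def test_estimate_fdr_order_invariance():
    ffpe, frozen = _paired_fixture()
    shuffled = ffpe.sample(frac=1, random_state=1)
    a = estimate_fdr(ffpe, frozen)
    b = estimate_fdr(shuffled, frozen)
    pd.testing.assert_frame_equal(a, b)


def test_estimate_fdr_recovers_planted_fraction():
    ffpe, frozen, truth = bb.generate_paired_ffpe_frozen(
        calls_per_category=600, seed=5
    )
    tab = estimate_fdr(ffpe, frozen).set_index("category")
    for cat, frac in truth.artifact_fraction_by_category["planted"].items():
        n = tab.loc[cat, "n_ffpe_calls"]
        half = 1.96 * np.sqrt(frac * (1 - frac) / n)
        assert abs(tab.loc[cat, "fdr"] - frac) < half + 1e-9, cat


def test_estimate_fdr_aaf_binned():
    """With AAF bins the FDR concentrates in the low-AAF bin, since true
    calls sit above 0.2 in this fixture."""
    ffpe, frozen, _ = bb.generate_paired_ffpe_frozen(
        calls_per_category=300, seed=9)
    tab = bb.estimate_fdr(ffpe, frozen, aaf_bins=[0.0, 0.2, 1.0])
    assert {"category", "aaf_bin", "fdr"} <= set(tab.columns)
    ct = tab[tab["category"] == "C>T"].sort_values("aaf_bin")
    low, high = ct["fdr"].to_numpy()
    assert low == 1.0 and high == 0.0  # artifacts below 0.2, truth above


def test_zero_artifacts_gives_identical_sets():
    ffpe, frozen, _ = bb.generate_paired_ffpe_frozen(
        calls_per_category=100,
        artifact_fraction_by_category={c: 0.0 for c in bb.MUTATION_CATEGORIES},
        seed=2,
    )
    key = ["pair_id", "chrom", "pos", "ref", "alt"]
    assert set(map(tuple, ffpe[key].values)) == set(map(tuple, frozen[key].values))
    tab = estimate_fdr(ffpe, frozen)
    assert (tab["fdr"].dropna() == 0).all()


# --------------------------------------------------------------------------
# AAF filter strategies


def test_filter_examples(toy_variants):
    classical = apply_aaf_filter(toy_variants, "classical")
    keys = set(classical["pos"])
    assert 101 not in keys      # C>T, aaf 0.07, no rsID -> removed
    assert 102 in keys          # same but rsID-annotated -> kept
    assert 105 in keys          # T>A 0.07 kept under classical
    strict = apply_aaf_filter(toy_variants, "strict")
    assert 105 not in set(strict["pos"])  # removed under strict
    liberal = apply_aaf_filter(toy_variants, "liberal")
    assert 100 not in set(liberal["pos"])  # aaf 0.04 removed everywhere


def test_filter_nesting_and_idempotence(toy_variants):
    rng = np.random.default_rng(0)
    for _ in range(50):
        t = toy_variants.copy()
        t["aaf"] = rng.uniform(0, 0.3, len(t)).round(3)
        t["rsid"] = np.where(rng.random(len(t)) < 0.3, "rs77", None)
        lib = apply_aaf_filter(t, "liberal")
        cla = apply_aaf_filter(t, "classical")
        stc = apply_aaf_filter(t, "strict")
        k = lambda d: set(map(tuple, d[["sample_id", "pos"]].values))
        assert k(stc) <= k(cla) <= k(lib)
        for strat, res in [("liberal", lib), ("classical", cla), ("strict", stc)]:
            again = apply_aaf_filter(res, strat)
            assert k(again) == k(res)


def test_filter_unknown_strategy(toy_variants):
    with pytest.raises(ValueError):
        apply_aaf_filter(toy_variants, "medium")


# --------------------------------------------------------------------------
# population AF concordance


def test_concordance_perfect_and_structure(small_cohort):
    _, sheet, variants, truth = small_cohort
    out = population_af_concordance(variants, sheet, by_category=True)
    overall = out[out["category"] == "all"].iloc[0]
    assert overall["correlation"] > 0.9   # germline-dominated cohort
    assert (out["category"] != "all").sum() >= 3


def test_concordance_exact_match():
    rows = []
    rng = np.random.default_rng(3)
    samples = pd.DataFrame({"sample_id": [f"S{i}" for i in range(40)],
                            "group": "control"})
    for j, p in enumerate([0.1, 0.2, 0.3, 0.4, 0.5]):
        # make the cohort genotype frequency exactly match population_af:
        # 2*p*40 alleles -> p*40 het carriers among 40 samples
        n_het = int(round(2 * p * 40 / 1))
        for i in range(40):
            aaf = 0.5 if i < n_het // 2 else 0.0
            rows.append(dict(sample_id=f"S{i}", chrom="1", pos=j, ref="A",
                             alt="C", aaf=aaf, rsid=f"rs{j}",
                             population_af=p, category="T>G"))
    variants = pd.DataFrame(rows)
    out = population_af_concordance(variants, samples)
    assert out.iloc[0]["correlation"] == pytest.approx(1.0)
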