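"""Variant weighting, gene burden, logistic burden regression and the
12-combination driver."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bbdburden as bb
from bbdburden.association import (
    build_covariates,
    compute_weights,
    gene_burden,
    logistic_burden_test,
    run_all_combinations,
)


def _sites(cats, freqs=None):
    n = len(cats)
    return pd.DataFrame(
        {
            "category": cats,
            "cohort_af": freqs if freqs is not None else [0.05] * n,
        }
    )


class TestWeights:
    def test_logistic_default_is_unit(self, fdr_table):
        w = compute_weights(_sites(["C>T", "T>A", None]), fdr_table,
                            "default", "logistic")
        assert (w == 1.0).all()

    def test_fdr_downweighting_orders_categories(self):
        fdr = pd.DataFrame({"category": ["C>T", "T>A"], "fdr": [0.6, 0.1]})
        w = compute_weights(_sites(["C>T", "T>A"]), fdr,
                            "fdr_downweighted", "logistic")
        assert w.tolist() == pytest.approx([0.4, 0.9])

    def test_zero_fdr_is_identity_and_indels_unscaled(self):
        fdr = pd.DataFrame({"category": ["C>T"], "fdr": [0.0]})
        w = compute_weights(_sites(["C>T", None]), fdr,
                            "fdr_downweighted", "logistic")
        assert w.tolist() == pytest.approx([1.0, 1.0])

    def test_missing_category_fdr_raises(self):
        fdr = pd.DataFrame({"category": ["C>T"], "fdr": [0.5]})
        with pytest.raises(ValueError, match="T>A"):
            compute_weights(_sites(["T>A"]), fdr, "fdr_downweighted", "logistic")

    def test_skat_weights_follow_beta_density(self):
        w = compute_weights(_sites(["C>T", "C>T"], [0.01, 0.2]), None,
                            "default", "skat")
        ref = stats.beta.pdf([0.01, 0.2], 1, 25)
        assert w.to_numpy() == pytest.approx(ref)
        assert w.iloc[0] > w.iloc[1]  # rarer variants weigh more


class TestGeneBurden:
    def test_weighted_sum_arithmetic(self, toy_variants):
        ids = ["A", "B"]
        burden, presence = gene_burden(toy_variants, ids, "GENE001")
        a = toy_variants[toy_variants.sample_id == "A"]["aaf"].sum()
        assert burden["A"] == pytest.approx(a)
        w = pd.Series(0.5, index=presence.columns)
        half, _ = gene_burden(toy_variants, ids, "GENE001", w)
        assert half["A"] == pytest.approx(a / 2)

    def test_absent_sample_zero(self, toy_variants):
        burden, presence = gene_burden(toy_variants, ["A", "B", "C"], "GENE001")
        assert burden["C"] == 0.0
        assert presence.loc["C"].sum() == 0


class TestLogisticBurden:
    def test_two_by_two_matches_cross_product_odds_ratio(self):
        """Binary burden without covariates reduces to the 2x2 table:
        cases 8 exposed / 12 unexposed, controls 3 / 17."""
        y = np.array([1.0] * 20 + [0.0] * 20)
        b = np.array([1.0] * 8 + [0.0] * 12 + [1.0] * 3 + [0.0] * 17)
        out = logistic_burden_test(b, y)
        assert out["converged"]
        assert out["odds_ratio"] == pytest.approx(8 * 17 / (12 * 3), abs=1e-6)

    def test_constant_burden_untestable(self):
        y = np.array([1.0, 0.0] * 10)
        out = logistic_burden_test(np.ones(20), y)
        assert not out["testable"]

    def test_separated_burden_flagged(self):
        y = np.array([1.0] * 10 + [0.0] * 10)
        b = y.copy()  # perfect separation
        out = logistic_burden_test(b, y)
        assert not out["converged"] and np.isnan(out["p_value"])

    def test_planted_log_odds_recovery(self):
        """With a planted burden coefficient the estimate lands within
        2 SE in the large majority of replicates."""
        rng = np.random.default_rng(8)
        hits = 0
        n_rep = 60
        for _ in range(n_rep):
            n = 400
            b = rng.exponential(1.0, n)
            logit = -0.5 * b + 0.2
            y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
            out = logistic_burden_test(b, y)
            beta = np.log(out["odds_ratio"])
            se = (np.log(out["or_ci_high"]) - np.log(out["or_ci_low"])) / (2 * 1.96)
            hits += abs(beta - (-0.5)) < 2 * se
        assert hits / n_rep >= 0.90


def test_covariate_design_drops_aliased_columns():
    sheet = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(12)],
            "epithelial_pct": np.arange(12, dtype=float),
            "histology": ["non_proliferative"] * 12,
            "age": 50.0,
            "biopsy_year": [1990] * 12,  # constant year: post1992 aliased
            "snp_call_rate": 0.99,
        }
    )
    with pytest.warns(UserWarning, match="aliased"):
        X, dropped = build_covariates(sheet)
    assert dropped
    M = np.column_stack([np.ones(len(X))] + [X[c] for c in X.columns])
    assert np.linalg.matrix_rank(M) == M.shape[1]


class TestRunAllCombinations:
    def test_row_bookkeeping(self, small_cohort, fdr_table):
        _, sheet, variants, _ = small_cohort
        genes = [f"GENE{i:03d}" for i in range(1, 4)]
        res = run_all_combinations(variants, sheet, fdr_table=fdr_table,
                                   genes=genes)
        assert len(res) == 36  # 3 genes x 3 strategies x 4 methods
        from bbdburden.association import METHODS

        assert set(res["method"].unique()) == set(METHODS)
        counts = res.groupby(["gene"]).size()
        assert (counts == 12).all()

    def test_sample_order_invariance(self, small_cohort, fdr_table):
        _, sheet, variants, _ = small_cohort
        res1 = run_all_combinations(variants, sheet, fdr_table=fdr_table,
                                    genes=["GENE001"])
        res2 = run_all_combinations(
            variants.sample(frac=1, random_state=0),
            sheet.sample(frac=1, random_state=1),
            fdr_table=fdr_table, genes=["GENE001"],
        )
        key = ["gene", "strategy", "method"]
        a = res1.set_index(key)["p_value"].sort_index()
        b = res2.set_index(key)["p_value"].sort_index()
        assert np.allclose(a, b, equal_nan=True, atol=1e-10)

    def test_downweight_to_zero_equals_removal(self, small_cohort):
        """FDR 1.0 for a category zeroes its weight; results equal running
        on a table with those variants dropped."""
        _, sheet, variants, _ = small_cohort
        fdr = pd.DataFrame({"category": list(bb.MUTATION_CATEGORIES),
                            "fdr": [1.0 if c == "C>A" else 0.2
                                    for c in bb.MUTATION_CATEGORIES]})
        res = run_all_combinations(variants, sheet, fdr_table=fdr,
                                   genes=["GENE001"],
                                   methods=("logistic_weighted",))
        dropped = variants[variants["category"] != "C>A"]
        res2 = run_all_combinations(dropped, sheet, fdr_table=fdr,
                                    genes=["GENE001"],
                                    methods=("logistic_weighted",))
        a = res.set_index("strategy")["p_value"]
        b = res2.set_index("strategy")["p_value"]
        assert np.allclose(a, b, equal_nan=True, atol=1e-10)

    def test_contrast_subsetting(self, small_cohort, fdr_table):
        _, sheet, variants, _ = small_cohort
        res = run_all_combinations(variants, sheet, contrast="er_neg_vs_control",
                                   fdr_table=fdr_table, genes=["GENE002"])
        assert (res["contrast"] == "er_neg_vs_control").all()
        with pytest.raises(ValueError, match="contrast"):
            run_all_combinations(variants, sheet, contrast="bogus",
                                 fdr_table=fdr_table)
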