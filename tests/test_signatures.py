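"""Mutation spectra, NMF signature extraction and exposure associations."""

import numpy as np
import pandas as pd
import pytest

import bbdburden as bb
from bbdburden.signatures import (
    TRINUCLEOTIDE_96,
    associate_exposures,
    compare_to_catalog,
    cosine_similarity,
    nmf_extract,
    spectrum_table,
)
from bbdburden.variants import MUTATION_CATEGORIES


class TestSpectrum:
    def test_counts_per_sample(self, toy_variants):
        spec = spectrum_table(toy_variants)
        assert list(spec.columns) == list(MUTATION_CATEGORIES)
        assert spec.loc["A"].sum() == (toy_variants.sample_id == "A").sum()
        a = toy_variants[toy_variants.sample_id == "A"]
        assert spec.loc["A", "C>T"] == (a["category"] == "C>T").sum()

    def test_empty_sample_zero_row(self, toy_variants):
        t = toy_variants.copy()
        t.loc[t.sample_id == "B", "category"] = None  # B has no classified SNVs
        spec = spectrum_table(t)
        assert (spec.loc["B"] == 0).all()

    def test_scheme_change_preserves_row_sums(self, toy_variants):
        seven = spectrum_table(toy_variants, "seven_category")
        tri = spectrum_table(toy_variants, "trinucleotide_96")
        assert list(tri.columns) == list(TRINUCLEOTIDE_96)
        assert (seven.sum(axis=1) == tri.sum(axis=1)).all()

    def test_missing_context_raises_under_tri96(self, toy_variants):
        t = toy_variants.copy()
        t.loc[0, "context"] = None
        with pytest.raises(ValueError, match="context"):
            spectrum_table(t, "trinucleotide_96")


class TestCosine:
    def test_known_values(self):
        assert cosine_similarity([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.random(7), rng.random(7)
            assert cosine_similarity(a, b) == pytest.approx(cosine_similarity(b, a))
            assert cosine_similarity(3.7 * a, b) == pytest.approx(
                cosine_similarity(a, b))

    def test_zero_vector_missing(self):
        assert np.isnan(cosine_similarity([0, 0], [1, 1]))


class TestNmf:
    def test_rank1_exact_recovery(self):
        profile = np.array([0.05, 0.05, 0.5, 0.25, 0.05, 0.05, 0.05])
        rng = np.random.default_rng(1)
        scale = rng.integers(50, 500, 12)
        spectrum = pd.DataFrame(
            np.outer(scale, profile), columns=list(MUTATION_CATEGORIES))
        res = nmf_extract(spectrum, k=1, n_restarts=5, seed=0)
        assert res.reconstruction_error < 1e-4
        assert cosine_similarity(
            res.signatures.iloc[:, 0].to_numpy(), profile) > 0.9999

    def test_disjoint_signatures_recovered(self):
        sigs = np.zeros((7, 2))
        sigs[:3, 0] = [0.5, 0.3, 0.2]
        sigs[3:, 1] = [0.4, 0.3, 0.2, 0.1]
        rng = np.random.default_rng(2)
        expo = rng.dirichlet([1, 1], size=60)
        spectrum, truth = bb.generate_signature_cohort(
            sigs, expo, n_mutations_per_sample=800, seed=3)
        res = nmf_extract(spectrum, k=2, n_restarts=10, seed=4)
        sim = np.array([
            [cosine_similarity(res.signatures.iloc[:, i], sigs[:, j])
             for j in range(2)] for i in range(2)
        ])
        assert max(min(sim[0, 0], sim[1, 1]), min(sim[0, 1], sim[1, 0])) >= 0.95
        assert (res.stability > 0.9).all()

    def test_objective_monotone_nonincreasing(self, small_cohort):
        _, _, variants, _ = small_cohort
        spec = spectrum_table(variants)
        res = nmf_extract(spec, k=2, n_restarts=3, max_iter=300, seed=0)
        obj = res.objective
        assert np.all(np.diff(obj) <= 1e-8 * np.maximum(np.abs(obj[:-1]), 1.0))

    def test_signatures_column_stochastic(self, small_cohort):
        _, _, variants, _ = small_cohort
        spec = spectrum_table(variants)
        res = nmf_extract(spec, k=3, n_restarts=5, seed=1)
        assert np.allclose(res.signatures.sum(axis=0), 1.0, atol=1e-9)
        assert (res.exposures.to_numpy() >= 0).all()

    def test_agrees_with_sklearn_nmf(self):
        """Independent cross-check: our KL objective at the solution is no
        worse than ~5% above scikit-learn's multiplicative-update KL NMF."""
        from sklearn.decomposition import NMF as SkNMF

        rng = np.random.default_rng(5)
        V = rng.poisson(8, size=(7, 40)).astype(float) + 1.0
        spec = pd.DataFrame(V.T, columns=list(MUTATION_CATEGORIES))
        res = nmf_extract(spec, k=3, n_restarts=8, max_iter=3000, seed=0)
        sk = SkNMF(n_components=3, solver="mu", beta_loss="kullback-leibler",
                   init="random", random_state=0, max_iter=3000, tol=1e-9)
        W = sk.fit_transform(V)
        H = sk.components_

        def kl(V, WH):
            mask = V > 0
            return np.sum(V[mask] * np.log(V[mask] / WH[mask])) - V.sum() + WH.sum()

        ours = kl(V, res.signatures.to_numpy()
                  @ res.exposures.to_numpy().T + 1e-12)
        theirs = kl(V, W @ H + 1e-12)
        assert ours <= 1.05 * theirs + 1.0

    def test_invalid_inputs(self):
        spec = pd.DataFrame(np.zeros((3, 7)), columns=list(MUTATION_CATEGORIES))
        with pytest.raises(ValueError, match="zero"):
            nmf_extract(spec, k=1)
        spec.iloc[0] = 1
        with pytest.raises(ValueError, match="k="):
            nmf_extract(spec, k=5)


def test_rank_scan_flags_the_generating_rank():
    from bbdburden.signatures import rank_scan

    sigs = np.zeros((7, 2))
    sigs[:3, 0] = [0.5, 0.3, 0.2]
    sigs[3:, 1] = [0.4, 0.3, 0.2, 0.1]
    rng = np.random.default_rng(9)
    spectrum, _ = bb.generate_signature_cohort(
        sigs, rng.dirichlet([1, 1], size=40), 600, seed=10)
    scan = rank_scan(spectrum, [1, 2, 3], n_restarts=5, seed=1)
    err = scan.set_index("k")["reconstruction_error"]
    assert err[2] < err[1]  # the second signature explains real structure
    assert scan.set_index("k").loc[2, "mean_stability"] > 0.95


def test_compare_to_catalog_identifies_match():
    sigs = pd.DataFrame(
        {"signature_A": [0.7, 0.2, 0.1, 0, 0, 0, 0]},
        index=list(MUTATION_CATEGORIES))
    catalog = pd.DataFrame(
        {"ref1": [0.7, 0.2, 0.1, 0, 0, 0, 0], "ref2": [0, 0, 0, 0.5, 0.3, 0.1, 0.1]},
        index=list(MUTATION_CATEGORIES))
    sim = compare_to_catalog(sigs, catalog)
    assert sim.loc["signature_A", "ref1"] == pytest.approx(1.0)
    assert sim.loc["signature_A", "ref2"] == pytest.approx(0.0)


class TestExposureAssociation:
    def test_identical_exposures_give_p_one(self):
        x = np.ones(20)
        g = np.array(["a"] * 10 + ["b"] * 10)
        assert associate_exposures(x, g) == pytest.approx(1.0)

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(1)
        x = rng.random(30)
        g = np.array(["a"] * 15 + ["b"] * 15)
        p1 = associate_exposures(x, g)
        p2 = associate_exposures(x, np.where(g == "a", "b", "a"))
        assert p1 == pytest.approx(p2)

    def test_planted_block_year_effect_detected(self):
        """A signature whose exposure shifts after the 1992 processing
        change is detected in >= 90% of replicates."""
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(40):
            pre = rng.gamma(2.0, 1.0, 60)
            post = rng.gamma(2.0, 1.0, 60) + 1.2
            x = np.concatenate([pre, post])
            g = np.array(["pre"] * 60 + ["post"] * 60)
            hits += associate_exposures(x, g) < 0.05
        assert hits / 40 >= 0.90

    def test_small_level_missing_with_warning(self):
        with pytest.warns(UserWarning):
            p = associate_exposures(np.ones(5), np.array(["a"] * 4 + ["b"]))
        assert np.isnan(p)

    def test_kruskal_three_groups(self):
        rng = np.random.default_rng(3)
        x = rng.random(30)
        g = np.repeat(["a", "b", "c"], 10)
        p = associate_exposures(x, g, test="kruskal_wallis")
        assert 0 < p <= 1
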