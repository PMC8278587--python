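"""Gene-level burden association under the 12 filter x method combinations.

Plants protective somatic effects (higher mutation rate in cancer-free
controls) in 10 genes, runs logistic burden regression and SKAT-O — plain
and FDR-down-weighted — under liberal/classical/strict filtering, and
summarizes the consensus and the label-permutation significance of the
protective-gene count.
"""

import bbdburden as bb
from bbdburden.association import run_all_combinations

planted = [f"GENE{i:03d}" for i in range(1, 11)]
cfg = bb.SimulationConfig(
    effect_genes=[bb.EffectSpec(g, "control", 3.0) for g in planted],
    seed=5,
)
sheet, variants, _ = bb.generate_cohort(cfg)

ffpe, frozen, _ = bb.generate_paired_ffpe_frozen(seed=6)
fdr = bb.estimate_fdr(ffpe, frozen)

results = run_all_combinations(variants, sheet, fdr_table=fdr)
tab = bb.consensus_count(results)
top = tab.sort_values(["n_nominal", "gene"], ascending=[False, True]).head(12)
print("top genes by consensus count (of 12 combinations with p < 0.05):")
print(top.to_string(index=False))
hits = set(top.head(10)["gene"]) & set(planted)
print(f"\nplanted genes among the top 10: {len(hits)}/10")

perm = bb.permutation_test(variants, sheet, statistic="s2", n_perm=100,
                           seed=1, fdr_table=fdr)
print(f"\nS2 = #genes protective under weighted-logistic/classical:"
      f" observed {perm.observed:.0f}")
print(f"empirical p over {perm.n_perm} label permutations: {perm.p_value:.4f}")
# A small empirical p says an excess of protective (OR < 1) genes of this
# size is not produced by shuffling genomic profiles across subjects.

print(f"\nBonferroni threshold for 93 genes: {bb.bonferroni_threshold(93):.5f}")
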