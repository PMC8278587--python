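"""Sample QC, replicate identity, FFPE FDR estimation and AAF filtering.

Walks the full quality-control chain on synthetic data: per-sample
acceptance (molecular-tag coverage and SNP call rate), rank-correlation
replicate identification, per-category false-discovery-rate estimation
from paired FFPE/fresh-frozen samples, and the three nested AAF filter
strategies.
"""

import bbdburden as bb
from bbdburden.qc import _snp_aaf_matrix

sheet, variants, truth = bb.generate_cohort(seed=3)

print("== sample QC ==")
print(f"pass: {int(sheet['qc_pass'].sum())}/{len(sheet)}"
      f"  (min call rate {sheet['snp_call_rate'].min():.3f},"
      f" min UMT coverage {sheet['mean_umt_coverage'].min():.0f}x)")

print("\n== replicate identity (Spearman over known SNPs) ==")
mat = _snp_aaf_matrix(sheet, variants,
                      truth.snp_positions[["chrom", "pos", "ref", "alt"]])
cmat, verdicts = bb.replicate_identity(mat)
same = verdicts[verdicts["same_source"].fillna(False)]
print(f"{len(same)} pairs called same-source (threshold 0.85);"
      f" highest unrelated correlation"
      f" {verdicts[~verdicts['same_source'].fillna(False)]['correlation'].max():.3f}")

print("\n== FFPE FDR by category (paired FFPE/frozen) ==")
ffpe, frozen, _ = bb.generate_paired_ffpe_frozen(seed=4)
fdr = bb.estimate_fdr(ffpe, frozen)
print(fdr.to_string(index=False))
# C>T categories carry the deamination signal: their estimated FDR is far
# above the other substitution types, which motivates the stricter AAF
# floor for C>T in the classical strategy.

print("\n== AAF filter strategies ==")
clean = bb.filter_technical(variants)
for strategy in bb.FILTER_STRATEGIES:
    kept = bb.apply_aaf_filter(clean, strategy)
    print(f"{strategy:>9}: {len(kept)} of {len(clean)} calls survive")

print("\n== population AF concordance ==")
conc = bb.population_af_concordance(variants, sheet)
print(f"cohort vs population allele frequency: Spearman "
      f"{conc.iloc[0]['correlation']:.3f} over {conc.iloc[0]['n_sites']} sites")
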