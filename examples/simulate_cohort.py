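"""Generate a synthetic FFPE benign-breast-disease cohort and inspect it.

Builds the default three-group cohort (42 controls, 42 future ER+, 36
future ER-) with germline SNPs, somatic mutations, FFPE C>T artifacts and
technical replicates, then prints what was generated and writes it to
standard formats (VCF + annotation TSV + sample sheet TSV).
"""

from pathlib import Path

import bbdburden as bb

out = Path("scratch_example_out")
out.mkdir(exist_ok=True)

sheet, variants, truth = bb.generate_cohort(seed=7)

print("samples:", len(sheet), "by group:",
      sheet["group"].value_counts().to_dict())
print("variant calls:", len(variants))
print("true origins:",
      truth.variant_origin["origin"].value_counts().to_dict())
print("calls per category:")
print(variants["category"].value_counts().to_string())

bb.write_variants(variants, out / "cohort.vcf", out / "annotation.tsv")
bb.write_sample_sheet(sheet, out / "samples.tsv")
back = bb.read_variants(out / "cohort.vcf", out / "annotation.tsv")
print(f"round-trip through VCF: {len(back)} calls re-read")

# The origin counts show the expected composition: germline calls dominate
# (one row per sample per panel SNP), artifacts concentrate in C>T and
# C>T_at_CpG at low allele fraction, and somatic calls are sparse.
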