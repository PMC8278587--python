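import numpy as np
import pandas as pd
import pytest

import bbdburden as bb


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced cohort (fast to generate, still exercises every stage)."""
    cfg = bb.SimulationConfig(
        n_control=20, n_er_pos=16, n_er_neg=14, n_genes=15,
        n_germline_snps=40, n_replicate_sets=2, seed=11,
    )
    sheet, variants, truth = bb.generate_cohort(cfg)
    return cfg, sheet, variants, truth


@pytest.fixture(scope="session")
def fdr_table():
    ffpe, frozen, _ = bb.generate_paired_ffpe_frozen(
        calls_per_category=400, seed=21
    )
    return bb.estimate_fdr(ffpe, frozen)


@pytest.fixture()
def toy_variants():
    """Hand-built variant table with known composition."""
    rows = []
    spec = [
        # sample, pos, ref, alt, aaf, rsid, context, flags
        ("A", 100, "C", "T", 0.04, None, "ACG", ""),
        ("A", 101, "C", "T", 0.07, None, "ACA", ""),
        ("A", 102, "C", "T", 0.07, "rs1", "ACA", ""),
        ("A", 103, "C", "T", 0.15, None, "ACT", ""),
        ("A", 104, "T", "A", 0.04, None, "ATA", ""),
        ("A", 105, "T", "A", 0.07, None, "ATC", ""),
        ("B", 106, "T", "G", 0.15, None, "ATG", ""),
        ("B", 107, "C", "A", 0.07, "rs2", "CCA", ""),
        ("B", 108, "G", "A", 0.07, None, "CGT", ""),  # C>T_at_CpG revcomp
        ("B", 109, "C", "G", 0.30, None, "GCC", ""),
        ("B", 110, "T", "C", 0.04, "rs3", "TTT", ""),
        ("B", 111, "A", "C", 0.55, None, "TAG", ""),
    ]
    for sid, pos, ref, alt, aaf, rsid, ctx, flags in spec:
        rows.append(
            dict(sample_id=sid, chrom="1", pos=pos, ref=ref, alt=alt, aaf=aaf,
                 umt_depth=500, rsid=rsid, gene="GENE001",
                 impact="nonsynonymous", population_af=np.nan, context=ctx,
                 technical_flags=flags)
        )
    from bbdburden.variants import classify_variant_table

    return classify_variant_table(pd.DataFrame(rows))
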