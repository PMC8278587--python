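"""Reading and writing the pipeline's standard formats.

Variant calls travel as VCF v4.2 plus a tab-separated annotation table keyed
by (chrom, pos, ref, alt) that supplies gene symbol, functional impact,
population allele frequency and trinucleotide context.  Sample sheets and
result tables are plain TSV; run configuration is YAML/JSON.

The alternate-allele fraction is taken from a configurable per-sample FORMAT
field (default ``VAF``); when the field is absent it is computed from allelic
depths ``AD`` as alt/(ref+alt).  htslib stores VCF floats as 32-bit; values
are restored to the shortest decimal that identifies the float32, so fractions
written with up to seven significant digits round-trip exactly.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml
from cyvcf2 import VCF

from .variants import VARIANT_COLUMNS, classify_variant_table, validate_variants

__all__ = [
    "read_variants",
    "write_variants",
    "read_sample_sheet",
    "write_sample_sheet",
    "load_config",
    "save_config",
]

_ANNOT_KEY = ["chrom", "pos", "ref", "alt"]
_ANNOT_FIELDS = ["gene", "impact", "population_af", "context"]


def _f32_repr(x: float) -> float:
    """Shortest-decimal float64 for an htslib float32."""
    return float(np.format_float_positional(np.float32(x), unique=True, trim="-"))


def _load_annotation(annotation_path) -> pd.DataFrame:
    ann = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str})
    missing = [c for c in _ANNOT_KEY + _ANNOT_FIELDS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann.duplicated(subset=_ANNOT_KEY).any():
        dup = ann[ann.duplicated(subset=_ANNOT_KEY, keep=False)]
        raise ValueError(
            f"annotation key collision on (chrom,pos,ref,alt): "
            f"{dup[_ANNOT_KEY].drop_duplicates().to_dict('records')}"
        )
    return ann.set_index(_ANNOT_KEY)


def read_variants(
    vcf_path: Union[str, Path],
    annotation_path: Union[str, Path, None] = None,
    aaf_key: str = "VAF",
) -> pd.DataFrame:
    """Read a VCF (+ optional annotation TSV) into a variant table.

    Returns one row per sample x ALT allele with the canonical columns.
    Multi-allelic records are split; ALT="." records are skipped with a
    warning.  Samples whose AAF field is missing at a site carry no call
    there.  Unmatched annotation keys leave the optional columns empty.
    """
    ann = _load_annotation(annotation_path) if annotation_path is not None else None
    vcf = VCF(str(vcf_path))
    sample_ids = list(vcf.samples)
    rows: list[dict] = []
    for rec in vcf:
        alts = rec.ALT
        if not alts:
            warnings.warn(
                f"skipping no-variant record at {rec.CHROM}:{rec.POS}", stacklevel=2
            )
            continue
        def _fmt(key):
            try:
                return rec.format(key)
            except KeyError:
                return None

        vaf = _fmt(aaf_key)
        if vaf is None:
            ad = _fmt("AD")
            if ad is None:
                raise ValueError(
                    f"record {rec.CHROM}:{rec.POS} has neither FORMAT/{aaf_key} nor AD"
                )
        dp = _fmt("DP")
        tf = _fmt("TF")
        rsid = rec.ID if rec.ID not in (None, ".") else None
        for ai, alt in enumerate(alts):
            for si, sid in enumerate(sample_ids):
                if vaf is not None:
                    val = vaf[si][ai] if vaf.shape[1] > ai else vaf[si][0]
                    if np.isnan(val) or val < 0:
                        continue
                    aaf = _f32_repr(val)
                else:
                    ref_d, alt_d = float(ad[si][0]), float(ad[si][1 + ai])
                    if ref_d + alt_d <= 0 or ref_d < 0 or alt_d < 0:
                        continue
                    aaf = alt_d / (ref_d + alt_d)
                depth = int(dp[si][0]) if dp is not None and dp[si][0] >= 0 else 0
                flags = ""
                if tf is not None:
                    raw = tf[si]
                    if isinstance(raw, bytes):
                        raw = raw.decode()
                    if raw and raw != ".":
                        flags = raw
                rows.append(
                    {
                        "sample_id": sid,
                        "chrom": rec.CHROM,
                        "pos": rec.POS,
                        "ref": rec.REF,
                        "alt": alt,
                        "aaf": aaf,
                        "umt_depth": depth,
                        "rsid": rsid,
                        "technical_flags": flags,
                    }
                )
    df = pd.DataFrame(rows)
    if df.empty:
        df = pd.DataFrame(columns=[c for c in VARIANT_COLUMNS if c != "category"])
    for col in _ANNOT_FIELDS:
        df[col] = None
    if ann is not None and not df.empty:
        key = pd.MultiIndex.from_frame(df[_ANNOT_KEY].astype({"chrom": str}))
        hit = key.isin(ann.index)
        if hit.any():
            matched = ann.reindex(key[hit])
            for col in _ANNOT_FIELDS:
                df.loc[hit, col] = matched[col].to_numpy()
    df["population_af"] = pd.to_numeric(df["population_af"], errors="coerce")
    df = classify_variant_table(df)
    df = df[VARIANT_COLUMNS]
    validate_variants(df)
    return df


def write_variants(
    variants: pd.DataFrame,
    vcf_path: Union[str, Path],
    annotation_path: Union[str, Path, None] = None,
    aaf_key: str = "VAF",
) -> None:
    """Write a variant table as a multi-sample VCF (+ annotation TSV).

    AAF goes to FORMAT/<aaf_key> (Float), molecular-tag depth to FORMAT/DP,
    per-call technical flags (comma-joined) to FORMAT/TF; rsID to the ID
    column.  One record is emitted per (chrom, pos, ref, alt) site.
    """
    samples = sorted(variants["sample_id"].unique())
    sidx = {s: i for i, s in enumerate(samples)}
    header = [
        "##fileformat=VCFv4.2",
        f'##FORMAT=<ID={aaf_key},Number=1,Type=Float,'
        'Description="Alternate allele fraction">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,'
        'Description="Unique molecular tag depth">',
        '##FORMAT=<ID=TF,Number=1,Type=String,'
        'Description="Technical failure flags, comma separated">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    lines = list(header)

    def _chrom_sort(c: str):
        c = str(c).removeprefix("chr")
        return (0, int(c)) if c.isdigit() else (1, c)

    site_cols = ["chrom", "pos", "ref", "alt"]
    grouped = variants.groupby(site_cols, sort=False)
    sites = sorted(grouped.groups, key=lambda k: (_chrom_sort(k[0]), k[1], k[2], k[3]))
    ann_rows = []
    for site in sites:
        grp = grouped.get_group(site)
        chrom, pos, ref, alt = site
        rsids = {r for r in grp["rsid"] if isinstance(r, str) and r}
        rsid = sorted(rsids)[0] if rsids else "."
        cells = ["."] * len(samples)
        for _, row in grp.iterrows():
            flags = row["technical_flags"]
            if not isinstance(flags, str) or not flags:
                flags = "."
            cells[sidx[row["sample_id"]]] = (
                f"{row['aaf']:.7g}:{int(row['umt_depth'])}:{flags}"
            )
        lines.append(
            f"{chrom}\t{pos}\t{rsid}\t{ref}\t{alt}\t.\t.\t.\t"
            f"{aaf_key}:DP:TF\t" + "\t".join(cells)
        )
        first = grp.iloc[0]
        ann_rows.append(
            {
                "chrom": chrom,
                "pos": pos,
                "ref": ref,
                "alt": alt,
                "gene": first["gene"],
                "impact": first["impact"],
                "population_af": first["population_af"],
                "context": first["context"],
            }
        )
    Path(vcf_path).write_text("\n".join(lines) + "\n")
    if annotation_path is not None:
        pd.DataFrame(ann_rows).to_csv(annotation_path, sep="\t", index=False)


def read_sample_sheet(path: Union[str, Path]) -> pd.DataFrame:
    """Read a TSV sample sheet (one row per sample)."""
    sheet = pd.read_csv(path, sep="\t")
    if "sample_id" not in sheet.columns or "group" not in sheet.columns:
        raise ValueError("sample sheet requires 'sample_id' and 'group' columns")
    return sheet


def write_sample_sheet(sheet: pd.DataFrame, path: Union[str, Path]) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def load_config(path: Union[str, Path]) -> dict:
    """Load a YAML (or JSON, a YAML subset) run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("configuration must be a mapping")
    return cfg


def save_config(cfg: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
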