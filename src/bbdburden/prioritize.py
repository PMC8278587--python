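"""Variant prioritization for gene-level association analysis.

Sites are removed when they are (a) common in reference populations
(population allele frequency > 0.5%), (b) common in the cohort's own
cancer-free controls (mean AAF across controls, counting absent calls as 0,
above 0.05), or (c) annotated as low functional impact.  Rules act on sites
(chrom, pos, ref, alt); every sample-level call at a removed site is dropped.
A removal ledger records which rule(s) fired for each removed site.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import pandas as pd

from .variants import HIGH_IMPACT_CLASSES, IMPACT_CLASSES

__all__ = ["prioritize"]

_SITE = ["chrom", "pos", "ref", "alt"]


def prioritize(
    variants: pd.DataFrame,
    control_sample_ids: Sequence[str],
    pop_maf_cut: float = 0.005,
    control_vmf_cut: float = 0.05,
    missing_impact: str = "retain",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Select analysis variants; return ``(retained, ledger)``.

    The ledger has one row per removed site with boolean columns
    ``common_population``, ``common_in_controls`` and ``low_impact``
    (several may be true at once).  Calls with an impact label outside the
    controlled vocabulary raise; missing impact is handled per
    ``missing_impact`` ("retain" with a warning, or "remove").
    """
    control_ids = set(control_sample_ids)
    if not control_ids:
        raise ValueError("control sample set is empty")
    if missing_impact not in ("retain", "remove"):
        raise ValueError("missing_impact must be 'retain' or 'remove'")
    known = set(IMPACT_CLASSES)
    bad = set(variants["impact"].dropna().unique()) - known
    if bad:
        raise ValueError(f"unknown impact labels: {sorted(bad)}")

    n_controls = len(control_ids)
    # .first() skips nulls, so site-level annotation survives sparse rows
    site_ann = variants.groupby(_SITE, observed=True, sort=False).agg(
        population_af=("population_af", "first"), impact=("impact", "first")
    )
    is_control = variants["sample_id"].isin(control_ids)
    ctrl_sum = (
        variants.loc[is_control].groupby(_SITE, observed=True)["aaf"].sum()
    )
    ctrl_mean = ctrl_sum.reindex(site_ann.index).fillna(0.0) / n_controls

    rule_a = site_ann["population_af"].gt(pop_maf_cut).fillna(False)
    rule_b = ctrl_mean > control_vmf_cut
    has_impact = site_ann["impact"].notna()
    if (~has_impact).any() and missing_impact == "retain":
        warnings.warn(
            f"{int((~has_impact).sum())} site(s) lack impact annotation; retained",
            stacklevel=2,
        )
    rule_c = ~site_ann["impact"].isin(HIGH_IMPACT_CLASSES)
    if missing_impact == "retain":
        rule_c &= has_impact
    removed = rule_a | rule_b | rule_c
    ledger = pd.DataFrame(
        {
            "common_population": rule_a[removed],
            "common_in_controls": rule_b[removed],
            "low_impact": rule_c[removed],
        }
    ).reset_index()
    if removed.any():
        vkeys = pd.MultiIndex.from_frame(variants[_SITE])
        retained = variants.loc[
            ~vkeys.isin(site_ann.index[removed])
        ].reset_index(drop=True)
    else:
        retained = variants.reset_index(drop=True)
    return retained, ledger
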