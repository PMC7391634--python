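"""Cross-referencing suggestive CpGs with published GWAS regions.

A CpG falls in a GWAS region when it lies within +/- 500 kb of the
region's index variant (inclusive, same chromosome, shared genome
build).  For any overlap, the CpG's meQTL instruments are tested for
linkage with the index variant in a reference genotype panel: if no
instrument reaches the r-squared threshold the methylation signal is
judged independent of the known GWAS association rather than mediating
it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, InstrumentSet
from .meqtl import MeqtlScanner, ld_r2

__all__ = ["overlap_gwas_regions", "instrument_index_ld"]


def overlap_gwas_regions(
    cpgs: pd.DataFrame,
    index_variants: pd.DataFrame,
    window: int = 500_000,
) -> pd.DataFrame:
    """(CpG, index variant) pairs within the window.

    ``cpgs`` needs columns ``cpg``, ``chrom``, ``pos``; ``index_variants``
    needs ``variant_id``, ``chrom``, ``pos``.  Bounds are inclusive and
    symmetric (same distance up- and downstream).
    """
    rows = []
    for _, cpg_row in cpgs.iterrows():
        same = index_variants[
            index_variants["chrom"].astype(str) == str(cpg_row["chrom"])
        ]
        dist = (same["pos"] - cpg_row["pos"]).abs()
        for _, iv_row in same[dist <= window].iterrows():
            rows.append(
                {
                    "cpg": cpg_row["cpg"],
                    "chrom": str(cpg_row["chrom"]),
                    "cpg_pos": int(cpg_row["pos"]),
                    "index_variant": iv_row["variant_id"],
                    "index_pos": int(iv_row["pos"]),
                    "distance": int(abs(iv_row["pos"] - cpg_row["pos"])),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["cpg", "chrom", "cpg_pos", "index_variant", "index_pos", "distance"],
    )


def instrument_index_ld(
    instruments: InstrumentSet,
    index_variant: str,
    panel: GenotypeMatrix,
    r2_threshold: float = 0.2,
    study_genotypes: GenotypeMatrix | None = None,
    study_mvalues: pd.Series | None = None,
) -> dict:
    """LD of each instrument with a GWAS index variant in a reference panel.

    Returns per-instrument r-squared and a mediation verdict: ``linked``
    iff the maximum r-squared reaches ``r2_threshold``, else
    ``independent``; ``untestable`` when the index variant is absent from
    the panel.  When study genotypes and M-values are provided, the
    direct meQTL p-value of the index variant in the study is also
    reported.
    """
    out: dict = {
        "cpg": instruments.cpg,
        "index_variant": index_variant,
        "r2": {},
        "max_r2": np.nan,
        "verdict": "untestable",
        "index_meqtl_p": np.nan,
    }
    if index_variant not in panel.variant_ids:
        return out
    r2s = {}
    for vid in instruments.variant_ids:
        if vid in panel.variant_ids:
            r2s[vid] = ld_r2(panel, vid, index_variant)
    out["r2"] = r2s
    if r2s:
        out["max_r2"] = max(r2s.values())
        out["verdict"] = (
            "linked" if out["max_r2"] >= r2_threshold else "independent"
        )
    if (
        study_genotypes is not None
        and study_mvalues is not None
        and index_variant in study_genotypes.variant_ids
    ):
        stats_table = (
            MeqtlScanner()
            .fit(study_genotypes.dosage[[index_variant]], study_mvalues)
            .results_
        )
        out["index_meqtl_p"] = float(stats_table.loc[index_variant, "p"])
    return out
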