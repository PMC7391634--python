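"""Two-sample Wald-ratio Mendelian randomization for cis genes.

Genes within +/- 500 kb of a suggestive CpG are candidate mediators of
its association.  For each (gene, tissue), the single expression-
associated variant's effects from exposure (eQTL) and outcome (GWAS)
summary statistics are harmonized to a common effect allele and combined
into the Wald ratio b_outcome / b_exposure with first-order delta-method
standard error se_outcome / |b_exposure|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "WaldResult",
    "map_cis_genes",
    "harmonize_summary_stats",
    "wald_ratio_mr",
    "WaldRatioMR",
]

PALINDROMIC = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass
class WaldResult:
    gene: str
    tissue: str
    iv: str
    estimate: float
    se: float
    p: float
    harmonization: str = "kept"  # kept | flipped | dropped_palindromic
    significant: bool = False


def map_cis_genes(
    cpg_pos: int,
    cpg_chrom,
    genes: pd.DataFrame,
    window: int = 500_000,
    mode: str = "interval",
) -> pd.DataFrame:
    """Genes in cis to a CpG: interval overlap with
    [pos - window, pos + window], inclusive bounds, 1-based coordinates.

    ``genes`` needs columns ``gene``, ``chrom``, ``start``, ``end``.
    ``mode="tss"`` instead requires the transcription start (``start``)
    itself to fall in the window.
    """
    chrom = str(cpg_chrom)
    same = genes[genes["chrom"].astype(str) == chrom]
    if same.empty:
        if chrom not in set(genes["chrom"].astype(str)):
            warnings.warn(f"chromosome {chrom!r} absent from gene annotation")
        return genes.iloc[0:0]
    lo, hi = cpg_pos - window, cpg_pos + window
    if mode == "interval":
        hit = (same["end"] >= lo) & (same["start"] <= hi)
    elif mode == "tss":
        hit = (same["start"] >= lo) & (same["start"] <= hi)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return same[hit].reset_index(drop=True)


def harmonize_summary_stats(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    drop_palindromic: bool = True,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Records are joined on ``variant_id``.  When the outcome effect
    allele equals the exposure *other* allele (and vice versa) the
    outcome beta is negated and its alleles swapped (action ``flipped``);
    palindromic A/T and C/G variants are dropped by default
    (``dropped_palindromic``), as are allele pairs that match neither way
    (``dropped_mismatch``).  Idempotent: harmonizing an already
    harmonized pair changes nothing.
    """
    merged = exposure.merge(
        outcome,
        on="variant_id",
        suffixes=("_exp", "_out"),
        how="inner",
    )
    if merged.empty:
        raise ValueError("no shared variants between exposure and outcome")
    actions = []
    betas = []
    for _, row in merged.iterrows():
        ea_x, oa_x = row["effect_allele_exp"], row["other_allele_exp"]
        ea_y, oa_y = row["effect_allele_out"], row["other_allele_out"]
        if drop_palindromic and frozenset((ea_x, oa_x)) in PALINDROMIC:
            actions.append("dropped_palindromic")
            betas.append(np.nan)
        elif (ea_x, oa_x) == (ea_y, oa_y):
            actions.append("kept")
            betas.append(row["beta_out"])
        elif (ea_x, oa_x) == (oa_y, ea_y):
            actions.append("flipped")
            betas.append(-row["beta_out"])
        else:
            actions.append("dropped_mismatch")
            betas.append(np.nan)
    out = merged.copy()
    out["harmonization"] = actions
    out["beta_out"] = betas
    out["effect_allele_out"] = out["effect_allele_exp"]
    out["other_allele_out"] = out["other_allele_exp"]
    return out


def wald_ratio_mr(
    beta_exposure: float,
    se_exposure: float,
    beta_outcome: float,
    se_outcome: float,
    second_order: bool = False,
) -> tuple[float, float, float]:
    """Single-IV Wald ratio: estimate, SE and two-sided normal p.

    estimate = b_y / b_x; SE = s_y / |b_x| (first-order delta method);
    the second-order option adds the exposure-uncertainty term
    b_y^2 s_x^2 / b_x^4.
    """
    if beta_exposure == 0:
        raise ZeroDivisionError("Wald ratio undefined for zero exposure effect")
    estimate = beta_outcome / beta_exposure
    var = (se_outcome / beta_exposure) ** 2
    if second_order:
        var += beta_outcome**2 * se_exposure**2 / beta_exposure**4
    se = float(np.sqrt(var))
    z = estimate / se if se > 0 else np.inf * np.sign(estimate)
    p = float(2 * stats.norm.sf(abs(z)))
    return float(estimate), se, p


class WaldRatioMR(BaseEstimator):
    """Per-(gene, tissue) single-IV Wald-ratio MR on summary statistics.

    ``fit(exposure, outcome)`` harmonizes the two tables and computes one
    Wald ratio per (gene, tissue) record; when a gene has several eQTL
    records in a tissue the smallest-p exposure variant is used as the
    instrument.

    Parameters
    ----------
    alpha : float, default 0.05
        Wald-test significance level used only to set the
        ``significant`` flag; no rows are dropped.
    iv_choice : {"top_p"}, default "top_p"
        How the single instrument per (gene, tissue) is chosen.

    Attributes
    ----------
    results_ : pandas.DataFrame
        gene, tissue, iv, estimate, se, p, harmonization, significant.
    """

    def __init__(
        self,
        alpha: float = 0.05,
        drop_palindromic: bool = True,
        second_order: bool = False,
        iv_choice: str = "top_p",
    ):
        self.alpha = alpha
        self.drop_palindromic = drop_palindromic
        self.second_order = second_order
        self.iv_choice = iv_choice

    def fit(self, exposure: pd.DataFrame, outcome: pd.DataFrame):
        if self.iv_choice != "top_p":
            raise ValueError(f"unknown iv_choice {self.iv_choice!r}")
        merged = harmonize_summary_stats(
            exposure, outcome, drop_palindromic=self.drop_palindromic
        )
        rows = []
        group_cols = ["gene"] + (["tissue"] if "tissue" in merged.columns else [])
        for key, grp in merged.groupby(group_cols, sort=True):
            key = key if isinstance(key, tuple) else (key,)
            gene = key[0]
            tissue = key[1] if len(key) > 1 else ""
            grp = grp.sort_values(["p_exp", "variant_id"], kind="mergesort")
            top = grp.iloc[0]
            if top["harmonization"].startswith("dropped"):
                rows.append(
                    WaldResult(
                        gene=gene,
                        tissue=tissue,
                        iv=top["variant_id"],
                        estimate=np.nan,
                        se=np.nan,
                        p=np.nan,
                        harmonization=top["harmonization"],
                    )
                )
                continue
            est, se, p = wald_ratio_mr(
                top["beta_exp"],
                top["se_exp"],
                top["beta_out"],
                top["se_out"],
                second_order=self.second_order,
            )
            rows.append(
                WaldResult(
                    gene=gene,
                    tissue=tissue,
                    iv=top["variant_id"],
                    estimate=est,
                    se=se,
                    p=p,
                    harmonization=top["harmonization"],
                    significant=bool(p < self.alpha),
                )
            )
        self.results_ = pd.DataFrame([r.__dict__ for r in rows])
        return self
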