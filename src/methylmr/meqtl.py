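"""Chromosome-wide meQTL scanning and instrument construction.

For each CpG of interest, every variant on the CpG's chromosome is
tested for association of its effect-allele dosage with the CpG's
M-value (adjusting for methylation PCs), and the qualifying variants
(P < 1e-3) are greedily pruned to pairwise r-squared < 0.2 to form an
independent instrument set for Mendelian randomization.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, InstrumentSet

__all__ = [
    "MeqtlScanner",
    "scan_meqtl",
    "ld_r2",
    "build_instrument_set",
    "instruments_for_cpgs",
]


class MeqtlScanner(BaseEstimator):
    """Per-variant OLS of one CpG's M-values on dosage plus covariates.

    Covariates (methylation PCs) are partialled out of both the M-values
    and each dosage vector (Frisch--Waugh--Lovell), then each variant's
    slope, classical SE, t and two-sided p are computed with residual
    degrees of freedom ``n - n_covariates - 2``.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per variant: ``slope`` (M per effect-allele dosage),
        ``se``, ``t``, ``p``; NaN for monomorphic variants.
    """

    def __init__(self, covariates: pd.DataFrame | None = None):
        self.covariates = covariates

    def fit(self, X, y):
        if isinstance(X, GenotypeMatrix):
            dosage = X.dosage
        else:
            dosage = X
        y = pd.Series(y) if not isinstance(y, pd.Series) else y
        samples = dosage.index.intersection(y.index)
        if len(samples) < 3:
            raise ValueError("need at least three aligned samples")
        G = dosage.loc[samples].to_numpy(dtype=float)
        m = y.loc[samples].to_numpy(dtype=float)
        n = len(samples)

        n_cov = 0
        if self.covariates is not None:
            C = self.covariates.loc[samples].to_numpy(dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            n_cov = C.shape[1]
            D = np.column_stack([np.ones(n), C])
            proj = D @ np.linalg.lstsq(D, np.column_stack([m[:, None], G]), rcond=None)[0]
            m = m - proj[:, 0]
            G = G - proj[:, 1:]
        else:
            m = m - m.mean()
            G = G - G.mean(axis=0)

        df = n - n_cov - 2
        gss = np.sum(G**2, axis=0)
        mono = gss == 0
        if mono.any():
            warnings.warn(f"{int(mono.sum())} monomorphic variant(s) set to NaN")
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = (G.T @ m) / gss
            rss = np.sum(m**2) - slope**2 * gss
            rss = np.maximum(rss, 0.0)
            se = np.sqrt(rss / max(df, 1) / gss)
            tval = slope / se
        pval = 2 * stats.t.sf(np.abs(tval), df)
        slope[mono] = np.nan
        se[mono] = np.nan
        tval[mono] = np.nan
        pval[mono] = np.nan
        self.results_ = pd.DataFrame(
            {"slope": slope, "se": se, "t": tval, "p": pval},
            index=dosage.columns.rename("variant_id"),
        )
        self.n_samples_ = n
        self.df_resid_ = df
        return self


def scan_meqtl(
    mvalues: pd.Series,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    chrom: str | None = None,
) -> pd.DataFrame:
    """meQTL statistics for one CpG against the variants of one chromosome
    (all variants in ``genotypes`` when ``chrom`` is None)."""
    g = genotypes.subset_chrom(chrom) if chrom is not None else genotypes
    return MeqtlScanner(covariates=covariates).fit(g, mvalues).results_


def ld_r2(g: GenotypeMatrix | pd.DataFrame, v1: str, v2: str) -> float:
    """Squared Pearson correlation of two variants' dosages.

    Symmetric and invariant to the allele flip ``g -> 2 - g``.
    """
    dosage = g.dosage if isinstance(g, GenotypeMatrix) else g
    for v in (v1, v2):
        if v not in dosage.columns:
            raise KeyError(f"variant {v!r} not present")
    a = dosage[v1].to_numpy(dtype=float)
    b = dosage[v2].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("r2 undefined for a constant-dosage variant")
    r = np.corrcoef(a, b)[0, 1]
    return float(r**2)


def build_instrument_set(
    stats_table: pd.DataFrame,
    g: GenotypeMatrix,
    p_threshold: float = 1e-3,
    r2_threshold: float = 0.2,
    cpg: str = "",
) -> InstrumentSet:
    """Greedy p-ordered LD pruning of qualifying meQTLs (clumping).

    Variants with p below ``p_threshold`` are visited in ascending-p
    order (ties broken by chromosome, position, then id); a variant is
    accepted iff its dosage r-squared with every already-accepted variant
    is below ``r2_threshold``.  The result is maximal for this greedy
    order: every excluded qualifying variant violates the LD bound with
    some retained variant.
    """
    qual = stats_table[stats_table["p"] < p_threshold].copy()
    if qual.empty:
        return InstrumentSet(
            cpg=cpg,
            stats=stats_table.iloc[0:0],
            p_threshold=p_threshold,
            r2_threshold=r2_threshold,
            flag="no_instruments",
        )
    meta = g.variants
    qual["_chrom"] = meta.loc[qual.index, "chrom"].astype(str)
    qual["_pos"] = meta.loc[qual.index, "pos"]
    qual["_id"] = qual.index
    qual = qual.sort_values(["p", "_chrom", "_pos", "_id"], kind="mergesort")

    dosage = g.dosage[qual.index].to_numpy(dtype=float)
    centered = dosage - dosage.mean(axis=0)
    norms = np.sqrt(np.sum(centered**2, axis=0))
    accepted: list[int] = []
    for j in range(len(qual)):
        if norms[j] == 0:
            continue  # constant dosage: r2 with anything undefined
        ok = True
        for i in accepted:
            r = centered[:, i] @ centered[:, j] / (norms[i] * norms[j])
            if r**2 >= r2_threshold:
                ok = False
                break
        if ok:
            accepted.append(j)
    kept = qual.iloc[accepted][["slope", "se", "t", "p"]]
    return InstrumentSet(
        cpg=cpg,
        stats=kept,
        p_threshold=p_threshold,
        r2_threshold=r2_threshold,
        flag="ok" if len(kept) else "no_instruments",
    )


def instruments_for_cpgs(
    cpgs: pd.DataFrame,
    mvalues: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
    p_threshold: float = 1e-3,
    r2_threshold: float = 0.2,
) -> dict[str, InstrumentSet]:
    """Scan and prune instruments for every CpG in a suggestive table.

    ``cpgs`` needs columns ``cpg`` and ``chrom``; ``mvalues`` is the
    probes x samples M-value matrix.
    """
    out: dict[str, InstrumentSet] = {}
    for _, row in cpgs.drop_duplicates(subset=["cpg"]).iterrows():
        cpg = row["cpg"]
        chrom = str(row["chrom"])
        g = genotypes.subset_chrom(chrom)
        if g.n_variants == 0 or cpg not in mvalues.index:
            out[cpg] = InstrumentSet(
                cpg=cpg,
                stats=pd.DataFrame(columns=["slope", "se", "t", "p"]),
                p_threshold=p_threshold,
                r2_threshold=r2_threshold,
                flag="no_instruments",
            )
            continue
        stats_table = MeqtlScanner(covariates=covariates).fit(
            g, mvalues.loc[cpg]
        ).results_
        out[cpg] = build_instrument_set(
            stats_table, g, p_threshold=p_threshold, r2_threshold=r2_threshold, cpg=cpg
        )
    return out
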