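"""Epigenome-wide association scans for the three study designs.

Three designs are supported: hypospadias case--control (all samples,
FDR < 0.20 suggestive threshold), and the chordee and severity case-only
designs (cases only, FDR < 0.15).  Each scan fits an ordinary
least-squares model of per-CpG beta values on the group indicator plus
covariates; group means and delta beta are reported unadjusted, matching
the convention of published per-CpG summary tables (delta beta =
comparison mean - case mean, so a case-hypermethylated CpG gets a
negative delta).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .datatypes import MethylationMatrix, QCReport

__all__ = [
    "EwasDesign",
    "DESIGNS",
    "EwasScanner",
    "run_ewas",
    "delta_beta",
    "genomic_inflation",
    "tune_covariates",
    "bh_fdr",
    "select_suggestive",
    "lookup_candidates",
]

#: Median of the 1-df chi-square distribution, the null reference for
#: the genomic inflation factor.
CHI2_1_MEDIAN = float(stats.chi2.median(1))


@dataclass(frozen=True)
class EwasDesign:
    """One association design: who is compared with whom, at what FDR."""

    name: str
    case_column: str  # phenotype column holding the 0/1 group label
    restrict_to_cases: bool = False
    fdr_threshold: float = 0.20

    def group_labels(self, phenotype: pd.DataFrame) -> pd.Series:
        pheno = phenotype
        if self.restrict_to_cases:
            pheno = pheno[pheno["case"] == 1]
        labels = pheno[self.case_column].astype("float")
        return labels.dropna().astype(int)


DESIGNS = {
    "hypospadias": EwasDesign("hypospadias", "case", False, 0.20),
    "chordee": EwasDesign("chordee", "chordee", True, 0.15),
    "severity": EwasDesign("severity", "severe", True, 0.15),
}


class EwasScanner(BaseEstimator):
    """Per-CpG OLS association scan.

    ``fit(X, y)`` regresses every CpG's beta value on the binary group
    label plus the covariate matrix supplied at construction.  Classical
    (homoskedastic) standard errors by default, matching standard EWAS
    linear-model tools; HC0 robust errors with ``robust=True``.

    Attributes
    ----------
    results_ : pandas.DataFrame
        One row per CpG: ``effect`` (adjusted case-minus-comparison
        difference in mean beta), ``se``, ``t``, ``p``, ``q`` (BH within
        the tested CpGs), unadjusted ``case_mean`` / ``comparison_mean``,
        ``delta_beta`` (comparison - case) and per-group n, sorted by p.
    lambda_ : float
        Genomic inflation factor of the scan.
    """

    def __init__(self, covariates: pd.DataFrame | None = None, robust: bool = False):
        self.covariates = covariates
        self.robust = robust

    def fit(self, X, y):
        if isinstance(X, MethylationMatrix):
            beta = X.beta
        else:
            beta = X
        y = pd.Series(y) if not isinstance(y, pd.Series) else y
        samples = beta.columns.intersection(y.index)
        y = y.loc[samples].astype(float)
        beta = beta[samples]
        groups = np.unique(y)
        if len(groups) != 2 or set(groups) != {0.0, 1.0}:
            raise ValueError("group label must be binary 0/1 with both groups present")
        if (y == 1).sum() < 2 or (y == 0).sum() < 2:
            raise ValueError("each group needs at least two samples")

        n = len(samples)
        design_cols = [np.ones(n), y.to_numpy()]
        if self.covariates is not None:
            C = self.covariates.loc[samples]
            design_cols.extend(C.to_numpy(dtype=float).T)
        Xmat = np.column_stack(design_cols)
        p_rank = np.linalg.matrix_rank(Xmat)
        if p_rank < Xmat.shape[1]:
            raise ValueError("covariate matrix is rank-deficient")
        k = Xmat.shape[1]
        df = n - k

        Y = beta.to_numpy(dtype=float).T  # samples x probes
        xtx_inv = np.linalg.inv(Xmat.T @ Xmat)
        coef = xtx_inv @ Xmat.T @ Y
        resid = Y - Xmat @ coef
        rss = np.sum(resid**2, axis=0)
        effect = coef[1]
        if self.robust:
            # HC0 sandwich variance for the group coefficient
            se = np.empty(Y.shape[1])
            for j in range(Y.shape[1]):
                meat = Xmat.T @ (resid[:, j, None] ** 2 * Xmat)
                se[j] = np.sqrt((xtx_inv @ meat @ xtx_inv)[1, 1])
        else:
            sigma2 = rss / max(df, 1)
            se = np.sqrt(sigma2 * xtx_inv[1, 1])

        constant = Y.var(axis=0) == 0
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant CpG(s) excluded from testing"
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = effect / se
        pval = 2 * stats.t.sf(np.abs(tval), df)
        tval[constant] = np.nan
        pval[constant] = np.nan

        case_mask = (y == 1).to_numpy()
        case_mean = Y[case_mask].mean(axis=0)
        comp_mean = Y[~case_mask].mean(axis=0)

        res = pd.DataFrame(
            {
                "effect": effect,
                "se": se,
                "t": tval,
                "p": pval,
                "case_mean": case_mean,
                "comparison_mean": comp_mean,
                "delta_beta": comp_mean - case_mean,
                "n_case": int(case_mask.sum()),
                "n_comparison": int((~case_mask).sum()),
            },
            index=beta.index.rename("cpg"),
        )
        res["q"] = np.nan
        tested = res["p"].notna()
        res.loc[tested, "q"] = bh_fdr(res.loc[tested, "p"].to_numpy())
        res = res.sort_values("p", kind="mergesort")
        self.results_ = res
        self.n_samples_ = n
        self.df_resid_ = df
        self.lambda_ = genomic_inflation(res.loc[tested, "p"].to_numpy())
        return self


def run_ewas(
    m,
    phenotype: pd.DataFrame,
    design: EwasDesign | str,
    covariates: pd.DataFrame | None = None,
    robust: bool = False,
) -> pd.DataFrame:
    """Run one EWAS design and return the per-CpG results table."""
    if isinstance(design, str):
        design = DESIGNS[design]
    labels = design.group_labels(phenotype)
    scanner = EwasScanner(covariates=covariates, robust=robust).fit(m, labels)
    res = scanner.results_
    res.attrs["design"] = design.name
    res.attrs["lambda"] = scanner.lambda_
    res.attrs["fdr_threshold"] = design.fdr_threshold
    return res


def delta_beta(case_mean: float, comparison_mean: float) -> tuple[float, float]:
    """Signed difference (comparison - case) and its magnitude in percent."""
    for v in (case_mean, comparison_mean):
        if not 0 <= v <= 1:
            raise ValueError("group mean betas must lie in [0, 1]")
    diff = comparison_mean - case_mean
    return diff, 100.0 * abs(diff)


def genomic_inflation(pvalues) -> float:
    """Genomic inflation factor: median observed 1-df chi-square over its
    null median (0.4549...)."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no finite p-values")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini--Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def tune_covariates(
    m,
    phenotype: pd.DataFrame,
    design: EwasDesign | str,
    candidate_sets: list[tuple[str, pd.DataFrame | None]],
) -> tuple[str, pd.DataFrame | None, pd.DataFrame]:
    """Choose the covariate set that best controls genomic inflation.

    Runs the scan once per candidate set (in the given order) and selects
    the set whose inflation factor is closest to 1; ties are broken in
    favour of fewer covariates.  Returns the chosen name, the chosen
    covariate frame and the full lambda trace.
    """
    if not candidate_sets:
        raise ValueError("need at least one candidate covariate set")
    trace = []
    for name, covars in candidate_sets:
        n_cov = 0 if covars is None else covars.shape[1]
        try:
            res = run_ewas(m, phenotype, design, covariates=covars)
            lam = res.attrs["lambda"]
        except ValueError:
            # infeasible candidate (e.g. collinear covariates): skip it
            lam = np.nan
        trace.append(
            {
                "candidate": name,
                "n_covariates": n_cov,
                "lambda": lam,
                "abs_dev": abs(lam - 1.0) if np.isfinite(lam) else np.inf,
            }
        )
    trace_df = pd.DataFrame(trace)
    order = trace_df.sort_values(
        ["abs_dev", "n_covariates"], kind="mergesort"
    ).index
    best = trace_df.loc[order[0], "candidate"]
    chosen = dict(candidate_sets)[best]
    return best, chosen, trace_df


def select_suggestive(
    results_by_design: dict[str, pd.DataFrame],
    manifest: pd.DataFrame | None = None,
    thresholds: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Suggestive CpGs per design: q below the design's FDR threshold.

    Deduplicates by (CpG, design); a CpG suggestive in two designs keeps
    one row per design of origin.  Positions and gene labels are joined
    from the manifest when provided.
    """
    frames = []
    for name, res in results_by_design.items():
        thr = (
            thresholds[name]
            if thresholds is not None
            else res.attrs.get("fdr_threshold", DESIGNS[name].fdr_threshold)
        )
        hits = res[res["q"] < thr].copy()
        hits["design"] = name
        hits["fdr_threshold"] = thr
        frames.append(hits.reset_index())
    if not frames:
        return pd.DataFrame(columns=["cpg", "design"])
    out = pd.concat(frames, ignore_index=True)
    out = out.drop_duplicates(subset=["cpg", "design"])
    if manifest is not None:
        ann_cols = [c for c in ("chrom", "pos", "gene") if c in manifest.columns]
        out = out.merge(
            manifest[ann_cols], left_on="cpg", right_index=True, how="left"
        )
    return out.sort_values(["design", "p"], kind="mergesort").reset_index(drop=True)


def lookup_candidates(
    results: pd.DataFrame,
    candidate_cpgs,
    manifest: pd.DataFrame,
    qc_report: QCReport | None = None,
) -> pd.DataFrame:
    """Replication lookup of externally reported CpGs.

    Per candidate, status is ``absent_from_array`` (not in the manifest),
    ``failed_qc`` (removed during probe QC) or ``tested`` (present in the
    scan results, with its effect and p reported).
    """
    if len(candidate_cpgs) == 0:
        raise ValueError("candidate list must be non-empty")
    failed = (
        set(qc_report.probes_removed["probe_id"]) if qc_report is not None else set()
    )
    rows = []
    for cpg in candidate_cpgs:
        if cpg not in manifest.index:
            rows.append({"cpg": cpg, "status": "absent_from_array"})
        elif cpg in failed or cpg not in results.index:
            rows.append({"cpg": cpg, "status": "failed_qc"})
        else:
            rows.append(
                {
                    "cpg": cpg,
                    "status": "tested",
                    "effect": results.loc[cpg, "effect"],
                    "p": results.loc[cpg, "p"],
                }
            )
    return pd.DataFrame(rows)
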