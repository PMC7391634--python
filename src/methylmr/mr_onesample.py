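"""One-sample two-stage least squares Mendelian randomization.

Estimates the causal effect of a CpG's methylation (M-value scale) on a
binary outcome using that CpG's independent meQTLs as instruments.
Stage 1 regresses the M-values on the instrument dosages; stage 2
regresses the outcome on the stage-1 fitted M-values.  The binary
outcome enters a linear probability model, so the causal estimate reads
as outcome-probability change per M-value unit.  Standard errors use the
classical 2SLS formula with residuals computed from the *observed*
exposure (y - X beta-hat), never the fitted one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import GenotypeMatrix, InstrumentSet

__all__ = [
    "MrResult",
    "TwoStageLeastSquares",
    "fit_2sls",
    "first_stage_diagnostics",
]

#: First-stage F statistics above this are reported as capped (the
#: noiseless limit would be infinite).
F_CAP = 1e12


@dataclass
class MrResult:
    """Causal estimate of one CpG on one outcome design."""

    cpg: str
    design: str
    estimate: float
    se: float
    t: float
    p: float
    n_instruments: int
    n_samples: int
    first_stage_f: float
    first_stage_r2: float
    flag: str = "ok"  # ok | weak_instrument | strong

    def to_dict(self) -> dict:
        return {
            "cpg": self.cpg,
            "design": self.design,
            "estimate": self.estimate,
            "se": self.se,
            "t": self.t,
            "p": self.p,
            "n_iv": self.n_instruments,
            "n": self.n_samples,
            "first_stage_f": self.first_stage_f,
            "first_stage_r2": self.first_stage_r2,
            "flag": self.flag,
        }


def _align(exposure, outcome, instruments, covariates):
    exposure = pd.Series(exposure) if not isinstance(exposure, pd.Series) else exposure
    outcome = pd.Series(outcome) if not isinstance(outcome, pd.Series) else outcome
    if isinstance(instruments, GenotypeMatrix):
        instruments = instruments.dosage
    if isinstance(instruments, pd.Series):
        instruments = instruments.to_frame()
    samples = exposure.index.intersection(outcome.index).intersection(
        instruments.index
    )
    if covariates is not None:
        samples = samples.intersection(covariates.index)
        covariates = covariates.loc[samples].to_numpy(dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
    if len(samples) < instruments.shape[1] + 2:
        raise ValueError("too few aligned samples for the instrument count")
    return (
        exposure.loc[samples].to_numpy(dtype=float),
        outcome.loc[samples].to_numpy(dtype=float),
        instruments.loc[samples],
        covariates,
        samples,
    )


def _check_instrument_rank(G: pd.DataFrame) -> None:
    mat = G.to_numpy(dtype=float)
    centered = mat - mat.mean(axis=0)
    rank = np.linalg.matrix_rank(np.column_stack([np.ones(len(mat)), mat]))
    if rank < mat.shape[1] + 1:
        # identify an offending pair by pairwise correlation
        cc = np.corrcoef(centered, rowvar=False)
        names = list(G.columns)
        worst = "unknown"
        if cc.ndim == 2:
            np.fill_diagonal(cc, 0.0)
            i, j = np.unravel_index(np.nanargmax(np.abs(cc)), cc.shape)
            worst = f"{names[i]} ~ {names[j]}"
        raise np.linalg.LinAlgError(
            f"instrument matrix is collinear (e.g. {worst})"
        )


class TwoStageLeastSquares(BaseEstimator):
    """2SLS instrumental-variable estimator for one exposure.

    ``fit(instruments, exposure, outcome)`` runs both stages; exogenous
    covariates supplied at construction are included in both.  With a
    single instrument the estimator reduces exactly to the Wald ratio
    cov(G, Y) / cov(G, M).

    Parameters
    ----------
    covariates : pandas.DataFrame, optional
        Exogenous covariates included in both stages (default none).
    robust : bool, default False
        Heteroskedasticity-robust (HC0) standard errors instead of the
        classical homoskedastic formula.
    weak_f_threshold : float, default 10.0
        First-stage F below which the result is flagged
        ``weak_instrument``.

    Attributes
    ----------
    estimate_, se_, t_, p_ : float
        Causal effect of the exposure on the outcome and its inference
        (two-sided t, ``n - k`` residual degrees of freedom).
    first_stage_f_, first_stage_r2_ : float
    flag_ : str
    """

    def __init__(
        self,
        covariates: pd.DataFrame | None = None,
        robust: bool = False,
        weak_f_threshold: float = 10.0,
    ):
        self.covariates = covariates
        self.robust = robust
        self.weak_f_threshold = weak_f_threshold

    def fit(self, instruments, exposure, outcome):
        m, y, G, C, samples = _align(exposure, outcome, instruments, self.covariates)
        _check_instrument_rank(G)
        n = len(samples)
        Gmat = G.to_numpy(dtype=float)
        ones = np.ones((n, 1))
        exog = ones if C is None else np.column_stack([ones, C])
        Z = np.column_stack([exog, Gmat])

        # stage 1: exposure on instruments (+ covariates)
        gamma, *_ = np.linalg.lstsq(Z, m, rcond=None)
        m_hat = Z @ gamma

        f_stat, r2 = _first_stage_f(m, Z, exog, n, Gmat.shape[1])

        # stage 2: outcome on fitted exposure (+ covariates)
        Xhat = np.column_stack([exog, m_hat])
        X = np.column_stack([exog, m])
        xtx = Xhat.T @ Xhat
        beta = np.linalg.solve(xtx, Xhat.T @ y)
        k = Xhat.shape[1]
        df = n - k
        resid = y - X @ beta  # observed exposure in the residual
        xtx_inv = np.linalg.inv(xtx)
        if self.robust:
            meat = Xhat.T @ (resid[:, None] ** 2 * Xhat)
            cov_beta = xtx_inv @ meat @ xtx_inv
        else:
            sigma2 = float(resid @ resid) / df
            cov_beta = sigma2 * xtx_inv
        est = float(beta[-1])
        se = float(np.sqrt(cov_beta[-1, -1]))
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = est / se if se > 0 else np.inf * np.sign(est)
        pval = float(2 * stats.t.sf(abs(tval), df))

        self.estimate_ = est
        self.se_ = se
        self.t_ = float(tval)
        self.p_ = pval
        self.n_samples_ = n
        self.n_instruments_ = Gmat.shape[1]
        self.first_stage_f_ = f_stat
        self.first_stage_r2_ = r2
        if f_stat >= F_CAP:
            self.flag_ = "strong"
        elif f_stat < self.weak_f_threshold:
            self.flag_ = "weak_instrument"
        else:
            self.flag_ = "ok"
        return self


def _first_stage_f(m, Z, exog, n, k_iv):
    """Partial F and R-squared for the joint instrument block."""
    coef0, *_ = np.linalg.lstsq(exog, m, rcond=None)
    rss0 = float(np.sum((m - exog @ coef0) ** 2))
    coef1, *_ = np.linalg.lstsq(Z, m, rcond=None)
    rss1 = float(np.sum((m - Z @ coef1) ** 2))
    df1 = n - Z.shape[1]
    r2 = 1.0 - rss1 / rss0 if rss0 > 0 else 0.0
    if rss1 <= max(rss0, 1.0) * 1e-14 or df1 <= 0:
        return F_CAP, r2
    f = ((rss0 - rss1) / k_iv) / (rss1 / df1)
    return float(min(f, F_CAP)), r2


def fit_2sls(
    mvalues,
    outcome,
    instruments,
    genotypes: GenotypeMatrix | None = None,
    covariates: pd.DataFrame | None = None,
    cpg: str = "",
    design: str = "",
) -> MrResult:
    """Two-stage least squares MR of one CpG on one binary outcome.

    ``instruments`` may be an :class:`InstrumentSet` (dosages are then
    pulled from ``genotypes``) or a dosage DataFrame.
    """
    if isinstance(instruments, InstrumentSet):
        if instruments.n_instruments == 0:
            raise ValueError(f"instrument set for {instruments.cpg!r} is empty")
        if genotypes is None:
            raise ValueError("genotypes required when passing an InstrumentSet")
        cpg = cpg or instruments.cpg
        dosages = genotypes.dosage[instruments.variant_ids]
    else:
        dosages = instruments
    est = TwoStageLeastSquares(covariates=covariates).fit(dosages, mvalues, outcome)
    return MrResult(
        cpg=cpg,
        design=design,
        estimate=est.estimate_,
        se=est.se_,
        t=est.t_,
        p=est.p_,
        n_instruments=est.n_instruments_,
        n_samples=est.n_samples_,
        first_stage_f=est.first_stage_f_,
        first_stage_r2=est.first_stage_r2_,
        flag=est.flag_,
    )


def first_stage_diagnostics(
    mvalues, instruments, covariates: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Instrument-strength diagnostics for one CpG.

    Returns a one-row frame with the joint-instrument F, first-stage
    R-squared and flag, plus per-instrument partial t statistics.
    """
    if isinstance(instruments, GenotypeMatrix):
        instruments = instruments.dosage
    m = pd.Series(mvalues) if not isinstance(mvalues, pd.Series) else mvalues
    samples = m.index.intersection(instruments.index)
    marr = m.loc[samples].to_numpy(dtype=float)
    Gmat = instruments.loc[samples].to_numpy(dtype=float)
    n = len(samples)
    ones = np.ones((n, 1))
    if covariates is not None:
        C = covariates.loc[samples].to_numpy(dtype=float)
        exog = np.column_stack([ones, C])
    else:
        exog = ones
    Z = np.column_stack([exog, Gmat])
    f_stat, r2 = _first_stage_f(marr, Z, exog, n, Gmat.shape[1])

    coef, *_ = np.linalg.lstsq(Z, marr, rcond=None)
    resid = marr - Z @ coef
    df = n - Z.shape[1]
    sigma2 = float(resid @ resid) / max(df, 1)
    ztz_inv = np.linalg.pinv(Z.T @ Z)
    se = np.sqrt(sigma2 * np.diag(ztz_inv))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = coef / se
    k0 = exog.shape[1]
    flag = (
        "strong"
        if f_stat >= F_CAP
        else ("weak_instrument" if f_stat < 10 else "ok")
    )
    out = pd.DataFrame(
        {
            "instrument": list(instruments.columns),
            "partial_t": tvals[k0:],
        }
    )
    out.attrs.update({"F": f_stat, "r2": r2, "flag": flag, "n": n})
    return out
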