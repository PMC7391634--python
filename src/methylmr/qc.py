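"""Methylation quality control, beta/M transforms, cell-type
deconvolution and latent-covariate estimation.

The estimators follow the scikit-learn protocol (``fit`` /
``transform``, fitted attributes with a trailing underscore,
``get_params`` / ``set_params``) so they compose with pipelines and
model selection.  Module-level functions are thin wrappers kept for
script use.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .datatypes import CellTypeReference, MethylationMatrix, QCReport

__all__ = [
    "filter_samples",
    "filter_probes",
    "beta_to_m",
    "m_to_beta",
    "CellTypeDeconvolver",
    "estimate_cell_fractions",
    "compare_cell_fractions",
    "SurrogateVariableEstimator",
    "estimate_surrogate_variables",
    "MethylationPCA",
    "methylation_pcs",
]


# ---------------------------------------------------------------------------
# filtering

def filter_samples(
    m: MethylationMatrix,
    detection_threshold: float = 0.01,
    max_fail_fraction: float = 0.05,
    sex_mismatch_flags=(),
) -> tuple[MethylationMatrix, QCReport]:
    """Remove low-quality and sex-mismatched samples.

    A sample is removed when the fraction of its probes with detection
    p-value above ``detection_threshold`` exceeds ``max_fail_fraction``,
    or when it appears in ``sex_mismatch_flags`` (sex inference itself
    happens upstream; only the flags are consumed here).
    """
    removed: list[dict] = []
    keep = list(m.sample_ids)
    if m.detection_p is not None:
        fail_frac = (m.detection_p > detection_threshold).mean(axis=0)
        for sid in m.sample_ids:
            if fail_frac[sid] > max_fail_fraction:
                removed.append({"sample_id": sid, "reason": "detection"})
    flagged = set(sex_mismatch_flags)
    for sid in m.sample_ids:
        if sid in flagged and not any(r["sample_id"] == sid for r in removed):
            removed.append({"sample_id": sid, "reason": "sex_mismatch"})
    removed_ids = {r["sample_id"] for r in removed}
    keep = [s for s in keep if s not in removed_ids]
    if not keep:
        raise ValueError("sample QC removed every sample")
    report = QCReport(
        samples_removed=pd.DataFrame(removed, columns=["sample_id", "reason"]),
        n_samples_before=m.n_samples,
        n_samples_after=len(keep),
        n_probes_before=m.n_probes,
        n_probes_after=m.n_probes,
    )
    return m.subset_samples(keep), report


def filter_probes(
    m: MethylationMatrix,
    detection_threshold: float = 0.01,
    detection_sample_fraction: float = 0.05,
    bead_fail_fraction_threshold: float = 0.05,
) -> tuple[MethylationMatrix, QCReport]:
    """Remove unreliable probes.

    Dropped, in order of precedence recorded in the report: probes with
    bead failures (fewer than three beads) in at least
    ``bead_fail_fraction_threshold`` of samples; non-CpG probes
    (``probe_class`` other than ``cg``); SNP-associated probes
    (``snp_flag``); probes failing detection (p above
    ``detection_threshold``) in at least ``detection_sample_fraction`` of
    samples.
    """
    manifest = m.manifest.loc[m.probe_ids]
    removed: list[dict] = []
    reasons = pd.Series("", index=m.probe_ids, dtype=object)

    if m.bead_fail is not None:
        bead_frac = m.bead_fail.mean(axis=1)
        reasons[(bead_frac >= bead_fail_fraction_threshold) & (reasons == "")] = "beads"
    reasons[(manifest["probe_class"] != "cg") & (reasons == "")] = "non-CpG"
    reasons[manifest["snp_flag"].astype(bool) & (reasons == "")] = "SNP-associated"
    if m.detection_p is not None:
        det_frac = (m.detection_p > detection_threshold).mean(axis=1)
        reasons[(det_frac >= detection_sample_fraction) & (reasons == "")] = "detection"

    for pid, reason in reasons.items():
        if reason:
            removed.append({"probe_id": pid, "reason": reason})
    keep = [p for p in m.probe_ids if reasons[p] == ""]
    if not keep:
        raise ValueError("probe QC removed every probe")
    report = QCReport(
        probes_removed=pd.DataFrame(removed, columns=["probe_id", "reason"]),
        n_samples_before=m.n_samples,
        n_samples_after=m.n_samples,
        n_probes_before=m.n_probes,
        n_probes_after=len(keep),
    )
    return m.subset_probes(keep), report


# ---------------------------------------------------------------------------
# beta / M transform

def beta_to_m(beta, epsilon: float = 1e-3):
    """M = log2(b / (1 - b)) with b clipped to [epsilon, 1 - epsilon].

    Accepts scalars, arrays, Series or DataFrames; the container type is
    preserved.
    """
    arr = np.asarray(beta, dtype=float)
    with np.errstate(invalid="ignore"):
        if np.any((arr < 0) | (arr > 1)):
            raise ValueError("beta values must lie in [0, 1]")
    clipped = np.clip(arr, epsilon, 1 - epsilon)
    m = np.log2(clipped / (1 - clipped))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    if np.isscalar(beta):
        return float(m)
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2^M / (1 + 2^M)."""
    arr = np.asarray(m, dtype=float)
    b = 1.0 / (1.0 + np.exp2(-arr))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(b, index=m.index, columns=m.columns)
    if isinstance(m, pd.Series):
        return pd.Series(b, index=m.index, name=m.name)
    if np.isscalar(m):
        return float(b)
    return b


# ---------------------------------------------------------------------------
# cell-type deconvolution

class CellTypeDeconvolver(BaseEstimator, TransformerMixin):
    """Reference-based cell-fraction estimation by non-negative least squares.

    For each sample, the beta values at the marker probes shared with the
    reference are regressed on the per-cell-type reference profiles under
    a non-negativity constraint; the coefficients are renormalized to sum
    to one, so the output lives on the cell-type simplex.

    Parameters
    ----------
    reference : CellTypeReference
        Marker-probe beta profiles per cell type.
    robust : bool, default False
        Iteratively reweighted (Huber) variant that down-weights marker
        probes with large residuals; useful when a few markers are
        contaminated.
    huber_delta : float, default 0.05
        Residual scale (beta units) beyond which Huber down-weighting
        kicks in; only used when ``robust=True``.

    Attributes
    ----------
    fractions_ : pandas.DataFrame
        Samples x cell types after :meth:`fit`; rows sum to one.
    marker_ids_ : pandas.Index
        Marker probes actually used (intersection with the input matrix).
    """

    def __init__(self, reference: CellTypeReference, robust: bool = False,
                 huber_delta: float = 0.05):
        self.reference = reference
        self.robust = robust
        self.huber_delta = huber_delta

    def fit(self, X, y=None):
        beta = X.beta if isinstance(X, MethylationMatrix) else X
        shared = beta.index.intersection(self.reference.marker_ids)
        if len(shared) == 0:
            raise ValueError("no marker probes shared with the reference")
        ref = self.reference.profiles.loc[shared].to_numpy()
        obs = beta.loc[shared].to_numpy(dtype=float)
        n_types = ref.shape[1]
        out = np.empty((obs.shape[1], n_types))
        for j in range(obs.shape[1]):
            coefs = self._solve(ref, obs[:, j])
            total = coefs.sum()
            out[j] = coefs / total if total > 0 else np.full(n_types, 1.0 / n_types)
        self.marker_ids_ = shared
        self.fractions_ = pd.DataFrame(
            out, index=beta.columns, columns=self.reference.cell_types
        )
        return self

    def _solve(self, ref: np.ndarray, y: np.ndarray) -> np.ndarray:
        coefs, _ = optimize.nnls(ref, y)
        if not self.robust:
            return coefs
        # Huber-weighted NNLS: reweight rows until the residual-based
        # weights stabilize (a few iterations suffice at this scale).
        for _ in range(10):
            resid = y - ref @ coefs
            absr = np.abs(resid)
            w = np.where(absr <= self.huber_delta, 1.0, self.huber_delta / absr)
            sw = np.sqrt(w)
            new, _ = optimize.nnls(ref * sw[:, None], y * sw)
            if np.allclose(new, coefs, atol=1e-10):
                coefs = new
                break
            coefs = new
        return coefs

    def transform(self, X):
        self.fit(X)
        return self.fractions_


def estimate_cell_fractions(
    m: MethylationMatrix, ref: CellTypeReference, robust: bool = False
) -> pd.DataFrame:
    """Per-sample cell-type fractions (samples x cell types, rows sum to 1)."""
    return CellTypeDeconvolver(ref, robust=robust).fit(m).fractions_


def compare_cell_fractions(
    fractions: pd.DataFrame, groups, test: str = "ranksum"
) -> pd.DataFrame:
    """Two-sample location test per cell type between two groups.

    Rank-based (Mann--Whitney) by default; Welch t-test with
    ``test="t"``.  Returns one row per cell type with the statistic and
    two-sided p-value.
    """
    groups = pd.Series(np.asarray(groups), index=fractions.index)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"expected exactly two groups, got {len(levels)}")
    a_idx = groups[groups == levels[0]].index
    b_idx = groups[groups == levels[1]].index
    if len(a_idx) < 2 or len(b_idx) < 2:
        raise ValueError("each group needs at least two samples")
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[a_idx, ct].to_numpy()
        b = fractions.loc[b_idx, ct].to_numpy()
        if test == "ranksum":
            if np.array_equal(np.sort(a), np.sort(b)):
                stat, p = np.nan, 1.0  # identical samples: no evidence
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        elif test == "t":
            stat, p = stats.ttest_ind(a, b, equal_var=False)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"cell_type": ct, "statistic": stat, "p": min(float(p), 1.0)})
    return pd.DataFrame(rows).set_index("cell_type")


# ---------------------------------------------------------------------------
# latent covariates

def _as_sample_matrix(X) -> tuple[np.ndarray, pd.Index]:
    """Coerce input to samples x probes with a sample index."""
    if isinstance(X, MethylationMatrix):
        return X.beta.to_numpy(dtype=float).T, X.sample_ids
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float).T, X.columns
    arr = np.asarray(X, dtype=float).T
    return arr, pd.RangeIndex(arr.shape[0])


class SurrogateVariableEstimator(BaseEstimator, TransformerMixin):
    """Latent technical covariates from the residual methylation matrix.

    The probes x samples matrix is residualized on the protected design
    (biological covariates whose signal must not be absorbed), and the
    surrogate variables are the top left singular directions of the
    residual matrix in sample space.  When ``n_components="auto"`` the
    number of components is chosen by permutation parallel analysis:
    each singular value is kept while it exceeds the 95th percentile of
    the corresponding singular value across ``n_permutations`` row-wise
    permutations of the residuals.

    Attributes
    ----------
    surrogate_variables_ : pandas.DataFrame
        Samples x k, mutually orthogonal columns (unit norm).
    n_components_ : int
        Number of components retained.
    singular_values_ : numpy.ndarray
    """

    def __init__(
        self,
        n_components="auto",
        n_permutations: int = 100,
        percentile: float = 95.0,
        random_state: int = 0,
    ):
        self.n_components = n_components
        self.n_permutations = n_permutations
        self.percentile = percentile
        self.random_state = random_state

    def fit(self, X, protected_design=None):
        mat, sample_index = _as_sample_matrix(X)  # samples x probes
        n, p = mat.shape
        if protected_design is not None:
            D = np.asarray(protected_design, dtype=float)
            if D.ndim == 1:
                D = D[:, None]
            D = np.column_stack([np.ones(n), D])
        else:
            D = np.ones((n, 1))
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("protected design is rank-deficient")
        # residualize samples-space matrix on the design
        coef, *_ = np.linalg.lstsq(D, mat, rcond=None)
        resid = mat - D @ coef

        k_max = min(n, p) - 1
        if self.n_components == "auto":
            k = self._parallel_analysis(resid, k_max)
        else:
            k = int(self.n_components)
            if n < k + D.shape[1] + 1:
                raise ValueError("too few samples for requested number of SVs")
        if k > 0:
            U, s, _ = np.linalg.svd(resid, full_matrices=False)
            sv = U[:, :k]
            self.singular_values_ = s[:k]
        else:
            sv = np.empty((n, 0))
            self.singular_values_ = np.empty(0)
        self.n_components_ = k
        self.surrogate_variables_ = pd.DataFrame(
            sv, index=sample_index, columns=[f"SV{i + 1}" for i in range(k)]
        )
        return self

    def _parallel_analysis(self, resid: np.ndarray, k_max: int) -> int:
        rng = np.random.default_rng(self.random_state)
        s_obs = np.linalg.svd(resid, compute_uv=False)
        n_keep = min(k_max, len(s_obs))
        null = np.empty((self.n_permutations, n_keep))
        work = resid.copy()
        for b in range(self.n_permutations):
            # permute entries within each probe (column of samples x probes)
            for j in range(work.shape[1]):
                rng.shuffle(work[:, j])
            null[b] = np.linalg.svd(work, compute_uv=False)[:n_keep]
        cutoff = np.percentile(null, self.percentile, axis=0)
        k = 0
        for i in range(n_keep):
            if s_obs[i] > cutoff[i]:
                k += 1
            else:
                break
        return k

    def transform(self, X=None):
        check_is_fitted(self, "surrogate_variables_")
        return self.surrogate_variables_


def estimate_surrogate_variables(
    m, protected_design=None, k="auto", n_permutations: int = 100, random_state: int = 0
) -> pd.DataFrame:
    """Surrogate variables (samples x k) for unmeasured batch structure."""
    est = SurrogateVariableEstimator(
        n_components=k, n_permutations=n_permutations, random_state=random_state
    )
    return est.fit(m, protected_design).surrogate_variables_


class MethylationPCA(BaseEstimator, TransformerMixin):
    """Principal components of the methylation matrix over samples.

    Columns (probes) are centered; the PCs are the projections of the
    samples on the top right singular directions, with variance explained
    reported in non-increasing order.

    Attributes
    ----------
    components_df_ : pandas.DataFrame
        Samples x k PC scores.
    explained_variance_ratio_ : numpy.ndarray
    """

    def __init__(self, n_components: int = 2, use_m_values: bool = False,
                 epsilon: float = 1e-3):
        self.n_components = n_components
        self.use_m_values = use_m_values
        self.epsilon = epsilon

    def fit(self, X, y=None):
        mat, sample_index = _as_sample_matrix(X)  # samples x probes
        if self.use_m_values:
            mat = beta_to_m(mat, epsilon=self.epsilon)
        n, p = mat.shape
        k = int(self.n_components)
        if k > min(n, p) - 1:
            raise ValueError(
                f"n_components={k} too large for matrix of shape {(n, p)}"
            )
        centered = mat - mat.mean(axis=0, keepdims=True)
        U, s, _ = np.linalg.svd(centered, full_matrices=False)
        scores = U[:, :k] * s[:k]
        total_var = float(np.sum(s**2))
        self.singular_values_ = s[:k]
        self.explained_variance_ratio_ = (
            s[:k] ** 2 / total_var if total_var > 0 else np.zeros(k)
        )
        self.components_df_ = pd.DataFrame(
            scores, index=sample_index, columns=[f"mePC{i + 1}" for i in range(k)]
        )
        return self

    def transform(self, X=None):
        check_is_fitted(self, "components_df_")
        return self.components_df_


def methylation_pcs(m, k: int, use_m_values: bool = False) -> tuple[pd.DataFrame, np.ndarray]:
    """Top-k methylation PCs and their variance-explained fractions."""
    est = MethylationPCA(n_components=k, use_m_values=use_m_values).fit(m)
    return est.components_df_, est.explained_variance_ratio_
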