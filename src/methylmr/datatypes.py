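"""Core data containers shared across the pipeline.

All containers are thin wrappers around pandas objects so that they
compose with the rest of the scientific Python stack; validation happens
at construction time and the underlying frames stay accessible.

Conventions used throughout the package:

* methylation matrices are probes x samples,
* genotype dosage matrices are samples x variants with dosages in [0, 2],
* genomic coordinates are 1-based and intervals are inclusive,
* every genetic table carries an explicit effect-allele column.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MethylationMatrix",
    "GenotypeMatrix",
    "CellTypeReference",
    "InstrumentSet",
    "QCReport",
    "CELL_TYPES",
]

#: Cell types resolved by reference-based deconvolution of preputial tissue:
#: the two structural tissue compartments plus six leukocyte lineages.
CELL_TYPES = (
    "epithelial",
    "fibroblast",
    "B",
    "NK",
    "CD4T",
    "monocyte",
    "neutrophil",
    "eosinophil",
)

MANIFEST_COLUMNS = ("chrom", "pos", "probe_class", "snp_flag")


@dataclass
class MethylationMatrix:
    """Methylation beta values with the linked probe manifest.

    Parameters
    ----------
    beta : pandas.DataFrame
        Probes x samples matrix of methylation fractions in [0, 1]
        (NaN allowed for missing calls).
    manifest : pandas.DataFrame
        Indexed by probe id with columns ``chrom``, ``pos`` (1-based),
        ``probe_class`` (one of ``cg``, ``ch``, ``rs``) and boolean
        ``snp_flag``.
    detection_p : pandas.DataFrame, optional
        Per-probe, per-sample detection p-values (same shape as ``beta``).
    bead_fail : pandas.DataFrame, optional
        Boolean matrix flagging probe/sample pairs measured with fewer
        than three beads.
    """

    beta: pd.DataFrame
    manifest: pd.DataFrame
    detection_p: pd.DataFrame | None = None
    bead_fail: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.beta.index.duplicated().any():
            raise ValueError("duplicate probe ids in beta matrix")
        if self.beta.columns.duplicated().any():
            raise ValueError("duplicate sample ids in beta matrix")
        vals = self.beta.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = (vals < 0) | (vals > 1)
        if np.any(bad & ~np.isnan(vals)):
            raise ValueError("beta values must lie in [0, 1] or be missing")
        missing = [c for c in MANIFEST_COLUMNS if c not in self.manifest.columns]
        if missing:
            raise ValueError(f"manifest is missing columns: {missing}")
        if not self.beta.index.isin(self.manifest.index).all():
            raise ValueError("every probe in beta must appear in the manifest")
        for aux_name in ("detection_p", "bead_fail"):
            aux = getattr(self, aux_name)
            if aux is not None and (
                not aux.index.equals(self.beta.index)
                or not aux.columns.equals(self.beta.columns)
            ):
                raise ValueError(f"{aux_name} must share beta's probe/sample axes")

    @property
    def probe_ids(self) -> pd.Index:
        return self.beta.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.beta.columns

    @property
    def n_probes(self) -> int:
        return self.beta.shape[0]

    @property
    def n_samples(self) -> int:
        return self.beta.shape[1]

    def subset_probes(self, probes) -> "MethylationMatrix":
        probes = pd.Index(probes)
        return MethylationMatrix(
            beta=self.beta.loc[probes],
            manifest=self.manifest.loc[probes],
            detection_p=None if self.detection_p is None else self.detection_p.loc[probes],
            bead_fail=None if self.bead_fail is None else self.bead_fail.loc[probes],
        )

    def subset_samples(self, samples) -> "MethylationMatrix":
        samples = pd.Index(samples)
        return MethylationMatrix(
            beta=self.beta[samples],
            manifest=self.manifest,
            detection_p=None if self.detection_p is None else self.detection_p[samples],
            bead_fail=None if self.bead_fail is None else self.bead_fail[samples],
        )


VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "effect_allele")


@dataclass
class GenotypeMatrix:
    """Genotype dosages (samples x variants) with variant metadata.

    ``dosage`` holds the expected count of the effect allele in [0, 2].
    ``variants`` is indexed by variant id with columns ``chrom``, ``pos``
    (1-based), ``ref``, ``alt`` and ``effect_allele``.
    """

    dosage: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        if self.dosage.columns.duplicated().any():
            raise ValueError("duplicate variant ids")
        if not self.dosage.columns.equals(pd.Index(self.variants.index)):
            raise ValueError("dosage columns must match variant metadata index")
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table missing columns: {missing}")
        vals = self.dosage.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 2)):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def variant_ids(self) -> pd.Index:
        return self.dosage.columns

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def subset_chrom(self, chrom) -> "GenotypeMatrix":
        keep = self.variants.index[self.variants["chrom"].astype(str) == str(chrom)]
        return GenotypeMatrix(self.dosage[keep], self.variants.loc[keep])

    def subset_samples(self, samples) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosage.loc[pd.Index(samples)], self.variants)


@dataclass
class CellTypeReference:
    """Reference beta profiles (marker probes x cell types) for deconvolution."""

    profiles: pd.DataFrame

    def __post_init__(self) -> None:
        if self.profiles.empty:
            raise ValueError("reference marker set must be non-empty")
        vals = self.profiles.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 1)):
            raise ValueError("reference profiles must lie in [0, 1]")

    @property
    def marker_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns


@dataclass
class InstrumentSet:
    """Independent meQTL variants serving as instruments for one CpG.

    ``stats`` holds the retained variants in acceptance order with their
    per-variant meQTL slope, SE, t and p.  ``flag`` is ``"ok"`` when at
    least one instrument survived pruning and ``"no_instruments"`` when
    no variant met the p-value threshold (empty sets are flagged, never
    silently dropped).
    """

    cpg: str
    stats: pd.DataFrame
    p_threshold: float = 1e-3
    r2_threshold: float = 0.2
    flag: str = "ok"

    @property
    def variant_ids(self) -> list[str]:
        return list(self.stats.index)

    @property
    def n_instruments(self) -> int:
        return len(self.stats)

    def __len__(self) -> int:
        return len(self.stats)


@dataclass
class QCReport:
    """Record of removed samples/probes with machine-readable reasons."""

    samples_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["sample_id", "reason"])
    )
    probes_removed: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["probe_id", "reason"])
    )
    n_samples_before: int = 0
    n_samples_after: int = 0
    n_probes_before: int = 0
    n_probes_after: int = 0

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "axis": ["samples", "probes"],
                "before": [self.n_samples_before, self.n_probes_before],
                "removed": [len(self.samples_removed), len(self.probes_removed)],
                "after": [self.n_samples_after, self.n_probes_after],
            }
        )
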