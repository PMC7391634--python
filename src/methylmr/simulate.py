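"""Synthetic study generator with known ground truth.

Generates genotype, methylation, phenotype and summary-statistic
fixtures that emulate a small case--control methylome/genome study of
hypospadias in preputial tissue: Hardy--Weinberg genotypes in LD blocks,
cis-meQTL effects on latent M-values, cell-mixture and batch structure
in beta values, binary outcomes with planted causal CpGs (including
chordee and severity sub-labels within cases), and two-sample
summary-statistic fixtures with known Wald ratios.

The default configuration mirrors the study design the pipeline is
aimed at: 45 cases and 46 controls, 21 cases with chordee, and 9 severe
cases (all of whom have chordee).

Every generator draws from ``numpy.random.default_rng`` seeded through a
``SeedSequence`` so identical seeds give bit-identical fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import CELL_TYPES, CellTypeReference, GenotypeMatrix, MethylationMatrix

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_genotypes",
    "simulate_methylation",
    "simulate_outcome",
    "simulate_summary_stats",
    "simulate_study",
    "make_cell_reference",
    "case_characteristics_table",
    "default_config",
]

DESIGN_LABELS = ("hypospadias", "chordee", "severity")

#: Table-style case breakdown for the default 45/21/9 design:
#: (severity group, meatal position, n with chordee, n without chordee).
_DEFAULT_CASE_TABLE = (
    ("moderate", "distal", 6, 17),
    ("moderate", "midshaft", 6, 6),
    ("moderate", "subcoronal", 0, 1),
    ("severe", "penoscrotal", 7, 0),
    ("severe", "perineal_or_proximal", 2, 0),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The sample-size defaults reproduce the target study design
    (45 cases / 46 controls, 21 with chordee, 9 severe).  Effect-size
    defaults are paper-scale: strong cis-meQTLs (around 1 M-value unit
    per allele against residual noise of 0.5) and liability effects of
    about 1.5 logits per M unit for planted causal CpGs.
    """

    n_cases: int = 45
    n_controls: int = 46
    n_chordee: int = 21
    n_severe: int = 9
    n_variants_per_chrom: int = 60
    n_cpgs: int = 200
    chromosomes: tuple = ("1", "2")
    maf_range: tuple = (0.1, 0.5)
    ld_block_size: int = 6
    ld_rho: float = 0.6
    # (cpg id, tuple of variant ids, per-allele effect in M units per dosage)
    meqtl_effects: list = field(default_factory=list)
    # (cpg id, design label, effect on outcome liability per true-M unit)
    causal_cpg_effects: list = field(default_factory=list)
    cell_fractions_alpha: tuple = (8.0, 6.0, 0.5, 0.5, 0.8, 0.8, 1.5, 0.4)
    n_marker_probes: int = 48
    marker_noise_sd: float = 0.01
    batch_assignment: dict | None = None
    n_batches: int = 2
    batch_case_confounding: float = 0.0
    batch_sd: float = 0.0
    bio_sd: float = 0.5
    noise_sd: float = 0.5
    baseline_m_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_variants_per_chrom": self.n_variants_per_chrom,
            "n_cpgs": self.n_cpgs,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if not 0 <= self.n_chordee <= self.n_cases:
            raise ValueError("n_chordee must lie in [0, n_cases]")
        if not 0 <= self.n_severe <= self.n_cases:
            raise ValueError("n_severe must lie in [0, n_cases]")
        _check_maf_range(self.maf_range)
        _check_rho(self.ld_rho)
        if len(self.cell_fractions_alpha) != len(CELL_TYPES):
            raise ValueError(
                f"cell_fractions_alpha must have {len(CELL_TYPES)} entries"
            )
        for label in {d for _, d, _ in self.causal_cpg_effects}:
            if label not in DESIGN_LABELS:
                raise ValueError(f"unknown design label {label!r}")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls

    def cpg_ids(self) -> list[str]:
        return [f"cg{i:08d}" for i in range(1, self.n_cpgs + 1)]


@dataclass
class GroundTruth:
    """Planted quantities recoverable from the generated fixtures."""

    m_true: pd.DataFrame  # noise-free genetic+baseline M (probes x samples)
    cell_fractions: pd.DataFrame  # samples x cell types, rows on the simplex
    meqtl_effects: dict  # (cpg, variant) -> M per dosage
    causal_effects: dict  # (cpg, design) -> liability per M unit
    batch_labels: pd.Series  # sample -> batch
    batch_effects: pd.DataFrame  # probes x batches, additive M shifts

    def __post_init__(self) -> None:
        frac = self.cell_fractions.to_numpy(dtype=float)
        if np.any(frac < 0) or not np.allclose(frac.sum(axis=1), 1.0):
            raise ValueError("cell fractions must be simplex-valued")


def _check_maf_range(maf_range) -> None:
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {maf_range}")


def _check_rho(rho: float) -> None:
    if not 0 <= rho < 1:
        raise ValueError(f"ld_rho must lie in [0, 1), got {rho}")


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_range=(0.1, 0.5),
    ld_block_size: int = 6,
    ld_rho: float = 0.6,
    seed: int = 0,
    chrom: str = "1",
    pos_start: int = 1_000_000,
    pos_step: int = 10_000,
    id_prefix: str = "rs",
) -> GenotypeMatrix:
    """Simulate HWE dosage genotypes in LD blocks.

    Each haplotype is drawn from a Gaussian copula with block-constant
    correlation ``ld_rho`` and thresholded at the allele-frequency
    quantile, so per-variant genotypes are Hardy--Weinberg binomial and
    variants within a block share tunable LD.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if n_variants < 1:
        raise ValueError("n_variants must be >= 1")
    _check_maf_range(maf_range)
    _check_rho(ld_rho)
    if ld_block_size < 1:
        raise ValueError("ld_block_size must be >= 1")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    from scipy import stats

    mafs = rng.uniform(maf_range[0], maf_range[1], size=n_variants)
    thresholds = stats.norm.ppf(mafs)

    sqrt_rho = np.sqrt(ld_rho)
    sqrt_res = np.sqrt(1.0 - ld_rho)
    n_blocks = int(np.ceil(n_variants / ld_block_size))
    haplos = np.empty((2, n_samples, n_variants))
    for h in range(2):
        shared = rng.standard_normal((n_samples, n_blocks))
        idio = rng.standard_normal((n_samples, n_variants))
        block_of = np.minimum(np.arange(n_variants) // ld_block_size, n_blocks - 1)
        z = sqrt_rho * shared[:, block_of] + sqrt_res * idio
        haplos[h] = (z < thresholds).astype(float)
    dosage = haplos.sum(axis=0)

    alleles = np.array(["A", "C", "G", "T"])
    ref_idx = rng.integers(0, 4, size=n_variants)
    # alt differs from ref and avoids the complementary (palindromic) base
    comp = np.array([3, 2, 1, 0])
    alt_idx = np.array(
        [
            rng.choice([j for j in range(4) if j != r and j != comp[r]])
            for r in ref_idx
        ]
    )
    variant_ids = [f"{id_prefix}{chrom}_{i + 1}" for i in range(n_variants)]
    variants = pd.DataFrame(
        {
            "chrom": str(chrom),
            "pos": pos_start + pos_step * np.arange(n_variants),
            "ref": alleles[ref_idx],
            "alt": alleles[alt_idx],
            "effect_allele": alleles[alt_idx],
            "maf": mafs,
        },
        index=pd.Index(variant_ids, name="variant_id"),
    )
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    dosage_df = pd.DataFrame(dosage, index=sample_ids, columns=variant_ids)
    return GenotypeMatrix(dosage_df, variants)


def make_cell_reference(
    n_markers: int = 48, seed: int = 12345, cell_types=CELL_TYPES
) -> CellTypeReference:
    """Construct a synthetic deconvolution reference.

    Each cell type receives a block of markers where it is strongly
    methylated while the others are hypomethylated, giving
    well-conditioned profiles for non-negative least squares.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    k = len(cell_types)
    per_type = max(n_markers // k, 1)
    n_markers = per_type * k
    profiles = rng.uniform(0.03, 0.15, size=(n_markers, k))
    for j in range(k):
        rows = slice(j * per_type, (j + 1) * per_type)
        profiles[rows, j] = rng.uniform(0.80, 0.97, size=per_type)
    marker_ids = [f"marker{i + 1:04d}" for i in range(n_markers)]
    return CellTypeReference(
        pd.DataFrame(profiles, index=marker_ids, columns=list(cell_types))
    )


def _assign_batches(config: SimulationConfig, case_mask: np.ndarray, rng) -> np.ndarray:
    """Batch labels, optionally confounded with case status.

    ``batch_case_confounding`` c in [0, 1) biases cases toward batch 0 and
    controls toward the remaining batches: with probability c the label is
    forced by case status, otherwise drawn uniformly.
    """
    n = len(case_mask)
    if config.batch_assignment is not None:
        return np.asarray([config.batch_assignment[i] for i in range(n)])
    labels = rng.integers(0, config.n_batches, size=n)
    if config.batch_case_confounding > 0 and config.n_batches > 1:
        forced = rng.random(n) < config.batch_case_confounding
        labels[forced & case_mask] = 0
        labels[forced & ~case_mask] = 1
    return labels


def m_to_beta_link(m: np.ndarray) -> np.ndarray:
    """Logistic (base-2) link from M-values to beta values."""
    return 1.0 / (1.0 + np.exp2(-np.asarray(m, dtype=float)))


def simulate_methylation(
    genotypes: GenotypeMatrix,
    config: SimulationConfig,
    cell_reference: CellTypeReference | None = None,
    case_mask: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[MethylationMatrix, GroundTruth]:
    """Simulate beta values with cis-meQTL, batch and cell-mixture structure.

    The true (outcome-relevant) methylation is
    ``m_true = baseline + sum(effect * dosage) + N(0, bio_sd)`` -- genetic
    plus per-sample biological variation; the measured latent value adds
    technical structure, ``M = m_true + batch + N(0, noise_sd)``, and
    ``beta = 2^M / (1 + 2^M)``.  Marker probes carry the convex
    combination of the reference cell-type profiles under the sample's
    Dirichlet-drawn mixture.
    """
    if cell_reference is None:
        cell_reference = make_cell_reference(config.n_marker_probes)
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(1)[0]
    )
    n_samples = genotypes.n_samples
    cpgs = config.cpg_ids()
    n_cpgs = len(cpgs)
    cpg_pos = {c: i for i, c in enumerate(cpgs)}

    for cpg, variant_ids, _ in config.meqtl_effects:
        if cpg not in cpg_pos:
            raise ValueError(f"meQTL effect references unknown CpG {cpg!r}")
        for vid in variant_ids:
            if vid not in genotypes.variant_ids:
                raise ValueError(f"meQTL effect references unknown variant {vid!r}")

    baseline = rng.normal(0.0, config.baseline_m_sd, size=n_cpgs)
    m_true = np.tile(baseline[:, None], (1, n_samples))
    meqtl_map: dict = {}
    dosage = genotypes.dosage.to_numpy()
    vidx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    for cpg, variant_ids, effect in config.meqtl_effects:
        i = cpg_pos[cpg]
        for vid in variant_ids:
            m_true[i] += effect * dosage[:, vidx[vid]]
            meqtl_map[(cpg, vid)] = effect
    m_true = m_true + rng.normal(0.0, config.bio_sd, size=m_true.shape)

    if case_mask is None:
        case_mask = np.zeros(n_samples, dtype=bool)
        case_mask[: config.n_cases] = True
    batch_labels = _assign_batches(config, case_mask, rng)
    batches = np.unique(batch_labels)
    batch_fx = rng.normal(0.0, config.batch_sd, size=(n_cpgs, len(batches)))
    if config.batch_sd == 0:
        batch_fx[:] = 0.0
    batch_component = batch_fx[:, np.searchsorted(batches, batch_labels)]

    noise = rng.normal(0.0, config.noise_sd, size=(n_cpgs, n_samples))
    m_measured = m_true + batch_component + noise
    beta_cpg = m_to_beta_link(m_measured)

    fractions = rng.dirichlet(np.asarray(config.cell_fractions_alpha), size=n_samples)
    ref = cell_reference.profiles.to_numpy()
    beta_markers = ref @ fractions.T
    beta_markers += rng.normal(0.0, config.marker_noise_sd, size=beta_markers.shape)
    beta_markers = np.clip(beta_markers, 1e-6, 1 - 1e-6)

    sample_ids = list(genotypes.sample_ids)
    all_probes = cpgs + list(cell_reference.marker_ids)
    beta = pd.DataFrame(
        np.vstack([beta_cpg, beta_markers]), index=all_probes, columns=sample_ids
    )

    # CpGs are placed interleaved with the variants along the same
    # chromosomes so chromosome-wide meQTL scans are meaningful.
    chrom_list = list(config.chromosomes)
    var_by_chrom = genotypes.variants.groupby("chrom")["pos"]
    chrom_of = []
    pos_of = []
    for i, cpg in enumerate(cpgs):
        chrom = chrom_list[i % len(chrom_list)]
        chrom_of.append(chrom)
        if chrom in var_by_chrom.groups:
            lo = int(var_by_chrom.get_group(chrom).min())
            hi = int(var_by_chrom.get_group(chrom).max())
        else:
            lo, hi = 1_000_000, 2_000_000
        pos_of.append(lo + ((i * 7919) % max(hi - lo, 1)))
    manifest = pd.DataFrame(
        {
            "chrom": chrom_of + ["M"] * len(cell_reference.marker_ids),
            "pos": pos_of + list(range(1, len(cell_reference.marker_ids) + 1)),
            "probe_class": ["cg"] * n_cpgs + ["cg"] * len(cell_reference.marker_ids),
            "snp_flag": False,
        },
        index=pd.Index(all_probes, name="probe_id"),
    )
    detection_p = pd.DataFrame(
        rng.uniform(0.0, 0.005, size=beta.shape), index=beta.index, columns=beta.columns
    )
    bead_fail = pd.DataFrame(False, index=beta.index, columns=beta.columns)
    matrix = MethylationMatrix(beta, manifest, detection_p, bead_fail)

    truth = GroundTruth(
        m_true=pd.DataFrame(m_true, index=cpgs, columns=sample_ids),
        cell_fractions=pd.DataFrame(
            fractions, index=sample_ids, columns=list(CELL_TYPES)
        ),
        meqtl_effects=meqtl_map,
        causal_effects={(c, d): e for c, d, e in config.causal_cpg_effects},
        batch_labels=pd.Series(batch_labels, index=sample_ids, name="batch"),
        batch_effects=pd.DataFrame(batch_fx, index=cpgs, columns=batches),
    )
    return matrix, truth


def _weighted_choice_without_replacement(
    log_weights: np.ndarray, k: int, rng
) -> np.ndarray:
    """Indices of k items sampled without replacement, P proportional to weights.

    Gumbel top-k: equivalent to sequential sampling proportional to the
    (remaining) weights, which conditions independent Bernoulli draws with
    odds exp(log_weights) on a fixed total.
    """
    gumbel = rng.gumbel(size=len(log_weights))
    return np.argsort(-(log_weights + gumbel))[:k]


def simulate_outcome(
    truth: GroundTruth, config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Assign case/control, chordee and severity labels from true M-values.

    Case liability is ``intercept + sum(effect * m_true_centered)`` over the
    planted causal CpGs of each design; exactly ``n_cases`` samples are
    drawn without replacement with probability proportional to the
    Bernoulli odds ``exp(liability)`` (retrospective case--control
    sampling at the configured totals).  Chordee and severity are assigned
    within cases the same way, with every severe case also having chordee.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(config.seed if seed is None else seed).spawn(2)[1]
    )
    samples = list(truth.m_true.columns)
    n = len(samples)
    if config.n_cases + config.n_controls != n:
        raise ValueError(
            "n_cases + n_controls must equal the number of simulated samples"
        )

    def liability(design: str) -> np.ndarray:
        eta = np.zeros(n)
        for (cpg, dsg), effect in truth.causal_effects.items():
            if dsg != design:
                continue
            if cpg not in truth.m_true.index:
                raise ValueError(f"causal effect references unknown CpG {cpg!r}")
            m = truth.m_true.loc[cpg].to_numpy()
            eta += effect * (m - m.mean())
        return eta

    case_idx = _weighted_choice_without_replacement(
        liability("hypospadias"), config.n_cases, rng
    )
    case = np.zeros(n, dtype=bool)
    case[case_idx] = True

    case_positions = np.flatnonzero(case)
    severe_local = _weighted_choice_without_replacement(
        liability("severity")[case_positions], config.n_severe, rng
    )
    severe = np.zeros(n, dtype=bool)
    severe[case_positions[severe_local]] = True

    # chordee: all severe cases plus a draw from the moderate cases
    moderate_positions = case_positions[~severe[case_positions]]
    n_extra = config.n_chordee - config.n_severe
    if n_extra < 0:
        raise ValueError("n_chordee must be >= n_severe (severe cases have chordee)")
    extra_local = _weighted_choice_without_replacement(
        liability("chordee")[moderate_positions], n_extra, rng
    )
    chordee = severe.copy()
    chordee[moderate_positions[extra_local]] = True

    subject_age = np.where(
        case,
        rng.normal(10.1, 2.0, size=n),
        rng.normal(10.7, 2.0, size=n),
    ).clip(min=1.0)
    tissue_age = rng.uniform(1.0, 60.0, size=n)

    pheno = pd.DataFrame(
        {
            "case": case.astype(int),
            "chordee": pd.array(
                np.where(case, chordee.astype(int), pd.NA), dtype="Int64"
            ),
            "severe": pd.array(
                np.where(case, severe.astype(int), pd.NA), dtype="Int64"
            ),
            "subject_age_months": np.round(subject_age, 2),
            "tissue_age_months": np.round(tissue_age, 2),
            "batch": truth.batch_labels.to_numpy(),
        },
        index=pd.Index(samples, name="sample_id"),
    )
    pheno["meatal_position"] = _assign_meatal_positions(pheno, config, rng)
    return pheno


def _assign_meatal_positions(
    pheno: pd.DataFrame, config: SimulationConfig, rng
) -> pd.Series:
    """Meatal-position labels within cases.

    When the configured design matches the default 45/21/9 structure the
    exact published cross-tabulation is reproduced; otherwise positions
    are drawn uniformly within severity group.
    """
    out = pd.Series(pd.NA, index=pheno.index, dtype="object")
    default_shape = (
        config.n_cases == 45 and config.n_chordee == 21 and config.n_severe == 9
    )
    for with_chordee in (True, False):
        for severe_group in ("moderate", "severe"):
            mask = (
                (pheno["case"] == 1)
                & (pheno["chordee"].astype("float") == float(with_chordee))
                & (
                    pheno["severe"].astype("float")
                    == float(severe_group == "severe")
                )
            )
            idx = pheno.index[mask.fillna(False)]
            if len(idx) == 0:
                continue
            if default_shape:
                cells = [
                    (pos, n_ch if with_chordee else n_no)
                    for grp, pos, n_ch, n_no in _DEFAULT_CASE_TABLE
                    if grp == severe_group
                ]
                labels = np.concatenate(
                    [[pos] * count for pos, count in cells]
                ) if cells else np.array([])
                if len(labels) == len(idx):
                    out.loc[idx] = labels
                    continue
            pool = [
                pos for grp, pos, _, _ in _DEFAULT_CASE_TABLE if grp == severe_group
            ]
            out.loc[idx] = rng.choice(pool, size=len(idx))
    return out


def case_characteristics_table(pheno: pd.DataFrame) -> pd.DataFrame:
    """Case breakdown as n and percent of all cases, by severity group,
    meatal position and chordee status."""
    cases = pheno[pheno["case"] == 1]
    n_cases = len(cases)
    rows = []
    for grp, pos, _, _ in _DEFAULT_CASE_TABLE:
        sub = cases[
            (cases["severe"] == int(grp == "severe"))
            & (cases["meatal_position"] == pos)
        ]
        for chord in (1, 0):
            count = int((sub["chordee"] == chord).sum())
            rows.append(
                {
                    "severity_group": grp,
                    "meatal_position": pos,
                    "chordee": "present" if chord else "absent",
                    "n": count,
                    "percent": round(100.0 * count / n_cases, 1) if n_cases else 0.0,
                }
            )
    return pd.DataFrame(rows)


def simulate_summary_stats(
    n_genes: int,
    true_wald_ratios,
    se_scales=(0.05, 0.05),
    seed: int = 0,
    flip_fraction: float = 0.0,
    palindromic_fraction: float = 0.0,
    noise: bool = True,
    tissue: str = "tissue_1",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-sample MR summary-statistic fixtures with known Wald ratios.

    One IV per gene.  The outcome effect is
    ``wald_ratio * exposure_beta + N(0, outcome_se)`` (noiseless when
    ``noise=False``).  A ``flip_fraction`` of outcome records has its
    alleles swapped and beta negated to exercise harmonization, and a
    ``palindromic_fraction`` of variants gets A/T or C/G allele pairs.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ratios = np.broadcast_to(np.asarray(true_wald_ratios, dtype=float), (n_genes,))
    se_x, se_y = se_scales

    beta_x = rng.uniform(0.3, 0.8, size=n_genes) * rng.choice([-1, 1], size=n_genes)
    beta_y = ratios * beta_x
    if noise:
        beta_y = beta_y + rng.normal(0.0, se_y, size=n_genes)

    pairs = np.array([("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"),
                      ("C", "A")])
    pick = rng.integers(0, len(pairs), size=n_genes)
    eff = pairs[pick, 0].copy()
    oth = pairs[pick, 1].copy()
    pal = rng.random(n_genes) < palindromic_fraction
    eff[pal] = "A"
    oth[pal] = "T"

    from scipy import stats

    variant_ids = [f"ivs{i + 1}" for i in range(n_genes)]
    genes = [f"GENE{i + 1}" for i in range(n_genes)]
    base = {
        "variant_id": variant_ids,
        "chrom": "1",
        "pos": 1_000_000 + 5_000 * np.arange(n_genes),
    }
    se_x_arr = np.full(n_genes, se_x)
    se_y_arr = np.full(n_genes, se_y)
    exposure = pd.DataFrame(
        {
            **base,
            "effect_allele": eff,
            "other_allele": oth,
            "beta": beta_x,
            "se": se_x_arr,
            "p": 2 * stats.norm.sf(np.abs(beta_x / se_x_arr)),
            "gene": genes,
            "tissue": tissue,
        }
    )
    flip = rng.random(n_genes) < flip_fraction
    out_eff = np.where(flip, oth, eff)
    out_oth = np.where(flip, eff, oth)
    out_beta = np.where(flip, -beta_y, beta_y)
    outcome = pd.DataFrame(
        {
            **base,
            "effect_allele": out_eff,
            "other_allele": out_oth,
            "beta": out_beta,
            "se": se_y_arr,
            "p": 2 * stats.norm.sf(np.abs(out_beta / se_y_arr)),
        }
    )
    return exposure, outcome


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """Default paper-scale study: planted causal CpGs for each design,
    each instrumented by a small set of strong cis-meQTLs."""
    base = dict(
        meqtl_effects=[
            ("cg00000001", ("rs1_1", "rs1_7", "rs1_13"), 1.2),
            ("cg00000002", ("rs2_1", "rs2_7"), 1.2),
            ("cg00000003", ("rs1_19", "rs1_25"), 1.2),
            ("cg00000010", ("rs2_13", "rs2_19"), 1.0),
        ],
        causal_cpg_effects=[
            ("cg00000001", "hypospadias", 1.5),
            ("cg00000002", "chordee", 1.5),
            ("cg00000003", "severity", 1.5),
        ],
        seed=seed,
    )
    base.update(overrides)
    return SimulationConfig(**base)


def simulate_study(
    config: SimulationConfig | None = None, seed: int | None = None
) -> dict:
    """Generate a complete coherent study (genotypes, methylation,
    phenotypes, ground truth, cell reference) from one configuration."""
    if config is None:
        config = default_config(seed=0 if seed is None else seed)
    root = np.random.SeedSequence(config.seed if seed is None else seed)
    geno_seeds = root.spawn(len(config.chromosomes) + 2)
    parts = [
        simulate_genotypes(
            config.n_samples,
            config.n_variants_per_chrom,
            maf_range=config.maf_range,
            ld_block_size=config.ld_block_size,
            ld_rho=config.ld_rho,
            seed=int(geno_seeds[i].generate_state(1)[0] % (2**31)),
            chrom=str(chrom),
        )
        for i, chrom in enumerate(config.chromosomes)
    ]
    genotypes = GenotypeMatrix(
        pd.concat([g.dosage for g in parts], axis=1),
        pd.concat([g.variants for g in parts]),
    )

    cell_reference = make_cell_reference(config.n_marker_probes)
    meth_seed = int(geno_seeds[-2].generate_state(1)[0] % (2**31))
    out_seed = int(geno_seeds[-1].generate_state(1)[0] % (2**31))

    # outcome depends on true M, which depends on genotypes only; batch
    # confounding with case status needs labels first, so draw outcome
    # from a batch-free truth, then re-generate measured betas with the
    # batch assignment keyed to the realized case labels.
    matrix, truth = simulate_methylation(
        genotypes, config, cell_reference, seed=meth_seed
    )
    pheno = simulate_outcome(truth, config, seed=out_seed)
    if config.batch_sd > 0:
        matrix, truth = simulate_methylation(
            genotypes,
            config,
            cell_reference,
            case_mask=pheno["case"].to_numpy().astype(bool),
            seed=meth_seed,
        )
        pheno["batch"] = truth.batch_labels.to_numpy()
    return {
        "config": config,
        "genotypes": genotypes,
        "methylation": matrix,
        "truth": truth,
        "phenotypes": pheno,
        "cell_reference": cell_reference,
    }
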