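"""End-to-end orchestration: simulate/load -> QC -> EWAS x3 -> meQTL ->
one-sample 2SLS MR -> two-sample Wald MR -> GWAS-region cross-reference.

One configuration dict drives the whole run; every stage writes a
self-describing TSV (``#``-prefixed provenance lines) into the output
directory and the per-CpG results are joined into a consolidated table
(EWAS effect, instrument count, 2SLS MR p) mirroring the layout of a
published per-CpG summary table.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import io as mio
from .datatypes import GenotypeMatrix, MethylationMatrix
from .ewas import DESIGNS, run_ewas, select_suggestive, tune_covariates
from .gwas_overlap import instrument_index_ld, overlap_gwas_regions
from .meqtl import instruments_for_cpgs
from .mr_onesample import fit_2sls
from .mr_twosample import WaldRatioMR, map_cis_genes
from .qc import (
    beta_to_m,
    estimate_cell_fractions,
    compare_cell_fractions,
    estimate_surrogate_variables,
    filter_probes,
    filter_samples,
    methylation_pcs,
)
from .simulate import default_config, simulate_study, simulate_summary_stats

logger = logging.getLogger("methylmr")

DEFAULT_PIPELINE_CONFIG = {
    "seed": 0,
    "simulation": {},  # overrides for simulate.default_config; None -> use inputs
    "inputs": None,  # dict of file paths when not simulating
    "qc": {
        "detection_threshold": 0.01,
        "max_fail_fraction": 0.05,
        "detection_sample_fraction": 0.05,
        "bead_fail_fraction_threshold": 0.05,
        "sex_mismatch_flags": [],
    },
    "covariates": {"n_mepcs": 3, "sv_k": "auto", "sv_permutations": 50},
    "ewas": {"designs": ["hypospadias", "chordee", "severity"], "tune": True},
    "meqtl": {"p_threshold": 1e-3, "r2_threshold": 0.2},
    "twosample": {"window": 500_000, "n_genes": 40, "true_ratio": 0.3},
    "gwas": {"window": 500_000, "r2_threshold": 0.2},
}


def _merge_config(overrides: dict | None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_PIPELINE_CONFIG))
    for key, value in (overrides or {}).items():
        if isinstance(value, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(value)
        else:
            cfg[key] = value
    return cfg


def _load_inputs(inputs: dict) -> dict:
    meth = mio.read_methylation(
        inputs["beta"], inputs["manifest"], inputs.get("detection_p")
    )
    if "vcf" in inputs:
        geno = mio.read_dosage_vcf(inputs["vcf"])
    else:
        geno = mio.read_dosage_tsv(inputs["dosage"], inputs["variants"])
    pheno = mio.read_phenotypes(inputs["phenotypes"])
    return {"methylation": meth, "genotypes": geno, "phenotypes": pheno,
            "truth": None, "cell_reference": None, "config": None}


def run_pipeline(config: dict | None = None, out_dir="pipeline_out",
                 seed: int | None = None) -> dict:
    """Run the full analysis; returns in-memory stage results and writes
    one TSV per stage plus a consolidated per-CpG table under ``out_dir``."""
    cfg = _merge_config(config)
    if seed is not None:
        cfg["seed"] = seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"tool": f"methylmr {__version__}", "seed": cfg["seed"]}
    logger.info("pipeline start (seed=%s, out=%s)", cfg["seed"], out)

    # ----- inputs -------------------------------------------------------
    if cfg.get("inputs"):
        study = _load_inputs(cfg["inputs"])
    else:
        sim_cfg = default_config(seed=cfg["seed"], **(cfg.get("simulation") or {}))
        study = simulate_study(sim_cfg)
        mio.write_methylation(study["methylation"], out, metadata=meta)
        mio.write_dosage_vcf(study["genotypes"], out / "genotypes.vcf")
        mio.write_phenotypes(study["phenotypes"], out / "phenotypes.tsv", meta)
    meth: MethylationMatrix = study["methylation"]
    geno: GenotypeMatrix = study["genotypes"]
    pheno: pd.DataFrame = study["phenotypes"]

    # ----- QC -----------------------------------------------------------
    qc_cfg = cfg["qc"]
    meth, sample_report = filter_samples(
        meth,
        qc_cfg["detection_threshold"],
        qc_cfg["max_fail_fraction"],
        qc_cfg["sex_mismatch_flags"],
    )
    meth, probe_report = filter_probes(
        meth,
        qc_cfg["detection_threshold"],
        qc_cfg["detection_sample_fraction"],
        qc_cfg["bead_fail_fraction_threshold"],
    )
    pheno = pheno.loc[meth.sample_ids]
    qc_table = pd.concat(
        [
            sample_report.samples_removed.rename(columns={"sample_id": "id"}).assign(axis="sample"),
            probe_report.probes_removed.rename(columns={"probe_id": "id"}).assign(axis="probe"),
        ],
        ignore_index=True,
    )
    mio.write_tsv(qc_table, out / "qc_report.tsv", meta, index=False)

    # ----- cell fractions ----------------------------------------------
    fractions = None
    if study.get("cell_reference") is not None:
        fractions = estimate_cell_fractions(meth, study["cell_reference"])
        mio.write_tsv(fractions.rename_axis("sample_id"), out / "cell_fractions.tsv", meta)
        tests = compare_cell_fractions(fractions, pheno["case"])
        mio.write_tsv(tests, out / "cell_fraction_tests.tsv", meta)

    # analysis probes: CpG probes on real chromosomes (markers sit apart)
    cpg_probes = meth.manifest.loc[meth.probe_ids]
    cpg_probes = cpg_probes[(cpg_probes["probe_class"] == "cg")
                            & (cpg_probes["chrom"].astype(str) != "M")].index
    analysis = meth.subset_probes(cpg_probes)

    # ----- covariates ---------------------------------------------------
    cov_cfg = cfg["covariates"]
    mepcs, _ = methylation_pcs(analysis, cov_cfg["n_mepcs"])
    svs = estimate_surrogate_variables(
        analysis,
        protected_design=pheno["case"].to_numpy(dtype=float),
        k=cov_cfg["sv_k"],
        n_permutations=cov_cfg["sv_permutations"],
        random_state=int(cfg["seed"]) % (2**31),
    )
    ages = pheno[["subject_age_months", "tissue_age_months"]].astype(float)
    covars_all = [
        ("none", None),
        ("svs", svs if svs.shape[1] else None),
        ("svs+mepcs", pd.concat([svs, mepcs], axis=1) if svs.shape[1] else mepcs),
    ]
    if fractions is not None:
        full = pd.concat([svs, mepcs, fractions.iloc[:, :-1], ages], axis=1)
        covars_all.append(("svs+mepcs+cells+ages", full))
    covariates_out = pd.concat([svs, mepcs], axis=1)
    mio.write_tsv(covariates_out.rename_axis("sample_id"), out / "covariates.tsv", meta)

    # ----- EWAS ---------------------------------------------------------
    results_by_design: dict[str, pd.DataFrame] = {}
    tuning_rows = []
    for name in cfg["ewas"]["designs"]:
        design = DESIGNS[name]
        if cfg["ewas"]["tune"]:
            chosen_name, chosen, trace = tune_covariates(
                analysis, pheno, design, covars_all
            )
            trace["design"] = name
            tuning_rows.append(trace)
        else:
            chosen_name, chosen = "none", None
        res = run_ewas(analysis, pheno, design, covariates=chosen)
        res.attrs["covariates"] = chosen_name
        results_by_design[name] = res
        mio.write_tsv(
            res,
            out / f"ewas_{name}.tsv",
            {**meta, "design": name, "covariates": chosen_name,
             "lambda": f"{res.attrs['lambda']:.4f}"},
        )
    if tuning_rows:
        mio.write_tsv(pd.concat(tuning_rows, ignore_index=True),
                      out / "covariate_tuning.tsv", meta, index=False)

    suggestive = select_suggestive(results_by_design, manifest=meth.manifest)
    mio.write_tsv(suggestive, out / "suggestive_cpgs.tsv", meta, index=False)

    # ----- meQTL + instruments -----------------------------------------
    mvalues = beta_to_m(analysis.beta)
    instruments = instruments_for_cpgs(
        suggestive,
        mvalues,
        geno,
        covariates=mepcs,
        p_threshold=cfg["meqtl"]["p_threshold"],
        r2_threshold=cfg["meqtl"]["r2_threshold"],
    )
    iv_rows = []
    for cpg, iv in instruments.items():
        for vid, row in iv.stats.iterrows():
            iv_rows.append({"cpg": cpg, "variant_id": vid, **row.to_dict(),
                            "flag": iv.flag})
        if iv.n_instruments == 0:
            iv_rows.append({"cpg": cpg, "variant_id": "", "flag": iv.flag})
    mio.write_tsv(pd.DataFrame(iv_rows), out / "instruments.tsv", meta, index=False)

    # ----- one-sample 2SLS MR ------------------------------------------
    mr_rows = []
    for _, row in suggestive.iterrows():
        cpg, design_name = row["cpg"], row["design"]
        iv = instruments.get(cpg)
        if iv is None or iv.n_instruments == 0:
            continue
        design = DESIGNS[design_name]
        labels = design.group_labels(pheno)
        result = fit_2sls(
            mvalues.loc[cpg, labels.index],
            labels,
            iv,
            genotypes=geno,
            design=design_name,
        )
        mr_rows.append(result.to_dict())
    mr_table = pd.DataFrame(mr_rows)
    mio.write_tsv(mr_table, out / "mr_onesample.tsv", meta, index=False)

    # ----- consolidated table ------------------------------------------
    consolidated = suggestive[
        ["cpg", "design", "chrom", "pos", "case_mean", "comparison_mean",
         "delta_beta", "p", "q"]
    ].copy()
    consolidated["n_meqtls"] = consolidated["cpg"].map(
        lambda c: instruments[c].n_instruments if c in instruments else 0
    )
    if not mr_table.empty:
        consolidated = consolidated.merge(
            mr_table[["cpg", "design", "p"]].rename(columns={"p": "mr_2sls_p"}),
            on=["cpg", "design"],
            how="left",
        )
    else:
        consolidated["mr_2sls_p"] = np.nan
    mio.write_tsv(consolidated, out / "consolidated.tsv", meta, index=False)

    # ----- two-sample Wald MR on summary fixtures ----------------------
    ts_cfg = cfg["twosample"]
    rng_seed = int(cfg["seed"]) % (2**31)
    exposure, outcome = simulate_summary_stats(
        ts_cfg["n_genes"], ts_cfg["true_ratio"], seed=rng_seed
    )
    wald = WaldRatioMR().fit(exposure, outcome)
    mio.write_tsv(wald.results_, out / "mr_twosample.tsv", meta, index=False)

    # cis gene mapping for the suggestive CpGs against a gene annotation
    genes = cfg.get("genes")
    cis_rows = []
    if genes is None and not suggestive.empty:
        # synthetic annotation tiled around the observed CpG positions
        genes = _synthetic_gene_annotation(suggestive)
    if genes is not None:
        for _, row in suggestive.iterrows():
            hits = map_cis_genes(int(row["pos"]), row["chrom"], genes,
                                 window=ts_cfg["window"])
            for _, g in hits.iterrows():
                cis_rows.append({"cpg": row["cpg"], "gene": g["gene"]})
    mio.write_tsv(pd.DataFrame(cis_rows, columns=["cpg", "gene"]),
                  out / "cis_genes.tsv", meta, index=False)

    # ----- GWAS-region cross-reference ---------------------------------
    gw_cfg = cfg["gwas"]
    index_variants = cfg.get("gwas_index")
    if index_variants is None and not suggestive.empty:
        first = suggestive.iloc[0]
        index_variants = pd.DataFrame(
            {
                "variant_id": ["index_near", "index_far"],
                "chrom": [str(first["chrom"])] * 2,
                "pos": [int(first["pos"]) + 100_000, int(first["pos"]) + 10_000_000],
            }
        )
    overlap = overlap_gwas_regions(suggestive, index_variants, gw_cfg["window"]) \
        if index_variants is not None else pd.DataFrame()
    ld_rows = []
    for _, pair in overlap.iterrows():
        iv = instruments.get(pair["cpg"])
        if iv is None:
            continue
        verdict = instrument_index_ld(
            iv, pair["index_variant"], geno, gw_cfg["r2_threshold"],
            study_genotypes=geno,
            study_mvalues=mvalues.loc[pair["cpg"]] if pair["cpg"] in mvalues.index else None,
        )
        ld_rows.append(
            {
                "cpg": pair["cpg"],
                "index_variant": pair["index_variant"],
                "max_r2": verdict["max_r2"],
                "verdict": verdict["verdict"],
                "index_meqtl_p": verdict["index_meqtl_p"],
            }
        )
    mio.write_tsv(
        pd.DataFrame(ld_rows, columns=["cpg", "index_variant", "max_r2",
                                       "verdict", "index_meqtl_p"]),
        out / "gwas_overlap.tsv", meta, index=False,
    )

    # ----- run log ------------------------------------------------------
    log = {
        "version": __version__,
        "seed": cfg["seed"],
        "parameters": {k: v for k, v in cfg.items()
                       if k not in ("genes", "gwas_index")},
        "n_samples": int(meth.n_samples),
        "n_probes": int(meth.n_probes),
        "n_suggestive": int(len(suggestive)),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    logger.info("pipeline done: %d suggestive CpGs", len(suggestive))

    return {
        "config": cfg,
        "methylation": meth,
        "phenotypes": pheno,
        "qc": {"samples": sample_report, "probes": probe_report},
        "cell_fractions": fractions,
        "covariates": {"svs": svs, "mepcs": mepcs},
        "ewas": results_by_design,
        "suggestive": suggestive,
        "instruments": instruments,
        "mr_onesample": mr_table,
        "consolidated": consolidated,
        "mr_twosample": wald.results_,
        "gwas_overlap": pd.DataFrame(ld_rows) if ld_rows else pd.DataFrame(),
        "out_dir": out,
    }


def _synthetic_gene_annotation(suggestive: pd.DataFrame) -> pd.DataFrame:
    """Deterministic gene intervals tiled around suggestive CpGs, used
    when no annotation table is supplied (synthetic runs)."""
    rows = []
    for i, (_, row) in enumerate(suggestive.drop_duplicates("cpg").iterrows()):
        pos = int(row["pos"])
        for j, offset in enumerate((-400_000, -100_000, 50_000, 300_000, 700_000)):
            start = max(pos + offset, 1)
            rows.append(
                {
                    "gene": f"GENE_{row['cpg']}_{j + 1}",
                    "chrom": str(row["chrom"]),
                    "start": start,
                    "end": start + 20_000,
                }
            )
    return pd.DataFrame(rows)
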