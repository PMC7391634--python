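"""Readers and writers for the pipeline's text formats.

All tables are TSV with optional ``#``-prefixed metadata lines before
the header.  Genotypes travel either as a dosage TSV (samples x
variants plus a variant metadata block) or as a VCF with a per-sample
``DS`` FORMAT field (hard-call ``GT`` sums are used when ``DS`` is
absent).  Coordinates are 1-based throughout.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CellTypeReference, GenotypeMatrix, MethylationMatrix

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_methylation",
    "read_methylation",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_phenotypes",
    "read_phenotypes",
    "write_summary_stats",
    "read_summary_stats",
]


def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None,
              index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def write_methylation(m: MethylationMatrix, out_dir, prefix: str = "methylation",
                      metadata: dict | None = None) -> dict:
    """Write beta matrix, manifest and optional detection-p/bead tables.

    The manifest TSV carries ``probe_id``, ``chrom``, ``pos_1based``,
    ``probe_class``, ``snp_flag`` and ``bead_fail_fraction``.
    """
    out_dir = Path(out_dir)
    paths = {"beta": out_dir / f"{prefix}_beta.tsv",
             "manifest": out_dir / f"{prefix}_manifest.tsv"}
    write_tsv(m.beta.rename_axis("probe_id"), paths["beta"], metadata)
    manifest = m.manifest.loc[m.probe_ids, ["chrom", "pos", "probe_class", "snp_flag"]]
    manifest = manifest.rename(columns={"pos": "pos_1based"})
    manifest = manifest.assign(
        bead_fail_fraction=(
            m.bead_fail.mean(axis=1) if m.bead_fail is not None else 0.0
        )
    )
    write_tsv(manifest.rename_axis("probe_id"), paths["manifest"], metadata)
    if m.detection_p is not None:
        paths["detection_p"] = out_dir / f"{prefix}_detection_p.tsv"
        write_tsv(m.detection_p.rename_axis("probe_id"), paths["detection_p"])
    return paths


def read_methylation(beta_path, manifest_path, detection_p_path=None) -> MethylationMatrix:
    beta = read_tsv(beta_path)
    manifest = read_tsv(manifest_path).rename(columns={"pos_1based": "pos"})
    detection = read_tsv(detection_p_path) if detection_p_path else None
    bead = None
    if "bead_fail_fraction" in manifest.columns:
        # reconstruct a per-sample boolean flag only when a probe fails
        # everywhere; per-sample bead data does not survive the round trip
        frac = manifest["bead_fail_fraction"].astype(float)
        bead = pd.DataFrame(
            np.tile((frac >= 1.0).to_numpy()[:, None], (1, beta.shape[1])),
            index=beta.index,
            columns=beta.columns,
        )
    return MethylationMatrix(beta, manifest, detection, bead)


def write_dosage_tsv(g: GenotypeMatrix, dosage_path, variants_path,
                     metadata: dict | None = None) -> None:
    write_tsv(g.dosage.rename_axis("sample_id"), dosage_path, metadata)
    write_tsv(g.variants.rename_axis("variant_id"), variants_path, metadata)


def read_dosage_tsv(dosage_path, variants_path) -> GenotypeMatrix:
    dosage = read_tsv(dosage_path)
    variants = read_tsv(variants_path)
    return GenotypeMatrix(dosage, variants)


def write_dosage_vcf(g: GenotypeMatrix, path) -> None:
    """Minimal VCF 4.2 with a per-sample DS (dosage) FORMAT field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    samples = list(g.sample_ids)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,'
            'Description="Estimated alternate allele dosage">\n'
        )
        fh.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        for chrom in pd.unique(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(samples) + "\n")
        order = g.variants.sort_values(["chrom", "pos"], kind="mergesort").index
        for vid in order:
            row = g.variants.loc[vid]
            doses = g.dosage[vid].to_numpy()
            calls = []
            for d in doses:
                gt = "0/0" if d < 0.5 else ("0/1" if d < 1.5 else "1/1")
                calls.append(f"{gt}:{d:.4f}")
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{vid}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT:DS\t" + "\t".join(calls) + "\n"
            )


def read_dosage_vcf(path) -> GenotypeMatrix:
    """Read dosages from a VCF (DS field; GT hard-call sum as fallback).

    The ALT allele is taken as the effect allele, matching the writer.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts, rows = [], [], [], [], [], []
    for variant in vcf:
        ds = variant.format("DS")
        if ds is not None:
            dose = np.asarray(ds, dtype=float).reshape(len(samples))
        else:
            gts = np.asarray(variant.genotype.array())[:, :2]
            dose = np.clip(gts, 0, None).sum(axis=1).astype(float)
        ids.append(variant.ID)
        chroms.append(str(variant.CHROM))
        poss.append(int(variant.POS))
        refs.append(variant.REF)
        alts.append(variant.ALT[0] if variant.ALT else ".")
        rows.append(dose)
    vcf.close()
    dosage = pd.DataFrame(
        np.column_stack(rows), index=samples, columns=ids
    )
    variants = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": poss,
            "ref": refs,
            "alt": alts,
            "effect_allele": alts,
        },
        index=pd.Index(ids, name="variant_id"),
    )
    return GenotypeMatrix(dosage, variants)


def write_phenotypes(pheno: pd.DataFrame, path, metadata: dict | None = None) -> None:
    write_tsv(pheno.rename_axis("sample_id"), path, metadata)


def read_phenotypes(path) -> pd.DataFrame:
    pheno = read_tsv(path)
    for col in ("chordee", "severe"):
        if col in pheno.columns:
            pheno[col] = pheno[col].astype("Int64")
    return pheno


SUMMARY_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p",
]


def write_summary_stats(df: pd.DataFrame, path, metadata: dict | None = None) -> None:
    cols = SUMMARY_COLUMNS + [c for c in ("gene", "tissue") if c in df.columns]
    write_tsv(df[cols], path, metadata, index=False)


def read_summary_stats(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
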