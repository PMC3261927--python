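"""TSV / VCF readers and writers, and the pipeline configuration.

On-disk layout: genotype TSV (rows = SNPs, columns = samples, dosage 0-2
or fractional, empty/NA = missing), expression TSV (rows = probes), SNP
annotation TSV (snp_id, chrom, pos, allele1, allele2), probe annotation
TSV (probe_id, chrom, midpoint), truth-table TSV for planted effects.
VCF input is read through cyvcf2 when installed; VCF output is plain text
with GT fields.  Coordinates are 1-based, windows inclusive.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import ExpressionMatrix, GenotypeMatrix, ParseError

log = logging.getLogger(__name__)


def write_genotypes(geno: GenotypeMatrix, dosage_path, annotation_path=None) -> None:
    frame = pd.DataFrame(geno.dosage, index=geno.snps.index, columns=geno.samples)
    frame.to_csv(dosage_path, sep="\t", float_format="%g", na_rep="NA")
    if annotation_path is not None:
        cols = [c for c in ("chrom", "pos", "allele1", "allele2") if c in geno.snps]
        geno.snps[cols].to_csv(annotation_path, sep="\t")


def read_genotypes(dosage_path, annotation_path) -> GenotypeMatrix:
    try:
        frame = pd.read_csv(dosage_path, sep="\t", index_col=0, na_values=["NA", ""])
    except Exception as err:
        raise ParseError(f"cannot parse genotype TSV {dosage_path}: {err}") from err
    snps = read_snp_annotation(annotation_path)
    if not frame.index.equals(snps.index):
        snps = snps.reindex(frame.index)
        if snps["pos"].isna().any():
            raise ParseError("genotype TSV contains SNPs missing from the annotation")
    return GenotypeMatrix(frame.to_numpy(float), snps, [str(c) for c in frame.columns])


def read_snp_annotation(path) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"snp_id", "chrom", "pos"}
    if not required.issubset(ann.columns):
        raise ParseError(f"SNP annotation needs columns {sorted(required)}")
    if ann["snp_id"].duplicated().any():
        raise ParseError("duplicated SNP id in annotation")
    return ann.set_index("snp_id")


def write_expression(expr: ExpressionMatrix, values_path, annotation_path=None) -> None:
    frame = pd.DataFrame(expr.values, index=expr.probes.index, columns=expr.samples)
    frame.to_csv(values_path, sep="\t", na_rep="NA")
    if annotation_path is not None:
        expr.probes[["chrom", "midpoint"]].to_csv(annotation_path, sep="\t")


def read_expression(values_path, annotation_path, **flags) -> ExpressionMatrix:
    try:
        frame = pd.read_csv(values_path, sep="\t", index_col=0, na_values=["NA", ""])
    except Exception as err:
        raise ParseError(f"cannot parse expression TSV {values_path}: {err}") from err
    probes = pd.read_csv(annotation_path, sep="\t", dtype={"chrom": str}).set_index("probe_id")
    if not frame.index.equals(probes.index):
        probes = probes.reindex(frame.index)
        if probes["midpoint"].isna().any():
            raise ParseError("expression TSV contains probes missing from the annotation")
    return ExpressionMatrix(
        frame.to_numpy(float), probes, [str(c) for c in frame.columns], **flags
    )


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Minimal diploid VCF with GT fields from rounded dosages."""
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.samples)
            + "\n"
        )
        for i, (snp_id, row) in enumerate(geno.snps.iterrows()):
            calls = [
                "./." if np.isnan(d) else gt_map[int(round(d))]
                for d in geno.dosage[i]
            ]
            fh.write(
                f"{row['chrom']}\t{int(row['pos'])}\t{snp_id}\t{row.get('allele1', 'A')}\t"
                f"{row.get('allele2', 'G')}\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read GT fields into alternate-allele dosages (requires cyvcf2)."""
    try:
        from cyvcf2 import VCF
    except ImportError as err:  # pragma: no cover - environment-dependent
        raise ImportError("VCF input requires the cyvcf2 package") from err
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, meta, ids = [], [], []
    for variant in vcf:
        gts = np.array(variant.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        dosage = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dosage)
        ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        meta.append(
            {
                "chrom": str(variant.CHROM),
                "pos": int(variant.POS),
                "allele1": variant.REF,
                "allele2": variant.ALT[0] if variant.ALT else ".",
            }
        )
    snps = pd.DataFrame(meta, index=pd.Index(ids, name="snp_id"))
    return GenotypeMatrix(np.asarray(rows), snps, samples)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; defaults follow the standard
    design: 1 Mb cis window, 50 PCs removed, FDR 0.05 with 100
    permutations, 100 subsampling rounds, calibrated or fixed (0.21)
    profile-correlation threshold."""

    cohorts: dict[str, dict[str, str]] = field(default_factory=dict)  # label -> file paths
    reference_cohort: str | None = None
    window_bp: int = 1_000_000
    n_pcs: int = 50
    fdr_level: float = 0.05
    n_permutations: int = 100
    n_resamples: int = 100
    alpha_bonf_mode: str = "auto"  # "auto" | "fixed"
    alpha_bonf_fixed: float = 6.23e-8
    r_thres_mode: str = "calibrate"  # "calibrate" | "fixed"
    r_thres_fixed: float = 0.21
    ld_unlinked_max: float = 0.05
    joint_pca: bool = True
    normalize: bool = True
    seed: int = 0

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
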