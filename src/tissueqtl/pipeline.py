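"""End-to-end orchestration: scans, meta-analysis, discordance, classification.

``analyze_tissue_pair`` runs the complete reference-versus-target
comparison for one tissue pair: per-tissue cis scans with permutation
FDR, subsampling + GEVD discordance tests on each eProbe's top eSNPs,
profile-correlation threshold calibration, and the four-category
classification of discordant, target-significant probes.

``run_pipeline`` wires the stages behind a ``PipelineConfig``: input
loading (or simulation), SNP QC, joint quantile normalisation and PC
removal, per-tissue scans plus the non-reference meta-analysis, stepwise
conditional mapping, tissue-pair analyses against the reference, and
summary tables, writing every stage's TSV plus a manifest with checksums.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cis import CisScanner, meta_scan_with_fdr, scan_with_fdr, FdrResult
from .conditional import stepwise_conditional
from .datatypes import DegenerateInputError, EmptyResultError, ExpressionMatrix, GenotypeMatrix
from .discordance import bonferroni_alpha, discordance_test
from .enrichment import distance_bin_summary, summarize_fractions
from .io import PipelineConfig, read_expression, read_genotypes, write_expression, write_genotypes
from .preprocess import joint_pca_correct, quantile_normalize_log2, snp_qc
from .profiles import (
    DEFAULT_R_THRESHOLD,
    association_profile,
    classify_category,
    empirical_r_threshold,
)

log = logging.getLogger(__name__)


@dataclass
class TissuePairResult:
    reference: str
    target: str
    scans: dict[str, pd.DataFrame]
    fdr: dict[str, FdrResult]
    alpha: float
    discordance: pd.DataFrame
    r_threshold: float
    calls: pd.DataFrame

    def category_counts(self) -> pd.Series:
        return self.calls["category"].value_counts() if len(self.calls) else pd.Series(dtype=int)


def _top_snp_per_probe(scan: pd.DataFrame) -> dict[str, str]:
    idx = scan.groupby("probe_id")["p"].idxmin()
    return dict(zip(scan.loc[idx, "probe_id"], scan.loc[idx, "snp_id"]))


def analyze_tissue_pair(
    expr: dict[str, ExpressionMatrix],
    genotypes: dict[str, GenotypeMatrix],
    reference: str,
    target: str,
    window_bp: int = 1_000_000,
    fdr_level: float = 0.05,
    n_permutations: int = 100,
    n_resamples: int = 100,
    alpha: float | None = None,
    n_comparisons: int = 1,
    r_thres: float | None = None,
    ld_unlinked_max: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> TissuePairResult:
    """Full reference-vs-target analysis for one tissue pair.

    ``alpha=None`` derives the Bonferroni level from the number of
    significant pairs (union of both analyses) and ``n_comparisons``;
    ``r_thres=None`` calibrates the profile-correlation threshold by
    genome-reassignment permutation (falling back to the fixed default
    when calibration is undefined).
    """
    rng = np.random.default_rng(rng)
    scans: dict[str, pd.DataFrame] = {}
    fdr: dict[str, FdrResult] = {}
    for tissue in (reference, target):
        scans[tissue], fdr[tissue], _ = scan_with_fdr(
            expr[tissue],
            genotypes[tissue],
            tissue=tissue,
            window_bp=window_bp,
            fdr_level=fdr_level,
            n_permutations=n_permutations,
            rng=rng,
        )
    sig = {
        t: set(
            map(tuple, scans[t].loc[scans[t]["significant"], ["probe_id", "snp_id"]].to_numpy())
        )
        for t in (reference, target)
    }
    union_pairs = sig[reference] | sig[target]
    if alpha is None:
        alpha = bonferroni_alpha(max(len(union_pairs), 1), n_comparisons)
    sig_probes = {t: {p for p, _ in sig[t]} for t in (reference, target)}
    top = {t: _top_snp_per_probe(scans[t]) for t in (reference, target)}

    eprobes = sorted(sig_probes[reference] | sig_probes[target])
    rows = []
    for probe in eprobes:
        candidates = {top[target].get(probe), top[reference].get(probe)} - {None}
        best = None
        for snp in sorted(candidates):
            try:
                rec = discordance_test(
                    probe,
                    snp,
                    expr[reference].row(probe),
                    genotypes[reference].row(snp),
                    expr[target].row(probe),
                    genotypes[target].row(snp),
                    (reference, target),
                    alpha=alpha,
                    n_resamples=n_resamples,
                    rng=rng,
                )
            except DegenerateInputError as err:
                log.warning("pair (%s, %s) skipped: %s", probe, snp, err)
                continue
            if best is None or rec.p_discordance < best.p_discordance:
                best = rec
        if best is None:
            continue
        rows.append(
            {
                "probe_id": probe,
                "snp_id": best.snp_id,
                "tissue_pair": f"{reference}|{target}",
                "z_target": best.z_target,
                "gamma": best.gevd.location_gamma,
                "beta": best.gevd.scale_beta,
                "alpha": best.gevd.shape_alpha,
                "converged": best.gevd.converged,
                "p_discordance": best.p_discordance,
                "call": best.call,
            }
        )
    discordance = pd.DataFrame(
        rows,
        columns=[
            "probe_id", "snp_id", "tissue_pair", "z_target", "gamma", "beta",
            "alpha", "converged", "p_discordance", "call",
        ],
    )
    discordant_probes = set(discordance.loc[discordance["call"] == "discordant", "probe_id"])
    candidates = sorted(discordant_probes & sig_probes[target])

    if r_thres is None:
        if candidates:
            try:
                r_thres = empirical_r_threshold(
                    candidates,
                    (reference, target),
                    expr,
                    genotypes,
                    window_bp=window_bp,
                    n_permutations=n_permutations,
                    fdr_level=fdr_level,
                    rng=rng,
                ).r_thres
            except EmptyResultError:
                log.warning(
                    "profile-threshold calibration undefined; using fixed default "
                    "%.2f (derived on the original study's cohorts)",
                    DEFAULT_R_THRESHOLD,
                )
                r_thres = DEFAULT_R_THRESHOLD
        else:
            r_thres = DEFAULT_R_THRESHOLD

    call_rows = []
    for probe in candidates:
        try:
            prof_ref = association_profile(probe, scans[reference], genotypes[reference].snps)
            prof_tgt = association_profile(probe, scans[target], genotypes[target].snps)
            call = classify_category(
                probe,
                (reference, target),
                prof_ref,
                prof_tgt,
                significant_reference=probe in sig_probes[reference],
                significant_target=probe in sig_probes[target],
                top_esnp_reference=top[reference].get(probe),
                top_esnp_target=top[target].get(probe),
                genotypes=genotypes[reference],
                r_thres=r_thres,
                ld_unlinked_max=ld_unlinked_max,
            )
        except DegenerateInputError as err:
            log.warning("probe %s not classified: %s", probe, err)
            continue
        call_rows.append(
            {
                "probe_id": probe,
                "tissue_pair": f"{reference}|{target}",
                "r_profile": call.r_profile,
                "r_thres": r_thres,
                "category": call.category,
                "sig_ref": call.significant_reference,
                "sig_target": call.significant_target,
                "top_ref": call.top_esnp_reference,
                "top_target": call.top_esnp_target,
                "ld_r2": call.ld_r2_between_tops,
                "direction": call.direction_agreement,
            }
        )
    calls = pd.DataFrame(
        call_rows,
        columns=[
            "probe_id", "tissue_pair", "r_profile", "r_thres", "category",
            "sig_ref", "sig_target", "top_ref", "top_target", "ld_r2", "direction",
        ],
    )
    return TissuePairResult(
        reference, target, scans, fdr, alpha, discordance, float(r_thres), calls
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig,
    outdir,
    expr: dict[str, ExpressionMatrix] | None = None,
    genotypes: dict[str, GenotypeMatrix] | None = None,
    max_conditional_probes: int | None = 50,
) -> dict:
    """Execute the full pipeline and write every stage's TSV plus a
    manifest (config, seed, per-file checksums).  Cohort data may be
    passed in memory (e.g. from the simulator) or read from the paths in
    ``config.cohorts``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    stage = "load"
    try:
        if expr is None or genotypes is None:
            expr, genotypes = {}, {}
            for label, paths in config.cohorts.items():
                genotypes[label] = read_genotypes(paths["genotypes"], paths["snp_annotation"])
                expr[label] = read_expression(paths["expression"], paths["probe_annotation"])
        else:
            expr, genotypes = dict(expr), dict(genotypes)  # never mutate caller data
        cohorts = list(expr)
        reference = config.reference_cohort or max(
            cohorts, key=lambda c: expr[c].n_samples
        )
        targets = [c for c in cohorts if c != reference]

        stage = "qc"
        qc_reports = {}
        for label in cohorts:
            ref_geno = genotypes[reference] if label != reference else None
            genotypes[label], qc_reports[label] = snp_qc(genotypes[label], ref_geno)
        shared = genotypes[reference].snp_ids
        for label in targets:
            shared = shared.intersection(genotypes[label].snp_ids)
        for label in cohorts:
            genotypes[label] = genotypes[label].subset_snps(list(shared))
            qc_reports[label].to_frame().to_csv(outdir / f"qc_{label}.tsv", sep="\t", index=False)

        stage = "normalize"
        mats = [expr[c] for c in cohorts]
        if config.normalize and not all(m.quantile_normalized for m in mats):
            mats = quantile_normalize_log2(mats)
        if config.n_pcs > 0:
            n_joint = sum(m.n_samples for m in mats)
            n_pcs = min(config.n_pcs, n_joint - 2)
            if config.joint_pca:
                mats = joint_pca_correct(mats, n_pcs)
            else:
                from .preprocess import pca_correct

                mats = [pca_correct(m, min(n_pcs, m.n_samples - 2)) for m in mats]
        expr = dict(zip(cohorts, mats))
        for label in cohorts:
            write_expression(expr[label], outdir / f"expression_corrected_{label}.tsv")

        stage = "cis_mapping"
        scans, fdrs, scanners = {}, {}, {}
        for label in cohorts:
            scans[label], fdrs[label], scanners[label] = scan_with_fdr(
                expr[label],
                genotypes[label],
                tissue=label,
                window_bp=config.window_bp,
                fdr_level=config.fdr_level,
                n_permutations=config.n_permutations,
                rng=rng,
            )
            scans[label].to_csv(outdir / f"eqtl_{label}.tsv", sep="\t", index=False)
        if len(targets) > 1:
            meta_frame, meta_fdr = meta_scan_with_fdr(
                {t: scanners[t] for t in targets},
                fdr_level=config.fdr_level,
                n_permutations=config.n_permutations,
                rng=rng,
            )
            meta_frame.to_csv(outdir / "eqtl_meta.tsv", sep="\t", index=False)
            fdrs["meta"] = meta_fdr
        pd.DataFrame(
            [
                {
                    "analysis": k,
                    "p_threshold": v.p_threshold,
                    "n_significant": v.n_significant,
                    "fdr_level": v.fdr_level,
                    "n_permutations": v.n_permutations,
                }
                for k, v in fdrs.items()
            ]
        ).to_csv(outdir / "fdr_summary.tsv", sep="\t", index=False)

        stage = "conditional"
        cond_rows = []
        for label in cohorts:
            sig = scans[label][scans[label]["significant"]]
            probes = list(dict.fromkeys(sig["probe_id"]))[:max_conditional_probes]
            for probe in probes:
                cis_snps = list(sig.loc[sig["probe_id"] == probe, "snp_id"])
                all_snps = list(
                    scans[label].loc[scans[label]["probe_id"] == probe, "snp_id"]
                )
                res = stepwise_conditional(
                    expr[label],
                    genotypes[label],
                    probe,
                    all_snps or cis_snps,
                    fdr_level=config.fdr_level,
                    n_permutations=config.n_permutations,
                    rng=rng,
                )
                for s in res.signals:
                    cond_rows.append(
                        {
                            "probe_id": probe,
                            "tissue": label,
                            "rank": s.rank,
                            "snp_id": s.snp_id,
                            "conditional_p": s.conditional_p,
                            "conditional_z": s.conditional_z,
                            "round_threshold": s.round_threshold,
                        }
                    )
        pd.DataFrame(
            cond_rows,
            columns=["probe_id", "tissue", "rank", "snp_id", "conditional_p",
                     "conditional_z", "round_threshold"],
        ).to_csv(outdir / "conditional_signals.tsv", sep="\t", index=False)

        stage = "discordance_classification"
        alpha = None if config.alpha_bonf_mode == "auto" else config.alpha_bonf_fixed
        r_thres = None if config.r_thres_mode == "calibrate" else config.r_thres_fixed
        all_calls, all_disc = [], []
        for target in targets:
            result = analyze_tissue_pair(
                expr,
                genotypes,
                reference,
                target,
                window_bp=config.window_bp,
                fdr_level=config.fdr_level,
                n_permutations=config.n_permutations,
                n_resamples=config.n_resamples,
                alpha=alpha,
                n_comparisons=len(targets),
                r_thres=r_thres,
                ld_unlinked_max=config.ld_unlinked_max,
                rng=rng,
            )
            all_disc.append(result.discordance)
            all_calls.append(result.calls)
        all_disc = [d for d in all_disc if len(d)]
        all_calls = [c for c in all_calls if len(c)]
        discordance = pd.concat(all_disc, ignore_index=True) if all_disc else pd.DataFrame(
            columns=["probe_id", "snp_id", "tissue_pair", "call"]
        )
        calls = pd.concat(all_calls, ignore_index=True) if all_calls else pd.DataFrame(
            columns=["probe_id", "tissue_pair", "category"]
        )
        discordance.to_csv(outdir / "discordance.tsv", sep="\t", index=False)
        calls.to_csv(outdir / "category_calls.tsv", sep="\t", index=False)

        stage = "report"
        summary = {}
        if len(discordance):
            n_disc = int((discordance["call"] == "discordant").sum())
            summary.update(
                summarize_fractions(
                    {"pct_probes_discordant": (n_disc, len(discordance))}
                )
            )
        if len(calls):
            for cat, cnt in calls["category"].value_counts().items():
                summary[f"n_{cat}"] = int(cnt)
        # distance summary over all significant pairs
        sig_frames = []
        for label in cohorts:
            s = scans[label][scans[label]["significant"]].copy()
            if len(s):
                mid = expr[label].probes.loc[s["probe_id"], "midpoint"].to_numpy()
                pos = genotypes[label].snps.loc[s["snp_id"], "pos"].to_numpy()
                s["distance_bp"] = np.abs(pos - mid)
                sig_frames.append(s)
        if sig_frames:
            dist = distance_bin_summary(pd.concat(sig_frames, ignore_index=True))
            summary["fraction_within_250kb"] = dist.fraction_within
        pd.Series(summary).to_csv(outdir / "summary.tsv", sep="\t", header=False)
    except Exception:
        (outdir / "manifest.json").write_text(
            json.dumps({"status": "failed", "stage": stage, "seed": config.seed}, indent=2)
        )
        raise

    files = sorted(p.name for p in outdir.glob("*.tsv"))
    manifest = {
        "status": "ok",
        "version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items() if k != "cohorts"},
        "checksums": {name: _sha256(outdir / name) for name in files},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
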