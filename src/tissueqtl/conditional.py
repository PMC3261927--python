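"""Stepwise conditional mapping of multiple independent eSNPs per probe.

Linkage disequilibrium makes many cis SNPs significant for one probe; to
find independently acting eSNPs, the top eSNP's effect is regressed out
and the residual is mapped again, repeating until no SNP passes that
round's permutation-FDR threshold.

The expression vector is rank-transformed once; every round regresses the
rank vector on the rank-dosages of all previously selected SNPs jointly
(least squares with intercept) and correlates the residual with each cis
SNP's rank-dosage.  Round 1 is therefore exactly the Spearman scan, and a
selected SNP's conditional correlation is exactly zero in later rounds.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cis import p_from_rho, permutation_fdr, z_from_p
from .datatypes import (
    ConfigurationError,
    DegenerateInputError,
    ExpressionMatrix,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)


@dataclass
class IndependentSignal:
    rank: int
    snp_id: str
    conditional_p: float
    conditional_z: float
    round_threshold: float


@dataclass
class IndependentSignalSet:
    """Ordered independent eSNPs for one probe in one tissue."""

    probe_id: str
    tissue: str
    signals: list[IndependentSignal] = field(default_factory=list)

    @property
    def n_signals(self) -> int:
        return len(self.signals)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.signals]


def _centred_ranks(x: np.ndarray) -> np.ndarray:
    r = stats.rankdata(x)
    return r - r.mean()


def stepwise_conditional(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    probe_id: str,
    cis_snps: list[str],
    fdr_level: float = 0.05,
    n_permutations: int = 100,
    max_rounds: int = 5,
    rng: np.random.Generator | None = None,
) -> IndependentSignalSet:
    """Detect independent eSNPs for one probe by conditional rounds.

    Each round scans the current residual against all cis SNPs, derives a
    fresh permutation-FDR threshold (permuting the residual vector), and
    selects the top SNP if significant.  Rank-deficient additions are
    skipped with a log entry.
    """
    rng = np.random.default_rng(rng)
    if expr.samples != genotypes.samples:
        raise ConfigurationError("expression and genotype samples differ")
    geno = genotypes.subset_snps(cis_snps)
    dosage = geno.dosage
    if np.isnan(dosage).any():
        col_mean = np.nanmean(dosage, axis=1, keepdims=True)
        dosage = np.where(np.isnan(dosage), col_mean, dosage)
    y = _centred_ranks(expr.row(probe_id))
    if not y.any():
        raise DegenerateInputError(f"constant expression for probe {probe_id}")
    n = len(y)
    g_ranks = np.array([_centred_ranks(row) for row in dosage])
    norms = np.sqrt((g_ranks**2).sum(axis=1))
    valid = norms > 0
    g_hat = np.zeros_like(g_ranks)
    g_hat[valid] = g_ranks[valid] / norms[valid, None]

    result = IndependentSignalSet(probe_id=probe_id, tissue="")
    selected: list[int] = []
    residual = y.copy()
    for _ in range(max_rounds):
        res_norm = np.sqrt((residual**2).sum())
        if res_norm == 0:
            break
        rho = np.where(valid, g_hat @ residual / res_norm, 0.0)
        p = p_from_rho(rho, n)
        perms = [
            p_from_rho(
                np.where(valid, g_hat @ (pr := rng.permutation(residual)) / res_norm, 0.0), n
            )
            for _ in range(n_permutations)
        ]
        fdr = permutation_fdr(p, perms, fdr_level)
        if fdr.n_significant == 0:
            break
        candidates = np.argsort(p, kind="stable")
        chosen = None
        for j in candidates:
            if j in selected or p[j] > fdr.p_threshold:
                if p[j] > fdr.p_threshold:
                    break
                continue
            design = np.column_stack(
                [np.ones(n)] + [g_ranks[i] for i in selected] + [g_ranks[j]]
            )
            if np.linalg.matrix_rank(design) < design.shape[1]:
                log.warning(
                    "probe %s: SNP %s collinear with selected set, skipped",
                    probe_id,
                    geno.snps.index[j],
                )
                continue
            chosen = j
            break
        if chosen is None:
            break
        selected.append(chosen)
        result.signals.append(
            IndependentSignal(
                rank=len(selected),
                snp_id=geno.snps.index[chosen],
                conditional_p=float(p[chosen]),
                conditional_z=float(z_from_p(p[chosen], np.sign(rho[chosen]) or 1.0)),
                round_threshold=fdr.p_threshold,
            )
        )
        design = np.column_stack([np.ones(n)] + [g_ranks[i] for i in selected])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        residual = y - design @ beta
    return result
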