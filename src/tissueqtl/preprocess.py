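"""Expression normalisation, principal-component correction and SNP QC.

Expression from all cohorts is jointly quantile normalised and log2
transformed, then the dominant principal components of the sample-sample
correlation matrix (which mostly capture tissue, batch and physiological
differences rather than genetics) are regressed out per probe.  SNP QC
applies, in order: call rate, strand-ambiguous alleles (A/T, G/C), minor
allele frequency, an exact Hardy-Weinberg test, and an optional
cross-cohort allele-frequency comparison against a reference cohort.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, DegenerateInputError, ExpressionMatrix, GenotypeMatrix

log = logging.getLogger(__name__)

FILTER_ORDER = ("call_rate", "strand_ambiguous", "maf", "hwe", "cross_cohort_freq")
_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("G", "C"))}


@dataclass
class QCReport:
    """Per-filter removal counts; a SNP is attributed to the first filter
    (in ``FILTER_ORDER``) that removes it."""

    removed: dict[str, int]
    n_input: int
    n_surviving: int
    thresholds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert sum(self.removed.values()) + self.n_surviving == self.n_input

    def to_frame(self) -> pd.DataFrame:
        rows = [{"filter": k, "removed": v} for k, v in self.removed.items()]
        rows.append({"filter": "surviving", "removed": self.n_surviving})
        return pd.DataFrame(rows)


def quantile_normalize_log2(
    expr_matrices: list[ExpressionMatrix],
) -> list[ExpressionMatrix]:
    """Joint quantile normalisation across all samples of all cohorts,
    then log2.

    Every sample's values are replaced by the mean order statistics of the
    concatenated matrix (tied ranks receive the mean of the reference
    quantiles they span), making all sample value multisets identical.
    """
    if not expr_matrices:
        raise ConfigurationError("no expression matrices given")
    probe_index = expr_matrices[0].probes.index
    for m in expr_matrices[1:]:
        if not m.probes.index.equals(probe_index):
            raise ConfigurationError("all matrices must share the probe set")
    joint = np.concatenate([m.values for m in expr_matrices], axis=1)
    if not np.all(joint > 0):
        p, s = np.argwhere(~(joint > 0))[0]
        raise DegenerateInputError(
            f"non-positive intensity at probe row {p}, joint sample column {s}"
        )
    n_probes, n_samples = joint.shape
    reference = np.sort(joint, axis=0).mean(axis=1)
    normalized = np.empty_like(joint)
    for j in range(n_samples):
        col = joint[:, j]
        order = np.argsort(col, kind="stable")
        out = np.empty(n_probes)
        out[order] = reference
        # ties: average the reference quantiles over each tied run
        sorted_vals = col[order]
        i = 0
        while i < n_probes:
            k = i
            while k + 1 < n_probes and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                out[order[i : k + 1]] = reference[i : k + 1].mean()
            i = k + 1
        normalized[:, j] = out
    if not np.all(normalized > 0):
        raise DegenerateInputError("non-positive value after quantile normalization")
    normalized = np.log2(normalized)
    out_matrices = []
    start = 0
    for m in expr_matrices:
        stop = start + m.n_samples
        out_matrices.append(
            m.with_values(normalized[:, start:stop], log2=True, quantile_normalized=True)
        )
        start = stop
    return out_matrices


def pca_correct(expr: ExpressionMatrix, n_components: int) -> ExpressionMatrix:
    """Residual expression after removing the top principal components.

    Components come from PCA of the probe-probe expression correlation
    matrix; the per-sample score vectors of the top ``n_components``
    components (computed equivalently via SVD of the row-standardised
    expression) are regressed out of each probe, with an intercept.
    Scores are linear in any underlying global factor, so a planted
    factor is removed down to the noise floor.  ``n_components = 0``
    returns the probe-centred input.
    """
    n = expr.n_samples
    if n_components < 0 or n_components >= n:
        raise ConfigurationError(
            f"n_components must lie in [0, {n - 1}] for {n} samples, got {n_components}"
        )
    x = expr.values - expr.values.mean(axis=1, keepdims=True)
    if n_components == 0:
        return expr.with_values(x, n_pcs_removed=expr.n_pcs_removed)
    sd = x.std(axis=1, keepdims=True)
    xs = np.divide(x, sd, out=np.zeros_like(x), where=sd > 0)
    # right singular vectors of the standardised matrix == eigenvectors of
    # the sample-score space of the probe-probe correlation matrix
    _, _, vt = np.linalg.svd(xs, full_matrices=False)
    scores = vt[:n_components].T
    design = np.column_stack([np.ones(n), scores])
    beta, *_ = np.linalg.lstsq(design, x.T, rcond=None)
    residuals = x - (design @ beta).T
    return expr.with_values(residuals, n_pcs_removed=expr.n_pcs_removed + n_components)


def joint_pca_correct(
    expr_matrices: list[ExpressionMatrix], n_components: int
) -> list[ExpressionMatrix]:
    """PCA correction on the column-concatenated matrix, split back per
    cohort (the default mode: one set of components spans all tissues)."""
    probes = expr_matrices[0].probes
    samples = [s for m in expr_matrices for s in m.samples]
    joint = ExpressionMatrix(
        np.concatenate([m.values for m in expr_matrices], axis=1), probes, samples
    )
    corrected = pca_correct(joint, n_components)
    out, start = [], 0
    for m in expr_matrices:
        stop = start + m.n_samples
        out.append(
            m.with_values(
                corrected.values[:, start:stop],
                n_pcs_removed=m.n_pcs_removed + n_components,
            )
        )
        start = stop
    return out


def hwe_exact_p(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact Hardy-Weinberg P value by conditional enumeration.

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the conditional probabilities of outcomes no more
    probable than the observed one (no mid-P adjustment).
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ConfigurationError("genotype counts must be non-negative")
    n = n_hom1 + n_het + n_hom2
    if n == 0:
        raise DegenerateInputError("no genotype calls")
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)
    # log P(het = h | allele counts), enumerated over h with h == n_rare (mod 2)
    hs = np.arange(n_rare % 2, n_rare + 1, 2)
    logp = np.array(
        [
            h * math.log(2)
            - math.lgamma(h + 1)
            - math.lgamma((n_rare - h) // 2 + 1)
            - math.lgamma(n - (n_rare + h) // 2 + 1)
            for h in hs
        ]
    )
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hs == n_het)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_p_from_dosage(dosage: np.ndarray) -> float:
    """Exact HWE P on rounded genotype counts (missing excluded)."""
    d = dosage[~np.isnan(dosage)]
    rounded = np.rint(d).astype(int)
    counts = np.bincount(rounded, minlength=3)
    return hwe_exact_p(counts[0], counts[1], counts[2])


def snp_qc(
    genotypes: GenotypeMatrix,
    reference_genotypes: GenotypeMatrix | None = None,
    maf_min: float = 0.05,
    call_rate_min: float = 0.95,
    hwe_p_min: float = 0.001,
    freq_diff_p_min: float = 0.01,
) -> tuple[GenotypeMatrix, QCReport]:
    """SNP quality control with the standard array-genotyping thresholds.

    Removes SNPs with call rate <= ``call_rate_min`` is violated
    (call rate must exceed the threshold), strand-ambiguous allele pairs,
    MAF not exceeding ``maf_min``, exact HWE P <= ``hwe_p_min``, and - when
    a reference cohort is supplied - allele frequencies differing from the
    reference at Fisher P < ``freq_diff_p_min``.
    """
    n_input = genotypes.n_snps
    removed = {k: 0 for k in FILTER_ORDER}
    alive = np.ones(n_input, dtype=bool)

    fail = genotypes.call_rate() < call_rate_min
    removed["call_rate"] = int((alive & fail).sum())
    alive &= ~fail

    pairs = [
        frozenset((a, b))
        for a, b in zip(genotypes.snps["allele1"], genotypes.snps["allele2"])
    ]
    fail = np.array([p in _AMBIGUOUS for p in pairs])
    removed["strand_ambiguous"] = int((alive & fail).sum())
    alive &= ~fail

    fail = ~(genotypes.maf() > maf_min)
    removed["maf"] = int((alive & fail).sum())
    alive &= ~fail

    hwe_fail = np.zeros(n_input, dtype=bool)
    for i in np.flatnonzero(alive):
        hwe_fail[i] = not (_hwe_p_from_dosage(genotypes.dosage[i]) > hwe_p_min)
    removed["hwe"] = int((alive & hwe_fail).sum())
    alive &= ~hwe_fail

    if reference_genotypes is not None:
        freq_fail = np.zeros(n_input, dtype=bool)
        for i in np.flatnonzero(alive):
            snp_id = genotypes.snps.index[i]
            if snp_id not in reference_genotypes.snps.index:
                continue
            freq_fail[i] = (
                _allele_freq_fisher_p(
                    genotypes.dosage[i], reference_genotypes.row(snp_id)
                )
                < freq_diff_p_min
            )
        removed["cross_cohort_freq"] = int((alive & freq_fail).sum())
        alive &= ~freq_fail

    survivors = GenotypeMatrix(
        genotypes.dosage[alive], genotypes.snps.loc[alive], list(genotypes.samples)
    )
    report = QCReport(
        removed=removed,
        n_input=n_input,
        n_surviving=int(alive.sum()),
        thresholds={
            "maf_min": maf_min,
            "call_rate_min": call_rate_min,
            "hwe_p_min": hwe_p_min,
            "freq_diff_p_min": freq_diff_p_min,
        },
    )
    if report.n_surviving == 0:
        log.warning("SNP QC removed every SNP (%d input)", n_input)
    return survivors, report


def _allele_freq_fisher_p(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """2x2 allele-count Fisher exact P between two cohorts at one SNP."""
    counts = []
    for d in (dosage_a, dosage_b):
        d = d[~np.isnan(d)]
        alt = int(np.rint(d).sum())
        counts.append((alt, 2 * len(d) - alt))
    table = np.array(counts)
    if table.sum() == 0:
        return 1.0
    return float(stats.fisher_exact(table)[1])
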