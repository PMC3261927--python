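"""Association profiles and the four-way tissue-dependent classifier.

The association profile of a probe in a tissue is the vector of absolute
association Z scores over all tested SNPs in its cis window, ordered by
genomic position.  Comparing profiles between two tissues by Pearson
correlation separates probes whose regulation is shared (correlated
profiles, driven by the same LD structure) from probes regulated
differently.  Because cis SNPs are in strong LD, the null distribution of
the profile correlation is calibrated empirically: genomes are randomly
reassigned to individuals per tissue, profiles recomputed, and a
correlation threshold r_thres chosen at a target FDR.

Discordant probes significant in the target tissue are then classified:

* r < r_thres, significant in one tissue only        -> specific
* r < r_thres, significant in both, top eSNPs unlinked -> alternative
* r >= r_thres, same allelic direction               -> different_effect_size
* r >= r_thres, opposite allelic direction           -> opposite_direction
* anything else                                      -> unclassified
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis import CisScanner, p_from_rho, z_from_p
from .datatypes import (
    ConfigurationError,
    DegenerateInputError,
    EmptyResultError,
    ExpressionMatrix,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)

#: profile-correlation threshold from the original study's permutation
#: calibration on its own cohorts; used only when calibration is skipped.
DEFAULT_R_THRESHOLD = 0.21

CATEGORY_LABELS = (
    "specific",
    "alternative",
    "different_effect_size",
    "opposite_direction",
    "unclassified",
)


@dataclass
class AssociationProfile:
    """Signed and absolute cis Z-score vectors of one probe in one tissue,
    ordered by SNP genomic position."""

    probe_id: str
    tissue: str
    snp_ids: list[str]
    positions: np.ndarray
    signed_z: np.ndarray

    def __post_init__(self) -> None:
        self.signed_z = np.asarray(self.signed_z, dtype=float)
        if len(self.snp_ids) != len(self.signed_z):
            raise ConfigurationError("snp_ids and signed_z lengths differ")

    @property
    def abs_z(self) -> np.ndarray:
        return np.abs(self.signed_z)


def association_profile(
    probe_id: str,
    eqtl_results: pd.DataFrame,
    snps: pd.DataFrame,
    tissue: str | None = None,
) -> AssociationProfile:
    """Build the profile of one probe from a tissue's cis-scan frame
    (columns probe_id, snp_id, z, tissue)."""
    sub = eqtl_results[eqtl_results["probe_id"] == probe_id]
    if tissue is None and "tissue" in sub:
        tissues = sub["tissue"].unique()
        if len(tissues) > 1:
            raise ConfigurationError("scan frame mixes tissues; pass tissue=")
        tissue = tissues[0] if len(tissues) else ""
    if len(sub) < 2:
        raise DegenerateInputError(
            f"probe {probe_id}: < 2 tested cis SNPs, profile correlation undefined"
        )
    pos = snps.loc[sub["snp_id"], "pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    return AssociationProfile(
        probe_id=probe_id,
        tissue=str(tissue),
        snp_ids=list(sub["snp_id"].to_numpy()[order]),
        positions=pos[order],
        signed_z=sub["z"].to_numpy()[order],
    )


def profile_correlation(a: AssociationProfile, b: AssociationProfile) -> float:
    """Pearson correlation of the two absolute-Z profiles.

    Returns nan (logged) when either profile is constant; callers treat
    nan as below any threshold, with the degeneracy flagged.
    """
    if a.snp_ids != b.snp_ids:
        raise ConfigurationError("profiles cover different SNP sets")
    if len(a.snp_ids) < 3:
        raise DegenerateInputError("need >= 3 shared SNPs for a profile correlation")
    x, y = a.abs_z, b.abs_z
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        log.info("constant profile for probe %s: correlation undefined", a.probe_id)
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class RThresholdResult:
    """Empirical profile-correlation threshold at a target FDR, from
    genome-reassignment permutations (FDR = n0{r0 >= c} / n{r >= c})."""

    r_thres: float
    fdr_level: float
    n_permutations: int
    n_real_at_thres: int
    mean_permuted_at_thres: float


def empirical_r_threshold(
    probe_ids: list[str],
    tissue_pair: tuple[str, str],
    expr: dict[str, ExpressionMatrix],
    genotypes: dict[str, GenotypeMatrix],
    window_bp: int = 1_000_000,
    n_permutations: int = 100,
    fdr_level: float = 0.05,
    rng: np.random.Generator | int | None = None,
) -> RThresholdResult:
    """Calibrate r_thres by randomly reassigning genomes to individuals.

    For each permutation round, the sample pairing between genotypes and
    expression is shuffled per tissue (one permutation for the whole
    matrix, preserving LD and probe-probe correlation), profiles are
    recomputed, and the permuted profile correlations r0 form the null.
    r_thres is the smallest observed r whose estimated FDR
    (mean #{r0 >= c} over permutations / #{r >= c}) is <= fdr_level.
    """
    rng = np.random.default_rng(rng)
    ref, tgt = tissue_pair
    scanners = {
        t: CisScanner(expr[t], genotypes[t], tissue=t, window_bp=window_bp)
        for t in (ref, tgt)
    }

    def profile_r(perm_round: bool) -> np.ndarray:
        absz = {}
        for t in (ref, tgt):
            sc = scanners[t]
            perm = rng.permutation(sc.n) if perm_round else None
            rho = sc.rho(perm)
            absz[t] = np.abs(z_from_p(p_from_rho(rho, sc.n), np.sign(rho)))
        rs = []
        probe_col = np.array([p for p, _ in scanners[ref].pairs])
        for probe in probe_ids:
            mask = probe_col == probe
            x, y = absz[ref][mask], absz[tgt][mask]
            if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rs.append(np.nan)
            else:
                rs.append(np.corrcoef(x, y)[0, 1])
        return np.asarray(rs)

    r_real = profile_r(False)
    r_perm = [profile_r(True) for _ in range(n_permutations)]
    candidates = np.sort(r_real[~np.isnan(r_real)])
    if candidates.size == 0:
        raise EmptyResultError("no defined profile correlations")
    perm_sorted = np.sort(np.concatenate(r_perm))
    perm_sorted = perm_sorted[~np.isnan(perm_sorted)]
    real_sorted = np.sort(r_real[~np.isnan(r_real)])
    for c in candidates:
        n_real = len(real_sorted) - np.searchsorted(real_sorted, c, side="left")
        n0 = (len(perm_sorted) - np.searchsorted(perm_sorted, c, side="left")) / n_permutations
        if n_real > 0 and n0 / n_real <= fdr_level:
            return RThresholdResult(
                float(c), fdr_level, n_permutations, int(n_real), float(n0)
            )
    raise EmptyResultError(
        f"no candidate threshold reaches FDR <= {fdr_level}: threshold undefined"
    )


def ld_r2(genotypes: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Composite LD: squared Pearson correlation of the dosage vectors."""
    a, b = genotypes.row(snp_a), genotypes.row(snp_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    a, b = a[keep], b[keep]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise DegenerateInputError("constant dosage: LD undefined")
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def d_prime(genotypes: GenotypeMatrix, snp_a: str, snp_b: str, n_iter: int = 100) -> float:
    """|D'| from EM haplotype-frequency estimation (reporting only; r^2
    drives all decisions).

    Double heterozygotes are phase-ambiguous; the EM splits them between
    the coupling (alt-alt / ref-ref) and repulsion configurations in
    proportion to the current haplotype frequencies.
    """
    a, b = genotypes.row(snp_a), genotypes.row(snp_b)
    keep = ~(np.isnan(a) | np.isnan(b))
    ga = np.rint(a[keep]).astype(int)
    gb = np.rint(b[keep]).astype(int)
    if ga.mean() in (0.0, 2.0) or gb.mean() in (0.0, 2.0):
        raise DegenerateInputError("monomorphic SNP: D' undefined")
    n = len(ga)
    dh = (ga == 1) & (gb == 1)
    n_dh = int(dh.sum())
    # unambiguous haplotype counts from all non-double-het genotypes
    x, y = ga[~dh], gb[~dh]
    c11 = np.maximum(0, x + y - 2).sum()
    c10 = (x - np.maximum(0, x + y - 2)).sum()
    c01 = (y - np.maximum(0, x + y - 2)).sum()
    c00 = (2 - x - y + np.maximum(0, x + y - 2)).sum()
    pa, pb = ga.mean() / 2.0, gb.mean() / 2.0
    p11, p10, p01, p00 = pa * pb, pa * (1 - pb), (1 - pa) * pb, (1 - pa) * (1 - pb)
    for _ in range(n_iter):
        coupling = p11 * p00
        repulsion = p10 * p01
        frac = coupling / (coupling + repulsion) if coupling + repulsion > 0 else 0.5
        tot = 2.0 * n
        p11 = (c11 + n_dh * frac) / tot
        p00 = (c00 + n_dh * frac) / tot
        p10 = (c10 + n_dh * (1 - frac)) / tot
        p01 = (c01 + n_dh * (1 - frac)) / tot
    pa_hat, pb_hat = p11 + p10, p11 + p01
    d = p11 - pa_hat * pb_hat
    if d >= 0:
        dmax = min(pa_hat * (1 - pb_hat), (1 - pa_hat) * pb_hat)
    else:
        dmax = min(pa_hat * pb_hat, (1 - pa_hat) * (1 - pb_hat))
    return float(abs(d) / dmax) if dmax > 0 else 0.0


@dataclass
class CategoryCall:
    """Classification of one discordant, target-significant probe for one
    (reference, target) tissue pair, with the evidence used."""

    probe_id: str
    tissue_pair: tuple[str, str]
    r_profile: float
    r_threshold: float
    category: str
    significant_reference: bool
    significant_target: bool
    top_esnp_reference: str | None
    top_esnp_target: str | None
    ld_r2_between_tops: float | None
    direction_agreement: str  # "same" | "opposite" | "undefined"


def _direction_agreement(
    ref: AssociationProfile, tgt: AssociationProfile
) -> str:
    """Sign agreement at the shared SNP with the strongest joint signal
    (largest min(|z_ref|, |z_target|)); undefined if that signal is 0."""
    strength = np.minimum(ref.abs_z, tgt.abs_z)
    k = int(np.argmax(strength))
    if strength[k] == 0:
        return "undefined"
    same = np.sign(ref.signed_z[k]) == np.sign(tgt.signed_z[k])
    return "same" if same else "opposite"


def classify_category(
    probe_id: str,
    tissue_pair: tuple[str, str],
    profile_reference: AssociationProfile,
    profile_target: AssociationProfile,
    significant_reference: bool,
    significant_target: bool,
    top_esnp_reference: str | None,
    top_esnp_target: str | None,
    genotypes: GenotypeMatrix,
    r_thres: float = DEFAULT_R_THRESHOLD,
    ld_unlinked_max: float = 0.05,
) -> CategoryCall:
    """Apply the four-category decision table to one discordant probe.

    Callers must already have established that the probe is discordant and
    significant in the target tissue; the decision table is total, with
    ``unclassified`` retaining the evidence for anything that fits no
    category (e.g. significant in both tissues but linked top eSNPs with
    an uncorrelated profile).
    """
    if profile_reference is None or profile_target is None:
        raise ConfigurationError(f"missing association profile for probe {probe_id}")
    r = profile_correlation(profile_reference, profile_target)
    direction = _direction_agreement(profile_reference, profile_target)
    ld = None
    if np.isnan(r) or r < r_thres:
        if significant_target and not significant_reference:
            category = "specific"
        elif significant_reference and significant_target:
            if top_esnp_reference is None or top_esnp_target is None:
                category = "unclassified"
            else:
                ld = ld_r2(genotypes, top_esnp_reference, top_esnp_target)
                category = "alternative" if ld <= ld_unlinked_max else "unclassified"
        else:
            category = "unclassified"
    else:
        if direction == "same":
            category = "different_effect_size"
        elif direction == "opposite":
            category = "opposite_direction"
        else:
            category = "unclassified"
    return CategoryCall(
        probe_id=probe_id,
        tissue_pair=tissue_pair,
        r_profile=r,
        r_threshold=r_thres,
        category=category,
        significant_reference=significant_reference,
        significant_target=significant_target,
        top_esnp_reference=top_esnp_reference,
        top_esnp_target=top_esnp_target,
        ld_r2_between_tops=ld,
        direction_agreement=direction,
    )
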