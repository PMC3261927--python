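"""Subsampling + GEVD test for tissue-dependent probe-SNP associations.

A probe-SNP association Z score from a small target cohort (n = 60-85)
cannot be compared directly with the Z score from a much larger reference
cohort.  Instead, the reference cohort is repeatedly subsampled without
replacement to the target size, the association Z is recomputed on each
subsample, and a generalized extreme value distribution (GEVD) is fitted
to the resampled Z cloud.  The target tissue's Z is then assigned a
two-sided tail probability under that fitted null; pairs below a
Bonferroni-corrected alpha are called discordant.

GEVD parameterization (location gamma, scale beta, shape alpha):
F(z) = exp(-[1 + alpha (z-gamma)/beta]^(-1/alpha)), with the Gumbel limit
exp(-exp(-(z-gamma)/beta)) at alpha = 0.  alpha > 0 is Frechet, alpha < 0
Weibull (bounded upper tail).  scipy's ``genextreme`` uses the opposite
shape sign, so c = -alpha at that boundary.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cis import spearman_assoc
from .datatypes import (
    ConfigurationError,
    DegenerateInputError,
    EmptyResultError,
    ExpressionMatrix,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)

_P_TINY = float(np.finfo(float).tiny)


@dataclass
class GevdFit:
    """Fitted GEVD for one probe-SNP resampled-Z null."""

    location_gamma: float
    scale_beta: float
    shape_alpha: float
    n_resamples: int
    converged: bool
    method: str = "gevd-ml"

    def cdf(self, z: float) -> float:
        return float(
            stats.genextreme.cdf(
                z, -self.shape_alpha, loc=self.location_gamma, scale=self.scale_beta
            )
        )

    def median(self) -> float:
        return float(
            stats.genextreme.median(
                -self.shape_alpha, loc=self.location_gamma, scale=self.scale_beta
            )
        )

    def in_support(self, z: float) -> bool:
        a, b = stats.genextreme.support(
            -self.shape_alpha, loc=self.location_gamma, scale=self.scale_beta
        )
        return bool(a < z < b)


@dataclass
class DiscordanceRecord:
    probe_id: str
    snp_id: str
    tissue_pair: tuple[str, str]
    z_target: float
    gevd: GevdFit
    p_discordance: float
    call: str  # "concordant" | "discordant"
    out_of_support: bool = False


def bonferroni_alpha(
    n_pairs: int, n_comparisons: int, family_alpha: float = 0.05
) -> float:
    """family_alpha / n_pairs / n_comparisons."""
    if n_pairs < 1 or n_comparisons < 1:
        raise ConfigurationError("n_pairs and n_comparisons must be positive")
    return family_alpha / n_pairs / n_comparisons


def subsample_z(
    reference_expr: np.ndarray,
    reference_dosage: np.ndarray,
    n_target: int,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
    max_attempts: int = 10,
) -> np.ndarray:
    """Signed association Z on ``n_resamples`` without-replacement
    subsamples of size ``n_target`` from the reference cohort.

    Subsamples on which the correlation is undefined (constant subvector)
    are redrawn up to ``max_attempts`` times; persistent degeneracy raises.
    """
    rng = np.random.default_rng(rng)
    reference_expr = np.asarray(reference_expr, dtype=float)
    reference_dosage = np.asarray(reference_dosage, dtype=float)
    n_ref = len(reference_expr)
    if n_target >= n_ref:
        raise ConfigurationError(
            f"target size {n_target} must be below reference size {n_ref}"
        )
    zs = np.empty(n_resamples)
    for i in range(n_resamples):
        for attempt in range(max_attempts):
            idx = rng.choice(n_ref, size=n_target, replace=False)
            try:
                zs[i] = spearman_assoc(reference_dosage[idx], reference_expr[idx])[2]
                break
            except DegenerateInputError:
                continue
        else:
            raise DegenerateInputError(
                f"correlation undefined on {max_attempts} consecutive subsamples"
            )
    return zs


def fit_gevd(z_samples: np.ndarray) -> GevdFit:
    """Maximum-likelihood GEVD fit to a resampled-Z cloud.

    Falls back to a two-parameter Gumbel fit (shape pinned to 0) when the
    three-parameter fit does not converge to a finite-likelihood optimum.
    """
    z = np.asarray(z_samples, dtype=float)
    if len(z) < 30:
        raise ConfigurationError(f"need >= 30 samples for a converged fit, got {len(z)}")
    if np.ptp(z) == 0:
        raise DegenerateInputError("constant Z samples: zero scale")
    try:
        c, loc, scale = stats.genextreme.fit(z)
        nll = -np.sum(stats.genextreme.logpdf(z, c, loc=loc, scale=scale))
        ok = np.isfinite([c, loc, scale]).all() and scale > 0 and np.isfinite(nll)
    except Exception:  # optimizer failure
        ok = False
    if ok:
        return GevdFit(float(loc), float(scale), float(-c), len(z), True, "gevd-ml")
    loc, scale = stats.gumbel_r.fit(z)
    log.warning("GEVD fit did not converge; Gumbel fallback (shape pinned to 0)")
    return GevdFit(float(loc), float(scale), 0.0, len(z), False, "gumbel-fallback")


def discordance_p(z_target: float, fit: GevdFit) -> float:
    """Two-sided tail probability of the target Z under the fitted GEVD:
    p = 2 * min(F(z), 1 - F(z)), clipped to (0, 1].  Targets outside the
    GEVD support get the machine-minimum tail (and a log entry)."""
    if fit.scale_beta <= 0:
        raise ConfigurationError("invalid fit: non-positive scale")
    if not fit.in_support(z_target) and fit.shape_alpha != 0.0:
        log.info("target z=%.3g outside fitted GEVD support", z_target)
        return _P_TINY
    f = fit.cdf(z_target)
    return float(np.clip(2.0 * min(f, 1.0 - f), _P_TINY, 1.0))


def discordance_test(
    probe_id: str,
    snp_id: str,
    reference_expr: np.ndarray,
    reference_dosage: np.ndarray,
    target_expr: np.ndarray,
    target_dosage: np.ndarray,
    tissue_pair: tuple[str, str],
    alpha: float,
    n_resamples: int = 100,
    rng: np.random.Generator | None = None,
) -> DiscordanceRecord:
    """Full subsampling + GEVD discordance test for one probe-SNP pair."""
    rng = np.random.default_rng(rng)
    z_target = spearman_assoc(target_dosage, target_expr)[2]
    keep = ~(np.isnan(np.asarray(reference_dosage, float)) | np.isnan(np.asarray(reference_expr, float)))
    zs = subsample_z(
        np.asarray(reference_expr, float)[keep],
        np.asarray(reference_dosage, float)[keep],
        n_target=int(np.sum(~np.isnan(np.asarray(target_dosage, float)))),
        n_resamples=n_resamples,
        rng=rng,
    )
    fit = fit_gevd(zs)
    out_of_support = not fit.in_support(z_target)
    p = discordance_p(z_target, fit)
    return DiscordanceRecord(
        probe_id=probe_id,
        snp_id=snp_id,
        tissue_pair=tissue_pair,
        z_target=float(z_target),
        gevd=fit,
        p_discordance=p,
        call="discordant" if p <= alpha else "concordant",
        out_of_support=out_of_support,
    )


@dataclass
class CalibrationResult:
    """Same-tissue split calibration: the machinery's false-positive rate."""

    false_discordance_rate: float
    n_pairs: int
    n_discordant: int
    alpha: float
    records: pd.DataFrame


def calibrate_same_tissue(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    split_sizes: tuple[int, int],
    pairs: list[tuple[str, str]],
    seed: int | np.random.Generator = 0,
    n_resamples: int = 100,
    family_alpha: float = 0.05,
) -> CalibrationResult:
    """Split one cohort into disjoint reference/target subsets and run the
    full discordance procedure between them.

    Every pair is genuinely concordant (same tissue, disjoint samples), so
    the discordant fraction at the Bonferroni alpha is the empirical
    false-positive rate of the subsampling + GEVD machinery.
    """
    if not pairs:
        raise EmptyResultError("no probe-SNP pairs supplied: rate undefined")
    n_ref, n_tgt = split_sizes
    if n_ref + n_tgt > expr.n_samples:
        raise ConfigurationError(
            f"split sizes {split_sizes} exceed cohort size {expr.n_samples}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(expr.n_samples)
    ref_idx, tgt_idx = perm[:n_ref], perm[n_ref : n_ref + n_tgt]
    alpha = bonferroni_alpha(len(pairs), 1, family_alpha)
    rows = []
    n_disc = 0
    for probe_id, snp_id in pairs:
        e = expr.row(probe_id)
        d = genotypes.row(snp_id)
        try:
            rec = discordance_test(
                probe_id,
                snp_id,
                e[ref_idx],
                d[ref_idx],
                e[tgt_idx],
                d[tgt_idx],
                ("reference_split", "target_split"),
                alpha=alpha,
                n_resamples=n_resamples,
                rng=rng,
            )
        except DegenerateInputError as err:
            log.warning("pair (%s, %s) skipped: %s", probe_id, snp_id, err)
            continue
        n_disc += rec.call == "discordant"
        rows.append(
            {
                "probe_id": probe_id,
                "snp_id": snp_id,
                "z_target": rec.z_target,
                "gamma": rec.gevd.location_gamma,
                "beta": rec.gevd.scale_beta,
                "alpha": rec.gevd.shape_alpha,
                "converged": rec.gevd.converged,
                "p_discordance": rec.p_discordance,
                "call": rec.call,
            }
        )
    records = pd.DataFrame(rows)
    n_tested = len(records)
    if n_tested == 0:
        raise EmptyResultError("all pairs degenerate: rate undefined")
    return CalibrationResult(n_disc / n_tested, n_tested, n_disc, alpha, records)
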