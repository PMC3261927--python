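"""Synthetic multi-tissue cohort generator with planted cis-eQTL.

Emulates the study design the pipeline targets: one large reference cohort
(peripheral blood, ~1,240 samples) and several small target cohorts
(~60-85 samples, optionally drawn from a shared pool of individuals, as
when multiple tissues are biopsied from the same donors).  Genotypes are
diallelic Hardy-Weinberg draws with optional LD blocks generated by a
latent-haplotype copier; expression is planted additive cis effects plus
shared global factors (removable by PCA) plus Gaussian noise.

Five planted architectures are supported, mirroring the four mechanisms of
tissue-dependent cis-regulation plus the concordant baseline:

* ``concordant``           - same SNP, same per-allele effect everywhere
* ``specific``             - effect in exactly one cohort
* ``alternative``          - different, unlinked SNPs drive different cohorts
* ``different_effect_size``- same SNP, same direction, unequal magnitude
* ``opposite_direction``   - same SNP, opposite allelic direction
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, ExpressionMatrix, GenotypeMatrix

CATEGORIES = (
    "concordant",
    "specific",
    "alternative",
    "different_effect_size",
    "opposite_direction",
)

#: cohort sizes of the study the generator emulates (reference blood cohort
#: plus four small tissues sharing donors)
STUDY_COHORTS: dict[str, int] = {
    "blood": 1240,
    "liver": 74,
    "SAT": 83,
    "VAT": 77,
    "muscle": 62,
}

_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("G", "T"), ("A", "C"))
_AMBIGUOUS_PAIRS = (("A", "T"), ("G", "C"))


@dataclass
class SimulationConfig:
    """Parameters of one synthetic multi-cohort dataset.

    All randomness derives from ``seed``; a fixed seed gives bitwise
    identical matrices.  ``ld_block_size`` consecutive SNPs share a latent
    haplotype; ``flip_prob`` is the per-SNP copy-error rate that relaxes
    within-block r-squared (0 gives r^2 = 1 for same-MAF block mates).
    """

    n_samples_per_cohort: Mapping[str, int] = field(
        default_factory=lambda: dict(STUDY_COHORTS)
    )
    n_snps: int = 2000
    n_probes: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 5
    flip_prob: float = 0.05
    n_global_factors: int = 10
    factor_sd: float = 1.0
    noise_sd: float = 1.0
    missing_rate: float = 0.0
    shared_individuals: bool = True
    snp_spacing_bp: int = 25_000
    window_bp: int = 1_000_000
    ambiguous_allele_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n_samples_per_cohort:
            raise ConfigurationError("at least one cohort is required")
        for label, n in self.n_samples_per_cohort.items():
            if n < 3:
                raise ConfigurationError(f"cohort {label!r} needs >= 3 samples")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5, got {self.maf_range}"
            )
        if self.ld_block_size < 1:
            raise ConfigurationError("ld_block_size must be >= 1")
        if self.n_global_factors < 0:
            raise ConfigurationError("n_global_factors must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.n_snps < 1 or self.n_probes < 1:
            raise ConfigurationError("n_snps and n_probes must be positive")

    @property
    def reference_cohort(self) -> str:
        """Largest cohort; plays the role of the blood reference."""
        return max(self.n_samples_per_cohort, key=self.n_samples_per_cohort.get)

    def cohort_index(self, cohort: str) -> int:
        labels = sorted(self.n_samples_per_cohort)
        try:
            return labels.index(cohort)
        except ValueError:
            raise ConfigurationError(f"unknown cohort {cohort!r}") from None


@dataclass
class PlantedEffect:
    """One planted cis effect: per-cohort causal SNP and additive beta.

    Betas are per counted-allele effects in residual-expression units.
    Cohorts absent from the maps carry no effect.
    """

    probe_id: str
    category: str
    causal_snp_per_cohort: dict[str, str]
    beta_per_cohort: dict[str, float]

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {self.category!r}")
        if set(self.causal_snp_per_cohort) != set(self.beta_per_cohort):
            raise ConfigurationError("causal SNP and beta maps must share cohorts")
        betas = {c: b for c, b in self.beta_per_cohort.items() if b != 0.0}
        snps = {c: self.causal_snp_per_cohort[c] for c in betas}
        if self.category == "specific" and len(betas) != 1:
            raise ConfigurationError("specific effects need exactly one nonzero beta")
        if self.category == "alternative" and len(set(snps.values())) < 2:
            raise ConfigurationError("alternative effects need >= 2 distinct SNPs")
        if self.category in ("different_effect_size", "opposite_direction"):
            if len(set(snps.values())) != 1 or len(betas) < 2:
                raise ConfigurationError(f"{self.category} needs one shared SNP, >= 2 cohorts")
            vals = list(betas.values())
            signs = {np.sign(v) for v in vals}
            if self.category == "opposite_direction" and len(signs) != 2:
                raise ConfigurationError("opposite_direction needs betas of opposite sign")
            if self.category == "different_effect_size":
                if len(signs) != 1:
                    raise ConfigurationError("different_effect_size needs same-sign betas")
                if len({round(abs(v), 12) for v in vals}) < 2:
                    raise ConfigurationError("different_effect_size needs unequal |beta|")
        if self.category == "concordant" and len({round(v, 12) for v in betas.values()}) > 1:
            raise ConfigurationError("concordant effects need one shared beta")


def beta_for_variance_explained(ve: float, maf: float, noise_sd: float = 1.0) -> float:
    """Per-allele beta giving fraction ``ve`` of (signal + noise) variance.

    Additive dosage variance at Hardy-Weinberg is 2*maf*(1-maf), so
    ve = 2m(1-m) b^2 / (2m(1-m) b^2 + noise_sd^2).
    """
    if not (0.0 < ve < 1.0):
        raise ConfigurationError("variance explained must lie in (0, 1)")
    if not (0.0 < maf <= 0.5):
        raise ConfigurationError("maf must lie in (0, 0.5]")
    return noise_sd * np.sqrt(ve / ((1.0 - ve) * 2.0 * maf * (1.0 - maf)))


def _snp_table(config: SimulationConfig) -> pd.DataFrame:
    """SNP annotation shared by every cohort: positions, blocks, MAFs, alleles."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    n = config.n_snps
    block = np.arange(n) // config.ld_block_size
    n_blocks = block[-1] + 1
    lo, hi = config.maf_range
    block_maf = rng.uniform(lo, hi, size=n_blocks)
    pos = (np.arange(n) + 1) * config.snp_spacing_bp
    alleles = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n)]
    if config.ambiguous_allele_frac > 0:
        amb = rng.random(n) < config.ambiguous_allele_frac
        for i in np.flatnonzero(amb):
            alleles[i] = _AMBIGUOUS_PAIRS[i % 2]
    return pd.DataFrame(
        {
            "chrom": "1",
            "pos": pos,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
            "block": block,
            "maf": block_maf[block],
        },
        index=pd.Index([f"rs{i + 1:05d}" for i in range(n)], name="snp_id"),
    )


def probe_table(config: SimulationConfig) -> pd.DataFrame:
    """Probe annotation: transcript midpoints evenly spread over the SNP
    span so that neighbouring cis windows overlap."""
    span = (config.n_snps + 1) * config.snp_spacing_bp
    mid = np.round((np.arange(config.n_probes) + 0.5) / config.n_probes * span).astype(int)
    return pd.DataFrame(
        {"chrom": "1", "midpoint": np.maximum(mid, 1)},
        index=pd.Index([f"probe{i + 1:04d}" for i in range(config.n_probes)], name="probe_id"),
    )


def _draw_dosage(config: SimulationConfig, snps: pd.DataFrame, n_ind: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Latent-haplotype block copier: two haplotypes per individual per
    block, each SNP copies the block allele with per-SNP flip probability."""
    n_snps = len(snps)
    dosage = np.empty((n_snps, n_ind))
    block_ids = snps["block"].to_numpy()
    maf = snps["maf"].to_numpy()
    for b in np.unique(block_ids):
        idx = np.flatnonzero(block_ids == b)
        m = maf[idx[0]]
        latent = rng.random((2, n_ind)) < m  # two latent haplotypes
        for j in idx:
            if config.flip_prob > 0:
                flips = rng.random((2, n_ind)) < config.flip_prob
                hap = latent ^ flips
            else:
                hap = latent
            dosage[j] = hap.sum(axis=0)
    return dosage


def simulate_genotypes(config: SimulationConfig, cohort: str) -> GenotypeMatrix:
    """Hardy-Weinberg dosages for one cohort.

    The reference (largest) cohort always has its own individuals.  With
    ``shared_individuals`` the remaining cohorts are prefix slices of one
    shared donor pool, so overlapping donors carry identical genotypes
    across tissues.
    """
    n = config.n_samples_per_cohort.get(cohort)
    if n is None:
        raise ConfigurationError(f"unknown cohort {cohort!r}")
    snps = _snp_table(config)
    ref = config.reference_cohort
    if cohort == ref or not config.shared_individuals:
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 201, config.cohort_index(cohort)])
        )
        dosage = _draw_dosage(config, snps, n, rng)
        samples = [f"{cohort}_{i + 1:05d}" for i in range(n)]
    else:
        pool_n = max(
            m for c, m in config.n_samples_per_cohort.items() if c != ref
        )
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
        pool = _draw_dosage(config, snps, pool_n, rng)
        dosage = pool[:, :n].copy()
        samples = [f"donor_{i + 1:05d}" for i in range(n)]
    if config.missing_rate > 0:
        mrng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 203, config.cohort_index(cohort)])
        )
        dosage[mrng.random(dosage.shape) < config.missing_rate] = np.nan
    return GenotypeMatrix(dosage, snps, samples)


def simulate_all_genotypes(config: SimulationConfig) -> dict[str, GenotypeMatrix]:
    return {c: simulate_genotypes(config, c) for c in config.n_samples_per_cohort}


def simulate_expression(
    genotypes: Mapping[str, GenotypeMatrix],
    effects: list[PlantedEffect],
    config: SimulationConfig,
) -> dict[str, ExpressionMatrix]:
    """Expression per cohort: planted cis effects + shared global factors
    + Gaussian noise, on the residual-expression scale.

    Factor loadings are shared across cohorts (so joint PCA can remove
    them); factor scores and noise are cohort-specific.  Raises if a
    planted causal SNP lies outside its probe's cis window.
    """
    probes = probe_table(config)
    snps = _snp_table(config)
    for eff in effects:
        if eff.probe_id not in probes.index:
            raise ConfigurationError(f"unknown probe {eff.probe_id!r}")
        mid = probes.loc[eff.probe_id, "midpoint"]
        for cohort, snp_id in eff.causal_snp_per_cohort.items():
            if cohort not in genotypes:
                raise ConfigurationError(f"effect references unknown cohort {cohort!r}")
            if snp_id not in snps.index:
                raise ConfigurationError(f"unknown SNP {snp_id!r}")
            if abs(snps.loc[snp_id, "pos"] - mid) > config.window_bp:
                raise ConfigurationError(
                    f"causal SNP {snp_id} is outside the {config.window_bp} bp cis "
                    f"window of probe {eff.probe_id}"
                )
    load_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 301]))
    loadings = (
        load_rng.normal(size=(config.n_probes, config.n_global_factors))
        if config.n_global_factors
        else None
    )
    out: dict[str, ExpressionMatrix] = {}
    for cohort in genotypes:
        geno = genotypes[cohort]
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 302, config.cohort_index(cohort)])
        )
        values = rng.normal(0.0, config.noise_sd, size=(config.n_probes, geno.n_samples))
        if loadings is not None:
            scores = rng.normal(0.0, config.factor_sd, size=(config.n_global_factors, geno.n_samples))
            values += loadings @ scores
        for eff in effects:
            beta = eff.beta_per_cohort.get(cohort, 0.0)
            if beta == 0.0:
                continue
            dos = geno.row(eff.causal_snp_per_cohort[cohort])
            if np.isnan(dos).any():
                dos = np.where(np.isnan(dos), np.nanmean(dos), dos)
            values[probes.index.get_loc(eff.probe_id)] += beta * dos
        out[cohort] = ExpressionMatrix(
            values, probes, list(geno.samples), log2=True, quantile_normalized=True
        )
    return out


def plan_effects(
    config: SimulationConfig,
    n_per_category: Mapping[str, int],
    reference: str,
    target: str,
    ve_target: float = 0.3,
    ve_reference: float | None = None,
    weak_ve: float = 0.03,
    seed: int | None = None,
) -> tuple[list[PlantedEffect], pd.DataFrame]:
    """Assign planted effects of each architecture to distinct probes.

    ``ve_target`` is the per-cohort variance explained of the strong
    effect; ``weak_ve`` is the reference-side effect of the
    ``different_effect_size`` architecture (same direction, much smaller).
    Causal SNPs are chosen near the probe midpoint; the ``alternative``
    architecture uses two SNPs from different LD blocks.  Returns the
    effect list and a truth table.
    """
    if ve_reference is None:
        ve_reference = ve_target
    snps = _snp_table(config)
    probes = probe_table(config)
    rng = np.random.default_rng(config.seed + 977 if seed is None else seed)
    total = sum(n_per_category.values())
    if total > config.n_probes:
        raise ConfigurationError("more planted effects than probes")
    probe_ids = list(probes.index[:total])
    pos = snps["pos"].to_numpy()
    block = snps["block"].to_numpy()
    effects: list[PlantedEffect] = []
    rows = []
    k = 0
    for category, count in n_per_category.items():
        if category not in CATEGORIES:
            raise ConfigurationError(f"unknown category {category!r}")
        for _ in range(count):
            probe_id = probe_ids[k]
            k += 1
            mid = probes.loc[probe_id, "midpoint"]
            near = np.flatnonzero(np.abs(pos - mid) <= config.window_bp // 2)
            snp_a = snps.index[rng.choice(near)]
            maf_a = snps.loc[snp_a, "maf"]
            b_tgt = beta_for_variance_explained(ve_target, maf_a, config.noise_sd)
            b_ref = beta_for_variance_explained(ve_reference, maf_a, config.noise_sd)
            if category == "concordant":
                causal = {reference: snp_a, target: snp_a}
                betas = {reference: b_tgt, target: b_tgt}
            elif category == "specific":
                causal = {target: snp_a}
                betas = {target: b_tgt}
            elif category == "alternative":
                other = near[block[near] != snps.loc[snp_a, "block"]]
                if len(other) == 0:
                    raise ConfigurationError("no unlinked SNP available in window")
                snp_b = snps.index[rng.choice(other)]
                b_ref_b = beta_for_variance_explained(
                    ve_reference, snps.loc[snp_b, "maf"], config.noise_sd
                )
                causal = {reference: snp_b, target: snp_a}
                betas = {reference: b_ref_b, target: b_tgt}
            elif category == "different_effect_size":
                b_weak = beta_for_variance_explained(weak_ve, maf_a, config.noise_sd)
                causal = {reference: snp_a, target: snp_a}
                betas = {reference: b_weak, target: b_tgt}
            else:  # opposite_direction
                causal = {reference: snp_a, target: snp_a}
                betas = {reference: -b_ref, target: b_tgt}
            effects.append(PlantedEffect(probe_id, category, causal, betas))
            rows.append(
                {
                    "probe_id": probe_id,
                    "category": category,
                    "snp_reference": causal.get(reference, ""),
                    "snp_target": causal.get(target, ""),
                    "beta_reference": betas.get(reference, 0.0),
                    "beta_target": betas.get(target, 0.0),
                }
            )
    truth = pd.DataFrame(rows).set_index("probe_id")
    return effects, truth
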