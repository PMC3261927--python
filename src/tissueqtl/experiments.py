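"""Seeded benchmark experiments exercising the pipeline end to end.

These functions define the synthetic study conditions used to validate
each stage: the same-tissue calibration of the discordance machinery, the
category-recovery benchmark at the study's sample sizes (reference 1,000
vs target 74), null behaviour of the permutation FDR and of the weighted-Z
meta-analysis, GEVD parameter recovery from closed-form samplers, and
conditional-mapping signal recovery.  Each takes a seed and returns plain
numbers or frames, so the test suite and the reproduction script share one
set of problem definitions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cis import meta_weighted_z, scan_with_fdr, spearman_assoc
from .conditional import stepwise_conditional
from .datatypes import ExpressionMatrix, GenotypeMatrix
from .discordance import calibrate_same_tissue, fit_gevd, CalibrationResult
from .pipeline import analyze_tissue_pair
from .simulate import (
    SimulationConfig,
    beta_for_variance_explained,
    plan_effects,
    probe_table,
    simulate_all_genotypes,
    simulate_expression,
)


def gevd_inverse_cdf(u: np.ndarray, gamma: float, beta: float, alpha: float) -> np.ndarray:
    """Closed-form GEVD quantile function (independent sampling oracle):
    Gumbel limit gamma - beta*log(-log u) at alpha = 0, otherwise
    gamma + beta*((-log u)^(-alpha) - 1)/alpha."""
    u = np.asarray(u, dtype=float)
    if alpha == 0.0:
        return gamma - beta * np.log(-np.log(u))
    return gamma + beta * ((-np.log(u)) ** (-alpha) - 1.0) / alpha


def gevd_recovery_experiment(
    seed: int, n: int = 10_000
) -> dict[str, float]:
    """Fit errors on closed-form Gumbel(0,1) and GEVD(2,1,0.2) samples."""
    rng = np.random.default_rng(seed)
    out = {}
    for name, (g, b, a) in {"gumbel": (0.0, 1.0, 0.0), "gevd": (2.0, 1.0, 0.2)}.items():
        z = gevd_inverse_cdf(rng.uniform(size=n), g, b, a)
        fit = fit_gevd(z)
        out[f"{name}_location_error"] = abs(fit.location_gamma - g)
        out[f"{name}_scale_error"] = abs(fit.scale_beta - b)
        out[f"{name}_shape_error"] = abs(fit.shape_alpha - a)
    return out


def meta_null_experiment(
    seed: int, n_replicates: int = 10_000, n_per_tissue: tuple[int, ...] = (74, 83, 77, 62)
) -> float:
    """Variance of the weighted-Z meta statistic over pure-null replicates
    of Spearman-derived Z scores at the small-cohort sample sizes."""
    rng = np.random.default_rng(seed)
    z_meta = np.empty(n_replicates)
    for i in range(n_replicates):
        zs = []
        for n in n_per_tissue:
            dosage = rng.binomial(2, 0.3, size=n).astype(float)
            while np.ptp(dosage) == 0:
                dosage = rng.binomial(2, 0.3, size=n).astype(float)
            zs.append(spearman_assoc(dosage, rng.normal(size=n))[2])
        z_meta[i] = meta_weighted_z(np.array(zs), np.array(n_per_tissue, float))[0]
    return float(z_meta.var())


def _single_cohort_config(
    seed: int, n_samples: int, n_probes: int, label: str = "cohort"
) -> SimulationConfig:
    return SimulationConfig(
        n_samples_per_cohort={label: n_samples},
        n_snps=n_probes,
        n_probes=n_probes,
        ld_block_size=1,
        flip_prob=0.0,
        n_global_factors=0,
        shared_individuals=False,
        snp_spacing_bp=2_000_000 // n_probes if n_probes > 2 else 500_000,
        seed=seed,
    )


def calibration_experiment(
    seed: int,
    n_pairs: int = 500,
    n_reference: int = 600,
    n_target: int = 80,
    ve_range: tuple[float, float] = (0.05, 0.5),
) -> CalibrationResult:
    """Same-tissue split control for the discordance machinery.

    One cohort of ``n_reference + n_target`` samples carries
    ``n_pairs`` concordant planted effects (one causal SNP per probe,
    variance explained drawn from ``ve_range``); the discordance
    procedure between disjoint splits should call almost nothing
    discordant at the Bonferroni alpha.
    """
    label = "blood_split"
    config = _single_cohort_config(seed, n_reference + n_target, n_pairs, label)
    rng = np.random.default_rng(seed + 1)
    geno = simulate_all_genotypes(config)
    snps = geno[label].snps
    probes = probe_table(config)
    # pair probe i with the nearest SNP; plant a concordant effect on it
    from .simulate import PlantedEffect

    effects, pairs = [], []
    for i, probe_id in enumerate(probes.index):
        pos = probes.loc[probe_id, "midpoint"]
        snp_id = snps.index[int(np.argmin(np.abs(snps["pos"].to_numpy() - pos)))]
        ve = rng.uniform(*ve_range)
        beta = beta_for_variance_explained(ve, snps.loc[snp_id, "maf"], config.noise_sd)
        effects.append(
            PlantedEffect(probe_id, "concordant", {label: snp_id}, {label: beta})
        )
        pairs.append((probe_id, snp_id))
    expr = simulate_expression(geno, effects, config)
    return calibrate_same_tissue(
        expr[label],
        geno[label],
        split_sizes=(n_reference, n_target),
        pairs=pairs,
        seed=np.random.default_rng(seed + 2),
    )


@dataclass
class CategoryRecoveryResult:
    truth_vs_called: pd.DataFrame
    accuracy: float
    accuracy_excluding_unclassified: float
    n_planted: int
    alpha: float
    r_threshold: float


def category_recovery_experiment(
    seed: int,
    n_per_category: dict[str, int] | None = None,
    n_reference: int = 1000,
    n_target: int = 74,
    ve_target: float = 0.35,
    n_snps: int = 2000,
    n_probes: int = 200,
) -> CategoryRecoveryResult:
    """End-to-end recovery of the four planted mechanisms at the study's
    sample-size regime (large blood-like reference, small target tissue).

    Every planted probe is tissue-dependent by construction; accuracy is
    the fraction of planted probes whose pipeline category matches the
    truth (a probe with no call counts as unclassified).
    """
    if n_per_category is None:
        n_per_category = {
            "specific": 50,
            "alternative": 50,
            "different_effect_size": 50,
            "opposite_direction": 50,
        }
    config = SimulationConfig(
        n_samples_per_cohort={"reference": n_reference, "target": n_target},
        n_snps=n_snps,
        n_probes=n_probes,
        ld_block_size=5,
        flip_prob=0.03,
        n_global_factors=0,
        shared_individuals=False,
        seed=seed,
    )
    geno = simulate_all_genotypes(config)
    effects, truth = plan_effects(
        config,
        n_per_category,
        reference="reference",
        target="target",
        ve_target=ve_target,
        ve_reference=0.05,
        weak_ve=0.02,
    )
    expr = simulate_expression(geno, effects, config)
    result = analyze_tissue_pair(
        expr,
        geno,
        "reference",
        "target",
        rng=np.random.default_rng(seed + 7),
    )
    called = result.calls.set_index("probe_id")["category"] if len(result.calls) else pd.Series(dtype=object)
    merged = truth.copy()
    merged["called"] = [called.get(p, "unclassified") for p in merged.index]
    exact = (merged["called"] == merged["category"]).mean()
    classified = merged[merged["called"] != "unclassified"]
    exact_classified = (
        (classified["called"] == classified["category"]).mean()
        if len(classified)
        else float("nan")
    )
    return CategoryRecoveryResult(
        truth_vs_called=merged,
        accuracy=float(exact),
        accuracy_excluding_unclassified=float(exact_classified),
        n_planted=len(merged),
        alpha=result.alpha,
        r_threshold=result.r_threshold,
    )


def fdr_null_experiment(
    seed: int,
    n_runs: int = 20,
    n_samples: int = 100,
    n_probes: int = 40,
    n_snps: int = 200,
    n_permutations: int = 100,
) -> float:
    """Fraction of pure-null runs with zero significant pairs at FDR 0.05."""
    zero = 0
    for run in range(n_runs):
        config = SimulationConfig(
            n_samples_per_cohort={"null": n_samples},
            n_snps=n_snps,
            n_probes=n_probes,
            ld_block_size=1,
            flip_prob=0.0,
            n_global_factors=0,
            shared_individuals=False,
            seed=seed * 1000 + run,
        )
        geno = simulate_all_genotypes(config)["null"]
        expr = simulate_expression({"null": geno}, [], config)["null"]
        _, fdr, _ = scan_with_fdr(
            expr,
            geno,
            n_permutations=n_permutations,
            rng=np.random.default_rng(seed * 1000 + run + 1),
        )
        zero += fdr.n_significant == 0
    return zero / n_runs


def conditional_recovery_experiment(
    seed: int,
    n_replicates: int = 50,
    n_samples: int = 300,
    ve: float = 0.2,
) -> dict[str, float]:
    """Two complementary stepwise-mapping checks.

    ``two_signal_recovery``: fraction of replicates where two planted
    unlinked causal SNPs (each explaining ``ve`` of variance) are both
    recovered.  ``single_signal_extra_rate``: fraction of single-signal
    replicates reporting a spurious second signal.
    """
    from .simulate import PlantedEffect

    both, extra = 0, 0
    for rep in range(n_replicates):
        config = SimulationConfig(
            n_samples_per_cohort={"t": n_samples},
            n_snps=40,
            n_probes=1,
            ld_block_size=1,
            flip_prob=0.0,
            n_global_factors=0,
            shared_individuals=False,
            snp_spacing_bp=40_000,
            seed=seed * 2000 + rep,
        )
        geno = simulate_all_genotypes(config)["t"]
        probes = probe_table(config)
        probe = probes.index[0]
        mid = probes.loc[probe, "midpoint"]
        in_window = np.flatnonzero(np.abs(geno.snps["pos"].to_numpy() - mid) <= config.window_bp)
        rng = np.random.default_rng(seed * 2000 + rep + 1)
        snp_a, snp_b = geno.snps.index[rng.choice(in_window, 2, replace=False)]
        betas = {
            s: beta_for_variance_explained(ve, geno.snps.loc[s, "maf"], config.noise_sd)
            for s in (snp_a, snp_b)
        }
        # two-signal replicate
        e2 = [
            PlantedEffect(probe, "concordant", {"t": snp_a}, {"t": betas[snp_a]}),
            PlantedEffect(probe, "concordant", {"t": snp_b}, {"t": betas[snp_b]}),
        ]
        expr2 = simulate_expression({"t": geno}, e2, config)["t"]
        cis = list(geno.snps.index[in_window])
        res2 = stepwise_conditional(
            expr2, geno, probe, cis, rng=np.random.default_rng(seed * 2000 + rep + 2)
        )
        both += {snp_a, snp_b} <= set(res2.snp_ids[:2])
        # single-signal replicate
        e1 = [PlantedEffect(probe, "concordant", {"t": snp_a}, {"t": betas[snp_a]})]
        expr1 = simulate_expression({"t": geno}, e1, config)["t"]
        res1 = stepwise_conditional(
            expr1, geno, probe, cis, rng=np.random.default_rng(seed * 2000 + rep + 3)
        )
        extra += res1.n_signals > 1
    return {
        "two_signal_recovery": both / n_replicates,
        "single_signal_extra_rate": extra / n_replicates,
    }
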