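# tissueqtl

Tissue-dependent *cis*-eQTL mapping and classification.

Most expression quantitative trait locus (eQTL) studies profile a single,
easily accessible tissue — usually peripheral blood — and hope that the
regulatory effects they find transfer to the tissues where disease
actually happens. They often do not: a SNP can regulate a gene in liver
but not in blood, act through different causal variants per tissue, or
even flip the direction of its allelic effect. `tissueqtl` implements a
complete pipeline for detecting and classifying such tissue-dependent
*cis*-regulation when one large reference cohort (e.g. blood,
n ≈ 1,000+) must be compared against much smaller target-tissue cohorts
(n ≈ 60–85), where naive Z-score comparisons are dominated by the
sample-size difference.

It is intended for statistical geneticists and computational biologists
running multi-tissue eQTL comparisons, and ships a synthetic-cohort
generator so every stage is testable without external data.

## Method

**Cis mapping.** For each probe–SNP pair with
|pos<sub>SNP</sub> − midpoint<sub>probe</sub>| ≤ 1 Mb, association is the
Spearman rank correlation ρ between dosage (0–2) and expression, with
two-sided *P* from the *t* approximation (df = n − 2) and signed
Z = sign(ρ)·Φ⁻¹(1 − P/2). Expression is first jointly quantile
normalised, log₂ transformed, and residualised on the top principal
components (default 50) of the expression correlation structure, which
absorb tissue, batch and physiological variation. The false-discovery
rate is controlled per analysis by comparing observed *P* values against
100 whole-matrix sample-label permutations. Tissues are combined by a
weighted Z-score meta-analysis,
Z<sub>meta</sub> = Σ√n<sub>i</sub>·Z<sub>i</sub> / √Σn<sub>i</sub>.

**Independent signals.** Stepwise conditional mapping regresses out the
top eSNP, rescans the residual, and repeats with a fresh permutation-FDR
threshold per round, yielding ranked independent eSNPs per probe.

**Discordance test.** To compare a pair's effect between the reference
and a small target tissue, the reference cohort is subsampled without
replacement to the target size 100 times, the association Z recomputed
on each subsample, and a generalized extreme value distribution (GEVD;
location γ, scale β, shape α) fitted by maximum likelihood to the
resampled Z cloud. The target tissue's Z gets a two-sided tail
probability p = 2·min(F(z), 1 − F(z)) under that fitted null; pairs
below a Bonferroni-corrected α (0.05 / pairs / comparisons) are called
*discordant*.

**Four categories.** For discordant probes significant in the target
tissue, the *association profiles* — vectors of |Z| over all cis SNPs —
are correlated between tissues (Pearson r), with the significance
threshold r<sub>thres</sub> calibrated by randomly reassigning genomes to
individuals. The decision table:

| profile r | evidence | category |
|---|---|---|
| r < r_thres | significant in one tissue only | specific regulation |
| r < r_thres | significant in both, top eSNPs unlinked (r² ≤ 0.05) | alternative regulation |
| r ≥ r_thres | same allelic direction | different effect size |
| r ≥ r_thres | opposite allelic direction | opposite allelic direction |

Anything else is reported as `unclassified` with its evidence.

## Worked example

```python
import numpy as np
from tissueqtl import (SimulationConfig, plan_effects, simulate_all_genotypes,
                       simulate_expression, analyze_tissue_pair)

config = SimulationConfig(
    n_samples_per_cohort={"blood": 600, "liver": 74},
    n_snps=600, n_probes=60, n_global_factors=0,
    shared_individuals=False, seed=11,
)
genotypes = simulate_all_genotypes(config)
effects, truth = plan_effects(
    config,
    {"concordant": 10, "specific": 5, "alternative": 5,
     "different_effect_size": 5, "opposite_direction": 5},
    reference="blood", target="liver",
    ve_target=0.35, ve_reference=0.05, weak_ve=0.02,
)
expr = simulate_expression(genotypes, effects, config)
result = analyze_tissue_pair(expr, genotypes, "blood", "liver",
                             rng=np.random.default_rng(1))
n_disc = (result.discordance["call"] == "discordant").sum()
print(f"eProbes tested: {len(result.discordance)}")
print(f"discordant probes: {n_disc}  (alpha = {result.alpha:.3g})")
print(f"profile-correlation threshold r_thres = {result.r_threshold:.3f}")
print(result.calls["category"].value_counts().to_string())
```

Output:

```
eProbes tested: 33
discordant probes: 21  (alpha = 0.000321)
profile-correlation threshold r_thres = 0.336
category
specific                 6
alternative              6
opposite_direction       5
different_effect_size    4
```

Thirty-three probes reach significance in at least one tissue; the
subsampling + GEVD test flags 21 as discordant at the derived Bonferroni
level, and none of the ten planted concordant probes is a false
discordant call. The category calls match the planted truth for 18 of
the 20 planted tissue-dependent probes: one planted `specific` probe is
called `alternative` (its null reference scan crossed the FDR threshold
by chance) and one planted `different_effect_size` probe is missed
because its weak reference-side effect makes the tissue contrast
undetectable at n = 74.

## Command line

```bash
tissueqtl simulate --outdir data --cohort blood=600 --cohort liver=74 --seed 1
tissueqtl run-all --config data/pipeline.yaml --outdir results_dir
```

`run-all` writes per-stage TSVs (QC reports, per-tissue and meta eQTL
scans, conditional signals, discordance records, category calls, a
summary table) plus a `manifest.json` with the configuration, seed and
per-file checksums; rerunning with the same config and seed reproduces
every file byte for byte. Individual stages are available as `qc`,
`map`, `meta`, `conditional`, `discord`/`classify` and `enrich`.

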