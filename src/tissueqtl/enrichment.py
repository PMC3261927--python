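"""Contingency-table enrichment analyses and summary arithmetic.

Fisher exact comparisons of tissue-dependent versus static eSNPs across
user-supplied annotation (functional class, distance to probe, trait
association), Wilcoxon-Mann-Whitney differential-expression checks, and
the percentage arithmetic used in result summaries (half-up rounding to
one decimal place).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, EmptyResultError, ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class ContingencyResult:
    """2x2 Fisher exact test (two-sided, point-probability convention)."""

    table: np.ndarray
    odds_ratio: float  # inf for a zero b*c cross product, nan for 0/0
    p_two_sided: float
    label: str = ""


def fisher_exact(table, label: str = "") -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 count table.

    The two-sided P sums hypergeometric probabilities of all tables (fixed
    margins) whose point probability is at most the observed one.  Odds
    ratio is the cross-product ratio; zero cells give inf/0 (no Haldane
    correction), flagged by a log entry.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ConfigurationError("table must be 2x2 with non-negative counts")
    if t.sum() == 0:
        raise ConfigurationError("all-zero table")
    a, b, c, d = t.ravel()
    if b * c == 0 and a * d == 0:
        odds = float("nan")
    elif b * c == 0:
        odds = float("inf")
        log.info("zero cell in 2x2 table %s: odds ratio infinite", label)
    else:
        odds = float(a * d) / float(b * c)
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    return ContingencyResult(t, odds, min(p, 1.0), label)


def summarize_fractions(counts: dict[str, tuple[int, int]]) -> dict[str, float]:
    """Named percentages, 100*num/den rounded half-up to one decimal."""
    out = {}
    for name, (num, den) in counts.items():
        if den <= 0:
            raise ConfigurationError(f"{name}: zero or negative denominator")
        pct = Decimal(100) * Decimal(num) / Decimal(den)
        out[name] = float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
    return out


@dataclass
class DistanceBinSummary:
    fraction_within: float
    n_within: int
    n_beyond: int
    contingency: ContingencyResult | None


def distance_bin_summary(
    pairs: pd.DataFrame, cut_bp: int = 250_000
) -> DistanceBinSummary:
    """Fraction of probe-SNP pairs within ``cut_bp`` of the probe midpoint
    and, when discordance calls are present, a 2x2 Fisher test of
    discordance by distance bin.

    ``pairs`` needs a ``distance_bp`` column and optionally a ``call``
    column with values concordant/discordant.
    """
    if "distance_bp" not in pairs:
        raise ConfigurationError("pairs frame needs a distance_bp column")
    within = pairs["distance_bp"] <= cut_bp
    n_within, n_beyond = int(within.sum()), int((~within).sum())
    contingency = None
    if "call" in pairs and len(pairs):
        disc = pairs["call"] == "discordant"
        table = [
            [int((within & disc).sum()), int((within & ~disc).sum())],
            [int((~within & disc).sum()), int((~within & ~disc).sum())],
        ]
        if np.asarray(table).sum() > 0 and min(np.asarray(table).sum(0).min(),
                                               np.asarray(table).sum(1).min()) > 0:
            contingency = fisher_exact(table, label=f"discordance_by_distance_{cut_bp}bp")
    frac = n_within / len(pairs) if len(pairs) else float("nan")
    return DistanceBinSummary(frac, n_within, n_beyond, contingency)


@dataclass
class TraitOverlapSummary:
    n_trait: int
    n_trait_esnp: int
    fraction_trait_esnp: float
    n_trait_discordant: int
    fraction_trait_discordant: float
    contingency: ContingencyResult | None


def trait_overlap_summary(
    esnp_set: set[str],
    discordant_esnp_set: set[str],
    trait_snp_list: list[str],
) -> TraitOverlapSummary:
    """Overlap of trait-associated SNPs with eSNPs and discordant eSNPs,
    with a Fisher comparison of the discordant fraction among trait eSNPs
    against the background discordant fraction."""
    if not trait_snp_list:
        raise EmptyResultError("empty trait SNP list")
    trait = set(trait_snp_list)
    trait_esnps = trait & esnp_set
    trait_disc = trait_esnps & discordant_esnp_set
    contingency = None
    background = esnp_set - trait
    if trait_esnps and background:
        bg_disc = len(background & discordant_esnp_set)
        table = [
            [len(trait_disc), len(trait_esnps) - len(trait_disc)],
            [bg_disc, len(background) - bg_disc],
        ]
        contingency = fisher_exact(table, label="trait_discordance_enrichment")
    return TraitOverlapSummary(
        n_trait=len(trait),
        n_trait_esnp=len(trait_esnps),
        fraction_trait_esnp=len(trait_esnps) / len(trait),
        n_trait_discordant=len(trait_disc),
        fraction_trait_discordant=(
            len(trait_disc) / len(trait_esnps) if trait_esnps else float("nan")
        ),
        contingency=contingency,
    )


def differential_expression_check(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    probe_ids: list[str],
    tissue_pair: tuple[str, str] = ("a", "b"),
) -> pd.DataFrame:
    """Wilcoxon-Mann-Whitney differential expression per probe between two
    tissues, on quantile-normalised (pre-PC-removal) intensities, with
    Bonferroni significance at 0.05 / number of probes tested."""
    rows = []
    for probe_id in probe_ids:
        a = expr_a.row(probe_id)
        b = expr_b.row(probe_id)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if len(a) < 2 or len(b) < 2:
            log.warning("probe %s skipped: group size < 2", probe_id)
            continue
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            method = "exact" if max(len(a), len(b)) <= 25 else "asymptotic"
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method)[1])
        rows.append({"probe_id": probe_id, "p": p})
    frame = pd.DataFrame(rows)
    if len(frame):
        bonf = 0.05 / len(frame)
        frame["significant"] = frame["p"] <= bonf
        frame.attrs["bonferroni_level"] = bonf
        frame.attrs["tissue_pair"] = tissue_pair
    return frame
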