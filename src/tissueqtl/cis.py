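"""Cis-eQTL mapping: Spearman association, permutation FDR, weighted-Z meta.

Associations are Spearman rank correlations between SNP dosage and
expression for probe-SNP pairs whose distance (SNP position to probe
transcript midpoint) is at most the cis window (default 1 Mb).  Two-sided
P values use the t approximation with n-2 degrees of freedom and are
transformed to signed Z scores (sign of rho).  The false-discovery rate is
controlled by comparing the observed P distribution against P distributions
from whole-matrix sample-label permutations of the expression data, which
preserve probe-probe correlation.  Tissues are combined by a weighted
Z-score meta-analysis with square-root-of-sample-size weights.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .datatypes import (
    ConfigurationError,
    DegenerateInputError,
    ExpressionMatrix,
    GenotypeMatrix,
)

log = logging.getLogger(__name__)

Z_MAX = 40.0
_P_TINY = float(np.finfo(float).tiny)


@dataclass
class EqtlResult:
    """One probe-SNP association in one tissue."""

    probe_id: str
    snp_id: str
    tissue: str
    n: int
    rho: float
    p: float
    z: float


@dataclass
class FdrResult:
    """Permutation-FDR summary for one analysis (one tissue or the meta)."""

    label: str
    p_threshold: float
    n_significant: int
    fdr_level: float
    n_permutations: int


def enumerate_cis_pairs(
    probes: pd.DataFrame, snps: pd.DataFrame, window_bp: int = 1_000_000
) -> list[tuple[str, str]]:
    """All probe-SNP pairs on the same chromosome with
    |snp_pos - probe_midpoint| <= window_bp (inclusive), ordered by probe
    (annotation order) then SNP position."""
    pairs: list[tuple[str, str]] = []
    by_chrom = {
        chrom: sub.sort_values("pos") for chrom, sub in snps.groupby("chrom", sort=False)
    }
    for probe_id, row in probes.iterrows():
        sub = by_chrom.get(row["chrom"])
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        lo = np.searchsorted(pos, row["midpoint"] - window_bp, side="left")
        hi = np.searchsorted(pos, row["midpoint"] + window_bp, side="right")
        pairs.extend((probe_id, snp_id) for snp_id in sub.index[lo:hi])
    return pairs


def _rank_center(v: np.ndarray) -> np.ndarray:
    r = stats.rankdata(v)
    return r - r.mean()


def p_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided P from Spearman rho via the t approximation, df = n-2."""
    rho = np.asarray(rho, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 0.0))
    p = np.where(np.isinf(t) | (np.abs(rho) >= 1.0), 0.0, 2.0 * stats.t.sf(np.abs(t), n - 2))
    return np.clip(p, _P_TINY, 1.0)


def z_from_p(p: np.ndarray, sign: np.ndarray, z_max: float = Z_MAX) -> np.ndarray:
    """Signed Z score: sign * Phi^-1(1 - p/2), capped at +-z_max."""
    # -ndtri(p/2) == ndtri(1 - p/2) without cancellation at tiny p
    p = np.asarray(p, dtype=float)
    z = -special.ndtri(p / 2.0)
    z = np.where(p <= _P_TINY, z_max, z)  # underflowed p (e.g. |rho| = 1) -> cap
    z = np.clip(z, 0.0, z_max)
    return np.where(np.asarray(sign) < 0, -z, z)


def spearman_assoc(
    dosage: np.ndarray, expression: np.ndarray, z_max: float = Z_MAX
) -> tuple[float, float, float]:
    """Spearman rho, two-sided P (t approximation) and signed Z for one
    probe-SNP pair.  Missing values are removed pairwise."""
    dosage = np.asarray(dosage, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if dosage.shape != expression.shape:
        raise ConfigurationError("dosage and expression lengths differ")
    keep = ~(np.isnan(dosage) | np.isnan(expression))
    dosage, expression = dosage[keep], expression[keep]
    n = len(dosage)
    if n < 3:
        raise DegenerateInputError(f"need >= 3 complete observations, got {n}")
    rd, re = _rank_center(dosage), _rank_center(expression)
    denom = np.sqrt((rd**2).sum() * (re**2).sum())
    if denom == 0.0:
        raise DegenerateInputError("constant dosage or expression vector")
    rho = float(np.clip((rd * re).sum() / denom, -1.0, 1.0))
    p = float(p_from_rho(rho, n))
    z = float(z_from_p(p, np.sign(rho) if rho != 0 else 1.0, z_max))
    return rho, p, z


class CisScanner:
    """Vectorised Spearman scan over a fixed set of cis pairs.

    Ranks are computed once; a permutation round only re-indexes the
    expression rank columns, so the 100-permutation FDR loop reuses all
    ranking work.  SNPs with missing dosages fall back to a per-pair
    path with pairwise deletion.
    """

    def __init__(
        self,
        expr: ExpressionMatrix,
        genotypes: GenotypeMatrix,
        tissue: str = "",
        window_bp: int = 1_000_000,
        pairs: list[tuple[str, str]] | None = None,
        z_max: float = Z_MAX,
    ):
        if expr.samples != genotypes.samples:
            raise ConfigurationError("expression and genotype samples differ")
        self.tissue = tissue
        self.n = expr.n_samples
        self.z_max = z_max
        if pairs is None:
            pairs = enumerate_cis_pairs(expr.probes, genotypes.snps, window_bp)
        self.pairs = pairs
        self.probe_idx = expr.probes.index.get_indexer([p for p, _ in pairs])
        self.snp_idx = genotypes.snps.index.get_indexer([s for _, s in pairs])
        if (self.probe_idx < 0).any() or (self.snp_idx < 0).any():
            raise ConfigurationError("pair list references unknown probe or SNP ids")
        self._expr = expr
        self._geno = genotypes
        self._e_hat = self._unit_ranks(expr.values)
        self._g_hat = self._unit_ranks(genotypes.dosage)
        self._g_missing = np.isnan(genotypes.dosage).any(axis=1)
        # group pair rows by probe for blocked dot products
        order = np.argsort(self.probe_idx, kind="stable")
        self._order = order
        self._groups: list[tuple[int, np.ndarray, np.ndarray]] = []
        pi = self.probe_idx[order]
        start = 0
        for stop in np.flatnonzero(np.r_[pi[1:] != pi[:-1], True]) + 1:
            self._groups.append((pi[start], order[start:stop], self.snp_idx[order[start:stop]]))
            start = stop

    @staticmethod
    def _unit_ranks(x: np.ndarray) -> np.ndarray:
        """Row-wise centred ranks scaled to unit norm; NaN rows flagged."""
        out = np.empty_like(x)
        for i in range(x.shape[0]):
            row = x[i]
            if np.isnan(row).any():
                out[i] = np.nan
                continue
            r = stats.rankdata(row)
            r -= r.mean()
            norm = np.sqrt((r**2).sum())
            out[i] = r / norm if norm > 0 else np.nan
        return out

    def rho(self, perm: np.ndarray | None = None) -> np.ndarray:
        """Spearman rho for every pair; ``perm`` permutes the expression
        sample labels (whole matrix at once)."""
        e = self._e_hat if perm is None else self._e_hat[:, perm]
        out = np.empty(len(self.pairs))
        for pi, rows, snp_rows in self._groups:
            out[rows] = self._g_hat[snp_rows] @ e[pi]
        # pairs involving missing dosages: pairwise-deletion path
        slow = np.flatnonzero(self._g_missing[self.snp_idx])
        if slow.size:
            expr_vals = self._expr.values if perm is None else self._expr.values[:, perm]
            for k in slow:
                try:
                    out[k] = spearman_assoc(
                        self._geno.dosage[self.snp_idx[k]], expr_vals[self.probe_idx[k]]
                    )[0]
                except DegenerateInputError:
                    out[k] = np.nan
        return np.clip(out, -1.0, 1.0)

    def pvalues(self, perm: np.ndarray | None = None) -> np.ndarray:
        return p_from_rho(self.rho(perm), self.n)

    def to_frame(self, rho: np.ndarray | None = None) -> pd.DataFrame:
        if rho is None:
            rho = self.rho()
        p = p_from_rho(rho, self.n)
        z = z_from_p(p, np.sign(rho))
        return pd.DataFrame(
            {
                "probe_id": [a for a, _ in self.pairs],
                "snp_id": [b for _, b in self.pairs],
                "tissue": self.tissue,
                "n": self.n,
                "rho": rho,
                "p": p,
                "z": z,
            }
        )


def permutation_fdr(
    observed_p: np.ndarray,
    permuted_p: list[np.ndarray],
    fdr_level: float = 0.05,
    label: str = "",
) -> FdrResult:
    """P-value threshold controlling the FDR against permutation nulls.

    For candidate thresholds t (the sorted observed P values),
    FDR(t) = mean over permutations of #{p_perm <= t} / #{p_obs <= t};
    the threshold is the largest t with FDR(t) <= fdr_level (none -> 0
    significant)."""
    observed_p = np.asarray(observed_p, dtype=float)
    if len(permuted_p) < 1:
        raise ConfigurationError("need >= 1 permutation")
    for v in permuted_p:
        if len(v) != len(observed_p):
            raise ConfigurationError("permuted vector length mismatch")
    obs_sorted = np.sort(observed_p)
    perm_sorted = np.sort(np.concatenate(permuted_p))
    n_perm = len(permuted_p)
    candidates = np.unique(obs_sorted)
    n_obs_le = np.searchsorted(obs_sorted, candidates, side="right")
    mean_perm_le = np.searchsorted(perm_sorted, candidates, side="right") / n_perm
    fdr = mean_perm_le / n_obs_le
    ok = np.flatnonzero(fdr <= fdr_level)
    if ok.size == 0:
        return FdrResult(label, 0.0, 0, fdr_level, n_perm)
    threshold = float(candidates[ok[-1]])
    return FdrResult(label, threshold, int(n_obs_le[ok[-1]]), fdr_level, n_perm)


def scan_with_fdr(
    expr: ExpressionMatrix,
    genotypes: GenotypeMatrix,
    tissue: str = "",
    window_bp: int = 1_000_000,
    fdr_level: float = 0.05,
    n_permutations: int = 100,
    rng: np.random.Generator | None = None,
    pairs: list[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, FdrResult, CisScanner]:
    """Full cis scan for one tissue plus its permutation-FDR threshold."""
    rng = np.random.default_rng(rng)
    scanner = CisScanner(expr, genotypes, tissue, window_bp, pairs)
    frame = scanner.to_frame()
    perms = [
        scanner.pvalues(rng.permutation(scanner.n)) for _ in range(n_permutations)
    ]
    fdr = permutation_fdr(frame["p"].to_numpy(), perms, fdr_level, label=tissue)
    frame["significant"] = frame["p"] <= fdr.p_threshold if fdr.n_significant else False
    return frame, fdr, scanner


def meta_weighted_z(
    z_per_tissue: np.ndarray, n_per_tissue: np.ndarray
) -> tuple[float, float]:
    """Weighted Z-score meta-analysis with sqrt(sample size) weights:
    z_meta = sum(sqrt(n_i) z_i) / sqrt(sum(n_i))."""
    z = np.asarray(z_per_tissue, dtype=float)
    n = np.asarray(n_per_tissue, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or len(z) < 1:
        raise ConfigurationError("z and n must be equal-length vectors, length >= 1")
    if (n < 1).any():
        raise ConfigurationError("all sample sizes must be >= 1")
    z_meta = float((np.sqrt(n) * z).sum() / np.sqrt(n.sum()))
    p_meta = float(np.clip(2.0 * stats.norm.sf(abs(z_meta)), _P_TINY, 1.0))
    return z_meta, p_meta


def meta_scan_with_fdr(
    scanners: dict[str, CisScanner],
    fdr_level: float = 0.05,
    n_permutations: int = 100,
    rng: np.random.Generator | None = None,
    label: str = "meta",
) -> tuple[pd.DataFrame, FdrResult]:
    """Weighted-Z meta-analysis across tissues sharing one pair list,
    with its own permutation FDR (each tissue permuted independently)."""
    rng = np.random.default_rng(rng)
    tissues = list(scanners)
    base = scanners[tissues[0]]
    for t in tissues[1:]:
        if scanners[t].pairs != base.pairs:
            raise ConfigurationError("meta-analysis requires identical pair lists")
    ns = np.array([scanners[t].n for t in tissues], dtype=float)
    w = np.sqrt(ns) / np.sqrt(ns.sum())

    def combine(perm_seeds=None):
        zs = []
        for i, t in enumerate(tissues):
            sc = scanners[t]
            perm = None if perm_seeds is None else rng.permutation(sc.n)
            rho = sc.rho(perm)
            zs.append(z_from_p(p_from_rho(rho, sc.n), np.sign(rho)))
        z_meta = np.einsum("t,tk->k", w, np.asarray(zs))
        p_meta = np.clip(2.0 * stats.norm.sf(np.abs(z_meta)), _P_TINY, 1.0)
        return z_meta, p_meta

    z_meta, p_meta = combine()
    perms = [combine(perm_seeds=i)[1] for i in range(n_permutations)]
    fdr = permutation_fdr(p_meta, perms, fdr_level, label=label)
    frame = pd.DataFrame(
        {
            "probe_id": [a for a, _ in base.pairs],
            "snp_id": [b for _, b in base.pairs],
            "tissue": label,
            "n": int(ns.sum()),
            "z": z_meta,
            "p": p_meta,
            "significant": p_meta <= fdr.p_threshold if fdr.n_significant else False,
        }
    )
    return frame, fdr
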