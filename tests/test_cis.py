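"""Cis-mapping unit and property tests: Spearman association against an
independent brute-force oracle, window enumeration, permutation FDR, and
the weighted-Z meta-analysis."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tissueqtl.cis import (
    CisScanner,
    Z_MAX,
    enumerate_cis_pairs,
    meta_weighted_z,
    permutation_fdr,
    scan_with_fdr,
    spearman_assoc,
)
from tissueqtl.datatypes import ConfigurationError, DegenerateInputError


def brute_force_spearman(x, y):
    """Independent oracle: explicit average ranking + Pearson on ranks +
    closed-form t CDF, no shared code with the implementation."""

    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r

    rx, ry = ranks(list(x)), ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    rho = num / den
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return rho, p


class TestSpearmanAssoc:
    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            n = rng.integers(5, 60)
            dosage = rng.binomial(2, 0.3, n).astype(float)
            if np.ptp(dosage) == 0:
                continue
            expression = rng.normal(size=n)
            rho, p, z = spearman_assoc(dosage, expression)
            rho0, p0 = brute_force_spearman(dosage, expression)
            assert abs(rho - rho0) < 1e-10
            assert abs(p - p0) < 1e-10

    def test_worked_example(self):
        rho, p, z = spearman_assoc(
            [0, 0, 1, 1, 2, 2], [3.1, 2.9, 4.2, 4.0, 5.1, 5.3]
        )
        rho0, p0 = brute_force_spearman(
            [0, 0, 1, 1, 2, 2], [3.1, 2.9, 4.2, 4.0, 5.1, 5.3]
        )
        assert rho == pytest.approx(rho0, abs=1e-12)
        assert p == pytest.approx(p0, abs=1e-12)
        assert z == pytest.approx(-stats.norm.ppf(p / 2), abs=1e-8)

    def test_perfect_monotone_hits_z_cap(self):
        rho, p, z = spearman_assoc([0, 1, 2], [1.0, 5.0, 9.0])
        assert rho == 1.0
        assert z == Z_MAX

    def test_constant_vector_raises(self):
        with pytest.raises(DegenerateInputError):
            spearman_assoc([0, 1, 2, 1], [3.0, 3.0, 3.0, 3.0])
        with pytest.raises(DegenerateInputError):
            spearman_assoc([1, 1, 1, 1], [1.0, 2.0, 3.0, 4.0])

    def test_too_few_observations(self):
        with pytest.raises(DegenerateInputError):
            spearman_assoc([0, 1], [1.0, 2.0])

    @pytest.mark.parametrize(
        "transform", [np.exp, lambda v: v**3, lambda v: 10 + 2 * v]
    )
    def test_monotone_transform_invariance(self, rng, transform):
        dosage = rng.binomial(2, 0.4, 50).astype(float)
        expression = rng.normal(size=50)
        rho1 = spearman_assoc(dosage, expression)[0]
        rho2 = spearman_assoc(dosage, transform(expression))[0]
        assert rho1 == pytest.approx(rho2, abs=1e-12)

    def test_allele_flip_negates(self, rng):
        dosage = rng.binomial(2, 0.4, 80).astype(float)
        expression = rng.normal(size=80) + 0.4 * dosage
        rho1, p1, z1 = spearman_assoc(dosage, expression)
        rho2, p2, z2 = spearman_assoc(2.0 - dosage, expression)
        assert rho2 == pytest.approx(-rho1, abs=1e-12)
        assert z2 == pytest.approx(-z1, abs=1e-10)
        assert p2 == pytest.approx(p1, abs=1e-12)

    def test_pairwise_deletion_of_missing(self, rng):
        dosage = rng.binomial(2, 0.4, 40).astype(float)
        expression = rng.normal(size=40)
        dosage_m = dosage.copy()
        dosage_m[:5] = np.nan
        rho_m = spearman_assoc(dosage_m, expression)[0]
        rho_d = spearman_assoc(dosage[5:], expression[5:])[0]
        assert rho_m == pytest.approx(rho_d, abs=1e-12)

    def test_null_z_standard_normal(self, rng):
        zs = []
        n = 200
        while len(zs) < 2000:
            dosage = rng.binomial(2, 0.3, n).astype(float)
            if np.ptp(dosage) == 0:
                continue
            zs.append(spearman_assoc(dosage, rng.normal(size=n))[2])
        d = stats.kstest(zs, "norm").statistic
        assert d < 0.05


class TestEnumerateCisPairs:
    def _frames(self):
        probes = pd.DataFrame(
            {"chrom": ["1"], "midpoint": [2_000_000]},
            index=pd.Index(["p1"], name="probe_id"),
        )
        snps = pd.DataFrame(
            {"chrom": ["1", "1", "2"], "pos": [1_000_000, 3_000_001, 2_000_000]},
            index=pd.Index(["s_in", "s_out", "s_chr2"], name="snp_id"),
        )
        return probes, snps

    def test_window_boundary_inclusive(self):
        probes, snps = self._frames()
        pairs = enumerate_cis_pairs(probes, snps, window_bp=1_000_000)
        assert pairs == [("p1", "s_in")]

    def test_chromosome_mismatch_excluded(self):
        probes, snps = self._frames()
        # SNP on chr2 at numerical distance 0 must not pair
        assert ("p1", "s_chr2") not in enumerate_cis_pairs(probes, snps, 10_000_000)

    def test_deterministic_order(self, two_cohort_data):
        config, genotypes, expr, _, _ = two_cohort_data
        g = genotypes["reference"]
        e = expr["reference"]
        pairs1 = enumerate_cis_pairs(e.probes, g.snps, config.window_bp)
        pairs2 = enumerate_cis_pairs(e.probes, g.snps, config.window_bp)
        assert pairs1 == pairs2
        # sorted by probe then snp position within probe
        for (pa, sa), (pb, sb) in zip(pairs1, pairs1[1:]):
            if pa == pb:
                assert g.snps.loc[sa, "pos"] <= g.snps.loc[sb, "pos"]


class TestScanner:
    def test_matches_per_pair_spearman(self, two_cohort_data):
        _, genotypes, expr, _, _ = two_cohort_data
        sc = CisScanner(expr["target"], genotypes["target"], "target")
        frame = sc.to_frame()
        sub = frame.sample(25, random_state=0)
        for _, row in sub.iterrows():
            rho, p, z = spearman_assoc(
                genotypes["target"].row(row["snp_id"]), expr["target"].row(row["probe_id"])
            )
            assert row["rho"] == pytest.approx(rho, abs=1e-10)
            assert row["p"] == pytest.approx(p, rel=1e-8)

    def test_permutation_preserves_marginals(self, two_cohort_data, rng):
        _, genotypes, expr, _, _ = two_cohort_data
        sc = CisScanner(expr["target"], genotypes["target"], "target")
        perm = rng.permutation(sc.n)
        rho_perm = sc.rho(perm)
        assert rho_perm.shape == (len(sc.pairs),)
        assert np.all(np.abs(rho_perm) <= 1.0)


class TestPermutationFdr:
    def test_perfect_separation(self):
        obs = np.full(50, 1e-10)
        perms = [np.ones(50) for _ in range(10)]
        res = permutation_fdr(obs, perms, 0.05)
        assert res.n_significant == 50
        assert res.p_threshold == pytest.approx(1e-10)

    def test_null_gives_nothing(self, rng):
        obs = rng.uniform(size=200)
        perms = [rng.uniform(size=200) for _ in range(20)]
        res = permutation_fdr(obs, perms, 0.001)
        assert res.n_significant == 0 or res.p_threshold <= np.sort(obs)[res.n_significant - 1]

    def test_mismatched_length_raises(self):
        with pytest.raises(ConfigurationError):
            permutation_fdr(np.ones(5), [np.ones(4)], 0.05)

    def test_threshold_controls_estimated_fdr(self, rng):
        obs = np.concatenate([rng.uniform(0, 1e-6, 20), rng.uniform(size=180)])
        perms = [rng.uniform(size=200) for _ in range(50)]
        res = permutation_fdr(obs, perms, 0.05)
        assert res.n_significant >= 20
        n_perm_le = np.mean([(p <= res.p_threshold).sum() for p in perms])
        assert n_perm_le / res.n_significant <= 0.05 + 1e-12


class TestMetaWeightedZ:
    def test_single_tissue_identity(self):
        z, p = meta_weighted_z([2.5], [100])
        assert z == pytest.approx(2.5, abs=1e-12)

    def test_hand_computed_example(self):
        z, _ = meta_weighted_z([2, 2], [100, 400])
        assert z == pytest.approx((10 * 2 + 20 * 2) / math.sqrt(500), abs=1e-10)
        assert z == pytest.approx(2.6833, abs=1e-4)

    def test_equal_weight_cancellation(self):
        z, p = meta_weighted_z([2, -2], [100, 100])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == 1.0

    def test_invalid_sample_size(self):
        with pytest.raises(ConfigurationError):
            meta_weighted_z([1.0, 2.0], [100, 0])


def test_scan_with_fdr_detects_planted_effects(two_cohort_data, rng):
    _, genotypes, expr, _, truth = two_cohort_data
    frame, fdr, _ = scan_with_fdr(
        expr["target"], genotypes["target"], tissue="target", rng=rng
    )
    assert fdr.n_significant > 0
    sig_probes = set(frame.loc[frame["significant"], "probe_id"])
    planted_target = set(truth.index[truth["beta_target"] != 0])
    assert len(sig_probes & planted_target) >= 0.8 * len(planted_target)
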