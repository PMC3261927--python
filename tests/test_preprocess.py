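"""Normalisation, PCA correction and SNP QC tests, including the exact
Hardy-Weinberg test against an independent enumeration oracle."""
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from tissueqtl.datatypes import (
    ConfigurationError,
    DegenerateInputError,
    ExpressionMatrix,
    GenotypeMatrix,
)
from tissueqtl.preprocess import (
    hwe_exact_p,
    joint_pca_correct,
    pca_correct,
    quantile_normalize_log2,
    snp_qc,
)


def _expr(values, probe_ids=None):
    values = np.asarray(values, dtype=float)
    n_probes, n_samples = values.shape
    probes = pd.DataFrame(
        {"chrom": "1", "midpoint": np.arange(n_probes) * 1000 + 1},
        index=pd.Index(probe_ids or [f"p{i}" for i in range(n_probes)], name="probe_id"),
    )
    return ExpressionMatrix(values, probes, [f"s{i}" for i in range(n_samples)])


def _geno(dosage, alleles=None):
    dosage = np.asarray(dosage, dtype=float)
    n = dosage.shape[0]
    alleles = alleles or [("A", "G")] * n
    snps = pd.DataFrame(
        {
            "chrom": "1",
            "pos": np.arange(n) * 1000 + 1,
            "allele1": [a for a, _ in alleles],
            "allele2": [b for _, b in alleles],
        },
        index=pd.Index([f"snp{i}" for i in range(n)], name="snp_id"),
    )
    return GenotypeMatrix(dosage, snps, [f"s{i}" for i in range(dosage.shape[1])])


class TestQuantileNormalize:
    def test_hand_computed_example(self):
        m = _expr(np.array([[1.0, 4.0], [2.0, 6.0], [3.0, 8.0]]))
        (out,) = quantile_normalize_log2([m])
        expected = np.log2([[2.5, 2.5], [4.0, 4.0], [5.5, 5.5]])
        np.testing.assert_allclose(out.values, expected, atol=1e-12)

    def test_identical_multisets_are_fixed_point(self):
        m = _expr(np.array([[3.0, 1.0], [1.0, 2.0], [2.0, 3.0]]))
        (out,) = quantile_normalize_log2([m])
        np.testing.assert_allclose(out.values, np.log2(m.values), atol=1e-12)

    def test_single_sample_is_identity(self):
        m = _expr(np.array([[5.0], [1.0], [3.0]]))
        (out,) = quantile_normalize_log2([m])
        np.testing.assert_allclose(out.values, np.log2(m.values), atol=1e-12)

    def test_all_samples_share_value_multiset(self, rng):
        mats = [
            _expr(rng.uniform(1, 100, size=(30, 7))),
            _expr(rng.uniform(1, 10, size=(30, 4))),
        ]
        out = quantile_normalize_log2(mats)
        joint = np.concatenate([m.values for m in out], axis=1)
        ref = np.sort(joint[:, 0])
        for j in range(1, joint.shape[1]):
            np.testing.assert_allclose(np.sort(joint[:, j]), ref, atol=1e-12)

    def test_ties_get_mean_reference_quantile(self):
        m = _expr(np.array([[2.0, 1.0], [2.0, 2.0], [8.0, 3.0]]))
        (out,) = quantile_normalize_log2([m])
        # sample 0 has a tie on its two smallest values
        assert out.values[0, 0] == pytest.approx(out.values[1, 0])

    def test_non_positive_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            quantile_normalize_log2([_expr(np.array([[1.0, -2.0], [2.0, 3.0]]))])

    def test_split_back_per_cohort(self, rng):
        a = _expr(rng.uniform(1, 50, size=(20, 5)))
        b = _expr(rng.uniform(1, 50, size=(20, 9)))
        out_a, out_b = quantile_normalize_log2([a, b])
        assert out_a.n_samples == 5 and out_b.n_samples == 9
        assert out_a.quantile_normalized and out_a.log2


class TestPcaCorrect:
    def test_zero_components_returns_centered(self, rng):
        m = _expr(rng.normal(size=(15, 10)))
        out = pca_correct(m, 0)
        np.testing.assert_allclose(
            out.values, m.values - m.values.mean(axis=1, keepdims=True), atol=1e-12
        )

    def test_rank_one_factor_removed(self, rng):
        n_probes, n = 500, 100
        factor = rng.normal(size=n)
        loadings = rng.normal(size=n_probes)
        values = np.outer(loadings, factor) + 0.05 * rng.normal(size=(n_probes, n))
        out = pca_correct(_expr(values), 1)
        # oracle: explicit least-squares projection on the known factor
        fc = factor - factor.mean()
        for row in out.values:
            r = np.corrcoef(row, fc)[0, 1]
            assert abs(r) <= 0.01

    def test_full_rank_removal_annihilates(self, rng):
        m = _expr(rng.normal(size=(30, 8)))
        out = pca_correct(m, 7)
        in_var = m.values.var(axis=1)
        assert np.all(out.values.var(axis=1) <= 1e-10 * in_var)

    def test_residuals_orthogonal_to_components(self, rng):
        m = _expr(rng.normal(size=(50, 20)))
        x = m.values - m.values.mean(axis=1, keepdims=True)
        # independent oracle: eigendecompose the probe-probe correlation
        # matrix and project onto sample-score vectors
        corr = np.corrcoef(x)
        eigvals, eigvecs = np.linalg.eigh(corr)
        top = eigvecs[:, np.argsort(eigvals)[::-1][:5]]
        xs = x / x.std(axis=1, keepdims=True)
        scores = xs.T @ top  # per-sample scores of the top components
        out = pca_correct(m, 5)
        resid_centered = out.values - out.values.mean(axis=1, keepdims=True)
        for k in range(5):
            s = scores[:, k] - scores[:, k].mean()
            corrs = resid_centered @ s / (
                np.linalg.norm(resid_centered, axis=1) * np.linalg.norm(s)
            )
            assert np.abs(corrs).max() < 1e-8

    def test_too_many_components_rejected(self, rng):
        m = _expr(rng.normal(size=(10, 6)))
        with pytest.raises(ConfigurationError):
            pca_correct(m, 6)

    def test_joint_mode_splits_back(self, rng):
        a = _expr(rng.normal(size=(25, 10)))
        b = _expr(rng.normal(size=(25, 6)))
        out_a, out_b = joint_pca_correct([a, b], 3)
        assert out_a.n_samples == 10 and out_b.n_samples == 6
        assert out_a.n_pcs_removed == 3


def hwe_oracle(n_hom1, n_het, n_hom2):
    """Independent exact-arithmetic oracle: conditional probability of each
    heterozygote count given allele counts, via integer combinatorics."""
    n = n_hom1 + n_het + n_hom2
    n_rare = min(2 * n_hom1 + n_het, 2 * n_hom2 + n_het)

    def weight(h):
        r_hom = (n_rare - h) // 2
        c_hom = n - h - r_hom
        return Fraction(
            2**h * math.factorial(n),
            math.factorial(h) * math.factorial(r_hom) * math.factorial(c_hom),
        )

    hs = list(range(n_rare % 2, n_rare + 1, 2))
    weights = {h: weight(h) for h in hs}
    total = sum(weights.values())
    obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHweExact:
    @pytest.mark.parametrize(
        "counts",
        [
            (50, 0, 50),
            (25, 50, 25),
            (5, 0, 5),
            (0, 10, 0),
            (40, 20, 40),
            (90, 9, 1),
            (1, 1, 1),
            (0, 0, 10),
            (12, 34, 5),
        ],
    )
    def test_matches_enumeration_oracle(self, counts):
        assert hwe_exact_p(*counts) == pytest.approx(hwe_oracle(*counts), rel=1e-10)

    def test_no_heterozygotes_is_extreme(self):
        assert hwe_exact_p(50, 0, 50) < 0.001

    def test_perfect_hwe_not_rejected(self):
        assert hwe_exact_p(25, 50, 25) > 0.05


class TestSnpQc:
    def test_monomorphic_removed_by_maf(self, rng):
        good = rng.binomial(2, 0.4, size=(3, 200)).astype(float)
        mono = np.zeros((1, 200))
        geno = _geno(np.vstack([good, mono]))
        survivors, report = snp_qc(geno)
        assert "snp3" not in survivors.snp_ids
        assert report.removed["maf"] >= 1

    def test_hwe_failure_removed(self, rng):
        hardy = rng.binomial(2, 0.5, size=(1, 100)).astype(float)
        broken = np.array([[0.0] * 50 + [2.0] * 50])  # no heterozygotes
        geno = _geno(np.vstack([hardy, broken]))
        survivors, report = snp_qc(geno)
        assert "snp1" not in survivors.snp_ids
        assert report.removed["hwe"] == 1

    def test_strand_ambiguous_removed(self, rng):
        dosage = rng.binomial(2, 0.4, size=(2, 100)).astype(float)
        geno = _geno(dosage, alleles=[("A", "T"), ("C", "T")])
        survivors, report = snp_qc(geno)
        assert list(survivors.snp_ids) == ["snp1"]
        assert report.removed["strand_ambiguous"] == 1

    def test_call_rate_filter(self, rng):
        dosage = rng.binomial(2, 0.4, size=(2, 100)).astype(float)
        dosage[0, :10] = np.nan  # call rate 0.90 < 0.95
        survivors, report = snp_qc(_geno(dosage))
        assert "snp0" not in survivors.snp_ids
        assert report.removed["call_rate"] == 1

    def test_cross_cohort_frequency_filter(self, rng):
        cohort = rng.binomial(2, 0.45, size=(2, 300)).astype(float)
        ref = cohort.copy()
        ref[0] = rng.binomial(2, 0.05, size=300)  # very different frequency
        survivors, report = snp_qc(_geno(cohort), reference_genotypes=_geno(ref))
        assert report.removed["cross_cohort_freq"] == 1
        assert "snp0" not in survivors.snp_ids

    def test_report_counts_add_up(self, rng):
        dosage = rng.binomial(2, 0.3, size=(20, 150)).astype(float)
        dosage[0] = 0.0
        dosage[1, :20] = np.nan
        survivors, report = snp_qc(_geno(dosage))
        assert sum(report.removed.values()) + report.n_surviving == 20

    def test_idempotent(self, rng):
        dosage = rng.binomial(2, 0.3, size=(30, 200)).astype(float)
        dosage[3] = 0.0
        first, _ = snp_qc(_geno(dosage))
        second, report2 = snp_qc(first)
        assert list(first.snp_ids) == list(second.snp_ids)
        assert sum(report2.removed.values()) == 0
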