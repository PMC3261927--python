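"""Association-profile construction, correlation, threshold calibration,
LD, and the four-category decision table."""
import numpy as np
import pandas as pd
import pytest

from tissueqtl.datatypes import ConfigurationError, DegenerateInputError, EmptyResultError
from tissueqtl.profiles import (
    AssociationProfile,
    association_profile,
    classify_category,
    d_prime,
    empirical_r_threshold,
    ld_r2,
    profile_correlation,
)
from tissueqtl.simulate import SimulationConfig, simulate_genotypes


def _profile(z, tissue="t", probe="p1", snp_ids=None):
    z = np.asarray(z, dtype=float)
    ids = snp_ids or [f"s{i}" for i in range(len(z))]
    return AssociationProfile(probe, tissue, list(ids), np.arange(len(z)), z)


def _scan_frame(probe, snp_z, tissue="t"):
    return pd.DataFrame(
        {
            "probe_id": probe,
            "snp_id": list(snp_z),
            "tissue": tissue,
            "z": list(snp_z.values()),
        }
    )


def _snp_ann(ids, positions):
    return pd.DataFrame(
        {"chrom": "1", "pos": positions}, index=pd.Index(ids, name="snp_id")
    )


class TestAssociationProfile:
    def test_abs_z_elementwise(self):
        p = _profile([-3.0, 2.0])
        np.testing.assert_array_equal(p.abs_z, [3.0, 2.0])

    def test_zero_profile(self):
        assert not _profile([0.0, 0.0, 0.0]).abs_z.any()

    def test_ordered_by_position(self):
        frame = _scan_frame("p1", {"a": 1.0, "b": -2.0, "c": 3.0})
        snps = _snp_ann(["a", "b", "c"], [300, 100, 200])
        prof = association_profile("p1", frame, snps)
        assert prof.snp_ids == ["b", "c", "a"]
        np.testing.assert_array_equal(prof.signed_z, [-2.0, 3.0, 1.0])

    def test_too_few_snps_rejected(self):
        frame = _scan_frame("p1", {"a": 1.0})
        with pytest.raises(DegenerateInputError):
            association_profile("p1", frame, _snp_ann(["a"], [100]))


class TestProfileCorrelation:
    def test_identical_profiles(self):
        a = _profile([1.0, 2.0, 3.0, 4.0])
        assert profile_correlation(a, _profile([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.0)

    def test_exact_anticorrelation(self):
        a = _profile([1.0, 2.0, 3.0, 4.0])
        b = _profile([4.0, 3.0, 2.0, 1.0])
        assert profile_correlation(a, b) == pytest.approx(-1.0)

    def test_symmetric(self, rng):
        a = _profile(rng.normal(size=30))
        b = _profile(rng.normal(size=30))
        assert profile_correlation(a, b) == pytest.approx(profile_correlation(b, a))

    def test_constant_profile_flagged_nan(self):
        a = _profile([1.0, 1.0, 1.0, 1.0])
        b = _profile([1.0, 2.0, 3.0, 4.0])
        assert np.isnan(profile_correlation(a, b))

    def test_mismatched_snps_rejected(self):
        a = _profile([1.0, 2.0, 3.0], snp_ids=["x", "y", "z"])
        b = _profile([1.0, 2.0, 3.0], snp_ids=["x", "y", "w"])
        with pytest.raises(ConfigurationError):
            profile_correlation(a, b)

    def test_null_correlation_rarely_large(self, rng):
        hits = 0
        for _ in range(200):
            a = _profile(np.abs(rng.normal(size=200)))
            b = _profile(np.abs(rng.normal(size=200)))
            hits += abs(profile_correlation(a, b)) < 0.21
        assert hits >= 190


class TestLd:
    def test_self_is_one(self, two_cohort_data):
        _, genotypes, _, _, _ = two_cohort_data
        g = genotypes["reference"]
        assert ld_r2(g, "rs00001", "rs00001") == pytest.approx(1.0)

    def test_independent_snps_low(self):
        cfg = SimulationConfig(
            n_samples_per_cohort={"a": 5000}, n_snps=10, n_probes=2,
            ld_block_size=1, flip_prob=0.0, n_global_factors=0,
            shared_individuals=False, seed=2,
        )
        g = simulate_genotypes(cfg, "a")
        assert ld_r2(g, "rs00001", "rs00009") < 0.01

    def test_block_copy_perfect_ld(self):
        cfg = SimulationConfig(
            n_samples_per_cohort={"a": 500}, n_snps=10, n_probes=2,
            ld_block_size=5, flip_prob=0.0, n_global_factors=0,
            shared_individuals=False, seed=3,
        )
        g = simulate_genotypes(cfg, "a")
        assert ld_r2(g, "rs00001", "rs00002") == pytest.approx(1.0)
        assert d_prime(g, "rs00001", "rs00002") == pytest.approx(1.0, abs=1e-6)

    def test_constant_dosage_rejected(self, two_cohort_data):
        import pandas as pd

        from tissueqtl.datatypes import GenotypeMatrix

        g = GenotypeMatrix(
            np.array([[1.0] * 10, [0.0, 1.0] * 5]),
            pd.DataFrame(
                {"chrom": "1", "pos": [1, 2], "allele1": "A", "allele2": "G"},
                index=pd.Index(["c", "v"], name="snp_id"),
            ),
            [f"s{i}" for i in range(10)],
        )
        with pytest.raises(DegenerateInputError):
            ld_r2(g, "c", "v")


class TestDecisionTable:
    """Each category exercised with constructed profiles and evidence."""

    def _geno(self, rng, r2_high=False):
        cfg = SimulationConfig(
            n_samples_per_cohort={"a": 800}, n_snps=10, n_probes=2,
            ld_block_size=5 if r2_high else 1, flip_prob=0.0,
            n_global_factors=0, shared_individuals=False, seed=9,
        )
        return simulate_genotypes(cfg, "a")

    def test_specific(self, rng):
        ref = _profile(np.abs(rng.normal(size=20)), "ref")
        tgt = _profile(np.abs(rng.normal(size=20)) + np.r_[np.zeros(10), 5 * np.ones(10)], "tgt")
        call = classify_category(
            "p1", ("ref", "tgt"), ref, tgt,
            significant_reference=False, significant_target=True,
            top_esnp_reference=None, top_esnp_target="s15",
            genotypes=self._geno(rng), r_thres=0.5,
        )
        assert call.category == "specific"

    def test_alternative_requires_unlinked_tops(self, rng):
        g = self._geno(rng)  # block size 1: rs00001 and rs00009 unlinked
        ref = _profile(np.abs(rng.normal(size=20)), "ref")
        tgt = _profile(np.abs(rng.normal(size=20)), "tgt")
        call = classify_category(
            "p1", ("ref", "tgt"), ref, tgt,
            significant_reference=True, significant_target=True,
            top_esnp_reference="rs00001", top_esnp_target="rs00009",
            genotypes=g, r_thres=0.99,
        )
        assert call.category == "alternative"
        assert call.ld_r2_between_tops < 0.05

    def test_linked_tops_unclassified(self, rng):
        g = self._geno(rng, r2_high=True)  # rs00001/rs00002 in perfect LD
        ref = _profile(np.abs(rng.normal(size=20)), "ref")
        tgt = _profile(np.abs(rng.normal(size=20)), "tgt")
        call = classify_category(
            "p1", ("ref", "tgt"), ref, tgt,
            significant_reference=True, significant_target=True,
            top_esnp_reference="rs00001", top_esnp_target="rs00002",
            genotypes=g, r_thres=0.99,
        )
        assert call.category == "unclassified"

    def test_different_effect_size_same_direction(self, rng):
        base = np.abs(rng.normal(size=20)) + np.linspace(0, 4, 20)
        ref = _profile(base + 0.1 * rng.normal(size=20), "ref")
        tgt = _profile(3 * base + 0.1 * rng.normal(size=20), "tgt")
        call = classify_category(
            "p1", ("ref", "tgt"), ref, tgt,
            significant_reference=True, significant_target=True,
            top_esnp_reference="s19", top_esnp_target="s19",
            genotypes=self._geno(rng), r_thres=0.21,
        )
        assert call.category == "different_effect_size"
        assert call.direction_agreement == "same"

    def test_opposite_direction(self, rng):
        base = np.abs(rng.normal(size=20)) + np.linspace(0, 4, 20)
        ref = _profile(base, "ref")
        tgt = _profile(-base, "tgt")  # same |z| profile, flipped signs
        call = classify_category(
            "p1", ("ref", "tgt"), ref, tgt,
            significant_reference=True, significant_target=True,
            top_esnp_reference="s19", top_esnp_target="s19",
            genotypes=self._geno(rng), r_thres=0.21,
        )
        assert call.category == "opposite_direction"
        assert call.direction_agreement == "opposite"

    def test_decision_table_total(self, rng):
        """Every combination of evidence yields exactly one category."""
        g = self._geno(rng)
        for sig_ref in (False, True):
            for sig_tgt in (True,):
                for scale in (1.0, -1.0):
                    ref = _profile(np.abs(rng.normal(size=10)), "ref")
                    tgt = _profile(scale * np.abs(rng.normal(size=10)), "tgt")
                    call = classify_category(
                        "p1", ("ref", "tgt"), ref, tgt, sig_ref, sig_tgt,
                        "rs00001", "rs00009", g, r_thres=0.21,
                    )
                    assert call.category in (
                        "specific", "alternative", "different_effect_size",
                        "opposite_direction", "unclassified",
                    )


class TestEmpiricalThreshold:
    def test_planted_shared_effects_separate_from_null(self, two_cohort_data):
        config, genotypes, expr, _, truth = two_cohort_data
        shared = list(truth.index[truth["category"] == "concordant"])
        res = empirical_r_threshold(
            shared,
            ("reference", "target"),
            expr,
            genotypes,
            n_permutations=20,
            rng=np.random.default_rng(5),
        )
        assert 0.0 < res.r_thres <= 1.0
        assert res.mean_permuted_at_thres / res.n_real_at_thres <= 0.05

    def test_no_probes_raises(self, two_cohort_data):
        _, genotypes, expr, _, _ = two_cohort_data
        with pytest.raises(EmptyResultError):
            empirical_r_threshold(
                [], ("reference", "target"), expr, genotypes, n_permutations=2
            )
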