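"""Genotype QC screens, relatedness, ancestry, weight filtering, scoring."""

from fractions import Fraction
from math import factorial

import numpy as np
import pandas as pd
import pytest

from trdprs.genoprs import (
    GenotypeMatrix,
    SampleQcThresholds,
    ancestry_outliers,
    filter_weights,
    hwe_exact_test,
    inbreeding_coefficient,
    pihat_matrix,
    relatedness_prune,
    sample_qc,
    score,
    snp_qc,
)
from conftest import make_genotypes


def hwe_exact_fraction(n_hom1, n_het, n_hom2):
    """Independent oracle: exact-rational enumeration over all heterozygote
    counts compatible with the observed allele counts."""
    n = n_hom1 + n_het + n_hom2
    n_a = 2 * n_hom1 + n_het
    n_minor = min(n_a, 2 * n - n_a)
    if n_minor == 0:
        return Fraction(1)

    def prob(h):
        r = (n_minor - h) // 2
        c = n - h - r
        return Fraction(
            factorial(n) * 2**h * factorial(n_a) * factorial(2 * n - n_a),
            factorial(r) * factorial(h) * factorial(c) * factorial(2 * n),
        )

    hs = range(n_minor % 2, n_minor + 1, 2)
    obs = prob(n_het)
    return sum(p for p in map(prob, hs) if p <= obs) / sum(map(prob, hs))


class TestHweExact:
    def test_modal_configuration(self):
        assert hwe_exact_test(25, 50, 25) == pytest.approx(1.0, abs=1e-3)

    def test_monomorphic(self):
        assert hwe_exact_test(50, 0, 0) == 1.0

    def test_heterozygote_deficit(self):
        assert hwe_exact_test(10, 0, 10) < 1e-5

    def test_all_heterozygotes_extreme(self):
        assert hwe_exact_test(0, 100, 0) < 1e-6

    @pytest.mark.parametrize(
        "counts",
        [(3, 5, 2), (40, 80, 80), (0, 7, 93), (12, 1, 12), (66, 67, 67), (1, 0, 199)],
    )
    def test_matches_rational_enumeration(self, counts):
        assert hwe_exact_test(*counts) == pytest.approx(
            float(hwe_exact_fraction(*counts)), abs=1e-12
        )

    def test_random_configurations_match_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(1, 200))
            n1 = int(rng.integers(0, n + 1))
            n2 = int(rng.integers(0, n - n1 + 1))
            counts = (n1, n2, n - n1 - n2)
            assert hwe_exact_test(*counts) == pytest.approx(
                float(hwe_exact_fraction(*counts)), abs=1e-12
            )

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_test(-1, 2, 3)


class TestSnpQc:
    def test_screens(self, rng):
        G, p = make_genotypes(100, 30, seed=3)
        status = rng.integers(0, 2, size=100)
        dos = G.dosages
        dos[:, 0] = 0.0                      # invariant
        dos[:, 1] = 1.0                      # all heterozygote -> HWE fail
        dos[:3, 2] = np.nan                  # call rate 0.97 < 0.98
        G2 = GenotypeMatrix(G.subjects, G.variants, dos)
        rep = snp_qc(G2, status)
        assert not rep.retained_mask[0] and rep.removed["invariant"] >= 1
        assert not rep.retained_mask[1] and rep.removed["hwe"] >= 1
        assert not rep.retained_mask[2] and rep.removed["call_rate"] >= 1
        rep.validate()

    def test_idempotent(self, rng):
        G, _ = make_genotypes(200, 60, seed=4, missing_rate=0.02)
        status = rng.integers(0, 2, size=200)
        rep1 = snp_qc(G, status)
        G2 = G.take_variants(rep1.retained_mask)
        rep2 = snp_qc(G2, status)
        assert rep2.n_removed == 0

    def test_all_removed_raises(self):
        G, _ = make_genotypes(50, 3, seed=5)
        G.dosages[:] = 0.0
        with pytest.raises(ValueError, match="every variant"):
            snp_qc(G, np.zeros(50))


class TestSampleQc:
    def test_clean_sample_f_near_zero_retained(self):
        G, _ = make_genotypes(60, 5000, seed=6)
        f = inbreeding_coefficient(G)
        assert np.all(np.abs(f) < 0.05)
        rep = sample_qc(G, np.array(["F"] * 60), np.full(60, 0.3))
        assert rep.n_retained == 60

    def test_fully_homozygous_sample_removed(self):
        G, _ = make_genotypes(60, 2000, seed=7)
        G.dosages[0] = np.where(G.dosages[0] == 1, 2.0, G.dosages[0])
        assert inbreeding_coefficient(G)[0] > 0.20
        rep = sample_qc(G, np.array(["F"] * 60), np.full(60, 0.3))
        assert not rep.retained_mask[0]
        assert rep.removed["fhet"] == 1

    def test_sex_mismatch(self):
        G, _ = make_genotypes(10, 500, seed=8)
        x_het = np.full(10, 0.3)
        x_het[0] = 0.0  # inferred male
        sex = np.array(["F"] * 10)
        rep = sample_qc(G, sex, x_het)
        assert not rep.retained_mask[0]
        # ambiguous rate is never a mismatch
        x_het[0] = 0.1
        assert sample_qc(G, sex, x_het).n_retained == 10

    def test_low_call_rate_removed(self):
        G, _ = make_genotypes(20, 1000, seed=9)
        G.dosages[0, :50] = np.nan  # call rate 0.95
        rep = sample_qc(G, np.array(["F"] * 20), np.full(20, 0.3))
        assert rep.removed["call_rate"] == 1


class TestRelatedness:
    def test_duplicate_pair(self):
        G, _ = make_genotypes(20, 2000, seed=10)
        G.dosages[1] = G.dosages[0]
        pihat = pihat_matrix(G)
        assert pihat[0, 1] == pytest.approx(1.0, abs=0.05)
        rep = relatedness_prune(G)
        assert rep.removed["relatedness"] == 1
        assert rep.retained_mask[0] and not rep.retained_mask[1]  # tie keeps first

    def test_lower_call_rate_member_dropped(self):
        G, _ = make_genotypes(20, 2000, seed=11)
        G.dosages[1] = G.dosages[0]
        G.dosages[0, :100] = np.nan
        rep = relatedness_prune(G)
        assert not rep.retained_mask[0] and rep.retained_mask[1]

    def test_unrelated_and_parent_offspring(self, rng):
        m = 5000
        p = rng.uniform(0.2, 0.5, m)
        parent = rng.binomial(2, p, m).astype(float)
        other = rng.binomial(2, p, m).astype(float)
        transmitted = (rng.random(m) < parent / 2).astype(float)
        child = transmitted + rng.binomial(1, p, m)
        variants = pd.DataFrame(
            {"id": [f"rs{i}" for i in range(m)], "chrom": 1,
             "pos": np.arange(m) + 1, "a1": "A", "a2": "G"}
        )
        G = GenotypeMatrix(
            np.array(["parent", "other", "child"], dtype=object),
            variants,
            np.vstack([parent, other, child]),
        )
        pihat = pihat_matrix(G)
        assert pihat[0, 1] == pytest.approx(0.0, abs=0.05)
        assert pihat[0, 2] == pytest.approx(0.5, abs=0.05)

    def test_requires_two_samples(self):
        G, _ = make_genotypes(1, 100)
        with pytest.raises(ValueError):
            relatedness_prune(G)


class TestAncestry:
    def build(self, rng, shift=0.2, n_study=100, m=2000, from_second=False):
        p = rng.uniform(0.2, 0.5, m)
        p2 = np.clip(p + np.where(p < 0.5, shift, -shift), 0.01, 0.99)
        variants = pd.DataFrame(
            {"id": [f"rs{i}" for i in range(m)], "chrom": 1,
             "pos": np.arange(m) + 1, "a1": "A", "a2": "G"}
        )
        ref = GenotypeMatrix(
            np.array([f"r{i}" for i in range(300)], dtype=object),
            variants,
            np.vstack([
                rng.binomial(2, p, size=(150, m)),
                rng.binomial(2, p2, size=(150, m)),
            ]).astype(float),
        )
        pops = np.array(["EUR"] * 150 + ["OTHER"] * 150, dtype=object)
        study = GenotypeMatrix(
            np.array([f"s{i}" for i in range(n_study)], dtype=object),
            variants,
            rng.binomial(2, p2 if from_second else p, size=(n_study, m)).astype(float),
        )
        return study, ref, pops

    def test_same_population_rarely_flagged(self, rng):
        study, ref, pops = self.build(rng)
        rep = ancestry_outliers(study, ref, pops, sd_threshold=6)
        assert rep.removed["ancestry_outlier"] == 0

    def test_shifted_population_flagged(self, rng):
        study, ref, pops = self.build(rng, from_second=True)
        rep = ancestry_outliers(study, ref, pops, sd_threshold=6)
        assert rep.removed["ancestry_outlier"] >= 90

    def test_infinite_threshold_flags_none(self, rng):
        study, ref, pops = self.build(rng, from_second=True)
        rep = ancestry_outliers(study, ref, pops, sd_threshold=np.inf)
        assert rep.removed["ancestry_outlier"] == 0

    def test_too_few_shared_snps_raises(self, rng):
        study, ref, pops = self.build(rng, m=150)
        ref.variants = ref.variants.copy()
        ref.variants["id"] = [f"x{i}" for i in range(150)]
        with pytest.raises(ValueError, match="shared"):
            ancestry_outliers(study, ref, pops)


def weight_row(**kw):
    base = dict(id="rs1", chrom=1, pos=1000, effect_allele="A", other_allele="G",
                eaf=0.3, weight=0.1, info=0.99)
    base.update(kw)
    return base


class TestFilterWeights:
    def setup_method(self):
        self.G, _ = make_genotypes(50, 10, seed=12)  # ids rs0..rs9, alleles A/G

    def test_each_rule(self):
        rows = [
            weight_row(id="rs0"),
            weight_row(id="rs1", eaf=0.05),
            weight_row(id="rs2", eaf=0.95),
            weight_row(id="rs3", info=0.5),
            weight_row(id="rs4", effect_allele="A", other_allele="T"),
            weight_row(id="rs5", chrom=6, pos=30_000_000),
            weight_row(id="rs6"), weight_row(id="rs6"),
            weight_row(id="nowhere"),
            weight_row(id="rs7", effect_allele="C", other_allele="T"),
        ]
        filtered, counts = filter_weights(pd.DataFrame(rows), self.G)
        assert counts == {
            "maf": 2, "info": 1, "duplicate_id": 2, "strand_ambiguous": 1,
            "mhc": 1, "absent_from_target": 1, "allele_mismatch": 1,
        }
        assert filtered["id"].tolist() == ["rs0"]

    def test_mhc_boundaries_inclusive(self):
        rows = [
            weight_row(id="rs0", chrom=6, pos=28_000_000),
            weight_row(id="rs1", chrom=6, pos=34_000_000),
            weight_row(id="rs2", chrom=6, pos=27_999_999),
            weight_row(id="rs3", chrom=6, pos=34_000_001),
        ]
        _, counts = filter_weights(pd.DataFrame(rows), self.G)
        assert counts["mhc"] == 2

    def test_whitelist(self):
        rows = [weight_row(id="rs0"), weight_row(id="rs1"), weight_row(id="rs2")]
        _, counts = filter_weights(
            pd.DataFrame(rows), self.G, snp_whitelist={"rs0", "rs2"}
        )
        assert counts["whitelist"] == 1

    def test_allele_flip_scoring_equivalence(self):
        """Scoring through a flipped weight row equals scoring the same
        effect on the complementary dosage orientation."""
        G = self.G
        direct = pd.DataFrame([weight_row(id="rs0", effect_allele="A",
                                          other_allele="G", weight=0.3)])
        flipped = pd.DataFrame([weight_row(id="rs0", effect_allele="G",
                                           other_allele="A", eaf=0.7, weight=0.3)])
        fd, _ = filter_weights(direct, G)
        ff, _ = filter_weights(flipped, G)
        assert not fd["flip"].iloc[0] and ff["flip"].iloc[0]
        d = G.dosages[:, 0]
        raw_direct = score(G, fd)["raw"].to_numpy()
        raw_flip = score(G, ff)["raw"].to_numpy()
        assert raw_direct == pytest.approx((0.3 * d).tolist())
        assert raw_flip == pytest.approx((0.3 * (2 - d)).tolist())
        # standardized scores are exact mirrors
        assert score(G, fd)["z"].to_numpy() == pytest.approx(
            -score(G, ff)["z"].to_numpy()
        )

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            filter_weights(pd.DataFrame(columns=["id"]), self.G)

    def test_empty_intersection_raises(self):
        rows = [weight_row(id="nope")]
        with pytest.raises(ValueError, match="no scorable"):
            filter_weights(pd.DataFrame(rows), self.G)


class TestScore:
    def test_weighted_sum(self):
        G, _ = make_genotypes(1, 3, seed=13)
        G.dosages[0] = [0.0, 1.0, 2.0]
        w = pd.DataFrame(
            [weight_row(id="rs0", weight=0.1), weight_row(id="rs1", weight=-0.2),
             weight_row(id="rs2", weight=0.3)]
        )
        w["flip"] = False
        with pytest.raises(ValueError, match="zero variance"):
            score(G, w)  # single subject: SD undefined
        G2, _ = make_genotypes(2, 3, seed=13)
        G2.dosages[0] = [0.0, 1.0, 2.0]
        G2.dosages[1] = [1.0, 1.0, 1.0]
        out = score(G2, w)
        assert out["raw"].iloc[0] == pytest.approx(0.4)

    def test_standardization_contract(self, small_study):
        from trdprs.genoprs import filter_weights as fw

        G = small_study.genotypes
        filtered, _ = fw(small_study.weights["lithium"], G)
        z = score(G, filtered)["z"]
        assert abs(z.mean()) < 1e-8
        assert abs(z.std(ddof=0) - 1) < 1e-8

    def test_zero_weights_error_not_silent(self):
        G, _ = make_genotypes(100, 2, seed=14)
        w = pd.DataFrame([weight_row(id="rs0", weight=0.0),
                          weight_row(id="rs1", weight=0.0)])
        w["flip"] = False
        with pytest.raises(ValueError, match="zero variance"):
            score(G, w)

    def test_permutation_equivariance(self, rng):
        G, _ = make_genotypes(50, 20, seed=15)
        w = pd.DataFrame([weight_row(id=f"rs{i}", weight=float(rng.normal()))
                          for i in range(20)])
        w["flip"] = False
        base = score(G, w).set_index("subject_id")["z"]
        perm = rng.permutation(50)
        Gp = G.take_subjects(perm)
        permuted = score(Gp, w).set_index("subject_id")["z"]
        pd.testing.assert_series_equal(base.sort_index(), permuted.sort_index())

    def test_missing_policies(self):
        G, _ = make_genotypes(100, 5, seed=16, missing_rate=0.1)
        w = pd.DataFrame([weight_row(id=f"rs{i}", weight=0.2) for i in range(5)])
        w["flip"] = False
        z_imp = score(G, w, missing_policy="impute_freq")
        z_omit = score(G, w, missing_policy="omit_rescale")
        assert np.corrcoef(z_imp["z"], z_omit["z"])[0, 1] > 0.9
        with pytest.raises(ValueError, match="missing_policy"):
            score(G, w, missing_policy="never")
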