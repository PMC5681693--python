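"""Zygosity-corrected percent-chimerism formulas, CIs and aggregation."""

import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

from chimerseq import (
    AlleleCount,
    Genotype,
    InformativeSnp,
    PairConfiguration,
    aggregate,
    classify_pair,
    discriminating_nucleotides,
    estimate_chimerism,
    longitudinal_table,
)

from conftest import make_locus


def make_snp(config_name: str, locus=None) -> InformativeSnp:
    locus = locus or make_locus("locE", seed=21)
    lid = locus.locus_id
    pairs = {
        "HET_DONOR_HOM_RECIPIENT": (Genotype(lid, ("A", "G")), Genotype(lid, ("A", "A"))),
        "HOM_DONOR_HET_RECIPIENT": (Genotype(lid, ("A", "A")), Genotype(lid, ("A", "G"))),
        "HOM_HOM_DIFFERENT": (Genotype(lid, ("G", "G")), Genotype(lid, ("A", "A"))),
    }
    d, r = pairs[config_name]
    config = classify_pair(d, r)
    assert config.name == config_name
    donor_nt, recip_nt = discriminating_nucleotides(d, r, config)
    return InformativeSnp(locus, config, donor_nt, recip_nt)


def count_of(locus_id="locE", sample_id="s", **nt_counts) -> AlleleCount:
    counts = {"A": 0, "C": 0, "G": 0, "T": 0, "N": 0}
    counts.update(nt_counts)
    return AlleleCount(locus_id=locus_id, sample_id=sample_id, counts=counts)


class TestFormulas:
    def test_pure_donor_het_donor_gives_100(self):
        # a heterozygote shows its private allele in half its reads: 2 x 50 = 100
        est = estimate_chimerism(count_of(G=500, A=500), make_snp("HET_DONOR_HOM_RECIPIENT"))
        assert est.percent == pytest.approx(100.0) and not est.clamped

    def test_pure_recipient_hom_donor_gives_0(self):
        est = estimate_chimerism(count_of(G=500, A=500), make_snp("HOM_DONOR_HET_RECIPIENT"))
        assert est.percent == pytest.approx(0.0) and not est.clamped

    def test_hom_hom_direct_fraction(self):
        est = estimate_chimerism(count_of(G=370, A=630), make_snp("HOM_HOM_DIFFERENT"))
        assert est.percent == pytest.approx(37.0)

    def test_sampling_noise_above_100_clamps_with_flag(self):
        est = estimate_chimerism(count_of(G=510, A=490), make_snp("HET_DONOR_HOM_RECIPIENT"))
        assert est.raw_percent == pytest.approx(102.0)
        assert est.percent == 100.0 and est.clamped

    def test_boundaries_for_every_configuration(self):
        # all-donor-consistent counts -> 100; all-recipient -> 0
        cases = {
            "HET_DONOR_HOM_RECIPIENT": (count_of(G=500, A=500), count_of(A=1000)),
            "HOM_DONOR_HET_RECIPIENT": (count_of(A=1000), count_of(G=500, A=500)),
            "HOM_HOM_DIFFERENT": (count_of(G=1000), count_of(A=1000)),
        }
        for name, (donor_counts, recip_counts) in cases.items():
            snp = make_snp(name)
            assert estimate_chimerism(donor_counts, snp).percent == pytest.approx(100.0)
            assert estimate_chimerism(recip_counts, snp).percent == pytest.approx(0.0)

    def test_estimator_expectation_equals_donor_read_fraction(self):
        """Exhaustive enumeration on a 20-read instance: for each
        configuration and each number k of donor-origin reads, averaging
        the estimate over every possible SNP-base outcome (heterozygote
        reads carry their private allele with probability 1/2) gives
        exactly 100*k/20."""
        n = 20
        for name in ("HET_DONOR_HOM_RECIPIENT", "HOM_DONOR_HET_RECIPIENT",
                     "HOM_HOM_DIFFERENT"):
            snp = make_snp(name)
            for k in range(n + 1):
                if name == "HET_DONOR_HOM_RECIPIENT":
                    # j of the k donor reads show G, weight C(k,j)/2^k
                    expectation = sum(
                        binom.pmf(j, k, 0.5)
                        * estimate_chimerism(
                            count_of(G=j, A=n - j), snp, min_coverage=1
                        ).raw_percent
                        for j in range(k + 1)
                    )
                elif name == "HOM_DONOR_HET_RECIPIENT":
                    m = n - k  # recipient reads; j of them show G
                    expectation = sum(
                        binom.pmf(j, m, 0.5)
                        * estimate_chimerism(
                            count_of(G=j, A=n - j), snp, min_coverage=1
                        ).raw_percent
                        for j in range(m + 1)
                    )
                else:
                    expectation = estimate_chimerism(
                        count_of(G=k, A=n - k), snp, min_coverage=1
                    ).raw_percent
                assert expectation == pytest.approx(100 * k / n, abs=1e-9), (name, k)

    @settings(derandomize=True, max_examples=60)
    @given(
        k1=st.integers(0, 400), k2=st.integers(0, 400),
        other=st.integers(0, 400),
        name=st.sampled_from(
            ["HET_DONOR_HOM_RECIPIENT", "HOM_DONOR_HET_RECIPIENT", "HOM_HOM_DIFFERENT"]
        ),
    )
    def test_monotonicity_and_clamp_containment(self, k1, k2, other, name):
        """percent is monotone in the discriminating-nucleotide count
        (non-decreasing for donor counting, non-increasing for recipient
        counting) and percent/ci always stay within [0, 100]."""
        snp = make_snp(name)
        lo, hi = sorted((k1, k2))
        nt = "G"
        ests = [
            estimate_chimerism(count_of(**{nt: k, "A": other + 50}), snp, min_coverage=1)
            for k in (lo, hi)
        ]
        for e in ests:
            assert 0.0 <= e.ci_low <= e.percent <= e.ci_high <= 100.0
        if name == "HOM_DONOR_HET_RECIPIENT":
            assert ests[1].percent <= ests[0].percent
        else:
            assert ests[0].percent <= ests[1].percent

    def test_low_coverage_flagged_and_excluded(self, caplog):
        snp = make_snp("HET_DONOR_HOM_RECIPIENT")
        with caplog.at_level("WARNING"):
            est = estimate_chimerism(count_of(G=10, A=10), snp, min_coverage=100)
        assert est.no_coverage and math.isnan(est.percent)
        good = estimate_chimerism(count_of(G=100, A=100), snp)
        agg = aggregate([est, good])
        assert agg.n_snps == 1

    def test_contamination_warning_on_stray_nucleotide(self, caplog):
        snp = make_snp("HET_DONOR_HOM_RECIPIENT")
        with caplog.at_level("WARNING"):
            est = estimate_chimerism(count_of(G=100, A=100, T=30), snp)
        assert est.contamination_warning
        assert any("contamination" in r.message for r in caplog.records)

    def test_ci_brackets_truth_at_depth(self):
        snp = make_snp("HOM_HOM_DIFFERENT")
        est = estimate_chimerism(count_of(G=300, A=700), snp)
        assert est.ci_low < 30.0 < est.ci_high
        assert est.ci_high - est.ci_low < 6.0


class TestAggregate:
    def test_two_snps_mean_and_sem(self):
        snp = make_snp("HOM_HOM_DIFFERENT")
        ests = [
            estimate_chimerism(count_of(G=400, A=600), snp),
            estimate_chimerism(count_of(G=600, A=400), snp),
        ]
        agg = aggregate(ests)
        assert agg.mean_percent == pytest.approx(50.0)
        assert agg.sem_percent == pytest.approx(10.0)  # sd 14.142.. / sqrt(2)
        assert agg.n_snps == 2

    def test_single_snp_mode_has_no_sem(self):
        snp = make_snp("HOM_HOM_DIFFERENT")
        agg = aggregate([estimate_chimerism(count_of(G=732, A=268), snp)])
        assert agg.mean_percent == pytest.approx(73.2)
        assert agg.sem_percent is None and agg.n_snps == 1

    def test_identical_estimates_have_zero_sem(self):
        snp = make_snp("HOM_HOM_DIFFERENT")
        ests = [estimate_chimerism(count_of(G=420, A=580), snp) for _ in range(3)]
        agg = aggregate(ests)
        assert agg.mean_percent == pytest.approx(42.0)
        assert agg.sem_percent == pytest.approx(0.0)

    def test_zero_usable_estimates_gives_none(self, caplog):
        snp = make_snp("HOM_HOM_DIFFERENT")
        low = estimate_chimerism(count_of(G=1, A=1), snp, min_coverage=100)
        with caplog.at_level("WARNING"):
            assert aggregate([low]) is None


class TestLongitudinalTable:
    @staticmethod
    def meta(rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "animal_id", "days_post_hsct", "subset"]
        )

    @staticmethod
    def agg_for(sample_id, percent):
        snp = make_snp("HOM_HOM_DIFFERENT")
        est = estimate_chimerism(
            count_of(sample_id=sample_id, G=int(percent * 10), A=1000 - int(percent * 10)),
            snp,
        )
        return aggregate([est], sample_id=sample_id)

    def test_rows_sorted_by_animal_subset_day(self):
        aggs = [self.agg_for(f"s{i}", 50) for i in range(4)]
        meta = self.meta(
            [("s0", "a1", 28, "T cell"), ("s1", "a1", 7, "T cell"),
             ("s2", "a1", 7, "whole blood"), ("s3", "a0", 14, "T cell")]
        )
        table = longitudinal_table(aggs, meta)
        assert list(table["sample_id"]) == ["s3", "s1", "s0", "s2"]
        assert list(table["days_post_hsct"]) == [14, 7, 28, 7]

    def test_subset_by_day_grid(self):
        rows, aggs = [], []
        for i, (subset, day) in enumerate(product(["wb", "gran", "T"], [0, 7, 14, 28])):
            rows.append((f"s{i}", "a1", day, subset))
            aggs.append(self.agg_for(f"s{i}", 40))
        assert len(longitudinal_table(aggs, self.meta(rows))) == 12

    def test_empty_input_empty_table(self):
        assert len(longitudinal_table([], self.meta([]))) == 0

    def test_duplicate_keys_rejected(self):
        aggs = [self.agg_for("s0", 50), self.agg_for("s1", 60)]
        meta = self.meta([("s0", "a1", 7, "wb"), ("s1", "a1", 7, "wb")])
        with pytest.raises(ValueError, match="duplicate"):
            longitudinal_table(aggs, meta)
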