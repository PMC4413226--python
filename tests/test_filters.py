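import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from haplorefine.filters import (
    FilterRuleSet,
    build_repeat_mask,
    classify_site,
    failure_tally,
    find_homopolymers_chrom,
    hardy_weinberg_p,
)
from haplorefine.io import IntervalSet, SiteRecord
from haplorefine.simulate import make_filter_fixture


def _snp(**ann):
    return SiteRecord("1", 100, "A", "G", annotations=ann)


def _indel(**ann):
    return SiteRecord("1", 100, "AT", "A", annotations=ann)


class TestClassifySite:
    def test_qd_below_threshold_fails(self):
        verdict = classify_site(_snp(QD=1.9))
        assert verdict.failed == ["QD"]
        assert not verdict.passed

    def test_boundary_value_passes_strict_inequality(self):
        assert classify_site(_snp(QD=2.0)).passed

    def test_type_specific_fs_threshold(self):
        assert classify_site(_indel(FS=100.0)).passed
        assert classify_site(_snp(FS=100.0)).failed == ["FS"]

    def test_type_specific_si_lower_bound(self):
        assert classify_site(_snp(SI=0.7)).passed
        assert classify_site(_indel(SI=0.7)).failed == ["SI_low_indel"]

    def test_missing_annotation_cannot_fail(self):
        assert classify_site(_snp()).passed

    def test_multiple_failures_reported(self):
        verdict = classify_site(_snp(QD=1.0, MQ=30.0, SI=2.0))
        assert set(verdict.failed) == {"QD", "MQ", "SI_high"}

    def test_rule_order_insensitive(self):
        record = _snp(QD=1.0, FS=80.0, DP=200000.0)
        rules = FilterRuleSet()
        reversed_rules = FilterRuleSet(list(reversed(rules.rules)))
        assert set(classify_site(record, rules).failed) == set(
            classify_site(record, reversed_rules).failed
        )

    def test_repeat_masking_uses_reference_span(self):
        mask = IntervalSet([("1", 104, 120)])
        long_del = SiteRecord("1", 100, "ATTTTT", "A")  # span [99,105)
        snp = SiteRecord("1", 100, "A", "G")  # span [99,100)
        assert classify_site(long_del, repeat_mask=mask).masked_by_repeat
        assert not classify_site(snp, repeat_mask=mask).masked_by_repeat

    def test_threshold_override(self):
        rules = FilterRuleSet().with_overrides({"QD": 5.0})
        assert classify_site(_snp(QD=3.0), rules).failed == ["QD"]
        with pytest.raises(KeyError):
            FilterRuleSet().with_overrides({"nope": 1.0})


class TestFilterFixture:
    def test_one_failing_rule_per_engineered_record(self):
        fixture = make_filter_fixture()
        verdicts = [classify_site(r) for r in fixture.records]
        for verdict, expected in zip(verdicts, fixture.expected_failures):
            assert verdict.failed == expected
        n_failing = sum(not v.passed for v in verdicts)
        assert n_failing == 14 and len(verdicts) == 16
        assert all(count == 1 for count in failure_tally(verdicts).values())

    def test_swapping_variant_type_flips_type_sensitive_verdicts(self):
        fixture = make_filter_fixture()
        by_note = {tuple(e): r for r, e in
                   zip(fixture.records, fixture.expected_failures)}
        passing = [r for r, e in zip(fixture.records, fixture.expected_failures)
                   if not e]
        indel_fs, snp_si = passing
        assert indel_fs.annotations["FS"] == 100.0
        as_snp = SiteRecord("1", indel_fs.pos, "A", "G",
                            annotations=indel_fs.annotations)
        assert classify_site(as_snp).failed == ["FS"]
        assert snp_si.annotations["SI"] == 0.7
        as_indel = SiteRecord("1", snp_si.pos, "AT", "A",
                              annotations=snp_si.annotations)
        assert classify_site(as_indel).failed == ["SI_low_indel"]
        # and the failing SNP FS record passes as an indel
        snp_fs = by_note[("FS",)]
        as_indel_fs = SiteRecord("1", snp_fs.pos, "AT", "A",
                                 annotations=snp_fs.annotations)
        assert classify_site(as_indel_fs).passed


def hw_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact-fraction enumeration over all genotype configurations."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    weights = {}
    for het in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2):
        aa = (n_a - het) // 2
        bb = n - aa - het
        weights[het] = Fraction(
            math.comb(n, aa) * math.comb(n - aa, het) * 2**het
        )
    total = sum(weights.values())
    obs = weights[n_ab]
    return float(sum(w for w in weights.values() if w <= obs) / total)


class TestHardyWeinberg:
    def test_monomorphic_is_one(self):
        assert hardy_weinberg_p(10, 0, 0) == 1.0
        assert hardy_weinberg_p(0, 0, 7) == 1.0

    def test_two_het_enumeration(self):
        # 2 individuals, alleles 2+2: configurations het in {0, 2}
        assert hardy_weinberg_p(0, 2, 0) == pytest.approx(hw_exact_oracle(0, 2, 0))

    def test_allele_relabeling_symmetry(self):
        for a, b, c in [(3, 2, 1), (5, 0, 5), (1, 7, 2)]:
            assert hardy_weinberg_p(a, b, c) == pytest.approx(
                hardy_weinberg_p(c, b, a)
            )

    @given(st.integers(0, 8), st.integers(0, 8), st.integers(0, 8))
    @settings(deadline=None, max_examples=80)
    def test_matches_exact_fraction_oracle(self, a, b, c):
        if a + b + c == 0:
            return
        assert hardy_weinberg_p(a, b, c) == pytest.approx(
            hw_exact_oracle(a, b, c), rel=1e-9
        )

    def test_extreme_deficit_is_small(self):
        # all homozygotes at intermediate frequency: strong HW violation
        assert hardy_weinberg_p(50, 0, 50) < 1e-7


class TestAnRule:
    def test_fully_called_cohort_passes_iff_enough_chromosomes(self):
        assert classify_site(_snp(AN=2.0 * 2636)).passed
        assert 2 * 2636 == 5272
        assert classify_site(_snp(AN=2.0 * 2000)).failed == ["AN"]


class TestHomopolymers:
    def test_run_of_six_found(self):
        s = find_homopolymers_chrom("GGAAAAAAGG", "1")
        assert s.intervals("1") == [(2, 8)]

    def test_run_of_five_ignored(self):
        assert find_homopolymers_chrom("GGAAAAAGG", "1").intervals("1") == []

    def test_n_runs_excluded(self):
        assert find_homopolymers_chrom("NNNNNNNN", "1").intervals("1") == []

    def test_matches_naive_scan_on_random_sequence(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGTN"), size=500))
        found = find_homopolymers_chrom(seq, "1")
        # naive oracle: per-position run extension
        mask = np.zeros(len(seq), dtype=bool)
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= 6 and seq[i] != "N":
                mask[i:j] = True
            i = j
        ours = np.zeros(len(seq), dtype=bool)
        for b, e in found.intervals("1"):
            ours[b:e] = True
        assert np.array_equal(ours, mask)


class TestRepeatMask:
    def test_disjoint_concatenation_and_nested_merge(self):
        trf = IntervalSet([("1", 0, 10), ("1", 100, 120)])
        hp = IntervalSet([("1", 102, 110), ("1", 200, 210)])
        mask = build_repeat_mask(trf, hp)
        assert mask.intervals("1") == [(0, 10), (100, 120), (200, 210)]

    def test_chromosome_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_repeat_mask(IntervalSet([("chr1", 0, 5)]),
                              IntervalSet([("1", 0, 5)]))

    def test_coverage_matches_per_base_bitmap(self):
        rng = np.random.default_rng(8)
        chrom_len = 300
        trf = IntervalSet()
        hp = IntervalSet()
        bitmap = np.zeros(chrom_len, dtype=bool)
        for target in (trf, hp):
            for _ in range(20):
                b = int(rng.integers(0, chrom_len - 1))
                e = int(b + rng.integers(1, 30))
                e = min(e, chrom_len)
                target.add("1", b, e)
                bitmap[b:e] = True
            target.merge()
        mask = build_repeat_mask(trf, hp)
        assert mask.total_coverage() == int(bitmap.sum())
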