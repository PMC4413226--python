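"""Hard-threshold variant quality filtering and simple-repeat masking.

A site fails if any applicable inequality on its call annotations holds
(strict comparisons, exactly as configured); a missing annotation can never
fail its rule.  Separate thresholds apply to SNPs and indels, and variants
whose reference span intersects the simple-repeat mask (tandem-repeat track
merged with homopolymer runs of 6 bp or more) are flagged as masked.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from haplorefine.io import IntervalSet, SiteRecord


@dataclass(frozen=True)
class FilterRule:
    name: str
    annotation: str
    comparator: str  # "lt" -> fail when value < threshold; "gt" -> fail when >
    threshold: float
    variant_types: tuple[str, ...] = ("SNP", "indel")

    def fails(self, record: SiteRecord) -> bool:
        if record.variant_type not in self.variant_types:
            return False
        value = record.annotations.get(self.annotation)
        if value is None:
            return False  # missing annotation cannot fail its rule
        if self.comparator == "lt":
            return value < self.threshold
        if self.comparator == "gt":
            return value > self.threshold
        raise ValueError(f"unknown comparator {self.comparator!r}")


def default_rules() -> list[FilterRule]:
    """The default hard-filter thresholds.

    The first six SNP rules and the three indel rules follow GATK Best
    Practices hard-filter values; the cohort-level DP/AN/HW/SI bounds assume
    a ~2,600-diploid cohort and are plain numbers to override elsewhere.
    """
    return [
        FilterRule("QD", "QD", "lt", 2.0, ("SNP",)),
        FilterRule("MQ", "MQ", "lt", 40.0, ("SNP",)),
        FilterRule("FS", "FS", "gt", 60.0, ("SNP",)),
        FilterRule("HaplotypeScore", "HaplotypeScore", "gt", 13.0, ("SNP",)),
        FilterRule("MQRankSum", "MQRankSum", "lt", -12.5, ("SNP",)),
        FilterRule("ReadPosRankSum", "ReadPosRankSum", "lt", -8.0, ("SNP",)),
        FilterRule("QD_indel", "QD", "lt", 2.0, ("indel",)),
        FilterRule("FS_indel", "FS", "gt", 200.0, ("indel",)),
        FilterRule("ReadPosRankSum_indel", "ReadPosRankSum", "lt", -20.0, ("indel",)),
        FilterRule("DP", "DP", "gt", 110000.0),
        FilterRule("AN", "AN", "lt", 4200.0),
        FilterRule("HW", "HW", "lt", 1e-7),
        FilterRule("SI_high", "SI", "gt", 1.4),
        FilterRule("SI_low", "SI", "lt", 0.6, ("SNP",)),
        FilterRule("SI_low_indel", "SI", "lt", 0.9, ("indel",)),
    ]


@dataclass
class FilterRuleSet:
    rules: list[FilterRule] = field(default_factory=default_rules)

    def with_overrides(self, overrides: dict[str, float]) -> "FilterRuleSet":
        """New rule set with thresholds replaced by rule name."""
        unknown = set(overrides) - {r.name for r in self.rules}
        if unknown:
            raise KeyError(f"unknown filter rule(s): {sorted(unknown)}")
        return FilterRuleSet([
            FilterRule(r.name, r.annotation, r.comparator,
                       overrides.get(r.name, r.threshold), r.variant_types)
            for r in self.rules
        ])


@dataclass
class FilterVerdict:
    failed: list[str] = field(default_factory=list)
    masked_by_repeat: bool = False

    @property
    def passed(self) -> bool:
        return not self.failed and not self.masked_by_repeat


def classify_site(
    record: SiteRecord,
    rules: FilterRuleSet | None = None,
    repeat_mask: IntervalSet | None = None,
) -> FilterVerdict:
    """Evaluate every applicable rule and the repeat mask for one site.

    Rules are independent, so the failed set is invariant under rule ordering.
    Repeat containment is tested over the variant's whole reference span.
    """
    if record.variant_type not in ("SNP", "indel"):
        raise ValueError(f"unknown variant type {record.variant_type!r}")
    rules = rules or FilterRuleSet()
    failed = [rule.name for rule in rules.rules if rule.fails(record)]
    masked = False
    if repeat_mask is not None:
        start, end = record.ref_span
        masked = repeat_mask.overlaps(record.chrom, start, end)
    return FilterVerdict(failed=failed, masked_by_repeat=masked)


def _log_het_prob(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Log probability of a genotype configuration given its allele counts.

    Standard exact Hardy-Weinberg conditional distribution over heterozygote
    counts: P(n_ab | n, n_a) = C(n, n_aa, n_ab, n_bb) 2^n_ab / C(2n, n_a).
    """
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_b = 2 * n_bb + n_ab
    return (
        math.lgamma(n + 1) - math.lgamma(n_aa + 1) - math.lgamma(n_ab + 1)
        - math.lgamma(n_bb + 1) + n_ab * math.log(2.0)
        + math.lgamma(n_a + 1) + math.lgamma(n_b + 1) - math.lgamma(2 * n + 1)
    )


def hardy_weinberg_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact two-sided Hardy-Weinberg test P-value from genotype counts.

    Conditions on the allele counts and sums the probabilities of every
    heterozygote-count configuration at most as probable as the observed one.
    Symmetric in allele relabeling; monomorphic samples give P = 1.
    """
    if min(n_aa, n_ab, n_bb) < 0 or n_aa + n_ab + n_bb == 0:
        raise ValueError("genotype counts must be non-negative with positive total")
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    het_max = min(n_a, 2 * n - n_a)
    # heterozygote count shares the parity of the minor-allele count
    hets = range(n_a % 2, het_max + 1, 2)
    logps = np.array([
        _log_het_prob((n_a - h) // 2, h, (2 * n - n_a - h) // 2) for h in hets
    ])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    observed = probs[list(hets).index(n_ab)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


def find_homopolymers(sequence: str, min_length: int = 6) -> IntervalSet:
    """Maximal single-base runs of at least ``min_length`` bp (N runs excluded).

    Returned intervals are 0-based half-open on the chromosome named '.' —
    use :func:`find_homopolymers_chrom` to attach a chromosome name.
    """
    return find_homopolymers_chrom(sequence, ".", min_length)


def find_homopolymers_chrom(
    sequence: str, chrom: str, min_length: int = 6
) -> IntervalSet:
    out = IntervalSet()
    for m in re.finditer(r"(A+|C+|G+|T+)", sequence.upper()):
        if m.end() - m.start() >= min_length:
            out.add(chrom, m.start(), m.end())
    out.merge()
    return out


def build_repeat_mask(
    trf_intervals: IntervalSet, homopolymer_intervals: IntervalSet
) -> IntervalSet:
    """Union of the tandem-repeat track and homopolymer runs, overlaps merged."""
    trf_chroms = trf_intervals.chromosomes
    hp_chroms = homopolymer_intervals.chromosomes
    if trf_chroms and hp_chroms and not (trf_chroms & hp_chroms):
        raise ValueError(
            f"chromosome naming mismatch between inputs: {sorted(trf_chroms)} "
            f"vs {sorted(hp_chroms)}"
        )
    return IntervalSet.union(trf_intervals, homopolymer_intervals)


def total_called_chromosomes(genotypes) -> int:
    """AN for a diploid cohort: two chromosomes per called genotype.

    ``genotypes`` holds per-individual genotype codes with negative values
    marking missing calls; a fully called cohort of n diploids gives 2n.
    """
    g = np.asarray(genotypes)
    return int(2 * np.count_nonzero(g >= 0))


def failure_tally(verdicts: list[FilterVerdict]) -> dict[str, int]:
    """Per-rule failure counts across a set of verdicts (plus repeat masking)."""
    tally: dict[str, int] = {}
    for v in verdicts:
        for name in v.failed:
            tally[name] = tally.get(name, 0) + 1
        if v.masked_by_repeat:
            tally["RepeatMask"] = tally.get("RepeatMask", 0) + 1
    return tally
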