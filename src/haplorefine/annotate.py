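"""Consequence-impact classification and transition/transversion summaries.

Sequence Ontology consequence terms (VEP snake_case vocabulary) are grouped
into four impact classes of decreasing severity — LoF, MODERATE, LOW, OTHER —
and a variant hitting several transcripts takes the most severe applicable
class.  Ts/Tv ratios (transitions A<->G, C<->T over all other substitutions)
summarize SNP sets, optionally stratified.
"""

from __future__ import annotations

import enum
import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)


class ImpactClass(enum.IntEnum):
    """Severity-ordered impact classes; lower value = more severe."""

    LOF = 0
    MODERATE = 1
    LOW = 2
    OTHER = 3

    def __str__(self) -> str:  # table-style label
        return "LoF" if self is ImpactClass.LOF else self.name


#: SO term -> impact class.  Initiator-codon variants are grouped with LoF
#: (full loss of the annotated start) even though VEP ranks them lower.
DEFAULT_IMPACT_MAP: dict[str, ImpactClass] = {
    "stop_gained": ImpactClass.LOF,
    "stop_lost": ImpactClass.LOF,
    "frameshift_variant": ImpactClass.LOF,
    "splice_acceptor_variant": ImpactClass.LOF,
    "splice_donor_variant": ImpactClass.LOF,
    "initiator_codon_variant": ImpactClass.LOF,
    "missense_variant": ImpactClass.MODERATE,
    "inframe_insertion": ImpactClass.MODERATE,
    "inframe_deletion": ImpactClass.MODERATE,
    "splice_region_variant": ImpactClass.MODERATE,
    "synonymous_variant": ImpactClass.LOW,
    "stop_retained_variant": ImpactClass.LOW,
    "3_prime_UTR_variant": ImpactClass.LOW,
    "5_prime_UTR_variant": ImpactClass.LOW,
    "intron_variant": ImpactClass.OTHER,
    "intergenic_variant": ImpactClass.OTHER,
    "upstream_gene_variant": ImpactClass.OTHER,
    "downstream_gene_variant": ImpactClass.OTHER,
}

_warned_terms: set[str] = set()

_TRANSITIONS = ({"A", "G"}, {"C", "T"})
_BASES = "ACGT"


def most_severe_impact(
    terms: Iterable[str], impact_map: Mapping[str, ImpactClass] | None = None
) -> ImpactClass:
    """Most severe impact class over all consequence terms across transcripts.

    Unrecognized terms classify as OTHER with a once-per-term warning; a
    variant with no terms at all defaults to intergenic, hence OTHER.
    """
    impact_map = impact_map if impact_map is not None else DEFAULT_IMPACT_MAP
    best = ImpactClass.OTHER
    for term in terms:
        cls = impact_map.get(term)
        if cls is None:
            if term not in _warned_terms:
                _warned_terms.add(term)
                logger.warning("unrecognized consequence term %r -> OTHER", term)
            cls = ImpactClass.OTHER
        best = min(best, cls)
    return best


def is_transition(ref: str, alt: str) -> bool:
    """True iff the substitution is A<->G or C<->T (symmetric in ref/alt)."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("transition/transversion is defined for SNPs only")
    ref, alt = ref.upper(), alt.upper()
    if ref not in _BASES or alt not in _BASES or ref == alt:
        raise ValueError(f"invalid SNP alleles {ref}/{alt}")
    return {ref, alt} in _TRANSITIONS


@dataclass
class TsTvStratum:
    n_transitions: int
    n_transversions: int

    @property
    def ratio(self) -> float:
        if self.n_transversions == 0:
            return float("inf") if self.n_transitions > 0 else float("nan")
        return self.n_transitions / self.n_transversions


def tstv_ratio(
    snps: Sequence[tuple[str, str]],
    strata: Sequence | None = None,
) -> dict:
    """Ts/Tv counts and ratio, overall or per stratum.

    ``snps`` is a sequence of (ref, alt) pairs; ``strata`` an optional parallel
    sequence of stratification keys.  Zero transversions report an infinite
    ratio with both counts retained; an empty stratum reports NaN.
    """
    if strata is None:
        strata = ["all"] * len(snps)
    if len(strata) != len(snps):
        raise ValueError("strata must parallel the SNP list")
    ts: Counter = Counter()
    tv: Counter = Counter()
    for (ref, alt), key in zip(snps, strata):
        if is_transition(ref, alt):
            ts[key] += 1
        else:
            tv[key] += 1
    return {
        key: TsTvStratum(ts[key], tv[key])
        for key in dict.fromkeys(list(ts) + list(tv))
    }


def stop_retained_substitutions() -> list[tuple[str, str]]:
    """All single-base substitutions that turn one stop codon into another.

    Brute-force enumeration over the three stop codons and every alternative
    base at every position; used to verify that stop-retained changes are
    obligate transitions.
    """
    stops = {"TAA", "TAG", "TGA"}
    out = []
    for codon in sorted(stops):
        for i, ref_base in enumerate(codon):
            for alt_base in _BASES:
                if alt_base == ref_base:
                    continue
                mutated = codon[:i] + alt_base + codon[i + 1:]
                if mutated in stops:
                    out.append((ref_base, alt_base))
    return out
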