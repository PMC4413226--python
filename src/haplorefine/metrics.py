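"""Validation summaries: imputation accuracy, catalogue overlap, indel spectra."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from haplorefine.io import IntervalSet, SiteRecord
from haplorefine.polarize import PolarizationState, derived_allele_frequency


def dosage_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between posterior dosages and truth genotypes.

    The standard imputation-accuracy statistic.  Returns NaN when either
    vector is constant (monomorphic truth or degenerate dosages).
    """
    dosages = np.asarray(dosages, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if dosages.shape != truth.shape:
        raise ValueError("dosage and truth vectors must have equal length")
    if not np.isin(truth, (0, 1, 2)).all():
        raise ValueError("truth genotypes must be 0, 1 or 2")
    if np.ptp(dosages) == 0 or np.ptp(truth) == 0:
        return float("nan")
    return float(np.corrcoef(dosages, truth)[0, 1] ** 2)


def call_concordance(calls: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of hard genotype calls equal to truth (uncalled counts as wrong)."""
    calls = np.asarray(calls)
    truth = np.asarray(truth)
    if calls.shape != truth.shape:
        raise ValueError("call and truth vectors must have equal length")
    return float(np.mean(calls == truth))


def _left_align_trim(ref: str, alt: str) -> tuple[str, str, int]:
    """Trim shared suffix then shared prefix; returns (ref, alt, pos offset)."""
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    offset = 0
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        offset += 1
    return ref, alt, offset


def normalized_key(record: SiteRecord) -> tuple[str, int, str, str]:
    """(chrom, pos, ref, alt) lookup key with indel alleles trimmed."""
    ref, alt, offset = _left_align_trim(record.ref, record.alt)
    return record.chrom, record.pos + offset, ref, alt


@dataclass
class OverlapReport:
    """Per DAF-bin fraction of variants found in a reference site catalogue."""

    bins: list[tuple[float, float]]
    fractions: dict[str, list[float]]  # variant type -> per-bin fraction
    counts: dict[str, list[int]]


def catalogue_overlap(
    records: list[SiteRecord],
    catalogue: set[tuple[str, int, str, str]],
    daf_bins: list[tuple[float, float]] | None = None,
) -> OverlapReport:
    """Fraction of sites present in a catalogue, per DAF bin and variant type.

    A variant counts as present if the same position and allele is in the
    catalogue (indels compared after left-align trimming).  Variants whose
    polarization is undetermined are excluded, as DAF is undefined for them.
    """
    daf_bins = daf_bins or [(0.0, 0.005), (0.005, 0.02), (0.02, 1.0)]
    catalogue = {(c, p, r.upper(), a.upper()) for c, p, r, a in catalogue}
    hits: dict[str, list[int]] = {}
    totals: dict[str, list[int]] = {}
    for rec in records:
        state = rec.polarization
        if state is None or state is PolarizationState.UNDETERMINED:
            continue
        if rec.allele_frequency is None:
            continue
        daf = derived_allele_frequency(rec.allele_frequency, state)
        vtype = rec.variant_type
        hits.setdefault(vtype, [0] * len(daf_bins))
        totals.setdefault(vtype, [0] * len(daf_bins))
        for b, (lo, hi) in enumerate(daf_bins):
            if lo <= daf < hi or (hi == 1.0 and daf == 1.0):
                c, p, r, a = normalized_key(rec)
                totals[vtype][b] += 1
                if (c, p, r.upper(), a.upper()) in catalogue:
                    hits[vtype][b] += 1
                break
    fractions = {
        vt: [h / t if t else float("nan") for h, t in zip(hits[vt], totals[vt])]
        for vt in hits
    }
    return OverlapReport(daf_bins, fractions, totals)


@dataclass
class IndelSpectrum:
    """Signed-length histogram with in/out of coding and frame splits."""

    coding: dict[int, int]
    noncoding: dict[int, int]

    def total(self) -> int:
        return sum(self.coding.values()) + sum(self.noncoding.values())

    def frame_split(self, coding: bool = True) -> tuple[int, int]:
        """(in-frame, frameshift) counts — in-frame means length multiple of 3."""
        hist = self.coding if coding else self.noncoding
        inframe = sum(c for length, c in hist.items() if length % 3 == 0)
        return inframe, sum(hist.values()) - inframe


def indel_length_spectrum(
    indels: list[SiteRecord], coding_mask: IntervalSet | None = None
) -> IndelSpectrum:
    """Histogram of signed indel lengths (insertions positive), split by
    overlap with protein-coding intervals."""
    coding: dict[int, int] = {}
    noncoding: dict[int, int] = {}
    for rec in indels:
        length = rec.signed_indel_length
        if length == 0:
            raise ValueError(f"zero-length indel record at {rec.chrom}:{rec.pos}")
        in_coding = bool(
            coding_mask is not None and coding_mask.overlaps(rec.chrom, *rec.ref_span)
        )
        hist = coding if in_coding else noncoding
        hist[length] = hist.get(length, 0) + 1
    return IndelSpectrum(coding, noncoding)
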