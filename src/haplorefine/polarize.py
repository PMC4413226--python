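"""Ancestral-state inference (polarization) for SNPs and indels.

SNPs are polarized by direct comparison with a primate-ancestor base.  Indels
are polarized from an aligned human/ancestor window spanning 5 bp either side
of the indel plus the indel length: if the two windows carry the same number
of bases and at most one flanking mismatch, the reference allele is ancestral;
if the base-count difference equals the indel length (in the direction the
indel implies, with inserted bases matching the insert exactly) and at most
one flanking mismatch, the alternative allele is ancestral; anything else is
left undetermined.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

import pandas as pd

#: flanking context on each side of the indel, in bp
FLANK = 5
GAP_CHARS = set("-.")


class PolarizationState(enum.Enum):
    REF_ANCESTRAL = "ref_ancestral"  # alternative allele is derived
    ALT_ANCESTRAL = "alt_ancestral"  # reference allele is derived
    UNDETERMINED = "undetermined"


@dataclass
class AncestralContext:
    """Aligned human/ancestor windows around one indel.

    Both strings are alignment rows of equal length (gap characters allowed),
    laid out as: ``FLANK`` human flanking bases, the indel region (the longer
    allele's extra bases, as alignment columns), then ``FLANK`` flanking bases.
    ``indel_start``/``indel_end`` delimit the indel columns; when omitted they
    default to the centred layout.
    """

    human: str
    ancestral: str
    indel_length: int
    indel_start: int | None = None
    indel_end: int | None = None

    def __post_init__(self) -> None:
        if len(self.human) != len(self.ancestral):
            raise ValueError("aligned windows must have equal length")
        if self.indel_start is None:
            self.indel_start = FLANK
        if self.indel_end is None:
            self.indel_end = len(self.human) - FLANK


def polarize_snp(ref: str, alt: str, ancestral_base: str) -> PolarizationState:
    """Polarize a SNP against the ancestor base at its position.

    Case is ignored by default (lowercase ancestor bases encode low-confidence
    calls in Ensembl-style ancestral FASTAs); pass ``high_confidence_only``
    handling at the call site by upper-filtering beforehand if needed.
    """
    anc = ancestral_base.upper()
    if anc == ref.upper():
        return PolarizationState.REF_ANCESTRAL
    if anc == alt.upper():
        return PolarizationState.ALT_ANCESTRAL
    return PolarizationState.UNDETERMINED


def _base_count(window: str) -> int:
    return sum(1 for c in window if c not in GAP_CHARS)


def polarize_indel(
    context: AncestralContext,
    indel_length: int,
    indel_type: str,
    insert_sequence: str | None = None,
) -> PolarizationState:
    """Polarize an indel from its aligned ancestral context.

    ``indel_type`` is "insertion" (alt longer than ref) or "deletion".
    Mismatches are counted over flanking columns only, never over the indel
    columns themselves.  For an insertion to be called ancestral the
    ancestor's bases at the indel columns must equal ``insert_sequence``
    exactly.
    """
    if indel_type not in ("insertion", "deletion"):
        raise ValueError(f"unknown indel type {indel_type!r}")
    if indel_length < 1:
        raise ValueError("indel length must be >= 1")
    if len(context.human) < 2 * FLANK + indel_length:
        warnings.warn("ancestral window shorter than required span", stacklevel=2)
        return PolarizationState.UNDETERMINED

    s, e = context.indel_start, context.indel_end
    flank_pairs = [
        (h, a)
        for h, a in list(zip(context.human, context.ancestral))[:s]
        + list(zip(context.human, context.ancestral))[e:]
    ]
    mismatches = sum(
        1 for h, a in flank_pairs
        if h not in GAP_CHARS and a not in GAP_CHARS and h.upper() != a.upper()
    )
    # count alignment columns where exactly one row has a base
    gap_cols = sum(
        1 for h, a in flank_pairs
        if (h in GAP_CHARS) != (a in GAP_CHARS)
    )
    if gap_cols:
        # an extra indel in the flanks: no clean comparison
        return PolarizationState.UNDETERMINED

    diff = _base_count(context.human) - _base_count(context.ancestral)
    # sign convention: for a deletion the human (reference) window carries the
    # indel bases, for an insertion it lacks them
    if diff == 0:
        if mismatches <= 1:
            return PolarizationState.REF_ANCESTRAL
        return PolarizationState.UNDETERMINED
    expected = indel_length if indel_type == "deletion" else -indel_length
    if diff == expected and mismatches <= 1:
        if indel_type == "insertion":
            anc_insert = "".join(
                a for a in context.ancestral[s:e] if a not in GAP_CHARS
            )
            if insert_sequence is None or anc_insert.upper() != insert_sequence.upper():
                return PolarizationState.UNDETERMINED
        return PolarizationState.ALT_ANCESTRAL
    return PolarizationState.UNDETERMINED


def derived_allele_frequency(
    alt_frequency: float, state: PolarizationState
) -> float | None:
    """DAF: alt frequency if the reference is ancestral, its complement if the
    alternative is ancestral, undefined otherwise."""
    if not 0.0 <= alt_frequency <= 1.0:
        raise ValueError("alt frequency must lie in [0, 1]")
    if state is PolarizationState.REF_ANCESTRAL:
        return alt_frequency
    if state is PolarizationState.ALT_ANCESTRAL:
        return 1.0 - alt_frequency
    return None


def read_alignment_windows(path: str) -> dict[tuple[str, int], AncestralContext]:
    """Read the toy tab-separated ancestral-window exchange format.

    Columns: chrom, pos (1-based), indel_length, human_window, ancestral_window.
    """
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "indel_length", "human", "ancestral"],
        dtype={"chrom": str},
    )
    return {
        (row.chrom, int(row.pos)): AncestralContext(
            row.human, row.ancestral, int(row.indel_length)
        )
        for row in df.itertuples(index=False)
    }


def write_alignment_windows(
    windows: dict[tuple[str, int], AncestralContext], path: str
) -> None:
    with open(path, "w") as fh:
        for (chrom, pos), ctx in sorted(windows.items()):
            fh.write(
                f"{chrom}\t{pos}\t{ctx.indel_length}\t{ctx.human}\t{ctx.ancestral}\n"
            )
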