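"""Data model and readers/writers for variants, likelihoods, scaffolds, maps, intervals.

Coordinate conventions: VCF records and all user-facing positions are 1-based;
:class:`IntervalSet` is 0-based half-open (BED convention) internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from intervaltree import IntervalTree

#: INFO annotation keys recognized on a SiteRecord (GATK-style call annotations
#: plus the cohort-level Hardy-Weinberg P and the imputation info score).
ANNOTATION_KEYS = (
    "QD",
    "MQ",
    "FS",
    "HaplotypeScore",
    "MQRankSum",
    "ReadPosRankSum",
    "DP",
    "AN",
    "HW",
    "SI",
)

#: Longest indel (bp length difference) admitted to the refinement set.
MAX_INDEL_LENGTH = 60


class GeneticMap:
    """Marker positions (bp, 1-based) with cumulative genetic positions (cM).

    Positions must be strictly increasing and genetic positions non-decreasing,
    so every inter-marker recombination distance r_i is >= 0.
    """

    def __init__(self, positions: Sequence[int], cm: Sequence[float]):
        positions = np.asarray(positions, dtype=np.int64)
        cm = np.asarray(cm, dtype=float)
        if positions.ndim != 1 or positions.shape != cm.shape:
            raise ValueError("positions and cm must be 1-D and equal length")
        if positions.size == 0:
            raise ValueError("genetic map must contain at least one marker")
        if np.any(np.diff(positions) <= 0):
            raise ValueError("genetic map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ValueError("genetic positions (cM) must be non-decreasing")
        self.positions = positions
        self.cm = cm

    def __len__(self) -> int:
        return self.positions.size

    def recomb_distances(self) -> np.ndarray:
        """r_i for i = 1..M-1: genetic distance between adjacent markers, in Morgans."""
        return np.diff(self.cm) / 100.0

    def cm_at(self, position: float) -> float:
        """Genetic position of an arbitrary bp coordinate, by linear interpolation.

        Outside the mapped span the nearest end's value is returned (np.interp
        clamping), which matches the nearest-marker convention used downstream.
        """
        return float(np.interp(position, self.positions, self.cm))


@dataclass
class ScaffoldHaplotypes:
    """Phased biallelic allele matrix over chip markers: the haplotype pool H.

    ``alleles`` is (n_haplotypes, n_markers) with entries in {0, 1}.  Haplotypes
    come in pairs: haplotype 2j and 2j+1 belong to individual ``individuals[j]``.
    """

    alleles: np.ndarray
    individuals: Sequence[str]
    chrom: str = "1"
    positions: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.ndim != 2:
            raise ValueError("allele matrix must be 2-D (haplotype x marker)")
        if not np.isin(self.alleles, (0, 1)).all():
            raise ValueError("scaffold alleles must be biallelic 0/1")
        if self.alleles.shape[0] != 2 * len(self.individuals):
            raise ValueError(
                "every individual must contribute exactly 2 haplotypes "
                f"(got {self.alleles.shape[0]} haplotypes for "
                f"{len(self.individuals)} individuals)"
            )
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=np.int64)
            if self.positions.size != self.alleles.shape[1]:
                raise ValueError("marker positions must match allele matrix width")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_markers(self) -> int:
        return self.alleles.shape[1]

    def haplotype_ids(self) -> list[str]:
        return [f"{ind}_{a}" for ind in self.individuals for a in (0, 1)]

    def individual_of(self, h: int) -> int:
        """Index of the individual carrying haplotype ``h``."""
        return h // 2

    def partner_of(self, h: int) -> int:
        """The other haplotype of the same individual."""
        return h ^ 1


class GenotypeLikelihoods:
    """Per-individual genotype likelihood triples (L0, L1, L2) at one variant.

    L_g is the probability of the observed sequencing data given true genotype
    g copies of the alternative allele.  Only ratios matter; rows are stored
    normalized to sum to 1.
    """

    def __init__(self, values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 3:
            raise ValueError("likelihoods must have shape (n_individuals, 3)")
        if np.any(values < 0):
            raise ValueError("likelihoods must be non-negative")
        sums = values.sum(axis=1)
        if np.any(sums <= 0):
            raise ValueError("each individual needs at least one positive likelihood")
        self.values = values / sums[:, None]

    def __len__(self) -> int:
        return self.values.shape[0]

    @classmethod
    def uniform(cls, n: int) -> "GenotypeLikelihoods":
        return cls(np.ones((n, 3)))

    @classmethod
    def from_pl(cls, pl: np.ndarray) -> "GenotypeLikelihoods":
        """Phred-scaled likelihood triples (VCF PL) to linear scale: 10^(-PL/10)."""
        return cls(10.0 ** (-np.asarray(pl, dtype=float) / 10.0))

    @classmethod
    def from_gl(cls, gl: np.ndarray) -> "GenotypeLikelihoods":
        """log10 likelihood triples (VCF GL) to linear scale."""
        return cls(10.0 ** np.asarray(gl, dtype=float))


@dataclass
class SiteRecord:
    """One biallelic variant with annotations and downstream classification slots."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    allele_frequency: float | None = None
    annotations: dict = field(default_factory=dict)
    consequences: list = field(default_factory=list)
    filter_verdict: object | None = None
    polarization: object | None = None
    impact: object | None = None

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"position must be positive, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.variant_type == "indel" and not 1 <= self.indel_length <= MAX_INDEL_LENGTH:
            raise ValueError(
                f"indel length {self.indel_length} outside [1, {MAX_INDEL_LENGTH}]"
            )

    @property
    def variant_type(self) -> str:
        """'SNP' iff both alleles are single bases, else 'indel'."""
        return "SNP" if len(self.ref) == 1 and len(self.alt) == 1 else "indel"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref) - len(self.alt))

    @property
    def signed_indel_length(self) -> int:
        """Insertions positive, deletions negative."""
        return len(self.alt) - len(self.ref)

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open interval covered by the reference allele."""
        return self.pos - 1, self.pos - 1 + len(self.ref)


class IntervalSet:
    """Merged genomic intervals per chromosome, 0-based half-open."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)
        self.merge()

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"interval end must exceed start: {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    def merge(self) -> None:
        for tree in self._trees.values():
            tree.merge_overlaps(strict=False)

    @property
    def chromosomes(self) -> set[str]:
        return set(self._trees)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    def contains(self, chrom: str, pos0: int) -> bool:
        """Point containment at a single 0-based position."""
        return self.overlaps(chrom, pos0, pos0 + 1)

    def intervals(self, chrom: str) -> list[tuple[int, int]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end) for iv in tree)

    def total_coverage(self) -> int:
        return sum(e - b for t in self._trees.values() for b, e in
                   ((iv.begin, iv.end) for iv in t))

    @classmethod
    def union(cls, *sets: "IntervalSet") -> "IntervalSet":
        out = cls()
        for s in sets:
            for chrom in s.chromosomes:
                for b, e in s.intervals(chrom):
                    out.add(chrom, b, e)
        out.merge()
        return out

    @classmethod
    def from_bed(cls, path: str) -> "IntervalSet":
        df = pd.read_csv(
            path, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={"chrom": str, "start": np.int64, "end": np.int64},
        )
        return cls(df.itertuples(index=False, name=None))

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.chromosomes):
                for b, e in self.intervals(chrom):
                    fh.write(f"{chrom}\t{b}\t{e}\n")


@dataclass
class VariantTable:
    """Result of :func:`read_vcf`: parallel site records and cohort likelihoods."""

    sites: list[SiteRecord]
    likelihoods: list[GenotypeLikelihoods]
    samples: list[str]
    #: phased genotype posteriors (n, 4) per site when the file carries a PP field
    phased_posteriors: list[np.ndarray | None] = field(default_factory=list)
    n_skipped_multiallelic: int = 0
    n_skipped_long_indels: int = 0

    def __iter__(self):
        return iter(zip(self.sites, self.likelihoods))

    def __len__(self) -> int:
        return len(self.sites)


def read_genetic_map(path: str) -> GeneticMap:
    """Read a two-column tab-separated bp -> cM table into a :class:`GeneticMap`."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1], names=["pos", "cm"])
    return GeneticMap(df["pos"].to_numpy(np.int64), df["cm"].to_numpy(float))


def write_genetic_map(gmap: GeneticMap, path: str) -> None:
    with open(path, "w") as fh:
        for p, c in zip(gmap.positions, gmap.cm):
            fh.write(f"{p}\t{c:.8g}\n")


def _site_from_vcf_record(rec: "pysam.VariantRecord") -> SiteRecord:
    annotations = {}
    for key in ANNOTATION_KEYS:
        if key in rec.info:
            val = rec.info[key]
            if isinstance(val, tuple):
                val = val[0]
            annotations[key] = float(val)
    consequences = []
    if "CSQ" in rec.info:
        raw = rec.info["CSQ"]
        entries = raw if isinstance(raw, tuple) else (raw,)
        for entry in entries:
            # minimal VEP-style CSQ: first pipe field is an &-joined term list
            consequences.extend(str(entry).split("|")[0].split("&"))
    af = None
    if "AF" in rec.info:
        raw_af = rec.info["AF"]
        af = float(raw_af[0] if isinstance(raw_af, tuple) else raw_af)
    return SiteRecord(
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alts[0],
        allele_frequency=af,
        annotations=annotations,
        consequences=consequences,
    )


def read_vcf(path: str) -> VariantTable:
    """Read biallelic records and per-sample genotype likelihoods from a VCF.

    PL (phred-scaled integer) and GL (log10) FORMAT fields are both accepted and
    converted to linear likelihoods; a sample with neither gets the uninformative
    triple (1, 1, 1).  Multi-allelic records and indels longer than 60 bp are
    skipped and counted, not decomposed.
    """
    sites: list[SiteRecord] = []
    liks: list[GenotypeLikelihoods] = []
    posteriors: list[np.ndarray | None] = []
    n_multi = 0
    n_long = 0
    try:
        vcf = pysam.VariantFile(path)
    except (ValueError, OSError) as exc:
        raise ValueError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.header.samples)
    for rec in vcf:
        if rec.alts is None or len(rec.alts) != 1:
            n_multi += 1
            continue
        if abs(len(rec.ref) - len(rec.alts[0])) > MAX_INDEL_LENGTH:
            n_long += 1
            continue
        try:
            site = _site_from_vcf_record(rec)
        except ValueError as exc:
            raise ValueError(
                f"malformed VCF record at {rec.chrom}:{rec.pos}: {exc}"
            ) from exc
        if rec.filter.keys() and "PASS" not in rec.filter.keys():
            from haplorefine.filters import FilterVerdict  # local import: avoid cycle

            site.filter_verdict = FilterVerdict(failed=list(rec.filter.keys()))
        rows = np.ones((len(samples), 3), dtype=float)
        pp_rows: np.ndarray | None = None
        for j, sample in enumerate(samples):
            fmt = rec.samples[sample]
            if "PL" in fmt and fmt["PL"] is not None and fmt["PL"][0] is not None:
                rows[j] = 10.0 ** (-np.asarray(fmt["PL"], dtype=float) / 10.0)
            elif "GL" in fmt and fmt["GL"] is not None and fmt["GL"][0] is not None:
                rows[j] = 10.0 ** np.asarray(fmt["GL"], dtype=float)
            if "PP" in fmt and fmt["PP"] is not None and fmt["PP"][0] is not None:
                if pp_rows is None:
                    pp_rows = np.full((len(samples), 4), np.nan)
                pp_rows[j] = np.asarray(fmt["PP"], dtype=float)
        sites.append(site)
        liks.append(GenotypeLikelihoods(rows))
        posteriors.append(pp_rows)
    vcf.close()
    if n_multi:
        warnings.warn(f"skipped {n_multi} multi-allelic record(s)", stacklevel=2)
    return VariantTable(sites, liks, samples, posteriors, n_multi, n_long)


def _refined_vcf_header(
    records: Sequence[SiteRecord], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for chrom in dict.fromkeys(r.chrom for r in records):
        header.contigs.add(chrom)
    header.info.add("AF", "A", "Float", "Estimated alternative allele frequency")
    header.info.add("SI", 1, "Float", "Imputation info score")
    header.info.add("AA", 1, "String", "Ancestral allele (REF/ALT/.)")
    header.info.add("DAF", 1, "Float", "Derived allele frequency")
    header.info.add("IMPACT", 1, "String", "Most severe impact class")
    for key in ANNOTATION_KEYS:
        if key not in header.info:
            header.info.add(key, 1, "Float", f"{key} call annotation")
    header.formats.add("GT", 1, "String", "Phased genotype")
    header.formats.add("GP", 3, "Float", "Genotype posteriors P(0),P(1),P(2)")
    header.formats.add("PP", 4, "Float", "Phased genotype posteriors P00,P01,P10,P11")
    filter_names = set()
    for rec in records:
        if rec.filter_verdict is not None:
            filter_names.update(rec.filter_verdict.failed)
            if getattr(rec.filter_verdict, "masked_by_repeat", False):
                filter_names.add("RepeatMask")
    for name in sorted(filter_names):
        header.filters.add(name, None, None, f"Failed {name} site filter")
    for sample in samples:
        header.add_sample(sample)
    return header


def write_refined_vcf(
    records: Sequence[SiteRecord],
    results: Sequence,
    path: str,
    samples: Sequence[str],
) -> None:
    """Write refined variants: phased GT, genotype posteriors, info score, verdicts.

    ``results`` are :class:`~haplorefine.refine.RefinedVariant` objects (or
    anything exposing ``posteriors``, ``genotype_strings()``, ``info``,
    ``frequency``), one per record.
    """
    if len(records) != len(results):
        raise ValueError(
            f"{len(records)} records but {len(results)} refinement results"
        )
    header = _refined_vcf_header(records, samples)
    out = pysam.VariantFile(path, "w", header=header)
    for site, res in zip(records, results):
        rec = out.new_record(
            contig=site.chrom, start=site.pos - 1, stop=site.pos - 1 + len(site.ref),
            alleles=(site.ref, site.alt),
        )
        rec.info["AF"] = (float(res.frequency),)
        rec.info["SI"] = float(res.info)
        for key, val in site.annotations.items():
            rec.info[key] = float(val)
        verdict = site.filter_verdict
        if verdict is None or verdict.passed:
            rec.filter.add("PASS")
        else:
            for name in verdict.failed:
                rec.filter.add(name)
            if getattr(verdict, "masked_by_repeat", False):
                rec.filter.add("RepeatMask")
        gts = res.genotype_strings()
        post = np.asarray(res.posteriors, dtype=float)
        for j, sample in enumerate(samples):
            p00, p01, p10, p11 = post[j]
            fmt = rec.samples[sample]
            fmt["GP"] = (float(p00), float(p01 + p10), float(p11))
            fmt["PP"] = tuple(float(x) for x in post[j])
            gt = gts[j]
            if gt == "./.":
                fmt["GT"] = (None, None)
            else:
                sep_phased = "|" in gt
                a, b = (int(x) for x in gt.replace("|", "/").split("/"))
                fmt["GT"] = (a, b)
                fmt.phased = sep_phased
        out.write(rec)
    out.close()


def write_simple_vcf(
    records: Sequence[SiteRecord],
    path: str,
    likelihoods: Sequence[GenotypeLikelihoods] | None = None,
    samples: Sequence[str] | None = None,
) -> None:
    """Write sites (and optional PL likelihoods) as an uncompressed VCF.

    Used by the simulator and fixtures; phred values are capped at 9999.
    """
    samples = list(samples or [])
    header = _refined_vcf_header(records, samples)
    # Number=3 (not G): records carry no GT, so pysam cannot infer ploidy
    header.formats.add("PL", 3, "Integer", "Phred-scaled genotype likelihoods")
    out = pysam.VariantFile(path, "w", header=header)
    for i, site in enumerate(records):
        rec = out.new_record(
            contig=site.chrom, start=site.pos - 1, stop=site.pos - 1 + len(site.ref),
            alleles=(site.ref, site.alt),
        )
        if site.allele_frequency is not None:
            rec.info["AF"] = (float(site.allele_frequency),)
        for key, val in site.annotations.items():
            rec.info[key] = float(val)
        if likelihoods is not None:
            lik = likelihoods[i].values
            with np.errstate(divide="ignore"):
                pl = -10.0 * np.log10(lik / lik.max(axis=1, keepdims=True))
            pl = np.minimum(pl, 9999.0)
            for j, sample in enumerate(samples):
                rec.samples[sample]["PL"] = tuple(int(round(x)) for x in pl[j])
        out.write(rec)
    out.close()
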