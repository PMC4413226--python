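"""Synthetic cohorts with the statistical structure the refiner assumes.

The generator emulates a chip-typed, long-range-phased diploid cohort: a small
set of founder haplotypes, sample haplotypes built as founder mosaics with
exponentially distributed segment lengths in genetic distance, a rare target
variant perfectly tagged by a founder lineage, and sequencing reads drawn as
Poisson depth with binomial allele counts.  Because the generative model
matches the copying-model assumptions, parameter-recovery tests are fair; a
misspecified mode (independent random haplotypes, no sharing) is provided to
show refinement degrading gracefully toward likelihood-only calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from haplorefine.io import (
    GeneticMap,
    GenotypeLikelihoods,
    ScaffoldHaplotypes,
    SiteRecord,
)
from haplorefine.polarize import AncestralContext, PolarizationState, FLANK

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters.

    Defaults give a 200-diploid cohort over 100 scaffold markers spanning
    ~5 cM — large enough for clear sharing signal, small enough for
    seconds-scale runs.  ``mean_depth`` 20 and ``error_rate`` 0.01 mirror a
    typical 20x short-read experiment.
    """

    n_individuals: int = 200
    n_markers: int = 100
    n_founders: int = 20
    switch_rate_per_cm: float = 1.0
    marker_spacing_cm: float = 0.05
    marker_spacing_bp: int = 10_000
    target_maf: float = 0.05
    mean_depth: float = 20.0
    error_rate: float = 0.01
    misspecified: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_individuals, self.n_markers, self.n_founders) < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.error_rate < 0.5:
            raise ValueError("error rate must lie in (0, 0.5)")
        if not 0.0 <= self.target_maf <= 0.5:
            raise ValueError("target MAF must lie in [0, 0.5]")


@dataclass
class SimulatedCohort:
    scaffold: ScaffoldHaplotypes
    genetic_map: GeneticMap
    founders: np.ndarray  # (n_founders, M)
    founder_truth: np.ndarray  # (2n, M) founder copied at each marker
    position: int  # target variant position (bp)
    truth_alleles: np.ndarray  # (2n,) 0/1 at the target variant
    truth_genotypes: np.ndarray  # (n,) 0/1/2
    likelihoods: GenotypeLikelihoods
    realized_maf: float
    config: SimulationConfig = field(repr=False, default=None)


def simulate_haplotype_pool(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[ScaffoldHaplotypes, GeneticMap, np.ndarray, np.ndarray]:
    """Founder pool plus mosaic sample haplotypes and their truth labels.

    Returns (scaffold, genetic map, founders, founder_truth) where
    founder_truth[h, i] is the founder each haplotype copies at marker i.
    In misspecified mode sample haplotypes are iid Bernoulli(1/2) and the
    truth labels are -1 (no copying structure exists).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.n_markers
    n_hap = 2 * config.n_individuals
    founders = rng.integers(0, 2, size=(config.n_founders, m), dtype=np.int8)
    positions = 1 + config.marker_spacing_bp * np.arange(m, dtype=np.int64)
    cm = config.marker_spacing_cm * np.arange(m)
    gmap = GeneticMap(positions, cm)

    if config.misspecified:
        alleles = rng.integers(0, 2, size=(n_hap, m), dtype=np.int8)
        truth = np.full((n_hap, m), -1, dtype=np.int32)
    else:
        # switch between adjacent markers with P = 1 - exp(-rate * d_cM),
        # i.e. exponential segment lengths in genetic distance
        d_cm = np.diff(cm)
        p_switch = 1.0 - np.exp(-config.switch_rate_per_cm * d_cm)
        truth = np.empty((n_hap, m), dtype=np.int32)
        truth[:, 0] = rng.integers(0, config.n_founders, size=n_hap)
        switches = rng.random(size=(n_hap, m - 1)) < p_switch[None, :]
        new_founders = rng.integers(0, config.n_founders, size=(n_hap, m - 1))
        for i in range(1, m):
            truth[:, i] = np.where(
                switches[:, i - 1], new_founders[:, i - 1], truth[:, i - 1]
            )
        alleles = founders[truth, np.arange(m)[None, :]]
    individuals = [f"ind{j:04d}" for j in range(config.n_individuals)]
    scaffold = ScaffoldHaplotypes(alleles, individuals, positions=positions)
    return scaffold, gmap, founders, truth


def plant_target_variant(
    founder_truth: np.ndarray,
    maf: float,
    position: int,
    genetic_map: GeneticMap,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, float]:
    """Assign allele 1 to haplotypes copying a chosen founder set at ``position``.

    The carrier set is a greedy subset of founder lineages whose copier count
    approaches maf * 2n, so the variant is perfectly tagged by the local
    haplotype background.  Returns (per-haplotype alleles, realized frequency);
    if the requested MAF is not exactly reachable the closest achievable
    frequency is used and reported via the second return value.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    n_hap = founder_truth.shape[0]
    if founder_truth.min() < 0:
        # misspecified pool: no lineages; assign carriers at random
        k = int(round(maf * n_hap))
        alleles = np.zeros(n_hap, dtype=np.int8)
        alleles[rng.choice(n_hap, size=k, replace=False)] = 1
        return alleles, k / n_hap
    marker = int(np.searchsorted(genetic_map.positions, position, side="right")) - 1
    marker = min(max(marker, 0), founder_truth.shape[1] - 1)
    local = founder_truth[:, marker]
    target = int(round(maf * n_hap))
    counts = np.bincount(local)
    # smallest lineages first: finest granularity toward the target count
    order = np.argsort(counts, kind="stable")
    chosen: list[int] = []
    total = 0
    for f in order:
        c = counts[f]
        if c == 0:
            continue
        if abs(total + c - target) <= abs(total - target):
            chosen.append(int(f))
            total += c
        if total == target:
            break
    alleles = np.isin(local, chosen).astype(np.int8)
    return alleles, alleles.mean()


def simulate_likelihoods(
    truth_genotypes: np.ndarray,
    mean_depth: float,
    error_rate: float,
    rng: np.random.Generator | None = None,
) -> tuple[GenotypeLikelihoods, np.ndarray, np.ndarray]:
    """Poisson read depth, binomial alternative counts, binomial likelihoods.

    The alternative-read probability is error_rate, 1/2 and 1 - error_rate for
    true genotypes 0, 1 and 2; L_g is the binomial probability of the observed
    alternative count under each genotype.  Zero reads give the uninformative
    triple.  Returns (likelihoods, read counts, alt counts).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    truth_genotypes = np.asarray(truth_genotypes)
    if mean_depth <= 0:
        raise ValueError("mean depth must be positive")
    n = truth_genotypes.size
    reads = rng.poisson(mean_depth, size=n)
    p_alt = np.array([error_rate, 0.5, 1.0 - error_rate])[truth_genotypes]
    alts = rng.binomial(reads, p_alt)
    probs = np.array([error_rate, 0.5, 1.0 - error_rate])
    lik = stats.binom.pmf(alts[:, None], reads[:, None], probs[None, :])
    lik[reads == 0] = 1.0
    return GenotypeLikelihoods(lik), reads, alts


def likelihoods_from_read_counts(
    n_reads: int, n_alt: int, error_rate: float
) -> GenotypeLikelihoods:
    """Closed-form likelihood triple for one individual's read counts."""
    probs = np.array([error_rate, 0.5, 1.0 - error_rate])
    lik = stats.binom.pmf(n_alt, n_reads, probs)
    return GenotypeLikelihoods(lik[None, :])


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Full chain: mosaic pool, planted tagged variant, sequencing likelihoods."""
    rng = np.random.default_rng(config.seed)
    scaffold, gmap, founders, truth = simulate_haplotype_pool(config, rng)
    # target sits mid-way between the two central scaffold markers
    mid = config.n_markers // 2
    position = int((gmap.positions[mid - 1] + gmap.positions[mid]) // 2)
    alleles, realized = plant_target_variant(
        truth, config.target_maf, position, gmap, rng
    )
    genotypes = alleles[0::2] + alleles[1::2]
    lik, _, _ = simulate_likelihoods(
        genotypes, config.mean_depth, config.error_rate, rng
    )
    return SimulatedCohort(
        scaffold=scaffold,
        genetic_map=gmap,
        founders=founders,
        founder_truth=truth,
        position=position,
        truth_alleles=alleles,
        truth_genotypes=genotypes,
        likelihoods=lik,
        realized_maf=float(realized),
        config=config,
    )


def random_snp_alleles(
    n: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """SNP ref/alt pairs drawn uniformly over the 12 ordered base pairs.

    Exactly 4 of the 12 are transitions, so the expected Ts/Tv ratio is 0.5 —
    a guard against inverted transition logic.
    """
    pairs = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]
    idx = rng.integers(0, len(pairs), size=n)
    return [pairs[i] for i in idx]


def _mutate(base: str, rng: np.random.Generator) -> str:
    return str(rng.choice([b for b in "ACGT" if b != base]))


def plant_ancestral_context(
    rng: np.random.Generator,
    indel_type: str,
    indel_length: int,
    true_state: PolarizationState,
    n_mismatches: int,
) -> tuple[AncestralContext, str, PolarizationState]:
    """Ancestor window with planted truth and controlled flank mismatches.

    Returns (context, insert sequence, expected polarization) where the
    expectation is the planted state when ``n_mismatches`` <= 1 and
    undetermined otherwise.
    """
    left = "".join(rng.choice(_BASES, size=FLANK))
    right = "".join(rng.choice(_BASES, size=FLANK))
    indel_seq = "".join(rng.choice(_BASES, size=indel_length))
    if indel_type == "deletion":
        human = left + indel_seq + right
        if true_state is PolarizationState.REF_ANCESTRAL:
            anc_mid = indel_seq
        else:
            anc_mid = "-" * indel_length
    else:
        human = left + "-" * indel_length + right
        if true_state is PolarizationState.REF_ANCESTRAL:
            anc_mid = "-" * indel_length
        else:
            anc_mid = indel_seq
    anc_left, anc_right = list(left), list(right)
    flank_cols = rng.choice(2 * FLANK, size=n_mismatches, replace=False)
    for col in flank_cols:
        if col < FLANK:
            anc_left[col] = _mutate(anc_left[col], rng)
        else:
            anc_right[col - FLANK] = _mutate(anc_right[col - FLANK], rng)
    ancestral = "".join(anc_left) + anc_mid + "".join(anc_right)
    expected = true_state if n_mismatches <= 1 else PolarizationState.UNDETERMINED
    ctx = AncestralContext(human, ancestral, indel_length)
    return ctx, indel_seq, expected


#: baseline annotation values that pass every default filter rule
_PASSING_ANNOTATIONS = {
    "QD": 10.0,
    "MQ": 60.0,
    "FS": 1.0,
    "HaplotypeScore": 2.0,
    "MQRankSum": 0.0,
    "ReadPosRankSum": 0.0,
    "DP": 50_000.0,
    "AN": 5272.0,
    "HW": 0.5,
    "SI": 1.0,
}


@dataclass
class FilterFixture:
    records: list[SiteRecord]
    expected_failures: list[list[str]]  # parallel to records


def make_filter_fixture() -> FilterFixture:
    """Toy site set with exactly one failing rule per engineered record.

    14 failing records (6 SNP-only rules, 3 indel-only rules, 5 shared rules)
    plus 2 passing records chosen so that swapping their SNP/indel type flips
    their verdicts under the type-specific FS and SI thresholds.
    """
    plan: list[tuple[str, dict[str, float], list[str]]] = [
        ("SNP", {"QD": 1.9}, ["QD"]),
        ("SNP", {"MQ": 39.0}, ["MQ"]),
        ("SNP", {"FS": 100.0}, ["FS"]),
        ("SNP", {"HaplotypeScore": 14.0}, ["HaplotypeScore"]),
        ("SNP", {"MQRankSum": -13.0}, ["MQRankSum"]),
        ("SNP", {"ReadPosRankSum": -9.0}, ["ReadPosRankSum"]),
        ("indel", {"QD": 1.9}, ["QD_indel"]),
        ("indel", {"FS": 250.0}, ["FS_indel"]),
        ("indel", {"ReadPosRankSum": -21.0}, ["ReadPosRankSum_indel"]),
        ("SNP", {"DP": 120_000.0}, ["DP"]),
        ("SNP", {"AN": 4000.0}, ["AN"]),
        ("SNP", {"HW": 1e-8}, ["HW"]),
        ("SNP", {"SI": 1.5}, ["SI_high"]),
        ("SNP", {"SI": 0.5}, ["SI_low"]),
        ("indel", {"FS": 100.0}, []),  # passes: indel FS bound is 200
        ("SNP", {"SI": 0.7}, []),  # passes: SNP SI lower bound is 0.6
    ]
    records = []
    expected = []
    for i, (vtype, overrides, failures) in enumerate(plan):
        ref, alt = ("A", "G") if vtype == "SNP" else ("AT", "A")
        ann = dict(_PASSING_ANNOTATIONS, **overrides)
        records.append(
            SiteRecord(
                chrom="1", pos=100 * (i + 1), ref=ref, alt=alt,
                allele_frequency=0.1, annotations=ann,
            )
        )
        expected.append(failures)
    return FilterFixture(records, expected)


def make_polarization_fixture(seed: int = 7) -> list[tuple]:
    """(context, insert_seq, indel_type, length, expected state) covering every
    determinate and undetermined branch for insertions and deletions."""
    rng = np.random.default_rng(seed)
    cases = []
    for indel_type in ("deletion", "insertion"):
        for state in (
            PolarizationState.REF_ANCESTRAL,
            PolarizationState.ALT_ANCESTRAL,
        ):
            for n_mm in (0, 1, 2):
                ctx, ins, expected = plant_ancestral_context(
                    rng, indel_type, 2, state, n_mm
                )
                cases.append((ctx, ins, indel_type, 2, expected))
    return cases


def make_fixtures(out_dir: str, seed: int = 7) -> dict:
    """Write the deterministic toy fixture files and return their paths.

    Produces a filter-fixture VCF, ancestral alignment windows (TSV), a toy
    tandem-repeat BED and a site catalogue with a known overlap fraction.
    """
    import os

    from haplorefine.io import write_simple_vcf
    from haplorefine.polarize import write_alignment_windows

    os.makedirs(out_dir, exist_ok=True)
    fixture = make_filter_fixture()
    vcf_path = os.path.join(out_dir, "filter_fixture.vcf")
    write_simple_vcf(fixture.records, vcf_path)

    windows = {}
    for i, (ctx, _ins, _t, _l, _exp) in enumerate(make_polarization_fixture(seed)):
        windows[("1", 1000 + 10 * i)] = ctx
    win_path = os.path.join(out_dir, "ancestor_windows.tsv")
    write_alignment_windows(windows, win_path)

    bed_path = os.path.join(out_dir, "trf.bed")
    with open(bed_path, "w") as fh:
        fh.write("1\t120\t180\n1\t150\t220\n1\t500\t560\n")

    rng = np.random.default_rng(seed)
    catalogue_path = os.path.join(out_dir, "catalogue.tsv")
    with open(catalogue_path, "w") as fh:
        for rec in fixture.records:
            if rng.random() < 0.5:
                fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.ref}\t{rec.alt}\n")
    return {
        "filter_vcf": vcf_path,
        "ancestor_windows": win_path,
        "trf_bed": bed_path,
        "catalogue": catalogue_path,
        "expected_failures": fixture.expected_failures,
    }
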