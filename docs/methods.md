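# Methods

## The problem

Genotype calls made from sequence reads alone err at a rate set by depth: at a
true heterozygous site covered by eight reads of which one carries the
alternative allele, the maximum-likelihood genotype is homozygous reference.
In a cohort where every sequenced individual is also chip-genotyped and
long-range phased, haplotype sharing carries exactly the information needed to
rescue such calls: if the ambiguous individual shares a haplotype background
with another individual who is confidently heterozygous, the ambiguous call
should move toward heterozygous, and conversely toward homozygous reference
when both backgrounds are shared with confident non-carriers. `haplorefine`
implements this refinement, together with the variant-processing machinery
that surrounds it in a sequencing study: hard-threshold site filtering with
repeat masking, ancestral-state polarization, impact classification with
Ts/Tv summaries, and validation metrics.

## Copying model

Each phased haplotype h in the scaffold pool H is modelled as an imperfect
mosaic of the other haplotypes (the Li & Stephens haplotype-copying model, as
used by IMPUTE-style imputation). The latent copying state z_i at scaffold
marker i is the donor haplotype, with

- emission: P(marker i | z_i = k) = 1 − λ if h and k agree at i, λ otherwise;
- transition over the inter-marker distance r_i (Morgans), with
  ρ_i = 4·N_e·r_i and N = |H \ {h}| donors:
  P(stay) = e^(−ρ_i/N) + (1 − e^(−ρ_i/N))/N and
  P(switch to a specific other donor) = (1 − e^(−ρ_i/N))/N.

Forward–backward over all markers yields γ_{h,k,i} = P(z_i = k | all markers)
simultaneously for all donors in O(MN) per haplotype. The forward pass is
initialized uniform over donors (the model gives no preference before the
first marker), and both passes are rescaled per marker; the posteriors are
invariant to this rescaling, which is verified against an exhaustive-path
reference on tiny pools (agreement well inside 1e−10).

Defaults: λ = 1e−7, N_e = 7000, and γ entries below 1e−6 of the per-marker
maximum are dropped after forward–backward (ties at the cutoff retained), so
at every marker the retained mass is at least 1 − N·threshold. N is always
recomputed from the actual pool (2(n−1) for n diploids). Note that λ and N_e
interact with pool size: with very few donors, ρ_i/N becomes large at marker
spacings that are unremarkable for thousands of haplotypes, and copying
becomes effectively local. Constructed small fixtures therefore use tight
genetic maps; the parameters are not estimated from data here.

At an off-scaffold target position, donor weights are obtained by linear
interpolation of the two flanking markers' γ vectors in genetic distance
(nearest marker outside the span; equal-cM flanks averaged), renormalized
over the stored donors.

## Iterative refinement

For the target variant, each individual contributes a genotype-likelihood
triple (L0, L1, L2) ∝ P(reads | g copies of the alternative allele); only
ratios matter and the triple is stored normalized. Per haplotype, θ_h is the
probability that h carries the alternative allele, initialized as
θ_h = (L2 + L1/2)/(L0 + L1 + L2) for both haplotypes of the individual.
Each sweep:

1. τ_h = Σ_l γ_{h,l} θ_l over the donor set — the sharing prediction;
2. for each individual with haplotypes (h, k), un-normalized phased genotype
   probabilities P00 = (1−τ_h)(1−τ_k)L0, P10 = τ_h(1−τ_k)·L1/2,
   P01 = (1−τ_h)τ_k·L1/2, P11 = τ_h·τ_k·L2;
3. θ_h ← (P10+P11)/ΣP and θ_k ← (P01+P11)/ΣP.

Sweeps repeat until max_h |θ_h' − θ_h| < ε (default 1e−7) or `max_iter`
(default 1000, non-convergence flagged, not raised). The default schedule is
synchronous — every τ in a sweep is computed from the previous sweep's θ —
so results are invariant to individual ordering; a sequential mode is kept
behind a flag. The donor set for h excludes h itself, exactly as the update
equations state; the individual's other haplotype k is a donor by default,
which lets a confident heterozygote inform its own phasing. A switch
(`exclude_self_individual`) removes both haplotypes of the individual and
renormalizes, for users who prefer strict leave-one-individual-out
prediction; if exclusion empties a donor set, τ falls back to the population
mean of θ and the result is flagged.

Outputs per variant: converged θ, phased posteriors (P00, P01, P10, P11) per
individual, hard calls (argmax; an exact P01 = P10 tie yields an unphased
heterozygote rather than an arbitrary phase), the allele-frequency estimate
(mean θ over haplotypes), and an info score. An individual with no reads
whose posterior stays below 0.5 everywhere is emitted as uncalled (`./.`);
with sharing information the same individual can still receive a confident
imputed call.

### Info score

The study design this package follows uses an "information" statistic with
bounds such as < 0.6 and > 1.4 but no printed formula. We use the IMPUTE-style
measure, consistent with the copying model itself:

SI = 1 − mean_i Var_i(g) / (2f(1−f)),

with Var_i the posterior genotype variance of individual i and f the
estimated frequency. SI is 1 for monomorphic f by convention, clipped below
at 0, and can exceed 1 when the posterior variance exceeds the binomial
expectation — which is what makes an upper filter bound like 1.4 meaningful.
This is a documented stand-in: the filter bounds are honored syntactically
but are not guaranteed to match the original statistic numerically.

## Site filtering

Hard thresholds on GATK-style call annotations, strict inequalities exactly
as configured: SNPs fail on QD < 2.0, MQ < 40.0, FS > 60.0,
HaplotypeScore > 13.0, MQRankSum < −12.5, ReadPosRankSum < −8.0; indels on
QD < 2.0, FS > 200.0, ReadPosRankSum < −20.0; both on DP > 110000, AN < 4200,
HW < 1e−7, SI > 1.4, and SI < 0.6 (SNPs) / SI < 0.9 (indels). Boundary values
pass; a missing annotation can never fail its rule; rules are independent so
the verdict is order-insensitive. The DP/AN bounds are cohort-scale numbers
(AN = 2n = 5272 for a fully called 2,636-diploid cohort) exposed as plain
config values for other cohorts.

The Hardy-Weinberg P is the exact conditional test: given the allele counts,
the probability of every heterozygote-count configuration is computed
(log-gamma form) and those no more probable than the observed one are summed
(two-sided). An exact test was chosen over the chi-square approximation
because the filter compares P-values down to 1e−7, far into the tail where
the asymptotic test is unreliable; the implementation is verified against
full exact-fraction enumeration for all configurations of up to 20
individuals.

Simple-repeat masking unions a tandem-repeat interval track with homopolymer
runs of ≥ 6 bp (N runs excluded); a variant is masked if any base of its
reference span POS..POS+len(ref)−1 intersects the mask. Indel left-alignment
is assumed done upstream.

## Polarization

SNPs: compare the ancestor base at the position with ref and alt; equality
decides ancestral state, anything else (including N) is undetermined. Both
FASTA cases are accepted by default, since lowercase encodes low confidence
rather than absence in Ensembl-style ancestor sequences.

Indels: the aligned human/ancestor window spans 5 bp either side of the indel
plus the indel length. Mismatches are counted over flanking columns only,
never the indel columns. If the two windows carry equal base counts and ≤ 1
flanking mismatch, the reference allele is ancestral; if the base-count
difference equals the indel length in the direction the indel implies and
≤ 1 flanking mismatch — insertions additionally requiring the ancestor's
inserted bases to equal the insert exactly — the alternative allele is
ancestral; every other case (including any extra gap column in the flanks,
or a length difference that matches neither branch) is undetermined. Windows
shorter than the required span warn and return undetermined. DAF is the alt
frequency when the reference is ancestral, its complement when the
alternative is, and undefined otherwise; undetermined sites are excluded
from DAF-stratified tallies.

## Impact classes and Ts/Tv

Consequence terms (snake_case VEP/SO vocabulary) map to four ordered classes:
LoF (stop gained/lost, frameshift, splice acceptor/donor, initiator codon),
MODERATE (missense, inframe indels, splice region), LOW (synonymous, stop
retained, 3′/5′ UTR), OTHER (intronic, intergenic, up/downstream). A variant
takes the most severe class across its transcripts; unrecognized terms fall
to OTHER with a once-per-term warning; a variant touching no transcript is
intergenic, hence OTHER. Initiator-codon variants are grouped with LoF
deliberately, although VEP ranks them below stop_gained. Transitions are
A↔G and C↔T; the Ts/Tv ratio is transitions/transversions per stratum, with
zero transversions reported as infinite alongside both counts (stop-retained
changes are obligate transitions, verified by enumerating all single-base
substitutions among TAA/TAG/TGA).

## Simulator

The generator produces exactly the structure the refiner assumes: founder
haplotypes with iid Bernoulli(1/2) alleles; sample haplotypes as founder
mosaics with switch probability 1 − e^(−rate·d) per inter-marker interval
(exponential segment lengths in genetic distance); a target variant planted
on a greedily chosen set of founder lineages so that carriers are perfectly
tagged by local haplotype background and the realized frequency approaches
the requested MAF (reported exactly); and sequencing likelihoods from
Poisson(depth) read counts with Binomial alt counts at success probability
ε, 1/2, 1−ε for genotypes 0/1/2. Defaults — 200 diploids, 100 markers at
0.05 cM spacing, 20 founders, switch rate 1/cM, MAF 0.05, depth 20×,
error 0.01 — give clear sharing signal in seconds-scale runs.

What it does not emulate: mapping or alignment artifacts, indel realignment,
depth heterogeneity along the genome, linkage beyond the mosaic process,
population structure or relatedness beyond founder sharing, and GATK
annotation values computed from reads (fixture annotations are set
directly). Passing the recovery tests therefore shows the algorithm is
implemented correctly under its own model assumptions, not that it attains
any particular accuracy on real data. A misspecified mode (iid random
haplotypes, no copying structure) is provided to show the refinement
degrading gracefully toward likelihood-only calls.

Every stochastic operation is keyed by an explicit seed or generator;
identical seeds give identical outputs.

## Numerical and design choices

- Likelihood triples are accepted as PL (phred integer) or GL (log10) and
  normalized to linear scale summing to one; downstream results are invariant
  to likelihood rescaling.
- Multi-allelic records are skipped and counted, not decomposed; indels
  longer than 60 bp are excluded from the refinement set.
- Coordinates: 1-based in VCF-facing code, 0-based half-open intervals
  (BED convention) internally.
- Catalogue overlap matches after shared-suffix/prefix trimming of indel
  alleles, since indel placement is ambiguous across callers.
- The exhaustive-path HMM reference and the exact-fraction Hardy-Weinberg
  enumeration exist purely as independent cross-checks; they are never used
  on problem sizes beyond toy pools.
- Problem sizes in the recovery checks (200 diploids, 100 markers, 20
  simulation seeds, depths 2× and 20×) were chosen as the smallest cohort
  at which the sharing signal is unambiguous while a full run stays within
  tens of seconds.

## Known limitations

- Autosomal diploid cohorts only; no chrX/chrY or haploid handling.
- λ and N_e are consumed, not estimated.
- Variants are refined one at a time; no joint multi-variant phasing and no
  trio awareness.
- The SI formula is a stand-in (above), so SI-based filter outcomes on real
  data may differ from the original pipeline's.
- The toy ancestral-window exchange format stands in for genuine multiple-
  alignment extracts; no EMF/MAF archive parsing.
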