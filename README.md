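# haplorefine

Haplotype-sharing genotype refinement and variant processing for sequenced,
chip-phased diploid cohorts.

## What it does

Sequencing-only genotype calls err at a rate set by depth: one alternative
read out of eight at a true heterozygous site looks homozygous reference to a
maximum-likelihood caller. When every sequenced individual is also
chip-genotyped and long-range phased, haplotype sharing resolves such calls.
`haplorefine` implements the full chain:

- **Copying HMM** (`haplorefine.hmm`): per haplotype *h*, forward–backward
  posteriors γ<sub>h,k,i</sub> = P(*h* copies donor *k* at marker *i* | all
  scaffold markers) under the Li & Stephens model, with emission 1−λ / λ on
  allele match/mismatch and transitions driven by ρ<sub>i</sub> = 4N<sub>e</sub>r<sub>i</sub>
  over the genetic map (defaults λ = 10⁻⁷, N<sub>e</sub> = 7000, sparsified at
  10⁻⁶ of the per-marker maximum).
- **Iterative refinement** (`haplorefine.refine`): per-haplotype
  alternative-allele probabilities θ<sub>h</sub>, initialized from genotype
  likelihoods as (L₂ + ½L₁)/(L₀+L₁+L₂), are repeatedly fused with the sharing
  predictions τ<sub>h</sub> = Σ<sub>l</sub> γ<sub>h,l</sub>θ<sub>l</sub> through the
  phased genotype update P₀₀ = (1−τ_h)(1−τ_k)L₀, P₁₀ = τ_h(1−τ_k)·½L₁,
  P₀₁ = (1−τ_h)τ_k·½L₁, P₁₁ = τ_hτ_kL₂ until max |Δθ| < ε = 10⁻⁷, yielding
  phased genotype posteriors, hard calls and an info score.
- **Site filtering** (`haplorefine.filters`): GATK-style hard thresholds
  (SNP: QD<2, MQ<40, FS>60, HaplotypeScore>13, MQRankSum<−12.5,
  ReadPosRankSum<−8; indel: QD<2, FS>200, ReadPosRankSum<−20; both:
  DP>110000, AN<4200, exact Hardy-Weinberg P<10⁻⁷, SI>1.4, SI<0.6/0.9),
  plus simple-repeat masking (tandem-repeat track ∪ homopolymers ≥ 6 bp).
- **Polarization** (`haplorefine.polarize`): ancestral/derived assignment for
  SNPs (ancestor-base comparison) and indels (aligned ancestor windows, ≤ 1
  flanking mismatch rules) and derived allele frequency.
- **Annotation** (`haplorefine.annotate`): SO consequence terms → ordered
  impact classes LoF > MODERATE > LOW > OTHER, most-severe-per-variant, and
  stratified Ts/Tv ratios.
- **Metrics** (`haplorefine.metrics`): dosage r², hard-call concordance,
  catalogue overlap by DAF bin, indel length spectra.
- **Simulator** (`haplorefine.simulate`): founder-mosaic haplotype pools,
  perfectly tagged target variants, Poisson/Binomial read likelihoods, and
  deterministic toy fixtures — every module is testable with no downloads.

The refiner is a scikit-learn-style estimator: `fit` learns the copying
posteriors of a scaffold, `refine` turns likelihoods into posteriors, and
`get_params`/`set_params` compose with sklearn tooling.

## Worked example

```python
import numpy as np
from haplorefine import GeneticMap, GenotypeLikelihoods, ScaffoldHaplotypes
from haplorefine.refine import HaplotypeSharingRefiner, likelihood_only_posteriors
from haplorefine.simulate import likelihoods_from_read_counts

# four diploids over six phased scaffold markers; the proband's first
# haplotype background (A) is shared with a confident heterozygote
A = [1, 1, 0, 0, 1, 1]; B = [0, 0, 0, 0, 0, 0]
C = [0, 1, 0, 1, 0, 1]; D = [1, 0, 1, 0, 1, 0]; E = [1, 1, 1, 1, 1, 1]
scaffold = ScaffoldHaplotypes(np.array([A, C, A, B, B, D, C, E]),
                              ["proband", "het", "ref1", "ref2"])
gmap = GeneticMap([1000, 2000, 3000, 4000, 5000, 6000], np.arange(6) * 0.001)

ambiguous = likelihoods_from_read_counts(n_reads=8, n_alt=1, error_rate=0.01)
lik = GenotypeLikelihoods(np.array([
    ambiguous.values[0],          # 1 alt read of 8: ML call is hom-ref
    [1e-8, 1.0, 1e-8],            # confident heterozygote
    [1.0, 1e-8, 1e-16],           # confident hom-ref
    [1.0, 1e-8, 1e-16],
]))

res = HaplotypeSharingRefiner().fit(scaffold, gmap).refine(3500, lik)
print("likelihood-only P(het):", round(likelihood_only_posteriors(lik)[0, 1], 4))
print("refined P(het):       ", round(res.posteriors[0, 1] + res.posteriors[0, 2], 4))
print("hard calls:           ", res.genotype_strings())
```

Output:

```
likelihood-only P(het): 0.2953
refined P(het):        0.9967
hard calls:            ['1|0', '1|0', '0|0', '0|0']
```

On the reads alone the proband would be called `0|0` (P(het) ≈ 0.30); after
refinement the shared background with the confident heterozygote lifts its
heterozygote posterior to ≈ 0.997, phased onto the shared haplotype (`1|0`).

A `haplorefine` CLI wraps the same library: `simulate`, `refine`, `filter`,
`polarize`, `annotate`, `metrics` (see `haplorefine --help`).

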