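"""Haplotype-copying hidden Markov model over a phased scaffold.

Each proband haplotype h is modelled as an imperfect mosaic of the other
haplotypes in the pool (the Li & Stephens copying model used by IMPUTE-style
imputation).  The latent state z_i at scaffold marker i is the donor haplotype
h copies from; the forward-backward posteriors

    gamma[h, k, i] = P(z_i = k | all scaffold markers)

quantify haplotype sharing and drive genotype refinement at off-scaffold
variants.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from haplorefine.io import GeneticMap, ScaffoldHaplotypes


def emission_prob(proband_allele: int, donor_allele: int, mismatch_penalty: float) -> float:
    """P(scaffold observation | copying donor): 1 - lambda on match, lambda on mismatch."""
    if not 0.0 < mismatch_penalty < 0.5:
        raise ValueError("mismatch penalty must lie in (0, 0.5)")
    if proband_allele not in (0, 1) or donor_allele not in (0, 1):
        raise ValueError("alleles must be 0 or 1")
    return 1.0 - mismatch_penalty if proband_allele == donor_allele else mismatch_penalty


def transition_matrix_row(
    r: float, n_effective: float, n_donors: int
) -> tuple[float, float]:
    """Copying-state transition probabilities across one inter-marker interval.

    With rho = 4 * Ne * r (r in Morgans) and N donor haplotypes:

        P(stay)            = exp(-rho/N) + (1 - exp(-rho/N)) / N
        P(switch to donor) = (1 - exp(-rho/N)) / N   per specific other donor

    so that stay + (N-1) * switch = 1.
    """
    if r < 0:
        raise ValueError("recombination distance must be non-negative")
    if n_donors < 1:
        raise ValueError("need at least one donor haplotype")
    rho = 4.0 * n_effective * r
    q = np.exp(-rho / n_donors)
    switch = (1.0 - q) / n_donors
    return q + switch, switch


@dataclass
class CopyingPosteriors:
    """Sparse forward-backward posteriors for one proband haplotype.

    For each marker i, ``donor_indices[i]`` holds global haplotype indices and
    ``weights[i]`` the corresponding gamma values; entries below
    ``threshold * max`` at that marker were dropped, so per-marker sums are
    <= 1 but >= 1 - (dropped mass).
    """

    haplotype: int
    donor_indices: list[np.ndarray]
    weights: list[np.ndarray]
    n_markers: int

    def dense(self, n_haplotypes: int) -> np.ndarray:
        """(n_markers, n_haplotypes) dense gamma matrix (zeros where dropped)."""
        out = np.zeros((self.n_markers, n_haplotypes))
        for i, (idx, w) in enumerate(zip(self.donor_indices, self.weights)):
            out[i, idx] = w
        return out

    def at_marker(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        return self.donor_indices[i], self.weights[i]


class HaplotypeCopyingHMM(BaseEstimator):
    """Copying-model forward-backward over a phased scaffold.

    Parameters
    ----------
    mismatch_penalty : float, default 1e-7
        Emission penalty lambda for a proband/donor allele mismatch.
    n_effective : float, default 7000
        Effective number of haplotypes Ne entering rho_i = 4 * Ne * r_i.
    sparsify_threshold : float, default 1e-6
        After forward-backward, gamma entries below this fraction of the
        per-marker maximum are dropped (ties at the cutoff are retained).

    Attributes
    ----------
    scaffold_ : ScaffoldHaplotypes
    genetic_map_ : GeneticMap
    recomb_distances_ : ndarray of inter-marker distances in Morgans
    """

    def __init__(
        self,
        mismatch_penalty: float = 1e-7,
        n_effective: float = 7000.0,
        sparsify_threshold: float = 1e-6,
    ):
        self.mismatch_penalty = mismatch_penalty
        self.n_effective = n_effective
        self.sparsify_threshold = sparsify_threshold

    def fit(self, scaffold: ScaffoldHaplotypes, genetic_map: GeneticMap):
        if not 0.0 < self.mismatch_penalty < 0.5:
            raise ValueError("mismatch_penalty must lie in (0, 0.5)")
        if self.n_effective <= 0:
            raise ValueError("n_effective must be positive")
        if not 0.0 <= self.sparsify_threshold < 1.0:
            raise ValueError("sparsify_threshold must lie in [0, 1)")
        if len(genetic_map) != scaffold.n_markers:
            raise ValueError(
                f"genetic map has {len(genetic_map)} markers but scaffold has "
                f"{scaffold.n_markers}"
            )
        if scaffold.n_haplotypes < 2:
            raise ValueError("pool must contain at least 2 haplotypes")
        self.scaffold_ = scaffold
        self.genetic_map_ = genetic_map
        self.recomb_distances_ = genetic_map.recomb_distances()
        return self

    def _gamma_dense(self, h: int) -> tuple[np.ndarray, np.ndarray]:
        """Forward-backward posteriors for haplotype h against donors H\\{h}.

        Returns (donor_global_indices, gamma) with gamma of shape
        (n_markers, n_donors), rows summing to 1.  Per-marker rescaling keeps
        the recursion in range; posteriors are invariant to the rescaling.
        """
        alleles = self.scaffold_.alleles
        n_hap, n_markers = alleles.shape
        donors = np.delete(np.arange(n_hap), h)
        n = donors.size
        if n == 0:
            raise ValueError("empty donor set")
        lam = self.mismatch_penalty
        match = alleles[donors] == alleles[h]  # (n, M)
        emis = np.where(match, 1.0 - lam, lam)
        q = np.exp(-4.0 * self.n_effective * self.recomb_distances_ / n)

        fwd = np.empty((n_markers, n))
        f = emis[:, 0] / n  # uniform initialization over donors
        f /= f.sum()
        fwd[0] = f
        for i in range(1, n_markers):
            f = emis[:, i] * (q[i - 1] * f + (1.0 - q[i - 1]) / n)
            f /= f.sum()
            fwd[i] = f

        bwd = np.empty((n_markers, n))
        b = np.ones(n)
        bwd[-1] = b
        for i in range(n_markers - 2, -1, -1):
            eb = emis[:, i + 1] * b
            b = q[i] * eb + (1.0 - q[i]) / n * eb.sum()
            b /= b.sum()
            bwd[i] = b

        gamma = fwd * bwd
        gamma /= gamma.sum(axis=1, keepdims=True)
        return donors, gamma

    def copying_posteriors(self, h: int) -> CopyingPosteriors:
        """Sparse copying posteriors for proband haplotype ``h``."""
        if not hasattr(self, "scaffold_"):
            raise RuntimeError("fit the model before requesting posteriors")
        if not 0 <= h < self.scaffold_.n_haplotypes:
            raise ValueError(f"haplotype {h} not in pool")
        donors, gamma = self._gamma_dense(h)
        idx_out: list[np.ndarray] = []
        w_out: list[np.ndarray] = []
        for i in range(gamma.shape[0]):
            row = gamma[i]
            keep = row >= self.sparsify_threshold * row.max()
            idx_out.append(donors[keep])
            w_out.append(row[keep])
        return CopyingPosteriors(h, idx_out, w_out, gamma.shape[0])


def interpolate_gamma(
    posteriors: CopyingPosteriors, position: int, genetic_map: GeneticMap
) -> tuple[np.ndarray, np.ndarray]:
    """Donor weights at an off-scaffold target position.

    Linear interpolation in genetic distance between the two flanking markers'
    gamma vectors; outside the scaffold span the nearest marker's gamma is
    used.  Weights are renormalized to sum to 1 over the stored donors.
    """
    if posteriors.n_markers == 0:
        raise ValueError("empty posteriors")
    pos = genetic_map.positions
    if position <= pos[0]:
        idx, w = posteriors.at_marker(0)
        return idx, w / w.sum()
    if position >= pos[-1]:
        idx, w = posteriors.at_marker(posteriors.n_markers - 1)
        return idx, w / w.sum()
    right = int(np.searchsorted(pos, position, side="left"))
    if pos[right] == position:
        idx, w = posteriors.at_marker(right)
        return idx, w / w.sum()
    left = right - 1
    cm_l, cm_r = genetic_map.cm[left], genetic_map.cm[right]
    if cm_r > cm_l:
        t = (genetic_map.cm_at(position) - cm_l) / (cm_r - cm_l)
    else:
        t = 0.5  # zero genetic distance: average the flanks
    li, lw = posteriors.at_marker(left)
    ri, rw = posteriors.at_marker(right)
    union = np.union1d(li, ri)
    combined = np.zeros(union.size)
    combined[np.searchsorted(union, li)] += (1.0 - t) * lw
    combined[np.searchsorted(union, ri)] += t * rw
    return union, combined / combined.sum()


def brute_force_posteriors(
    h: int,
    scaffold: ScaffoldHaplotypes,
    genetic_map: GeneticMap,
    mismatch_penalty: float,
    n_effective: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustive-path reference for the copying posteriors.

    Sums emission x transition products over every donor path explicitly —
    O(N^M) — so it is usable only on tiny pools, as an independent check of
    the forward-backward recursion.
    """
    alleles = scaffold.alleles
    donors = np.delete(np.arange(scaffold.n_haplotypes), h)
    n = donors.size
    n_markers = scaffold.n_markers
    r = genetic_map.recomb_distances()
    stay_switch = [transition_matrix_row(ri, n_effective, n) for ri in r]
    mass = np.zeros((n_markers, n))
    for path in itertools.product(range(n), repeat=n_markers):
        p = 1.0 / n
        for i, d in enumerate(path):
            if i > 0:
                stay, switch = stay_switch[i - 1]
                p *= stay if d == path[i - 1] else switch
            p *= emission_prob(
                int(alleles[h, i]), int(alleles[donors[d], i]), mismatch_penalty
            )
        for i, d in enumerate(path):
            mass[i, d] += p
    mass /= mass.sum(axis=1, keepdims=True)
    return donors, mass
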