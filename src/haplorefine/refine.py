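"""Iterative haplotype-sharing genotype refinement.

Sequencing genotype likelihoods alone miscall ambiguous sites (e.g. one
alternative read out of eight looks homozygous reference).  Refinement fuses
each individual's likelihood triple with a prediction from haplotype sharing:
theta_h, the probability that haplotype h carries the alternative allele, is
initialized from the likelihoods and then iteratively updated through the
copying posteriors of the scaffold HMM until convergence, yielding phased
genotype posteriors per individual.

Phased-posterior column order throughout is (P00, P01, P10, P11), where the
first index is the individual's first haplotype h and P10 means h carries the
alternative allele.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from haplorefine.io import GeneticMap, GenotypeLikelihoods, ScaffoldHaplotypes
from haplorefine.hmm import CopyingPosteriors, HaplotypeCopyingHMM, interpolate_gamma

#: hard-call codes -> VCF genotype strings
GT_STRINGS = {0: "0|0", 1: "0|1", 2: "1|0", 3: "1|1", 4: "0/1", -1: "./."}


def init_theta(likelihoods: GenotypeLikelihoods) -> np.ndarray:
    """Initial per-haplotype alternative-allele probability.

    theta = (L2 + L1/2) / (L0 + L1 + L2), assigned to both haplotypes of each
    individual, so the vector has length 2n.
    """
    lik = likelihoods.values
    theta_ind = (lik[:, 2] + 0.5 * lik[:, 1]) / lik.sum(axis=1)
    return np.repeat(theta_ind, 2)


def predict_tau(
    donor_indices: np.ndarray,
    donor_weights: np.ndarray,
    theta: np.ndarray,
    exclude: tuple[int, ...] = (),
) -> tuple[float, bool]:
    """Haplotype-sharing prediction tau = sum_l gamma_l * theta_l over donors.

    ``exclude`` removes haplotypes from the donor set (weights renormalized).
    If no donors remain, tau falls back to the population mean of theta and the
    second return value flags the fallback.
    """
    if exclude:
        keep = ~np.isin(donor_indices, exclude)
        donor_indices = donor_indices[keep]
        donor_weights = donor_weights[keep]
    total = donor_weights.sum()
    if donor_indices.size == 0 or total <= 0:
        return float(theta.mean()), True
    return float(donor_weights @ theta[donor_indices] / total), False


def update_pair(
    tau_h: float, tau_k: float, l0: float, l1: float, l2: float
) -> tuple[np.ndarray, float, float]:
    """Fuse sharing predictions with likelihoods for one individual.

    Un-normalized phased genotype probabilities:

        P00 = (1-tau_h)(1-tau_k) L0        P10 = tau_h (1-tau_k) L1/2
        P01 = (1-tau_h) tau_k  L1/2        P11 = tau_h tau_k L2

    Returns the normalized quadruple (P00, P01, P10, P11) and the updated
    theta pair (theta_h' = P10+P11, theta_k' = P01+P11 after normalization).
    """
    p = np.array([
        (1.0 - tau_h) * (1.0 - tau_k) * l0,
        (1.0 - tau_h) * tau_k * 0.5 * l1,
        tau_h * (1.0 - tau_k) * 0.5 * l1,
        tau_h * tau_k * l2,
    ])
    total = p.sum()
    if total <= 0:
        raise ValueError(
            "contradictory sharing predictions and likelihoods (all phased "
            "genotype probabilities zero)"
        )
    p /= total
    return p, p[2] + p[3], p[1] + p[3]


def info_score(posteriors: np.ndarray, frequency: float) -> float:
    """IMPUTE-style imputation info measure.

    1 - (mean posterior genotype variance) / (2 f (1-f)); 1 at monomorphic
    frequency by convention, clipped below at 0, and allowed to exceed 1 when
    the observed posterior variance exceeds the binomial expectation.
    """
    if not 0.0 < frequency < 1.0:
        return 1.0
    post = np.asarray(posteriors, dtype=float)
    dose = post[:, 1] + post[:, 2] + 2.0 * post[:, 3]
    second = post[:, 1] + post[:, 2] + 4.0 * post[:, 3]
    mean_var = float(np.mean(second - dose**2))
    return max(0.0, 1.0 - mean_var / (2.0 * frequency * (1.0 - frequency)))


@dataclass
class RefinedVariant:
    """Converged refinement output for one target variant."""

    theta: np.ndarray  # (2n,) per-haplotype alt-allele probability
    posteriors: np.ndarray  # (n, 4) phased genotype posteriors P00,P01,P10,P11
    hard_calls: np.ndarray  # (n,) codes into GT_STRINGS
    frequency: float  # mean of theta over haplotypes
    info: float  # imputation info score
    n_iter: int
    converged: bool
    tau_fallback: bool = False  # some haplotype had no donors after exclusion
    no_data: np.ndarray | None = None  # (n,) True where likelihoods were uniform

    @property
    def dosages(self) -> np.ndarray:
        """Posterior expected alternative-allele count per individual."""
        p = self.posteriors
        return p[:, 1] + p[:, 2] + 2.0 * p[:, 3]

    def genotype_strings(self) -> list[str]:
        return [GT_STRINGS[int(c)] for c in self.hard_calls]


def _hard_call(p: np.ndarray, no_data: bool) -> int:
    best = int(np.argmax(p))
    if p[1] == p[2] and p[1] >= p[0] and p[1] >= p[3]:
        best = 4  # exactly tied het orientations: emit unphased het
    if no_data and p.max() < 0.5:
        return -1  # no reads and sharing resolves nothing: uncalled
    return best


def refine_variant(
    likelihoods: GenotypeLikelihoods,
    donor_weights: list[tuple[np.ndarray, np.ndarray]],
    epsilon: float = 1e-7,
    max_iter: int = 1000,
    exclude_self_individual: bool = False,
    schedule: str = "synchronous",
) -> RefinedVariant:
    """Run the iterative theta-update algorithm for one variant.

    ``donor_weights[h]`` is the (donor indices, weights) pair for haplotype h,
    normally obtained by interpolating its copying posteriors at the variant
    position.  Iterates tau-prediction and pairwise likelihood fusion until
    max |theta' - theta| < ``epsilon`` or ``max_iter`` sweeps.

    The synchronous schedule computes every tau from the previous sweep's
    theta, making the result independent of individual ordering; the
    sequential schedule updates theta in place.
    """
    if schedule not in ("synchronous", "sequential"):
        raise ValueError(f"unknown update schedule {schedule!r}")
    n = len(likelihoods)
    if len(donor_weights) != 2 * n:
        raise ValueError(
            f"need donor weights for {2 * n} haplotypes, got {len(donor_weights)}"
        )
    lik = likelihoods.values
    no_data = np.isclose(lik, lik[:, :1]).all(axis=1)
    theta = init_theta(likelihoods)
    posteriors = np.zeros((n, 4))
    tau_fallback = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        theta_prev = theta.copy()
        for j in range(n):
            h, k = 2 * j, 2 * j + 1
            exclude = (k, h) if exclude_self_individual else ()
            # synchronous: every tau from the previous sweep's theta;
            # sequential: from the continuously updated theta
            src = theta_prev if schedule == "synchronous" else theta
            tau_h, fb_h = predict_tau(*donor_weights[h], src, exclude)
            tau_k, fb_k = predict_tau(*donor_weights[k], src, exclude)
            tau_fallback |= fb_h or fb_k
            try:
                p, th, tk = update_pair(tau_h, tau_k, *lik[j])
            except ValueError as exc:
                raise ValueError(f"individual {j}: {exc}") from exc
            posteriors[j] = p
            theta[h], theta[k] = th, tk
        delta = float(np.max(np.abs(theta - theta_prev)))
        if delta < epsilon:
            converged = True
            break
    frequency = float(theta.mean())
    hard = np.array([_hard_call(posteriors[j], bool(no_data[j])) for j in range(n)])
    return RefinedVariant(
        theta=theta,
        posteriors=posteriors,
        hard_calls=hard,
        frequency=frequency,
        info=info_score(posteriors, frequency),
        n_iter=it,
        converged=converged,
        tau_fallback=tau_fallback,
        no_data=no_data,
    )


def likelihood_only_posteriors(likelihoods: GenotypeLikelihoods) -> np.ndarray:
    """Flat-prior genotype posteriors (n, 3) from the likelihoods alone."""
    lik = likelihoods.values
    return lik / lik.sum(axis=1, keepdims=True)


def likelihood_only_calls(likelihoods: GenotypeLikelihoods) -> np.ndarray:
    """Maximum-likelihood genotype (0/1/2) per individual, ignoring sharing."""
    return np.argmax(likelihoods.values, axis=1)


def likelihood_only_dosage(likelihoods: GenotypeLikelihoods) -> np.ndarray:
    post = likelihood_only_posteriors(likelihoods)
    return post[:, 1] + 2.0 * post[:, 2]


class HaplotypeSharingRefiner(BaseEstimator):
    """Genotype refinement estimator over a phased scaffold.

    ``fit`` learns the copying posteriors of every haplotype in the scaffold
    pool; ``refine`` then turns a target variant's genotype likelihoods into
    phased genotype posteriors.  Composes with sklearn via get_params /
    set_params / clone.

    Parameters
    ----------
    mismatch_penalty, n_effective, sparsify_threshold
        Copying-HMM parameters (see :class:`HaplotypeCopyingHMM`).
    epsilon : float, default 1e-7
        Convergence threshold on max |theta' - theta| between sweeps.
    max_iter : int, default 1000
        Sweep budget; non-convergence is flagged, not raised.
    exclude_self_individual : bool, default False
        The donor pool for haplotype h always excludes h itself; with this
        flag the individual's other haplotype is excluded too.
    schedule : {"synchronous", "sequential"}

    Attributes
    ----------
    hmm_ : fitted HaplotypeCopyingHMM
    copying_posteriors_ : list of CopyingPosteriors, one per haplotype
    n_haplotypes_ : int
    """

    def __init__(
        self,
        mismatch_penalty: float = 1e-7,
        n_effective: float = 7000.0,
        sparsify_threshold: float = 1e-6,
        epsilon: float = 1e-7,
        max_iter: int = 1000,
        exclude_self_individual: bool = False,
        schedule: str = "synchronous",
    ):
        self.mismatch_penalty = mismatch_penalty
        self.n_effective = n_effective
        self.sparsify_threshold = sparsify_threshold
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.exclude_self_individual = exclude_self_individual
        self.schedule = schedule

    def fit(self, scaffold: ScaffoldHaplotypes, genetic_map: GeneticMap):
        self.hmm_ = HaplotypeCopyingHMM(
            mismatch_penalty=self.mismatch_penalty,
            n_effective=self.n_effective,
            sparsify_threshold=self.sparsify_threshold,
        ).fit(scaffold, genetic_map)
        self.copying_posteriors_ = [
            self.hmm_.copying_posteriors(h) for h in range(scaffold.n_haplotypes)
        ]
        self.n_haplotypes_ = scaffold.n_haplotypes
        return self

    def donor_weights_at(self, position: int) -> list[tuple[np.ndarray, np.ndarray]]:
        """Interpolated donor weights for every haplotype at a bp position."""
        if not hasattr(self, "copying_posteriors_"):
            raise RuntimeError("fit the refiner before refining variants")
        gmap = self.hmm_.genetic_map_
        return [interpolate_gamma(cp, position, gmap) for cp in self.copying_posteriors_]

    def refine(self, position: int, likelihoods: GenotypeLikelihoods) -> RefinedVariant:
        """Refine one variant at ``position`` given cohort genotype likelihoods."""
        return refine_variant(
            likelihoods,
            self.donor_weights_at(position),
            epsilon=self.epsilon,
            max_iter=self.max_iter,
            exclude_self_individual=self.exclude_self_individual,
            schedule=self.schedule,
        )

    def refine_sites(
        self, positions: list[int], likelihoods: list[GenotypeLikelihoods]
    ) -> list[RefinedVariant]:
        if len(positions) != len(likelihoods):
            raise ValueError("positions and likelihoods must be parallel")
        return [self.refine(p, l) for p, l in zip(positions, likelihoods)]
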