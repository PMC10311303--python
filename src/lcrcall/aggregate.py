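"""Aggregate (pooled polyploid) genotype likelihoods and posteriors.

At a candidate site the reads of all repeat copies are pooled, so the
sample behaves like a polyploid of ploidy ``agcn`` (the aggregate copy
number).  The allelic depth vector ``X`` over the allele set ``A`` is
modelled as multinomial:

    P(X | g) = MN(X; p(a_1, g), ..., p(a_|A|, g))

with per-allele category weights

    p(a, g) ∝ (|r| - |a| - 1) * max(eps * agcn, mu(a, g))

where ``|r|`` is the mean read length, ``|a|`` the allele length,
``mu(a, g)`` the multiplicity of allele ``a`` in the aggregate genotype
``g`` and ``eps`` the per-base error rate.  The ``eps * agcn`` floor keeps
every weight positive so that sequencing errors do not zero out a
genotype's likelihood; the length factor down-weights long alleles, which
fewer read placements can span completely.  Posteriors use a uniform
prior over the enumerated genotype space.

Likelihoods are evaluated in log space (depths beyond ~100 underflow the
linear-scale pmf).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .model import (
    AggregateGenotype,
    canonical_genotype,
    enumerate_aggregate_genotypes,
    multiplicity,
    sort_alleles,
)

__all__ = [
    "GenotypingParams",
    "allele_weight",
    "allele_weights",
    "aggregate_log_likelihood",
    "aggregate_posterior",
    "AggregateGenotypePosterior",
]


@dataclass(frozen=True)
class GenotypingParams:
    """Tunable parameters of the caller's probabilistic model.

    epsilon
        Per-base error rate used throughout (multinomial floor, read-pair
        location model, conflict test); default 0.01.
    mean_read_len
        Mean aligned read length ``|r|`` of the pooled pileup.
    xi
        Prior mutation rate penalising non-reference copies at novel
        (non-PSV) variants; default 1e-3.
    informative_threshold
        Minimum posterior of a reference-compatible paralog genotype for a
        PSV to be called informative; default 0.99.
    conflict_pvalue
        One-tailed binomial p-value threshold for conflicting PSV pairs;
        default 1e-3.
    fet_pvalue
        Two-sided Fisher's-exact strand-bias threshold; default 0.01.
    min_base_quality
        Allele observations below this base quality are discarded
        (default 10).
    min_candidate_qual
        Candidate variants with quality below this are dropped after
        discovery (default 1).
    output_qual_threshold
        Recommended variant-quality threshold for the final call set
        (default 21).
    agg_posterior_floor
        Aggregate genotypes with posterior below this are excluded from
        the paralog-genotype sum in the final genotyping step.
    """

    epsilon: float = 0.01
    mean_read_len: float = 150.0
    xi: float = 1e-3
    informative_threshold: float = 0.99
    conflict_pvalue: float = 1e-3
    fet_pvalue: float = 0.01
    min_base_quality: int = 10
    min_candidate_qual: float = 1.0
    output_qual_threshold: float = 21.0
    agg_posterior_floor: float = 1e-6

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if not 0.0 <= self.xi < 1.0:
            raise ValueError("xi must be in [0, 1)")


def allele_weights(
    genotype: AggregateGenotype,
    alleles: list[str],
    mean_read_len: float,
    epsilon: float,
    agcn: int,
) -> np.ndarray:
    """Multinomial category weights p(a, g) over ``alleles`` for one genotype."""
    raw = np.empty(len(alleles))
    for k, a in enumerate(alleles):
        length_factor = mean_read_len - len(a) - 1
        if length_factor <= 0:
            raise ValueError(
                f"mean read length {mean_read_len} too short for allele {a!r}"
            )
        raw[k] = length_factor * max(epsilon * agcn, multiplicity(a, genotype))
    return raw / raw.sum()


def allele_weight(
    allele: str,
    genotype: AggregateGenotype,
    alleles: list[str],
    mean_read_len: float,
    epsilon: float,
    agcn: int,
) -> float:
    """Weight of a single allele; see :func:`allele_weights`."""
    alleles = sort_alleles(alleles)
    w = allele_weights(genotype, alleles, mean_read_len, epsilon, agcn)
    return float(w[alleles.index(allele)])


def _multinomial_logpmf(depths: np.ndarray, probs: np.ndarray) -> float:
    n = depths.sum()
    return float(
        gammaln(n + 1)
        - gammaln(depths + 1).sum()
        + (depths * np.log(probs)).sum()
    )


def aggregate_log_likelihood(
    depths: np.ndarray,
    genotype: AggregateGenotype,
    alleles: list[str],
    params: GenotypingParams,
    agcn: int,
) -> float:
    """log P(X | g): multinomial log-pmf of the allelic depths under ``g``."""
    probs = allele_weights(
        genotype, alleles, params.mean_read_len, params.epsilon, agcn
    )
    return _multinomial_logpmf(np.asarray(depths, dtype=float), probs)


@dataclass
class AggregateGenotypePosterior:
    """Posterior over the aggregate genotype space at one site."""

    alleles: list[str]
    agcn: int
    genotypes: list[AggregateGenotype]
    log_likelihoods: np.ndarray
    posteriors: np.ndarray
    _index: dict[AggregateGenotype, int] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genotypes)}

    @property
    def map_genotype(self) -> AggregateGenotype:
        return self.genotypes[int(np.argmax(self.posteriors))]

    @property
    def map_posterior(self) -> float:
        return float(self.posteriors.max())

    def prob(self, genotype) -> float:
        """Posterior mass of one genotype (0 if outside the space)."""
        i = self._index.get(canonical_genotype(genotype))
        return float(self.posteriors[i]) if i is not None else 0.0

    def quality_vs(self, genotype) -> float:
        """Phred-scaled evidence against ``genotype``: -10 log10 P(g | X), capped."""
        p = min(max(self.prob(genotype), 0.0), 1.0)
        if p <= 1e-100:
            return 1000.0
        return min(-10.0 * np.log10(p), 1000.0)


def aggregate_posterior(
    depths,
    alleles,
    agcn: int,
    params: GenotypingParams,
) -> AggregateGenotypePosterior:
    """Posterior over all aggregate genotypes with a uniform genotype prior.

    With the uniform prior the posterior argmax coincides with the
    maximum-likelihood genotype; normalisation uses log-sum-exp.
    """
    alleles = sort_alleles(alleles)
    genotypes = enumerate_aggregate_genotypes(alleles, agcn)
    depths = np.asarray(depths, dtype=float)
    if depths.shape != (len(alleles),):
        raise ValueError("depth vector must align with the sorted allele set")
    logl = np.array([
        aggregate_log_likelihood(depths, g, alleles, params, agcn)
        for g in genotypes
    ])
    post = np.exp(logl - logsumexp(logl))
    post /= post.sum()
    return AggregateGenotypePosterior(
        alleles=alleles,
        agcn=agcn,
        genotypes=genotypes,
        log_likelihoods=logl,
        posteriors=post,
    )
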