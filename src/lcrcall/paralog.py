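"""Paralog-specific genotyping of candidate variants from read-pair evidence.

Once informative PSVs are known, each read pair that covers a variant is
probabilistically located among the repeat copies.  With ``W_r`` the set
of informative PSVs covered by pair ``r``, the location probability of
copy ``i`` is

    p_r(i) = c_i * prod_{v in W_r} P(a_vi | r)
             / sum_j c_j * prod_{v in W_r} P(a_vj | r)

where ``P(a_vi | r)`` is ``1 - eps`` when the pair's base matches copy
i's PSV allele, ``eps`` on a mismatch and ``eps^2`` when the PSV has no
counterpart on copy i (gap).  A pair that extends into the
non-duplicated flank of a copy is anchored there: the flank acts as one
perfectly matching pseudo-PSV for that copy.

The likelihood of a pair carrying allele ``a_r`` under paralog genotype
``g`` mixes per-copy allele emissions over locations:

    P(r | g) = sum_i p_r(i)/c_i * ((1-eps) * mu(a_r, g_i)
                                   + eps * (c_i - mu(a_r, g_i)))

and the genotype posterior multiplies pair likelihoods with a prior
that combines the aggregate-genotype posterior with either the PSV
population prior or, for novel variants, a mutation-rate prior ``xi``
penalising each copy that carries any non-reference allele.

Strand-biased artifact sites are flagged with a two-sided Fisher's exact
test on the reference/alternate by forward/reverse 2x2 read-count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

from .aggregate import AggregateGenotypePosterior, GenotypingParams
from .model import (
    ParalogGenotype,
    PSVRecord,
    enumerate_paralog_genotypes,
    multiplicity,
    reference_compatible,
)
from .psv import psv_prior

__all__ = [
    "ReadPairObservation",
    "locate_read_pair",
    "ps_genotype_likelihood",
    "novel_variant_prior",
    "ParalogPosterior",
    "ps_genotype_posterior",
    "fisher_exact_two_sided",
    "strand_bias_filter",
]


@dataclass(frozen=True)
class ReadPairObservation:
    """One read pair's evidence at a variant site.

    ``psv_alleles`` lists ``(psv_id, observed_allele)`` for every
    informative PSV the pair covers; ``anchor_copy`` is set when a mate
    aligns into the non-duplicated flank of that copy.
    """

    pair_id: str
    allele: str
    strand: bool = True  # True = forward strand of the observing mate
    psv_alleles: tuple[tuple[object, str], ...] = ()
    anchor_copy: int | None = None

    @property
    def linked(self) -> bool:
        """True when the pair carries copy-identifying evidence."""
        return bool(self.psv_alleles) or self.anchor_copy is not None


def locate_read_pair(
    pair: ReadPairObservation,
    psv_copy_alleles: dict,
    pscn,
    epsilon: float,
) -> np.ndarray:
    """Location probabilities ``p_r(i)`` of a read pair over repeat copies.

    ``psv_copy_alleles[psv_id]`` is the tuple of per-copy PSV alleles
    (``None`` marks a copy where the PSV is missing).  With no covered
    PSVs and no anchor the result reduces to the copy-number prior
    ``c_i / sum_j c_j``.
    """
    pscn = np.asarray(pscn, dtype=float)
    n = len(pscn)
    log_w = np.where(pscn > 0, np.log(pscn, where=pscn > 0, out=np.zeros_like(pscn)), -np.inf)
    for psv_id, observed in pair.psv_alleles:
        copy_alleles = psv_copy_alleles[psv_id]
        for i in range(n):
            a_i = copy_alleles[i]
            if a_i is None:
                log_w[i] += 2.0 * np.log(epsilon)
            elif observed == a_i:
                log_w[i] += np.log1p(-epsilon)
            else:
                log_w[i] += np.log(epsilon)
    if pair.anchor_copy is not None:
        for i in range(n):
            log_w[i] += np.log1p(-epsilon) if i == pair.anchor_copy else np.log(epsilon)
    if np.all(np.isinf(log_w)):
        raise ValueError(
            f"read pair {pair.pair_id}: no candidate location has copy number > 0"
        )
    w = np.exp(log_w - log_w[np.isfinite(log_w)].max())
    w[~np.isfinite(w)] = 0.0
    return w / w.sum()


def ps_genotype_likelihood(
    pr: np.ndarray,
    allele: str,
    genotype: ParalogGenotype,
    pscn,
    epsilon: float,
) -> float:
    """P(r | g): probability of observing ``allele`` from one read pair."""
    total = 0.0
    for i, (p_i, c_i) in enumerate(zip(pr, pscn)):
        if c_i == 0 or p_i == 0.0:
            continue
        m = multiplicity(allele, genotype[i])
        total += p_i / c_i * ((1.0 - epsilon) * m + epsilon * (c_i - m))
    return total


def novel_variant_prior(
    genotype: ParalogGenotype,
    ref_allele: str,
    xi: float,
) -> float:
    """Mutation-rate prior for non-PSV variants.

    Each copy contributes ``1 - xi`` when it carries only the reference
    allele and ``xi`` otherwise; homozygous and heterozygous non-reference
    copies are penalised equally.
    """
    p = 1.0
    for copy_gt in genotype:
        if multiplicity(ref_allele, copy_gt) == len(copy_gt):
            p *= 1.0 - xi
        else:
            p *= xi
    return p


@dataclass
class ParalogPosterior:
    """Posterior over paralog genotypes for one variant."""

    pscn: tuple[int, ...]
    genotypes: list[ParalogGenotype]
    posteriors: np.ndarray
    resolved: bool
    _index: dict = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self._index = {g: i for i, g in enumerate(self.genotypes)}

    @property
    def map_genotype(self) -> ParalogGenotype:
        return self.genotypes[int(np.argmax(self.posteriors))]

    @property
    def map_posterior(self) -> float:
        return float(self.posteriors.max())

    def prob(self, genotype: ParalogGenotype) -> float:
        i = self._index.get(genotype)
        return float(self.posteriors[i]) if i is not None else 0.0

    def copy_genotype_quality(self, copy_index: int) -> float:
        """Phred-scaled confidence in the MAP genotype of one copy."""
        map_copy = self.map_genotype[copy_index]
        mass = sum(
            p
            for g, p in zip(self.genotypes, self.posteriors)
            if g[copy_index] == map_copy
        )
        err = max(1.0 - mass, 0.0)
        if err <= 1e-100:
            return 1000.0
        return min(-10.0 * float(np.log10(err)), 1000.0)

    def reference_prob(self, ref_alleles) -> float:
        """Posterior mass of the reference-compatible genotype."""
        return sum(
            float(p)
            for g, p in zip(self.genotypes, self.posteriors)
            if reference_compatible(g, ref_alleles)
        )


def ps_genotype_posterior(
    agg_posterior: AggregateGenotypePosterior,
    read_pairs: list[ReadPairObservation],
    pscn,
    params: GenotypingParams,
    psv_copy_alleles: dict,
    ref_alleles,
    psv_record: PSVRecord | None = None,
) -> ParalogPosterior:
    """Posterior over paralog genotypes given located read pairs.

    The genotype space is the union of paralog expansions of every
    aggregate genotype whose posterior exceeds
    ``params.agg_posterior_floor``; each genotype's prior is the product
    of its aggregate posterior and its class prior (PSV population prior
    when ``psv_record`` is given, otherwise the novel-variant prior)
    renormalised within the aggregate class.  A variant with no read pair
    linked to an informative PSV or a non-duplicated flank is left
    unresolved: the posterior is still computed (priors only separate the
    mirror assignments) but downstream reporting falls back to the
    aggregate genotype.
    """
    pscn = tuple(pscn)
    eps = params.epsilon
    genotypes: list[ParalogGenotype] = []
    log_prior: list[float] = []
    for g_hat, agg_p in zip(agg_posterior.genotypes, agg_posterior.posteriors):
        if agg_p <= params.agg_posterior_floor:
            continue
        expansion = enumerate_paralog_genotypes(g_hat, pscn)
        if psv_record is not None:
            cls = [
                psv_prior(g, psv_record.site.ref_alleles, psv_record.freqs, pscn)
                for g in expansion
            ]
        else:
            cls = [novel_variant_prior(g, ref_alleles[0], params.xi) for g in expansion]
        total = sum(cls)
        for g, c in zip(expansion, cls):
            genotypes.append(g)
            log_prior.append(float(np.log(agg_p)) + float(np.log(c / total)))
    if not genotypes:  # degenerate floor; fall back to the MAP class
        expansion = enumerate_paralog_genotypes(agg_posterior.map_genotype, pscn)
        genotypes = list(expansion)
        log_prior = [0.0] * len(genotypes)

    located = [
        (p, locate_read_pair(p, psv_copy_alleles, pscn, eps)) for p in read_pairs
    ]
    log_post = np.array(log_prior)
    for k, g in enumerate(genotypes):
        for pair, pr in located:
            log_post[k] += float(
                np.log(ps_genotype_likelihood(pr, pair.allele, g, pscn, eps))
            )
    post = np.exp(log_post - logsumexp(log_post))
    post /= post.sum()
    resolved = any(p.linked for p in read_pairs)
    return ParalogPosterior(
        pscn=pscn, genotypes=genotypes, posteriors=post, resolved=resolved
    )


def fisher_exact_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p-value for the 2x2 table [[a, b], [c, d]].

    Conditional on the margins, the first cell is hypergeometric; the
    p-value sums the probabilities of all tables at most as probable as
    the observed one (ties included, with a 1e-12 relative tolerance so
    exactly-tied mirror tables are kept despite floating-point rounding).
    """
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)
    support = np.arange(k_min, k_max + 1)
    pmf = hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - k_min]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def strand_bias_filter(
    ref_fwd: int,
    ref_rev: int,
    alt_fwd: int,
    alt_rev: int,
    pvalue_threshold: float = 0.01,
) -> tuple[float, bool]:
    """Fisher's exact strand-bias test; returns ``(p_value, passed)``.

    Fails (flags the variant) when the two-sided p-value is below the
    threshold.  An all-zero table carries no evidence and passes.
    """
    p = fisher_exact_two_sided(ref_fwd, ref_rev, alt_fwd, alt_rev)
    return p, p >= pvalue_threshold
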