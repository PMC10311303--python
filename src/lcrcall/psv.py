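"""Informative-PSV calling: paralog posteriors, conflict testing, pruning.

A PSV (paralogous sequence variant) is a position where the repeat
copies' reference sequences differ.  PSVs are the only signal that can
assign a read to a copy — but only when the sample actually carries each
copy's reference allele on that copy.  A PSV is *informative* for a
sample when its most likely paralog-specific genotype is
reference-compatible with high posterior (>= 0.99 by default).

The paralog-genotype prior at a PSV comes from population reference
allele frequencies ``f``:

    P(g; f) = prod_i f_i^mu(ref_i, g_i) * (1 - f_i)^(c_i - mu(ref_i, g_i))

and the posterior combines the aggregate-genotype posterior with this
prior renormalised within each aggregate genotype's expansion class.

Read pairs spanning two informative PSVs can contradict the pair's
reference genotypes; each such PSV pair (co-covered by >= 3 read pairs)
is tested with a one-tailed binomial test at discordance probability
``pi = 2*eps - eps^2`` (the chance that at least one of the two allele
observations is an error).  Conflicting pairs form a graph which is
pruned greedily: repeatedly drop the PSV maximising
``degree * sqrt(1 - min_freq)`` until no edges remain — a heuristic for
the NP-hard problem of keeping an edgeless subset with maximal total
minimum frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt

import networkx as nx
from scipy.stats import binom

from .aggregate import AggregateGenotypePosterior, GenotypingParams
from .model import (
    ParalogGenotype,
    PSVRecord,
    enumerate_paralog_genotypes,
    multiplicity,
    reference_compatible,
)

__all__ = [
    "psv_prior",
    "psv_paralog_posterior",
    "PSVCall",
    "conflict_test",
    "build_conflict_graph",
    "prune_conflicts",
]


def psv_prior(
    genotype: ParalogGenotype,
    ref_alleles,
    freqs,
    pscn,
) -> float:
    """Population prior of a paralog genotype at a PSV.

    Each allele on copy i contributes ``f_i`` when it equals the copy's
    reference allele and ``1 - f_i`` otherwise.
    """
    p = 1.0
    for copy_gt, ref, f, c in zip(genotype, ref_alleles, freqs, pscn):
        m = multiplicity(ref, copy_gt)
        p *= f ** m * (1.0 - f) ** (c - m)
    return p


@dataclass
class PSVCall:
    """Posterior paralog-genotype table for one PSV and its informative flag."""

    psv: PSVRecord
    pscn: tuple[int, ...]
    genotypes: list[ParalogGenotype]
    posteriors: list[float]
    informative: bool

    @property
    def map_genotype(self) -> ParalogGenotype:
        i = max(range(len(self.posteriors)), key=self.posteriors.__getitem__)
        return self.genotypes[i]

    @property
    def map_posterior(self) -> float:
        return max(self.posteriors)


def psv_paralog_posterior(
    psv: PSVRecord,
    agg_posterior: AggregateGenotypePosterior,
    pscn,
    params: GenotypingParams,
) -> PSVCall:
    """Posterior over paralog genotypes of a PSV.

    For a paralog genotype ``g`` in the expansion class ``G(g_hat)`` of
    aggregate genotype ``g_hat``:

        P(g | X; f) = P(g_hat | X) * P(g; f) / sum_{g' in G(g_hat)} P(g'; f)

    Summed over all aggregate genotypes these posteriors total 1.  The PSV
    is informative iff the most likely paralog genotype has posterior at
    least ``params.informative_threshold`` and is reference-compatible.
    """
    pscn = tuple(pscn)
    refs = psv.site.ref_alleles
    genotypes: list[ParalogGenotype] = []
    posteriors: list[float] = []
    for g_hat, agg_p in zip(agg_posterior.genotypes, agg_posterior.posteriors):
        expansion = enumerate_paralog_genotypes(g_hat, pscn)
        priors = [psv_prior(g, refs, psv.freqs, pscn) for g in expansion]
        total = sum(priors)
        for g, pr in zip(expansion, priors):
            genotypes.append(g)
            posteriors.append(float(agg_p) * (pr / total))
    i_map = max(range(len(posteriors)), key=posteriors.__getitem__)
    informative = (
        posteriors[i_map] >= params.informative_threshold
        and reference_compatible(genotypes[i_map], refs)
    )
    return PSVCall(
        psv=psv,
        pscn=pscn,
        genotypes=genotypes,
        posteriors=posteriors,
        informative=informative,
    )


def conflict_test(
    n_pairs: int,
    n_discordant: int,
    epsilon: float,
    pvalue_threshold: float = 1e-3,
    min_pairs: int = 3,
) -> tuple[float | None, bool]:
    """One-tailed binomial test for a conflicting pair of informative PSVs.

    ``n_discordant`` of ``n_pairs`` co-covering read pairs carry an allele
    combination matching neither reference haplotype of the two PSVs.
    Under the null (both PSVs informative) a pair is discordant only
    through sequencing error, with probability ``pi = 2*eps - eps^2``.
    Returns ``(p_value, is_conflict)``; no test is performed below
    ``min_pairs`` coverage.
    """
    if n_pairs < min_pairs:
        return None, False
    pi = 2.0 * epsilon - epsilon ** 2
    # P[K >= k] under Binomial(n, pi)
    p = float(binom.sf(n_discordant - 1, n_pairs, pi))
    return p, p < pvalue_threshold


def build_conflict_graph(
    psv_ids,
    weights,
    conflict_edges,
) -> nx.Graph:
    """Undirected graph of informative PSVs with conflict edges.

    ``weights[v]`` is the PSV's minimal population frequency (f-tilde);
    ``conflict_edges`` is an iterable of ``(u, v, p_value)``.
    """
    g = nx.Graph()
    for v in psv_ids:
        g.add_node(v, min_freq=weights[v])
    for u, v, p in conflict_edges:
        if u != v:
            g.add_edge(u, v, pvalue=p)
    return g


def prune_conflicts(graph: nx.Graph) -> list:
    """Greedy removal of conflicting PSVs until the graph is edgeless.

    While edges remain, remove the node maximising
    ``degree * sqrt(1 - min_freq)``; equal scores break towards the node
    with the smaller ``min_freq``, then the smaller node id, keeping the
    retained set deterministic and biased to high-confidence PSVs.
    Returns retained node ids in sorted order.
    """
    g = graph.copy()
    while g.number_of_edges() > 0:
        candidates = [n for n in g.nodes if g.degree(n) > 0]
        best_score = max(
            g.degree(n) * sqrt(1.0 - g.nodes[n]["min_freq"]) for n in candidates
        )
        tied = [
            n
            for n in candidates
            if g.degree(n) * sqrt(1.0 - g.nodes[n]["min_freq"]) == best_score
        ]
        worst = min(tied, key=lambda n: (g.nodes[n]["min_freq"], n))
        g.remove_node(worst)
    return sorted(g.nodes)
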