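"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive: plain-float or exact-Fraction
arithmetic, full enumeration, no log-space tricks and no imports from
the package's numerical code paths (only the genotype *definitions* are
re-derived locally).  The oracles are the reference the fast
implementations are checked against.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations_with_replacement, permutations
from math import comb


def sort_key(allele: str):
    return (len(allele), allele)


def enumerate_aggregate(alleles, agcn):
    distinct = sorted(set(alleles), key=sort_key)
    return [tuple(g) for g in combinations_with_replacement(distinct, agcn)]


def labeled_paralog_enumeration(aggregate, pscn):
    """All distinct per-copy distributions via labeled-permutation brute force."""
    out = set()
    for perm in permutations(aggregate):
        chunks = []
        k = 0
        for c in pscn:
            chunks.append(tuple(sorted(perm[k : k + c], key=sort_key)))
            k += c
        out.add(tuple(chunks))
    return sorted(out)


def oracle_aggregate_posterior(depths, alleles, agcn, mean_len, eps):
    """Uniform-prior multinomial posterior over aggregate genotypes."""
    alleles = sorted(set(alleles), key=sort_key)
    assert len(depths) == len(alleles)
    n = sum(depths)
    posts = {}
    for g in enumerate_aggregate(alleles, agcn):
        raw = [
            (mean_len - len(a) - 1) * max(eps * agcn, g.count(a)) for a in alleles
        ]
        tot = sum(raw)
        probs = [r / tot for r in raw]
        coef = 1
        left = n
        for x in depths:
            coef *= comb(left, x)
            left -= x
        lik = coef
        for p, x in zip(probs, depths):
            lik *= p ** x
        posts[g] = lik
    z = sum(posts.values())
    return {g: v / z for g, v in posts.items()}


def psv_class_prior(genotype, refs, freqs, pscn):
    p = 1.0
    for copy_gt, ref, f, c in zip(genotype, refs, freqs, pscn):
        m = copy_gt.count(ref)
        p *= f ** m * (1.0 - f) ** (c - m)
    return p


def oracle_psv_posterior(depths, refs, freqs, pscn, mean_len, eps):
    """Joint posterior over paralog genotypes of a PSV (population prior)."""
    alleles = sorted(set(refs), key=sort_key)
    agcn = sum(pscn)
    agg = oracle_aggregate_posterior(depths, alleles, agcn, mean_len, eps)
    posts = {}
    for g_hat, agg_p in agg.items():
        expansion = labeled_paralog_enumeration(g_hat, pscn)
        priors = [psv_class_prior(g, refs, freqs, pscn) for g in expansion]
        tot = sum(priors)
        for g, pr in zip(expansion, priors):
            posts[g] = agg_p * pr / tot
    return posts


def novel_class_prior(genotype, ref, xi):
    p = 1.0
    for copy_gt in genotype:
        p *= (1.0 - xi) if copy_gt.count(ref) == len(copy_gt) else xi
    return p


def oracle_read_pair_location(read, psv_alleles, pscn, eps):
    """Eq-6 style location probabilities by direct product."""
    allele, links, anchor = read
    weights = []
    for i, c in enumerate(pscn):
        w = float(c)
        for psv_id, obs in links:
            a_i = psv_alleles[psv_id][i]
            if a_i is None:
                w *= eps * eps
            elif obs == a_i:
                w *= 1.0 - eps
            else:
                w *= eps
        if anchor is not None:
            w *= (1.0 - eps) if i == anchor else eps
        weights.append(w)
    tot = sum(weights)
    return [w / tot for w in weights]


def oracle_read_posterior(
    depths,
    alleles,
    pscn,
    reads,
    psv_alleles,
    refs,
    mean_len,
    eps,
    xi,
    psv_freqs=None,
    floor=1e-6,
):
    """Direct evaluation of the read-set paralog posterior.

    ``reads`` are ``(allele, [(psv_id, observed_allele)], anchor)``
    triples.  Class priors are the PSV population prior when
    ``psv_freqs`` is given, otherwise the novel-variant prior on
    ``refs[0]``.  The genotype space unions the expansions of every
    aggregate genotype with posterior above ``floor``; class priors are
    renormalised within each expansion.
    """
    agcn = sum(pscn)
    agg = oracle_aggregate_posterior(depths, alleles, agcn, mean_len, eps)
    genotypes, priors = [], []
    for g_hat, agg_p in agg.items():
        if agg_p <= floor:
            continue
        expansion = labeled_paralog_enumeration(g_hat, pscn)
        if psv_freqs is not None:
            cls = [psv_class_prior(g, refs, psv_freqs, pscn) for g in expansion]
        else:
            cls = [novel_class_prior(g, refs[0], xi) for g in expansion]
        tot = sum(cls)
        for g, c in zip(expansion, cls):
            genotypes.append(g)
            priors.append(agg_p * c / tot)
    posts = []
    for g, prior in zip(genotypes, priors):
        p = prior
        for read in reads:
            pr = oracle_read_pair_location(read, psv_alleles, pscn, eps)
            allele = read[0]
            lik = 0.0
            for i, c in enumerate(pscn):
                if c == 0:
                    continue
                m = g[i].count(allele)
                lik += pr[i] / c * ((1.0 - eps) * m + eps * (c - m))
            p *= lik
        posts.append(p)
    z = sum(posts)
    return {g: p / z for g, p in zip(genotypes, posts)}


def oracle_binom_tail(k: int, n: int, pi: float) -> float:
    """Exact P[K >= k] for K ~ Binomial(n, pi) via Fractions."""
    if k <= 0:
        return 1.0
    p = Fraction(pi)
    total = Fraction(0)
    for j in range(k, n + 1):
        total += comb(n, j) * p ** j * (1 - p) ** (n - j)
    return float(total)


def oracle_fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Exact two-sided Fisher p: sum of table probabilities <= observed."""
    n = a + b + c + d
    if n == 0:
        return 1.0
    row1, col1 = a + b, a + c
    k_min = max(0, row1 + col1 - n)
    k_max = min(row1, col1)

    def pmf(k: int) -> Fraction:
        return Fraction(comb(col1, k) * comb(n - col1, row1 - k), comb(n, row1))

    p_obs = pmf(a)
    total = sum(pmf(k) for k in range(k_min, k_max + 1) if pmf(k) <= p_obs)
    return float(min(total, Fraction(1)))


def oracle_max_weight_independent_set(nodes, weights, edges):
    """Exhaustive maximum-total-weight edgeless subset (<= ~16 nodes)."""
    nodes = list(nodes)
    edge_set = {frozenset(e) for e in edges}
    best = 0.0
    best_set: tuple = ()
    for mask in range(1 << len(nodes)):
        subset = [nodes[i] for i in range(len(nodes)) if mask >> i & 1]
        ok = all(
            frozenset((u, v)) not in edge_set
            for i, u in enumerate(subset)
            for v in subset[i + 1 :]
        )
        if ok:
            w = sum(weights[v] for v in subset)
            if w > best:
                best, best_set = w, tuple(subset)
    return best, best_set
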