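"""Benchmark a call set against a truth set, genotype-aware.

Matching is internal (no external comparison tools): a call and a truth
record match when they share contig and normalised position and their
genotypes agree as allele strings — the *aggregate* comparison uses the
pooled allele multiset, the *paralog* comparison additionally requires
the per-copy genotype tuple to equal the truth where the truth provides
one (an unresolved call therefore never matches at paralog level).

Precision is reported as ``None`` when no call qualifies (no evidence),
following the convention that an empty call set has undefined precision
and zero recall.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from .io import VcfRecord

__all__ = ["PRStats", "Evaluation", "evaluate_calls"]


@dataclass
class PRStats:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def precision(self) -> float | None:
        n = self.tp + self.fp
        return None if n == 0 else self.tp / n

    @property
    def recall(self) -> float | None:
        n = self.tp + self.fn
        return None if n == 0 else self.tp / n

    def f_beta(self, beta: float = 1.0) -> float | None:
        p, r = self.precision, self.recall
        if p is None or r is None or p + r == 0:
            return None
        b2 = beta * beta
        denom = b2 * p + r
        return None if denom == 0 else (1 + b2) * p * r / denom

    @property
    def f1(self) -> float | None:
        return self.f_beta(1.0)

    @property
    def f05(self) -> float | None:
        return self.f_beta(0.5)


@dataclass
class Evaluation:
    """Precision/recall at three levels of strictness, plus concordance.

    ``allele``: a call matches truth when contig, position, reference and
    at least one alternate allele agree — precision/recall of variant
    *discovery*.  ``aggregate``: additionally the pooled allele multiset
    (aggregate genotype) must be identical.  ``paralog``: additionally
    the per-copy genotype tuple must equal the truth where the truth
    provides one.
    """

    allele: dict[str, PRStats]
    aggregate: dict[str, PRStats]  # keys: all, snv, indel (and strata)
    paralog: dict[str, PRStats]
    concordance: dict[str, tuple[int, int]]  # resolved matches: (correct, total)

    def concordance_rate(self, key: str = "all") -> float | None:
        correct, total = self.concordance.get(key, (0, 0))
        return None if total == 0 else correct / total


def _is_snv(alleles) -> bool:
    return all(len(a) == 1 for a in alleles)


def _agg_key(rec: VcfRecord):
    return rec.genotype_alleles()


def evaluate_calls(
    calls: list[VcfRecord],
    truth: list[VcfRecord],
    qual_threshold: float | None = None,
    exclude_filtered: bool = True,
    strata: dict[str, str] | None = None,
    concordance_min_gq: float | None = None,
) -> Evaluation:
    """Compare calls to truth.

    ``qual_threshold`` drops calls below the variant-quality cutoff;
    ``exclude_filtered`` drops calls with a non-PASS FILTER field;
    ``strata`` optionally maps contig names to stratum labels for
    stratified reporting.  ``concordance_min_gq`` restricts the
    genotype-concordance tally to calls whose per-copy genotype
    qualities all reach the cutoff — assignments the caller itself
    reports as low-confidence are emitted but not trusted.  Call and
    truth sets must share at least one contig, otherwise the comparison
    is meaningless and an error is raised.
    """
    call_contigs = {r.contig for r in calls}
    truth_contigs = {r.contig for r in truth}
    if calls and truth and not (call_contigs & truth_contigs):
        raise ValueError("call and truth sets cover disjoint loci")

    qualifying = [
        c
        for c in calls
        if (qual_threshold is None or (c.qual or 0.0) >= qual_threshold)
        and (not exclude_filtered or not c.filters)
    ]
    truth_by_key: dict[tuple[str, int], list[VcfRecord]] = defaultdict(list)
    for t in truth:
        truth_by_key[(t.contig, t.pos)].append(t)

    allele: dict[str, PRStats] = defaultdict(PRStats)
    agg: dict[str, PRStats] = defaultdict(PRStats)
    par: dict[str, PRStats] = defaultdict(PRStats)
    conc: dict[str, list[int]] = defaultdict(lambda: [0, 0])
    site_matched: set[int] = set()
    agg_matched: set[int] = set()

    def keys_for(rec: VcfRecord, snv: bool):
        yield "all"
        yield "snv" if snv else "indel"
        if strata and rec.contig in strata:
            yield strata[rec.contig]

    for c in qualifying:
        cands = truth_by_key.get((c.contig, c.pos), [])
        snv = _is_snv(c.alleles)
        site_match = None
        agg_match = None
        for t in cands:
            if t.ref == c.ref and set(t.alts) & set(c.alts):
                site_match = site_match or t
                if _agg_key(c) == _agg_key(t):
                    agg_match = t
                    break
        if site_match is not None:
            site_matched.add(id(site_match))
            for k in keys_for(c, snv):
                allele[k].tp += 1
        else:
            for k in keys_for(c, snv):
                allele[k].fp += 1
        if agg_match is not None:
            agg_matched.add(id(agg_match))
            for k in keys_for(c, snv):
                agg[k].tp += 1
            t_pgt = agg_match.paralog_alleles()
            c_pgt = c.paralog_alleles()
            pg_ok = t_pgt is None or (c_pgt is not None and c_pgt == t_pgt)
            for k in keys_for(c, snv):
                if pg_ok:
                    par[k].tp += 1
                else:
                    par[k].fp += 1
                    par[k].fn += 1
            if t_pgt is not None and c_pgt is not None:
                cgq = c.sample.get("CGQ")
                confident = (
                    concordance_min_gq is None
                    or cgq is None
                    or min(cgq) >= concordance_min_gq
                )
                if confident:
                    for k in keys_for(c, snv):
                        conc[k][1] += 1
                        conc[k][0] += int(c_pgt == t_pgt)
        else:
            for k in keys_for(c, snv):
                agg[k].fp += 1
                par[k].fp += 1
    for t in truth:
        snv = _is_snv(t.alleles)
        if id(t) not in site_matched:
            for k in keys_for(t, snv):
                allele[k].fn += 1
        if id(t) not in agg_matched:
            for k in keys_for(t, snv):
                agg[k].fn += 1
                par[k].fn += 1

    return Evaluation(
        allele=dict(allele),
        aggregate=dict(agg),
        paralog=dict(par),
        concordance={k: (v[0], v[1]) for k, v in conc.items()},
    )
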