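"""End-to-end variant calling for one LCR locus.

Three steps, run per locus and per sample:

1. *Aggregate variant calling* — project all reads onto the
   representative copy, discover candidate alleles, and genotype every
   candidate site (plus every PSV) as a polyploid of ploidy ``agcn``
   with the pooled multinomial model.  Candidates with quality < 1 are
   dropped; PSVs are always kept.
2. *Informative-PSV identification* — combine each PSV's aggregate
   posterior with its population-frequency prior, flag PSVs whose MAP
   paralog genotype is reference-compatible at posterior >= 0.99, test
   pairs of informative PSVs for read-level conflicts and prune the
   conflict graph greedily.
3. *Paralog-specific genotyping* — locate each read pair among the
   copies via the retained informative PSVs (and non-duplicated flank
   anchors), compute the paralog-genotype posterior of every candidate
   variant, convert to qualities, and apply the strand-bias filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np

from .aggregate import (
    AggregateGenotypePosterior,
    GenotypingParams,
    aggregate_posterior,
)
from .model import (
    CopyNumberProfile,
    ParalogousSite,
    PSVRecord,
    reference_compatible,
    sort_alleles,
)
from .paralog import (
    ParalogPosterior,
    ReadPairObservation,
    ps_genotype_posterior,
    strand_bias_filter,
)
from .pooling import (
    AlignedRead,
    ReadPair,
    SiteAlleles,
    SitePileup,
    build_site_pileup,
    filter_observations,
    group_read_pairs,
    merge_sites,
    project_read,
    scan_candidate_alleles,
)
from .psv import PSVCall, build_conflict_graph, conflict_test, prune_conflicts, psv_paralog_posterior

logger = logging.getLogger(__name__)

__all__ = ["VariantCall", "LocusResult", "call_locus"]


@dataclass
class VariantCall:
    """One called variant on the representative copy (0-based position)."""

    position: int
    site: SiteAlleles
    depths: np.ndarray
    agg: AggregateGenotypePosterior
    agg_qual: float
    paralog: ParalogPosterior | None
    resolved: bool
    qual: float
    copy_gq: list[float] | None
    strand_p: float
    filters: list[str]

    @property
    def ref(self) -> str:
        return self.site.ref

    @property
    def alleles(self) -> tuple[str, ...]:
        return self.site.alleles

    @property
    def aggregate_genotype(self):
        return self.agg.map_genotype

    @property
    def paralog_genotype(self):
        if self.paralog is not None and self.resolved:
            return self.paralog.map_genotype
        return None

    @property
    def passed(self) -> bool:
        return not self.filters


@dataclass
class LocusResult:
    locus_id: str
    sample_id: str
    calls: list[VariantCall]
    psv_calls: list[PSVCall]
    retained_informative: list[int]  # representative positions after pruning
    conflict_edges: list[tuple[int, int, float]]
    stats: dict = field(default_factory=dict)


def _psv_site_alleles(psv: PSVRecord) -> SiteAlleles:
    site = psv.site
    return SiteAlleles(
        position=site.rep_position,
        ref=site.ref_alleles[0],
        alleles=tuple(sort_alleles(site.ref_alleles)),
        is_psv=True,
        copy_refs=tuple(site.ref_alleles),
    )


def _padded_psv_record(psv: PSVRecord, site: SiteAlleles) -> PSVRecord:
    """Re-express a PSV record with the (possibly suffix-padded) site alleles."""
    if tuple(psv.site.ref_alleles) == site.copy_refs:
        return psv
    return PSVRecord(
        site=ParalogousSite(
            copy_positions=psv.site.copy_positions,
            ref_alleles=site.copy_refs,
            allele_set=site.alleles,
        ),
        freqs=psv.freqs,
    )


def call_locus(
    reads: list[AlignedRead],
    hmap,
    rep_seq: str,
    psvs: list[PSVRecord],
    profile: CopyNumberProfile,
    params: GenotypingParams | None = None,
    locus_id: str = "locus",
) -> LocusResult:
    """Run the three-step caller on one locus for one sample.

    ``rep_seq`` is the representative copy's full contig sequence.  When
    the paralog-specific copy number is not fully known the locus is
    called in aggregate-only mode: pooled genotypes are reported without
    per-copy assignment.
    """
    params = params or GenotypingParams()
    agcn = profile.agcn
    pscn = profile.known_pscn if profile.fully_known else None
    n = hmap.n_copies

    projected = []
    for r in reads:
        p = project_read(r, hmap)
        if p is not None:
            projected.append(p)
    pairs = group_read_pairs(projected)
    pair_by_name = {p.name: p for p in pairs}

    aligned_lens = [r.n_aligned for p in pairs for r in p.reads if r.n_aligned]
    if aligned_lens:
        params = replace(params, mean_read_len=float(np.mean(aligned_lens)))

    rep_cp = hmap.representative
    rep_core = rep_seq[rep_cp.start : rep_cp.end]
    candidates = scan_candidate_alleles(
        pairs, rep_core, rep_cp.start, params.min_base_quality
    )
    psv_by_pos = {p.site.rep_position: p for p in psvs}
    sites = merge_sites(candidates, [_psv_site_alleles(p) for p in psvs])

    # -- step 1: aggregate genotyping of candidates ----------------------
    pileups: dict[int, SitePileup] = {}
    agg_posts: dict[int, AggregateGenotypePosterior] = {}
    agg_quals: dict[int, float] = {}
    kept: list[SiteAlleles] = []
    for site in sites:
        pile = filter_observations(build_site_pileup(site, pairs), params.min_base_quality)
        post = aggregate_posterior(pile.depths(), list(site.alleles), agcn, params)
        ref_agg = site.reference_aggregate(pscn or (agcn,) + (0,) * (n - 1))
        qual = post.quality_vs(ref_agg)
        pileups[site.position] = pile
        agg_posts[site.position] = post
        agg_quals[site.position] = qual
        if site.is_psv or qual >= params.min_candidate_qual:
            kept.append(site)

    # -- step 2: informative PSVs ----------------------------------------
    psv_calls: list[PSVCall] = []
    informative: dict[int, PSVCall] = {}
    if pscn is not None:
        for site in kept:
            if not site.is_psv:
                continue
            rec = _padded_psv_record(psv_by_pos[site.position], site)
            call = psv_paralog_posterior(
                rec, agg_posts[site.position], pscn, params
            )
            psv_calls.append(call)
            if call.informative:
                informative[site.position] = call

    # conflict detection between informative PSVs sharing read pairs
    psv_obs: dict[int, dict[str, str]] = {
        pos: {o.pair_id: o.allele for o in pileups[pos].observations}
        for pos in informative
    }
    pair_psvs: dict[str, list[int]] = {}
    for pos, obs in psv_obs.items():
        for pid in obs:
            pair_psvs.setdefault(pid, []).append(pos)
    co_cover: dict[tuple[int, int], list[str]] = {}
    for pid, poss in pair_psvs.items():
        for a, b in combinations(sorted(poss), 2):
            co_cover.setdefault((a, b), []).append(pid)
    edges: list[tuple[int, int, float]] = []
    site_by_pos = {s.position: s for s in sites}
    for (a, b), pids in co_cover.items():
        refs_a = site_by_pos[a].copy_refs
        refs_b = site_by_pos[b].copy_refs
        ref_combos = {(refs_a[i], refs_b[i]) for i in range(n)}
        k = sum(
            1
            for pid in pids
            if (psv_obs[a][pid], psv_obs[b][pid]) not in ref_combos
        )
        p, is_conflict = conflict_test(
            len(pids), k, params.epsilon, params.conflict_pvalue
        )
        if is_conflict:
            edges.append((a, b, p))
    graph = build_conflict_graph(
        list(informative),
        {pos: informative[pos].psv.min_freq for pos in informative},
        edges,
    )
    retained = prune_conflicts(graph)
    retained_set = set(retained)

    # -- step 3: paralog-specific genotyping -----------------------------
    psv_copy_alleles = {pos: site_by_pos[pos].copy_refs for pos in retained_set}
    calls: list[VariantCall] = []
    n_resolved = n_unresolved = 0
    for site in kept:
        pos = site.position
        pile = pileups[pos]
        post = agg_posts[pos]
        copy_refs = site.copy_refs or (site.ref,) * n
        paralog = None
        resolved = False
        copy_gq = None
        qual = agg_quals[pos]
        if pscn is not None:
            read_obs = []
            for o in pile.observations:
                pair = pair_by_name[o.pair_id]
                wr = tuple(
                    (ppos, psv_obs[ppos][o.pair_id])
                    for ppos in pair_psvs.get(o.pair_id, ())
                    if ppos in retained_set and ppos != pos
                )
                read_obs.append(
                    ReadPairObservation(
                        pair_id=o.pair_id,
                        allele=o.allele,
                        strand=o.strand,
                        psv_alleles=wr,
                        anchor_copy=pair.anchor_copy,
                    )
                )
            psv_rec = (
                _padded_psv_record(psv_by_pos[pos], site) if site.is_psv else None
            )
            paralog = ps_genotype_posterior(
                post,
                read_obs,
                pscn,
                params,
                psv_copy_alleles,
                copy_refs,
                psv_record=psv_rec,
            )
            resolved = paralog.resolved
            if resolved:
                ref_p = min(max(paralog.reference_prob(copy_refs), 0.0), 1.0)
                qual = (
                    1000.0
                    if ref_p <= 1e-100
                    else min(-10.0 * float(np.log10(ref_p)), 1000.0)
                )
                copy_gq = [
                    paralog.copy_genotype_quality(i) for i in range(n)
                ]

        # variant-ness: MAP of the most specific posterior is non-reference
        if pscn is not None and resolved:
            is_variant = not reference_compatible(paralog.map_genotype, copy_refs)
        elif pscn is not None:
            ref_agg = site.reference_aggregate(pscn)
            is_variant = post.map_genotype != ref_agg
        else:
            copy_ref_set = set(copy_refs)
            is_variant = any(a not in copy_ref_set for a in post.map_genotype)
        if not is_variant:
            continue
        if resolved:
            n_resolved += 1
        else:
            n_unresolved += 1
        rf, rr, af, ar = pile.strand_counts()
        strand_p, strand_ok = strand_bias_filter(
            rf, rr, af, ar, params.fet_pvalue
        )
        filters = []
        if not strand_ok:
            filters.append("StrandBias")
        if qual < params.output_qual_threshold:
            filters.append("LowQual")
        calls.append(
            VariantCall(
                position=pos,
                site=site,
                depths=pile.depths(),
                agg=post,
                agg_qual=agg_quals[pos],
                paralog=paralog,
                resolved=resolved,
                qual=qual,
                copy_gq=copy_gq,
                strand_p=strand_p,
                filters=filters,
            )
        )
    calls.sort(key=lambda c: c.position)

    stats = {
        "reads": len(reads),
        "reads_pooled": len(projected),
        "pairs": len(pairs),
        "candidate_sites": len(sites),
        "kept_sites": len(kept),
        "psvs": len(psvs),
        "informative_psvs": len(informative),
        "retained_informative": len(retained),
        "conflict_edges": len(edges),
        "variants": len(calls),
        "resolved": n_resolved,
        "unresolved": n_unresolved,
    }
    logger.info(
        "%s: %d pairs pooled, %d candidate sites, %d/%d informative PSVs, "
        "%d variants (%d resolved)",
        locus_id,
        stats["pairs"],
        stats["kept_sites"],
        stats["retained_informative"],
        stats["psvs"],
        stats["variants"],
        stats["resolved"],
    )
    return LocusResult(
        locus_id=locus_id,
        sample_id=profile.sample_id,
        calls=calls,
        psv_calls=psv_calls,
        retained_informative=retained,
        conflict_edges=edges,
        stats=stats,
    )
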