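"""Read pooling: projection onto the representative copy and pileups.

Reads aligned to any repeat copy are lifted through the homology map
onto the representative copy, *regardless of mapping quality* — in an
LCR the mapper cannot distinguish copies, so mapping quality carries
little information and discarding low-MAPQ reads would discard most of
the signal.  Projection is local: read bases follow their alignment
columns; bases falling in columns where the representative copy is
gapped stay unaligned, and a read lying entirely in such a gap is
dropped.

From the pooled projected reads the module discovers candidate variant
sites (positions whose non-reference allele is seen in at least two read
pairs, plus every PSV), and builds per-site pileups of read-*pair*
allele observations: each pair contributes at most one observation per
site (mates agreeing are collapsed; mates disagreeing are dropped),
observations with base quality below 10 or not fully spanning the
allele are discarded.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from .homology import GAP, HomologyMap
from .model import sort_alleles

logger = logging.getLogger(__name__)

__all__ = [
    "AlignedRead",
    "ProjectedRead",
    "ReadPair",
    "project_read",
    "group_read_pairs",
    "read_sam",
    "normalize_variant",
    "scan_candidate_alleles",
    "SiteAlleles",
    "SiteObservation",
    "SitePileup",
    "PooledPileup",
    "build_site_pileup",
    "filter_observations",
]


@dataclass
class AlignedRead:
    """Minimal alignment record (one read) on a repeat copy's contig."""

    name: str
    copy_index: int
    start: int  # 0-based leftmost aligned position
    cigar: tuple[tuple[str, int], ...]  # ops M/I/D/S/H (=/X folded into M)
    seq: str
    quals: np.ndarray
    is_reverse: bool = False
    mate: int = 1  # 1 or 2 within the pair


@dataclass
class ProjectedRead:
    """A read lifted onto the representative copy.

    ``rep_pos[k]`` is the representative position of read base
    ``read_idx[k]`` (both sorted by position).  ``insertions`` holds
    ``(anchor_rep_pos, read_start, length)`` for read bases without a
    representative column (sample insertions and copy-only columns);
    ``deletions`` holds representative spans absent from the read.
    ``flank_bases`` counts aligned bases outside the homologous interval
    of the read's copy — evidence anchoring the pair to that copy.
    """

    name: str
    copy_index: int
    is_reverse: bool
    mate: int
    seq: str
    quals: np.ndarray
    rep_pos: np.ndarray
    read_idx: np.ndarray
    insertions: list[tuple[int, int, int]] = field(default_factory=list)
    deletions: list[tuple[int, int]] = field(default_factory=list)
    flank_bases: int = 0

    @property
    def n_aligned(self) -> int:
        return int(self.rep_pos.size)

    def base_at(self, pos: int) -> tuple[str, int] | None:
        """(base, quality) aligned at a representative position, else None."""
        i = int(np.searchsorted(self.rep_pos, pos))
        if i < self.rep_pos.size and self.rep_pos[i] == pos:
            j = int(self.read_idx[i])
            return self.seq[j], int(self.quals[j])
        return None

    def in_deletion(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.deletions)


def project_read(read: AlignedRead, hmap: HomologyMap) -> ProjectedRead | None:
    """Lift one read from its copy onto the representative copy.

    Returns ``None`` (and logs why) when no base projects and the read
    carries no flank evidence either.
    """
    cp = hmap.copies[read.copy_index]
    rep_chunks: list[np.ndarray] = []
    idx_chunks: list[np.ndarray] = []
    insertions: list[tuple[int, int, int]] = []
    deletions: list[tuple[int, int]] = []
    flank = 0
    last_rep = None
    ref = read.start
    q = 0
    for op, length in read.cigar:
        if op in ("S",):
            q += length
        elif op in ("H", "P"):
            pass
        elif op == "M":
            pos = np.arange(ref, ref + length)
            inside = (pos >= cp.start) & (pos < cp.end)
            flank += int((~inside).sum())
            rep = hmap.project(read.copy_index, pos)
            mapped = inside & (rep != GAP)
            mapped_off = np.nonzero(mapped)[0]
            if mapped.any():
                rep_chunks.append(rep[mapped])
                idx_chunks.append(q + mapped_off)
            unal = inside & (rep == GAP)
            if unal.any():
                # bases in copy-only columns: unaligned to L, kept as an
                # insertion anchored on the closest mapped base to the left
                for r0, r1 in _runs(np.nonzero(unal)[0]):
                    before = mapped_off[mapped_off < r0]
                    anchor = (
                        int(rep[before[-1]]) if before.size else last_rep
                    )
                    if anchor is not None:
                        insertions.append((anchor, q + r0, r1 - r0))
            if mapped.any():
                last_rep = int(rep[mapped][-1])
            ref += length
            q += length
        elif op == "I":
            if last_rep is not None:
                insertions.append((last_rep, q, length))
            q += length
        elif op == "D":
            pos = np.arange(ref, ref + length)
            inside = (pos >= cp.start) & (pos < cp.end)
            rep = hmap.project(read.copy_index, pos)
            mapped = rep[inside & (rep != GAP)]
            if mapped.size:
                deletions.append((int(mapped.min()), int(mapped.max()) + 1))
            ref += length
        else:
            raise ValueError(f"unsupported CIGAR op {op!r}")
    if rep_chunks:
        rep_pos = np.concatenate(rep_chunks)
        read_idx = np.concatenate(idx_chunks)
        order = np.argsort(rep_pos, kind="stable")
        rep_pos, read_idx = rep_pos[order], read_idx[order]
        # Copy-internal gaps relative to L: adjacent read bases spanning a
        # representative-only stretch imply a deletion w.r.t. L.
        jump = np.nonzero(
            (np.diff(read_idx) == 1) & (np.diff(rep_pos) > 1)
        )[0]
        for k in jump:
            deletions.append((int(rep_pos[k]) + 1, int(rep_pos[k + 1])))
    else:
        if flank == 0:
            logger.debug(
                "read %s dropped: no base projects onto the representative copy",
                read.name,
            )
            return None
        rep_pos = np.empty(0, dtype=np.int64)
        read_idx = np.empty(0, dtype=np.int64)
    return ProjectedRead(
        name=read.name,
        copy_index=read.copy_index,
        is_reverse=read.is_reverse,
        mate=read.mate,
        seq=read.seq,
        quals=read.quals,
        rep_pos=rep_pos,
        read_idx=read_idx,
        insertions=insertions,
        deletions=sorted(set(deletions)),
        flank_bases=flank,
    )


def _runs(indices: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous runs [start, end) within a sorted index array."""
    if indices.size == 0:
        return []
    breaks = np.nonzero(np.diff(indices) > 1)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks + 1, [indices.size]))
    return [(int(indices[s]), int(indices[e - 1]) + 1) for s, e in zip(starts, ends)]


@dataclass
class ReadPair:
    """Both mates of a pair, projected; one observation source per site."""

    name: str
    reads: list[ProjectedRead]
    copy_index: int
    anchor_copy: int | None = None


def group_read_pairs(
    projected: list[ProjectedRead], min_anchor_bases: int = 20
) -> list[ReadPair]:
    """Group projected reads by pair name; collapse duplicate projections.

    A pair whose mate aligns ``min_anchor_bases`` or more into the
    non-duplicated flank of its copy is anchored to that copy.
    """
    by_name: dict[str, list[ProjectedRead]] = defaultdict(list)
    for r in projected:
        by_name[r.name].append(r)
    pairs = []
    for name in sorted(by_name):
        reads = by_name[name]
        # one true origin per pair: keep at most one projection per mate
        seen: dict[int, ProjectedRead] = {}
        for r in reads:
            if r.mate not in seen or r.n_aligned > seen[r.mate].n_aligned:
                seen[r.mate] = r
        kept = list(seen.values())
        anchor = None
        for r in kept:
            if r.flank_bases >= min_anchor_bases:
                anchor = r.copy_index
        pairs.append(
            ReadPair(
                name=name,
                reads=[r for r in kept if r.n_aligned > 0],
                copy_index=kept[0].copy_index,
                anchor_copy=anchor,
            )
        )
    return [p for p in pairs if p.reads or p.anchor_copy is not None]


def read_sam(path, hmap: HomologyMap) -> list[AlignedRead]:
    """Parse a SAM/BAM file into alignment records keyed to repeat copies.

    Contigs are matched to copies by contig name; reads on contigs not in
    the homology map are ignored.
    """
    import pysam

    by_contig: dict[str, int] = {}
    for i, cp in enumerate(hmap.copies):
        by_contig.setdefault(cp.contig, i)
    out: list[AlignedRead] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh.fetch(until_eof=True):
            if aln.is_unmapped or aln.reference_name not in by_contig:
                continue
            cigar = tuple(
                ("M" if op in (0, 7, 8) else "IDNSHP"[op - 1], ln)
                for op, ln in aln.cigartuples
            )
            quals = (
                np.asarray(aln.query_qualities, dtype=np.int16)
                if aln.query_qualities is not None
                else np.full(len(aln.query_sequence), 30, dtype=np.int16)
            )
            out.append(
                AlignedRead(
                    name=aln.query_name,
                    copy_index=by_contig[aln.reference_name],
                    start=aln.reference_start,
                    cigar=cigar,
                    seq=aln.query_sequence,
                    quals=quals,
                    is_reverse=aln.is_reverse,
                    mate=2 if aln.is_read2 else 1,
                )
            )
    return out


# ---------------------------------------------------------------------------
# candidate discovery and pileups
# ---------------------------------------------------------------------------


def normalize_variant(pos: int, ref: str, alt: str, seq: str) -> tuple[int, str, str]:
    """Left-aligned minimal representation of a variant against ``seq``.

    ``seq`` is the representative reference (contig coordinates).
    """
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            continue
        if (
            len(ref) != len(alt)
            and ref[-1] == alt[-1]
            and pos > 0
        ):
            b = seq[pos - 1]
            ref, alt = b + ref[:-1], b + alt[:-1]
            pos -= 1
            continue
        break
    return pos, ref, alt


def scan_candidate_alleles(
    pairs: list[ReadPair],
    rep_ref: str,
    rep_start: int,
    min_base_quality: int = 10,
    min_pairs: int = 2,
) -> dict[tuple[int, str, str], int]:
    """Scan projected reads for non-reference alleles seen in >= min_pairs pairs.

    Returns ``{(position, ref, alt): n_pairs}`` with indels left-aligned
    and minimally represented.  Substitutions below the base-quality
    cutoff do not count.
    """
    ref_arr = np.frombuffer(rep_ref.encode(), dtype=np.uint8)
    support: dict[tuple[int, str, str], set[str]] = defaultdict(set)
    for pair in pairs:
        for r in pair.reads:
            off = r.rep_pos - rep_start
            valid = (off >= 0) & (off < ref_arr.size)
            if not valid.all():
                off, idx = off[valid], r.read_idx[valid]
            else:
                idx = r.read_idx
            bases = np.frombuffer(r.seq.encode(), dtype=np.uint8)[idx]
            mism = np.nonzero(
                (bases != ref_arr[off]) & (r.quals[idx] >= min_base_quality)
            )[0]
            for k in mism:
                p = int(off[k]) + rep_start
                support[(p, rep_ref[p - rep_start], chr(bases[k]))].add(pair.name)
            for anchor, q0, ln in r.insertions:
                a = anchor - rep_start
                if 0 <= a < ref_arr.size:
                    ins = r.seq[q0 : q0 + ln]
                    key = normalize_variant(
                        anchor, rep_ref[a], rep_ref[a] + ins, _Shifted(rep_ref, rep_start)
                    )
                    support[key].add(pair.name)
            for ds, de in r.deletions:
                s, e = ds - rep_start, de - rep_start
                if s >= 1 and e <= ref_arr.size:
                    key = normalize_variant(
                        ds - 1,
                        rep_ref[s - 1 : e],
                        rep_ref[s - 1],
                        _Shifted(rep_ref, rep_start),
                    )
                    support[key].add(pair.name)
    return {
        key: len(names) for key, names in support.items() if len(names) >= min_pairs
    }


class _Shifted:
    """Expose a contig-coordinate view of the representative sequence."""

    def __init__(self, seq: str, start: int):
        self._seq, self._start = seq, start

    def __getitem__(self, pos):
        if isinstance(pos, slice):
            return self._seq[pos.start - self._start : pos.stop - self._start]
        return self._seq[pos - self._start]


@dataclass(frozen=True)
class SiteAlleles:
    """Allele set of one candidate site on the representative copy."""

    position: int  # contig coordinate of the first ref base
    ref: str
    alleles: tuple[str, ...]  # canonical order, includes ref (and copy refs)
    is_psv: bool = False
    copy_refs: tuple[str, ...] | None = None  # per-copy reference alleles

    @property
    def is_indel_site(self) -> bool:
        return any(len(a) != 1 for a in self.alleles) or len(self.ref) != 1

    def reference_aggregate(self, pscn) -> tuple[str, ...]:
        """The reference aggregate genotype multiset for given copy numbers."""
        if self.copy_refs is not None:
            alleles = [
                a for ref, c in zip(self.copy_refs, pscn) for a in (ref,) * c
            ]
        else:
            alleles = [self.ref] * sum(pscn)
        return tuple(sorted(alleles, key=lambda a: (len(a), a)))


@dataclass(frozen=True)
class SiteObservation:
    pair_id: str
    allele: str
    base_quality: int
    strand: bool  # True = forward
    copy_index: int


@dataclass
class SitePileup:
    site: SiteAlleles
    observations: list[SiteObservation]

    def depths(self) -> np.ndarray:
        counts = {a: 0 for a in self.site.alleles}
        for obs in self.observations:
            counts[obs.allele] += 1
        return np.array([counts[a] for a in self.site.alleles], dtype=float)

    def strand_counts(self) -> tuple[int, int, int, int]:
        """(ref_fwd, ref_rev, alt_fwd, alt_rev) counts for the strand test.

        'Reference' means any copy's reference allele at a PSV.
        """
        refs = set(self.site.copy_refs or (self.site.ref,))
        rf = rr = af = ar = 0
        for obs in self.observations:
            if obs.allele in refs:
                rf, rr = rf + obs.strand, rr + (not obs.strand)
            else:
                af, ar = af + obs.strand, ar + (not obs.strand)
        return rf, rr, af, ar


@dataclass
class PooledPileup:
    sites: list[SitePileup]

    def __iter__(self):
        return iter(self.sites)


def _observe_read(
    read: ProjectedRead, site: SiteAlleles
) -> tuple[str, int] | None:
    """The allele (and quality) one read shows at a site; None when the
    read does not fully span the allele or matches no site allele."""
    pos, ref = site.position, site.ref
    if not site.is_indel_site:
        if read.in_deletion(pos):
            return None
        hit = read.base_at(pos)
        if hit is None:
            return None
        base, qual = hit
        return (base, qual) if base in site.alleles else None
    # indel site: read must span [pos, pos + len(ref)] entirely
    span_end = pos + len(ref)
    if read.n_aligned == 0 or read.rep_pos[0] > pos or read.rep_pos[-1] < span_end:
        return None
    ins_by_anchor: dict[int, str] = {}
    for anchor, q0, ln in read.insertions:
        if pos <= anchor < span_end:
            ins_by_anchor[anchor] = read.seq[q0 : q0 + ln]
    obs = []
    quals = []
    for p in range(pos, span_end):
        hit = read.base_at(p)
        if hit is not None:
            obs.append(hit[0])
            quals.append(hit[1])
        elif not read.in_deletion(p):
            return None  # alignment gap: partial observation
        if p in ins_by_anchor:
            obs.append(ins_by_anchor[p])
    observed = "".join(obs)
    if observed not in site.alleles:
        return None
    return observed, min(quals) if quals else 30


def build_site_pileup(site: SiteAlleles, pairs: list[ReadPair]) -> SitePileup:
    """Collect one allele observation per read pair at a site.

    Mates observing different alleles are ambiguous and dropped; agreeing
    mates are collapsed to the higher-quality observation.
    """
    observations: list[SiteObservation] = []
    for pair in pairs:
        best: tuple[str, int, bool] | None = None
        conflict = False
        for r in pair.reads:
            hit = _observe_read(r, site)
            if hit is None:
                continue
            allele, qual = hit
            if best is None or qual > best[1]:
                if best is not None and best[0] != allele:
                    conflict = True
                best = (allele, qual, not r.is_reverse)
            elif best[0] != allele:
                conflict = True
        if best is not None and not conflict:
            observations.append(
                SiteObservation(
                    pair_id=pair.name,
                    allele=best[0],
                    base_quality=best[1],
                    strand=best[2],
                    copy_index=pair.copy_index,
                )
            )
    return SitePileup(site=site, observations=observations)


def filter_observations(pileup: SitePileup, min_base_quality: int = 10) -> SitePileup:
    """Drop allele observations below the base-quality cutoff."""
    return SitePileup(
        site=pileup.site,
        observations=[
            o for o in pileup.observations if o.base_quality >= min_base_quality
        ],
    )


def merge_sites(
    candidates: dict[tuple[int, str, str], int],
    psv_sites: list[SiteAlleles],
) -> list[SiteAlleles]:
    """Combine discovered alleles and PSV sites into per-position sites.

    Alleles sharing a position are merged into one (multi-allelic) site;
    when reference spans differ the longest reference wins and shorter
    alleles are padded with the extra reference suffix.
    """
    by_pos: dict[int, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    psv_by_pos = {s.position: s for s in psv_sites}
    for (pos, ref, alt), _count in candidates.items():
        by_pos[pos][ref].add(alt)
    out: list[SiteAlleles] = []
    for pos in sorted(set(by_pos) | set(psv_by_pos)):
        psv = psv_by_pos.get(pos)
        refs = dict(by_pos.get(pos, {}))
        if psv is not None:
            refs.setdefault(psv.ref, set()).update(
                a for a in psv.alleles if a != psv.ref
            )
        site_ref = max(refs, key=len)
        alleles = {site_ref}
        copy_refs = None
        for ref, alts in refs.items():
            pad = site_ref[len(ref):]
            alleles.update(alt + pad for alt in alts)
        if psv is not None:
            pad = site_ref[len(psv.ref):]
            copy_refs = tuple(r + pad for r in psv.copy_refs)
            alleles.update(copy_refs)
        out.append(
            SiteAlleles(
                position=pos,
                ref=site_ref,
                alleles=tuple(sort_alleles(alleles)),
                is_psv=psv is not None,
                copy_refs=copy_refs,
            )
        )
    return out
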