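"""Synthetic LCR locus, sample and read simulator.

The simulator builds everything the caller consumes, so the whole
pipeline is testable without external data:

* a locus: ``n`` repeat-copy contigs sharing a homologous core that
  differs at substitution PSVs (PSV density set by the pairwise
  similarity target), each flanked by copy-private (non-duplicated)
  sequence; plus the homology map and a PSV table with per-copy
  population reference-allele frequencies;
* a sample: per-copy haplotypes carrying (i) polymorphic-PSV
  realisations drawn from the PSV frequencies and (ii) artificial
  sequence variants at a configurable rate (default one per kilobase;
  80% substitutions, 10% insertions, 10% deletions; 61.5% heterozygous),
  with a truth set of aggregate and paralog-specific genotypes;
* reads: uniformly sampled paired-end fragments per haplotype with
  per-base substitution errors, "mapped" by emulating an ambiguity-aware
  aligner — pairs covering PSVs go to the best-matching copy, PSV-free
  pairs to a random copy, pairs reaching into a copy-private flank to
  their true copy — with the true origin recorded for benchmarking.

All randomness flows from the mandatory seed; equal seeds give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .homology import CopyInterval, HomologyMap
from .model import CopyNumberProfile, ParalogousSite, PSVRecord, canonical_genotype
from .pooling import AlignedRead, normalize_variant

__all__ = [
    "SimConfig",
    "SimLocus",
    "SimSample",
    "Haplotype",
    "TruthVariant",
    "simulate_locus",
    "simulate_sample",
    "simulate_reads",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated experiment.

    ``depth`` is diploid-style coverage per repeat copy: a copy present in
    two haplotypes receives ``depth``-fold coverage, so the pooled
    aggregate coverage is ``depth / 2 * sum(pscn)``.  ``similarity`` sets
    the PSV density (expected ``copy_length * (1 - similarity)`` PSVs).
    ``psv_freq_mix`` draws per-copy PSV reference-allele frequencies from
    a mixture of uniform components ``(weight, low, high)`` standing in
    for empirical population frequencies: most PSVs are almost fixed,
    a minority are clearly polymorphic.  ``fixed_psv_freq`` overrides the
    mixture with one near-one frequency (the fixed-PSV scenario).
    """

    seed: int
    n_copies: int = 2
    copy_length: int = 10_000
    similarity: float = 0.995
    flank: int = 500
    psv_freq_mix: tuple[tuple[float, float, float], ...] = (
        (0.7, 0.9, 1.0),
        (0.3, 0.5, 0.9),
    )
    fixed_psv_freq: float | None = None
    variant_rate: float = 1e-3
    het_fraction: float = 0.615
    type_mix: tuple[float, float, float] = (0.8, 0.1, 0.1)
    max_indel_len: int = 6
    pscn: tuple[int, ...] = (2, 2)
    depth: float = 30.0
    read_length: int = 150
    fragment_mean: float = 500.0
    fragment_sd: float = 50.0
    error_rate: float = 0.01
    base_quality: int = 30
    discard_variants_on_psvs: bool = True

    def __post_init__(self) -> None:
        for name in ("similarity", "variant_rate", "het_fraction", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if abs(sum(self.type_mix) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        if len(self.pscn) != self.n_copies:
            raise ValueError("pscn must have one entry per copy")
        if 1.0 - self.similarity > 0.2:
            raise ValueError(
                "similarity target incompatible with copy length: PSV "
                "density above 0.2/bp cannot be realised as isolated "
                "substitution columns"
            )


@dataclass
class SimLocus:
    """One simulated LCR locus: contigs, homology map and PSV table."""

    locus_id: str
    config: SimConfig
    contig_names: list[str]
    contig_seqs: list[str]  # flank + homologous core + flank
    hmap: HomologyMap
    psvs: list[PSVRecord]  # positions in contig coordinates

    @property
    def rep_seq(self) -> str:
        return self.contig_seqs[0]

    @property
    def core(self) -> tuple[int, int]:
        cp = self.hmap.representative
        return cp.start, cp.end

    def psv_positions(self) -> np.ndarray:
        return np.array([p.site.rep_position for p in self.psvs], dtype=np.int64)


@dataclass
class Haplotype:
    """One haplotype of one repeat copy, with its variants applied."""

    copy_index: int
    hap_index: int
    variants: list[tuple[int, str, str]]  # (contig pos, ref, alt), sorted
    seq: str = ""
    _ops: list[tuple[str, int, int, int, int]] = field(default_factory=list)
    # ops: (op, ref_start, ref_len, hap_start, hap_len)

    def build(self, ref_seq: str) -> None:
        parts: list[str] = []
        ops: list[tuple[str, int, int, int, int]] = []
        r = h = 0
        for pos, ref, alt in self.variants:
            if pos > r:
                parts.append(ref_seq[r:pos])
                ops.append(("M", r, pos - r, h, pos - r))
                h += pos - r
                r = pos
            if len(ref) == len(alt):
                parts.append(alt)
                ops.append(("M", r, len(ref), h, len(alt)))
            else:
                # anchored indel: shared first base, then pure I or D
                parts.append(alt)
                ops.append(("M", r, 1, h, 1))
                if len(ref) > len(alt):
                    ops.append(("D", r + 1, len(ref) - 1, h + 1, 0))
                else:
                    ops.append(("I", r + 1, 0, h + 1, len(alt) - 1))
            r += len(ref)
            h += len(alt)
        if r < len(ref_seq):
            parts.append(ref_seq[r:])
            ops.append(("M", r, len(ref_seq) - r, h, len(ref_seq) - r))
            h += len(ref_seq) - r
        self.seq = "".join(parts)
        self._ops = ops
        assert len(self.seq) == h

    def align_fragment(self, start: int, end: int) -> tuple[int, tuple[tuple[str, int], ...]]:
        """Reference start and CIGAR for haplotype interval [start, end).

        Leading/trailing partial insertions become soft clips, as an
        aligner would report them.
        """
        cigar: list[tuple[str, int]] = []
        ref_start = None
        for op, r0, rlen, h0, hlen in self._ops:
            if op == "D":
                if ref_start is not None and h0 < end:
                    cigar.append(("D", rlen))
                continue
            lo, hi = max(start, h0), min(end, h0 + hlen)
            if lo >= hi:
                continue
            if op == "M":
                if ref_start is None:
                    ref_start = r0 + (lo - h0)
                cigar.append(("M", hi - lo))
            else:  # I
                cigar.append(("I" if ref_start is not None else "S", hi - lo))
        # trailing D belongs only between matches; drop it if last
        while cigar and cigar[-1][0] == "D":
            cigar.pop()
        # trailing insertion with nothing after it: soft clip
        if cigar and cigar[-1][0] == "I":
            cigar[-1] = ("S", cigar[-1][1])
        merged: list[tuple[str, int]] = []
        for op, ln in cigar:
            if merged and merged[-1][0] == op:
                merged[-1] = (op, merged[-1][1] + ln)
            else:
                merged.append((op, ln))
        if ref_start is None:
            raise ValueError("fragment lies entirely within inserted sequence")
        return ref_start, tuple(merged)


@dataclass
class TruthVariant:
    """A simulated variant with its true genotypes (contig coordinates)."""

    position: int
    ref: str
    alleles: tuple[str, ...]
    per_copy: tuple[tuple[str, ...], ...]  # paralog-specific genotype
    per_hap: dict  # (copy_index, hap_index) -> allele
    at_psv: bool = False
    copy_refs: tuple[str, ...] | None = None  # per-copy reference alleles (PSVs)

    @property
    def aggregate(self) -> tuple[str, ...]:
        return canonical_genotype([a for copy in self.per_copy for a in copy])

    @property
    def is_snv(self) -> bool:
        return all(len(a) == 1 for a in self.alleles)


@dataclass
class SimSample:
    sample_id: str
    locus: SimLocus
    profile: CopyNumberProfile
    haplotypes: list[Haplotype]
    truth: list[TruthVariant]


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def simulate_locus(
    config: SimConfig,
    locus_id: str = "locus1",
    rng: np.random.Generator | None = None,
) -> SimLocus:
    """Generate repeat-copy contigs, the homology map and the PSV table.

    Copies share an identical core except at PSV columns (substitutions,
    so the inter-copy alignment is gap-free); each contig adds
    copy-private random flanks emulating the surrounding non-duplicated
    genome.
    """
    rng = rng or np.random.default_rng(config.seed)
    n, L, fl = config.n_copies, config.copy_length, config.flank
    core = _random_seq(rng, L)
    n_psv = min(int(rng.poisson(L * (1.0 - config.similarity))), L)
    psv_offsets = np.sort(rng.choice(L, size=n_psv, replace=False))
    contig_names = [f"{locus_id}_copy{i}" for i in range(n)]
    cores = [bytearray(core.encode()) for _ in range(n)]
    psvs: list[PSVRecord] = []
    copies = [
        CopyInterval(f"copy{i}", contig_names[i], fl, fl + L) for i in range(n)
    ]
    columns = np.tile(np.arange(fl, fl + L)[:, None], (1, n))
    hmap = HomologyMap(copies, columns)
    for off in psv_offsets:
        ref_base = core[off]
        alt_base = chr(rng.choice([b for b in _BASES if chr(b) != ref_base]))
        if n == 2:
            diff = [1]
        else:
            k = 1 + int(rng.integers(0, n - 1))
            diff = sorted(rng.choice(np.arange(1, n), size=k, replace=False))
        for i in diff:
            cores[i][off] = ord(alt_base)
        ref_alleles = tuple(alt_base if i in diff else ref_base for i in range(n))
        if config.fixed_psv_freq is not None:
            freqs = (config.fixed_psv_freq,) * n
        else:
            freqs = tuple(_draw_freq(rng, config.psv_freq_mix) for _ in range(n))
        psvs.append(
            PSVRecord(
                site=ParalogousSite(
                    copy_positions=tuple(
                        (f"copy{i}", contig_names[i], fl + int(off))
                        for i in range(n)
                    ),
                    ref_alleles=ref_alleles,
                ),
                freqs=freqs,
            )
        )
    contig_seqs = [
        _random_seq(rng, fl) + bytes(cores[i]).decode() + _random_seq(rng, fl)
        for i in range(n)
    ]
    return SimLocus(
        locus_id=locus_id,
        config=config,
        contig_names=contig_names,
        contig_seqs=contig_seqs,
        hmap=hmap,
        psvs=psvs,
    )


def _draw_freq(rng: np.random.Generator, mix) -> float:
    weights = np.array([w for w, _, _ in mix])
    k = rng.choice(len(mix), p=weights / weights.sum())
    _, lo, hi = mix[k]
    f = float(rng.uniform(lo, hi))
    return min(max(f, 1e-4), 1.0 - 1e-4)


def simulate_sample(
    locus: SimLocus,
    sample_id: str = "sample1",
    rng: np.random.Generator | None = None,
) -> SimSample:
    """Draw one sample: PSV realisations, artificial variants, haplotypes.

    Variants are placed at rate ``variant_rate`` per core base with a
    minimum spacing so alleles never overlap; each is heterozygous (one
    haplotype of one copy) with probability ``het_fraction``, else
    homozygous within its copy.  Truth records include realised
    polymorphic PSVs whose paralog genotype differs from the reference.
    """
    config = locus.config
    rng = rng or np.random.default_rng(config.seed + 1)
    n = config.n_copies
    pscn = config.pscn
    core_start, core_end = locus.core
    L = core_end - core_start
    rep = locus.rep_seq

    hap_variants: dict[tuple[int, int], dict[int, tuple[str, str]]] = {
        (i, h): {} for i in range(n) for h in range(pscn[i])
    }
    truth: list[TruthVariant] = []

    # -- polymorphic PSV realisation -------------------------------------
    psv_pos = set()
    for psv in locus.psvs:
        pos = psv.site.rep_position
        psv_pos.add(pos)
        refs = psv.site.ref_alleles
        alleles = sorted(set(refs), key=lambda a: (len(a), a))
        per_hap: dict = {}
        nonref = False
        for i in range(n):
            others = [a for a in alleles if a != refs[i]]
            for h in range(pscn[i]):
                if rng.random() < psv.freqs[i]:
                    allele = refs[i]
                else:
                    allele = others[int(rng.integers(0, len(others)))]
                    nonref = True
                per_hap[(i, h)] = allele
                if allele != refs[i]:
                    # against the copy's own contig base
                    hap_variants[(i, h)][pos] = (refs[i], allele)
        if nonref:
            truth.append(
                TruthVariant(
                    position=pos,
                    ref=rep[pos],
                    alleles=tuple(alleles),
                    copy_refs=refs,
                    per_copy=tuple(
                        tuple(sorted(per_hap[(i, h)] for h in range(pscn[i])))
                        for i in range(n)
                    ),
                    per_hap=per_hap,
                    at_psv=True,
                )
            )

    # -- artificial sequence variants ------------------------------------
    n_var = int(rng.poisson(L * config.variant_rate))
    spacing = config.max_indel_len + 2
    candidates = np.sort(rng.choice(L - 2 * spacing, size=min(n_var, L // (2 * spacing)), replace=False)) + spacing
    positions: list[int] = []
    for off in candidates:
        pos = core_start + int(off)
        if positions and pos - positions[-1] < spacing:
            continue
        if config.discard_variants_on_psvs and any(
            pos - config.max_indel_len <= p <= pos + config.max_indel_len
            for p in psv_pos
        ):
            continue
        positions.append(pos)

    for pos in positions:
        kind = rng.choice(3, p=config.type_mix)
        ref_base = rep[pos]
        if kind == 0:
            ref, alt = ref_base, chr(
                rng.choice([b for b in _BASES if chr(b) != ref_base])
            )
        elif kind == 1:
            ln = 1 + int(rng.integers(0, config.max_indel_len))
            ref, alt = ref_base, ref_base + _random_seq(rng, ln)
        else:
            ln = 1 + int(rng.integers(0, config.max_indel_len))
            ref, alt = rep[pos : pos + ln + 1], ref_base
        npos, nref, nalt = normalize_variant(pos, ref, alt, rep)
        copy = int(rng.choice(n, p=np.array(pscn) / sum(pscn)))
        het = rng.random() < config.het_fraction
        carriers = (
            [(copy, int(rng.integers(0, pscn[copy])))]
            if het
            else [(copy, h) for h in range(pscn[copy])]
        )
        per_hap = {}
        for i in range(n):
            for h in range(pscn[i]):
                allele = nalt if (i, h) in carriers else nref
                per_hap[(i, h)] = allele
                if allele != nref:
                    hap_variants[(i, h)][npos] = (nref, nalt)
        truth.append(
            TruthVariant(
                position=npos,
                ref=nref,
                alleles=(nref, nalt),
                per_copy=tuple(
                    tuple(sorted((per_hap[(i, h)] for h in range(pscn[i])),
                                 key=lambda a: (len(a), a)))
                    for i in range(n)
                ),
                per_hap=per_hap,
            )
        )

    haplotypes: list[Haplotype] = []
    for i in range(n):
        for h in range(pscn[i]):
            variants = sorted(
                (pos, ref, alt) for pos, (ref, alt) in hap_variants[(i, h)].items()
            )
            # per-copy coordinates equal representative coordinates, but
            # alleles must be rewritten against the copy's own contig
            contig = locus.contig_seqs[i]
            adj = [
                (pos, contig[pos : pos + len(ref)], alt)
                if contig[pos : pos + len(ref)] != ref and len(ref) == len(alt) == 1
                else (pos, ref, alt)
                for pos, ref, alt in variants
            ]
            hap = Haplotype(copy_index=i, hap_index=h, variants=adj)
            hap.build(contig)
            haplotypes.append(hap)

    profile = CopyNumberProfile(
        sample_id=sample_id, pscn=tuple(pscn), agcn=sum(pscn)
    )
    truth.sort(key=lambda t: t.position)
    return SimSample(
        sample_id=sample_id,
        locus=locus,
        profile=profile,
        haplotypes=haplotypes,
        truth=truth,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _bases_at(
    ref_start: int, cigar, seq: str, wanted: np.ndarray
) -> list[tuple[int, str]]:
    """(position, base) for reference positions in ``wanted`` covered by M ops."""
    out = []
    r, q = ref_start, 0
    for op, ln in cigar:
        if op == "M":
            lo = int(np.searchsorted(wanted, r))
            hi = int(np.searchsorted(wanted, r + ln))
            for k in range(lo, hi):
                p = int(wanted[k])
                out.append((p, seq[q + p - r]))
            r += ln
            q += ln
        elif op in ("I", "S"):
            q += ln
        elif op == "D":
            r += ln
    return out


def simulate_reads(
    sample: SimSample,
    rng: np.random.Generator | None = None,
) -> list[AlignedRead]:
    """Paired-end reads with substitution errors and emulated mapping.

    Fragments are uniform per haplotype at per-haplotype coverage
    ``depth / 2``.  The reported alignment copy follows PSV evidence in
    the (error-bearing) read bases: best-matching copy for PSV-covering
    pairs, uniform random copy otherwise, true copy when the pair touches
    a copy-private flank.  The true copy and haplotype are kept in the
    read name (``pair:COPY:HAP:INDEX``).
    """
    locus = sample.locus
    config = locus.config
    rng = rng or np.random.default_rng(config.seed + 2)
    rl = config.read_length
    psv_pos = locus.psv_positions()
    psv_alleles = [p.site.ref_alleles for p in locus.psvs]
    core_start, core_end = locus.core
    reads: list[AlignedRead] = []
    for hap in sample.haplotypes:
        hap_len = len(hap.seq)
        n_frag = int(round(config.depth / 2.0 * hap_len / (2.0 * rl)))
        for k in range(n_frag):
            frag = int(round(rng.normal(config.fragment_mean, config.fragment_sd)))
            frag = max(frag, 2 * rl)
            frag = min(frag, hap_len)
            start = int(rng.integers(0, hap_len - frag + 1))
            name = f"{locus.locus_id}:{hap.copy_index}:{hap.hap_index}:{k}"
            mates = []
            for mate, (s, e, rev) in enumerate(
                ((start, start + rl, False), (start + frag - rl, start + frag, True)),
                start=1,
            ):
                try:
                    ref_start, cigar = hap.align_fragment(s, e)
                except ValueError:
                    continue
                seq = hap.seq[s:e]
                if config.error_rate > 0:
                    arr = bytearray(seq.encode())
                    n_err = rng.binomial(len(arr), config.error_rate)
                    for j in rng.choice(len(arr), size=n_err, replace=False):
                        arr[j] = int(
                            rng.choice([b for b in _BASES if b != arr[j]])
                        )
                    seq = bytes(arr).decode()
                mates.append((mate, ref_start, cigar, seq, rev))
            if not mates:
                continue
            # -- mapping emulation, at pair level -------------------------
            touches_flank = any(
                ref_start < core_start
                or _ref_end(ref_start, cigar) > core_end
                for _, ref_start, cigar, _, _ in mates
            )
            if touches_flank:
                copy = hap.copy_index
            else:
                scores = np.zeros(config.n_copies)
                covered = False
                for _, ref_start, cigar, seq, _ in mates:
                    for pos, base in _bases_at(ref_start, cigar, seq, psv_pos):
                        covered = True
                        idx = int(np.searchsorted(psv_pos, pos))
                        for i, allele in enumerate(psv_alleles[idx]):
                            scores[i] += base == allele
                if covered:
                    best = np.flatnonzero(scores == scores.max())
                    copy = int(best[rng.integers(0, best.size)])
                else:
                    copy = int(rng.integers(0, config.n_copies))
            for mate, ref_start, cigar, seq, rev in mates:
                reads.append(
                    AlignedRead(
                        name=name,
                        copy_index=copy,
                        start=ref_start,
                        cigar=cigar,
                        seq=seq,
                        quals=np.full(len(seq), config.base_quality, dtype=np.int16),
                        is_reverse=rev,
                        mate=mate,
                    )
                )
    return reads


def _ref_end(ref_start: int, cigar) -> int:
    return ref_start + sum(ln for op, ln in cigar if op in ("M", "D"))
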