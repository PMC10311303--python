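"""On-disk formats and locus-eligibility logic.

Tab-separated tables (copy-number profiles, PSV tables, manifests) use
``#``-prefixed headers and UTF-8.  Variant output is VCF 4.2 with the
paralog-specific genotype in a custom ``PGT`` FORMAT field: per-copy
genotypes (allele indices into REF+ALT, ``/``-joined) joined by ``|`` in
homology-map copy order, e.g. ``0/1|0/0`` for a two-copy locus with the
alternate allele on the first copy.  Standard ``GT`` carries the pooled
aggregate genotype of ploidy ``agcn``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import CopyNumberProfile, ParalogousSite, PSVRecord

logger = logging.getLogger(__name__)

__all__ = [
    "read_copy_number_profiles",
    "write_copy_number_profiles",
    "read_psv_table",
    "write_psv_table",
    "write_fasta",
    "read_fasta",
    "write_sam",
    "VcfRecord",
    "write_vcf",
    "read_vcf",
    "calls_to_vcf_records",
    "truth_to_vcf_records",
    "LocusStatus",
    "assess_locus",
    "write_manifest",
    "read_manifest",
    "extended_copy_profile",
]


# ---------------------------------------------------------------------------
# copy-number profiles
# ---------------------------------------------------------------------------


def read_copy_number_profiles(path) -> dict[tuple[str, str], CopyNumberProfile]:
    """Parse a copy-number TSV into ``{(sample, locus): profile}``.

    Columns: sample, locus, pscn (comma-separated integers, ``?`` for
    unknown copies), optional agcn.  When both pscn and agcn are given
    they are cross-checked.
    """
    out: dict[tuple[str, str], CopyNumberProfile] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: expected >= 3 columns")
            sample, locus, pscn_str = parts[0], parts[1], parts[2]
            pscn: list[int | None] = []
            for tok in pscn_str.split(","):
                if tok == "?":
                    pscn.append(None)
                else:
                    try:
                        pscn.append(int(tok))
                    except ValueError as exc:
                        raise ValueError(
                            f"{path}:{ln}: malformed copy number {tok!r}"
                        ) from exc
            known = sum(c for c in pscn if c is not None)
            if len(parts) > 3 and parts[3] not in ("", "."):
                try:
                    agcn = int(parts[3])
                except ValueError as exc:
                    raise ValueError(f"{path}:{ln}: malformed agcn") from exc
                if None not in pscn and agcn != known:
                    raise ValueError(
                        f"{path}:{ln}: agcn {agcn} != sum(pscn) {known}"
                    )
            else:
                if None in pscn:
                    raise ValueError(
                        f"{path}:{ln}: agcn required when pscn has unknowns"
                    )
                agcn = known
            out[(sample, locus)] = CopyNumberProfile(
                sample_id=sample, pscn=tuple(pscn), agcn=agcn
            )
    return out


def write_copy_number_profiles(profiles: dict, path) -> None:
    with open(path, "w") as fh:
        fh.write("#sample\tlocus\tpscn\tagcn\n")
        for (sample, locus), prof in sorted(profiles.items()):
            pscn = ",".join("?" if c is None else str(c) for c in prof.pscn)
            fh.write(f"{sample}\t{locus}\t{pscn}\t{prof.agcn}\n")


def extended_copy_profile(
    profile: CopyNumberProfile,
) -> tuple[CopyNumberProfile, list[int]]:
    """Merge copies with unknown copy number into one pseudo-copy.

    The pseudo-copy's copy number is ``agcn`` minus the known copies'
    total; variants assigned to it receive aggregate genotypes only.
    This is a documented approximation for loci where copy-number
    estimation resolved only part of the repeat.  Returns the merged
    profile and the indices of the merged copies.
    """
    if profile.fully_known:
        return profile, []
    merged = [i for i, c in enumerate(profile.pscn) if c is None]
    known = [c for c in profile.pscn if c is not None]
    pseudo = profile.agcn - sum(known)
    if pseudo < 0:
        raise ValueError("known copy numbers exceed agcn")
    return (
        CopyNumberProfile(
            sample_id=profile.sample_id,
            pscn=tuple(known) + (pseudo,),
            agcn=profile.agcn,
        ),
        merged,
    )


# ---------------------------------------------------------------------------
# PSV tables
# ---------------------------------------------------------------------------


def write_psv_table(psvs_by_locus: dict[str, list[PSVRecord]], path) -> None:
    """One row per PSV: per-copy positions, reference alleles, frequencies."""
    with open(path, "w") as fh:
        fh.write("#locus\tpositions\tref_alleles\tfreqs\n")
        for locus in sorted(psvs_by_locus):
            for psv in psvs_by_locus[locus]:
                pos = ",".join(
                    f"{contig}:{p}" for _, contig, p in psv.site.copy_positions
                )
                refs = ",".join(psv.site.ref_alleles)
                freqs = ",".join(f"{f:.6g}" for f in psv.freqs)
                fh.write(f"{locus}\t{pos}\t{refs}\t{freqs}\n")


def read_psv_table(path) -> dict[str, list[PSVRecord]]:
    out: dict[str, list[PSVRecord]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                locus, pos_s, refs_s, freqs_s = line.split("\t")
                positions = []
                for k, tok in enumerate(pos_s.split(",")):
                    contig, p = tok.rsplit(":", 1)
                    positions.append((f"copy{k}", contig, int(p)))
                refs = tuple(refs_s.split(","))
                freqs = tuple(float(f) for f in freqs_s.split(","))
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed PSV row") from exc
            out.setdefault(locus, []).append(
                PSVRecord(
                    site=ParalogousSite(
                        copy_positions=tuple(positions), ref_alleles=refs
                    ),
                    freqs=freqs,
                )
            )
    return out


# ---------------------------------------------------------------------------
# FASTA / SAM
# ---------------------------------------------------------------------------


def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    import pysam

    with pysam.FastxFile(str(path)) as fh:
        return {entry.name: entry.sequence for entry in fh}


def write_sam(reads, contigs: dict[str, int], path) -> None:
    """Write simulated alignments as plain-text SAM with truth tags.

    Read names of the form ``locus:COPY:HAP:INDEX`` get their true copy
    and haplotype stored in ``tc``/``th`` tags.
    """
    import pysam

    names = list(contigs)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [{"SN": n, "LN": contigs[n]} for n in names],
        }
    )
    by_name: dict[str, list] = {}
    for r in reads:
        by_name.setdefault(r.name, []).append(r)
    with pysam.AlignmentFile(str(path), "wh", header=header) as fh:
        for name in by_name:
            group = by_name[name]
            for r in group:
                a = pysam.AlignedSegment(header)
                a.query_name = r.name
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    "".join(chr(q + 33) for q in r.quals)
                )
                a.reference_id = r.copy_index
                a.reference_start = r.start
                a.mapping_quality = 0
                a.cigarstring = "".join(f"{ln}{op}" for op, ln in r.cigar)
                flag = 0x1
                if r.is_reverse:
                    flag |= 0x10
                flag |= 0x40 if r.mate == 1 else 0x80
                other = [m for m in group if m.mate != r.mate]
                if other:
                    m = other[0]
                    a.next_reference_id = m.copy_index
                    a.next_reference_start = m.start
                    if m.is_reverse:
                        flag |= 0x20
                else:
                    a.next_reference_id = -1
                    a.next_reference_start = -1
                    flag |= 0x8
                a.flag = flag
                parts = r.name.split(":")
                if len(parts) == 4 and parts[1].isdigit() and parts[2].isdigit():
                    a.set_tag("tc", int(parts[1]))
                    a.set_tag("th", int(parts[2]))
                fh.write(a)


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER_LINES = [
    '##FILTER=<ID=StrandBias,Description="Fisher exact strand-bias p below threshold">',
    '##FILTER=<ID=LowQual,Description="Variant quality below the recommended threshold">',
    '##INFO=<ID=PSV,Number=0,Type=Flag,Description="Site is a paralogous sequence variant">',
    '##INFO=<ID=CREF,Number=.,Type=String,Description="Per-copy reference alleles in homology-map copy order">',
    '##INFO=<ID=AGQ,Number=1,Type=Float,Description="Aggregate genotype quality (Phred vs reference aggregate genotype)">',
    '##INFO=<ID=SB,Number=1,Type=Float,Description="Strand-bias Fisher exact p-value">',
    '##INFO=<ID=RESOLVED,Number=0,Type=Flag,Description="Paralog-specific genotype was inferred">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Aggregate (pooled) genotype of ploidy agcn">',
    '##FORMAT=<ID=PGT,Number=1,Type=String,Description="Paralog-specific genotype: per-copy genotypes joined by |, copy order as in the homology map; . when unresolved">',
    '##FORMAT=<ID=CGQ,Number=.,Type=Integer,Description="Per-copy genotype qualities (Phred), homology-map copy order">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Pooled read-pair depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Pooled allelic depths (REF first)">',
]


@dataclass
class VcfRecord:
    """One VCF data line in 0-based in-memory form."""

    contig: str
    pos: int
    ref: str
    alts: tuple[str, ...]
    qual: float | None = None
    filters: tuple[str, ...] = ()  # empty means PASS
    info: dict = field(default_factory=dict)
    sample: dict = field(default_factory=dict)

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts

    def genotype_alleles(self, key: str = "GT") -> tuple[str, ...] | None:
        """Aggregate genotype as sorted allele strings, or None if missing."""
        gt = self.sample.get(key)
        if gt in (None, "."):
            return None
        idx = [int(i) for i in str(gt).replace("|", "/").split("/") if i != "."]
        return tuple(sorted((self.alleles[i] for i in idx), key=lambda a: (len(a), a)))

    def paralog_alleles(self) -> tuple[tuple[str, ...], ...] | None:
        pgt = self.sample.get("PGT")
        if pgt in (None, "."):
            return None
        out = []
        for copy_gt in str(pgt).split("|"):
            if copy_gt in ("", "."):
                out.append(())
                continue
            idx = [int(i) for i in copy_gt.split("/")]
            out.append(
                tuple(sorted((self.alleles[i] for i in idx), key=lambda a: (len(a), a)))
            )
        return tuple(out)


def _fmt_info(info: dict) -> str:
    if not info:
        return "."
    parts = []
    for k, v in info.items():
        if v is True:
            parts.append(k)
        elif isinstance(v, float):
            parts.append(f"{k}={v:.6g}")
        elif isinstance(v, (list, tuple)):
            parts.append(f"{k}={','.join(map(str, v))}")
        else:
            parts.append(f"{k}={v}")
    return ";".join(parts)


def write_vcf(
    records: list[VcfRecord],
    contigs: dict[str, int],
    sample_id: str,
    path,
) -> None:
    """Write VCF 4.2; records must be coordinate-sorted within contigs."""
    last: dict[str, int] = {}
    for rec in records:
        if rec.contig in last and rec.pos < last[rec.contig]:
            raise ValueError(
                f"unsorted input: {rec.contig}:{rec.pos + 1} after "
                f"{rec.contig}:{last[rec.contig] + 1}"
            )
        last[rec.contig] = rec.pos
    fmt_keys = ["GT", "PGT", "CGQ", "DP", "AD"]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lcrcall\n")
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        for line in _VCF_HEADER_LINES:
            fh.write(line + "\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + sample_id
            + "\n"
        )
        for rec in records:
            alt = ",".join(rec.alts) if rec.alts else "."
            qual = "." if rec.qual is None else f"{rec.qual:.6g}"
            filt = "PASS" if not rec.filters else ";".join(rec.filters)
            keys = [k for k in fmt_keys if k in rec.sample]
            fmt = ":".join(keys) if keys else "."
            vals = (
                ":".join(_fmt_sample(rec.sample[k]) for k in keys) if keys else "."
            )
            fh.write(
                f"{rec.contig}\t{rec.pos + 1}\t.\t{rec.ref}\t{alt}\t{qual}\t"
                f"{filt}\t{_fmt_info(rec.info)}\t{fmt}\t{vals}\n"
            )


def _fmt_sample(v) -> str:
    if isinstance(v, (list, tuple)):
        return ",".join(map(str, v))
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def read_vcf(path) -> tuple[list[VcfRecord], str]:
    """Read a VCF written by this package back into records."""
    import pysam

    records: list[VcfRecord] = []
    with pysam.VariantFile(str(path)) as vf:
        sample_id = list(vf.header.samples)[0] if list(vf.header.samples) else ""
        for rec in vf:
            info = {}
            for k, v in rec.info.items():
                if isinstance(v, tuple):
                    v = list(v)
                info[k] = v
            sample = {}
            if sample_id:
                s = rec.samples[sample_id]
                for k in s.keys():
                    v = s[k]
                    if k == "GT":
                        # stored as custom string ploidy; pysam returns tuple
                        v = "/".join(
                            "." if a is None else str(a) for a in s["GT"]
                        )
                    elif isinstance(v, tuple):
                        v = list(v)
                    if v is not None:
                        sample[k] = v
            filters = tuple(f for f in rec.filter.keys() if f != "PASS")
            records.append(
                VcfRecord(
                    contig=rec.contig,
                    pos=rec.pos - 1,
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    qual=rec.qual,
                    filters=filters,
                    info=info,
                    sample=sample,
                )
            )
    return records, sample_id


def calls_to_vcf_records(result, hmap) -> list[VcfRecord]:
    """Convert a locus result into VCF records on the representative contig."""
    contig = hmap.representative.contig
    out: list[VcfRecord] = []
    for call in result.calls:
        alleles = list(call.site.alleles)
        ref = call.site.ref
        alts = tuple(a for a in alleles if a != ref)
        index = {a: i for i, a in enumerate((ref,) + alts)}
        info: dict = {"AGQ": round(call.agg_qual, 2), "SB": call.strand_p}
        if call.site.is_psv:
            info["PSV"] = True
            info["CREF"] = list(call.site.copy_refs)
        if call.resolved:
            info["RESOLVED"] = True
        gt = "/".join(
            str(index[a]) for a in call.aggregate_genotype
        )
        sample = {
            "GT": gt,
            "DP": int(call.depths.sum()),
            "AD": [int(call.depths[alleles.index(a)]) for a in (ref,) + alts],
        }
        pg = call.paralog_genotype
        if pg is not None:
            sample["PGT"] = "|".join(
                "/".join(str(index[a]) for a in copy_gt) if copy_gt else "."
                for copy_gt in pg
            )
            sample["CGQ"] = [int(round(q)) for q in call.copy_gq]
        else:
            sample["PGT"] = "."
        out.append(
            VcfRecord(
                contig=contig,
                pos=call.position,
                ref=ref,
                alts=alts,
                qual=call.qual,
                filters=tuple(call.filters),
                info=info,
                sample=sample,
            )
        )
    return out


def truth_to_vcf_records(sim_sample) -> list[VcfRecord]:
    """Truth variants of a simulated sample as VCF records."""
    locus = sim_sample.locus
    contig = locus.contig_names[0]
    out: list[VcfRecord] = []
    for tv in sim_sample.truth:
        # PSV sites list every copy's reference allele so that
        # gene-conversion-like genotypes are expressible relative to it
        extra = set(tv.copy_refs or ())
        alleles_used = sorted(
            {a for copy in tv.per_copy for a in copy} | {tv.ref} | extra,
            key=lambda a: (len(a), a),
        )
        ref = tv.ref
        alts = tuple(a for a in alleles_used if a != ref)
        index = {a: i for i, a in enumerate((ref,) + alts)}
        info: dict = {}
        if tv.at_psv:
            info["PSV"] = True
            if tv.copy_refs:
                info["CREF"] = list(tv.copy_refs)
        sample = {
            "GT": "/".join(str(index[a]) for a in tv.aggregate),
            "PGT": "|".join(
                "/".join(str(index[a]) for a in copy_gt) if copy_gt else "."
                for copy_gt in tv.per_copy
            ),
        }
        out.append(
            VcfRecord(
                contig=contig,
                pos=tv.position,
                ref=ref,
                alts=alts,
                qual=None,
                info=info,
                sample=sample,
            )
        )
    out.sort(key=lambda r: r.pos)
    return out


# ---------------------------------------------------------------------------
# locus manifest / eligibility
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocusStatus:
    locus_id: str
    status: str  # callable | aggregate_only | skipped
    reason: str = ""


def assess_locus(
    locus_id: str,
    profile: CopyNumberProfile | None,
    n_copies: int,
    benchmark_mode: bool = False,
    max_copies: int = 4,
) -> LocusStatus:
    """Eligibility of a locus for paralog-specific calling.

    Loci with too many copies or without any copy-number estimate are
    skipped.  Partially known copy numbers demote the locus to
    aggregate-only (extended-copy) calling — or skip it entirely in
    benchmark mode, which additionally requires every copy at the
    diploid copy number 2.
    """
    if profile is None:
        return LocusStatus(locus_id, "skipped", "pscn_unavailable")
    if n_copies > max_copies:
        return LocusStatus(locus_id, "skipped", "too_many_copies")
    if not profile.fully_known:
        if benchmark_mode:
            return LocusStatus(locus_id, "skipped", "pscn_unavailable")
        return LocusStatus(locus_id, "aggregate_only", "pscn_partially_unknown")
    if benchmark_mode and any(c != 2 for c in profile.known_pscn):
        return LocusStatus(locus_id, "skipped", "nonreference_pscn")
    return LocusStatus(locus_id, "callable", "")


def write_manifest(rows: list[LocusStatus], path) -> None:
    with open(path, "w") as fh:
        fh.write("#locus\tstatus\treason\n")
        for row in rows:
            fh.write(f"{row.locus_id}\t{row.status}\t{row.reason or '.'}\n")


def read_manifest(path) -> list[LocusStatus]:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            locus, status, reason = line.split("\t")
            rows.append(
                LocusStatus(locus, status, "" if reason == "." else reason)
            )
    return rows
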