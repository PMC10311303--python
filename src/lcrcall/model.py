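"""Domain types and genotype-space combinatorics for multilocus variant calling.

A low-copy repeat (LCR) locus consists of ``n >= 2`` homologous repeat
copies.  Because short reads cannot be reliably assigned to an individual
copy, variants are modelled jointly across copies:

* a *paralogous site* is an n-tuple of genomic positions (one per copy)
  related through the multiple sequence alignment of the copies;
* the *aggregate genotype* at a site is an unordered multiset of
  ``agcn`` alleles pooled over all copies, where ``agcn`` is the sample's
  aggregate copy number;
* a *paralog-specific genotype* distributes that multiset into per-copy
  multisets whose sizes are the paralog-specific copy numbers ``pscn``.

Alleles are plain strings.  Genotypes are stored as canonically sorted
tuples so that enumeration order (and therefore every downstream argmax
tie-break) is deterministic: alleles compare by ``(length, lexicographic)``
and genotypes compare lexicographically over their sorted allele keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb
from typing import Iterator, Sequence

__all__ = [
    "allele_key",
    "sort_alleles",
    "multiplicity",
    "enumerate_aggregate_genotypes",
    "enumerate_paralog_genotypes",
    "flatten_paralog_genotype",
    "reference_compatible",
    "reference_paralog_genotype",
    "ParalogousSite",
    "PSVRecord",
    "CopyNumberProfile",
]

# An aggregate genotype is a sorted tuple of allele strings; a paralog
# genotype is a tuple of sorted per-copy tuples.
AggregateGenotype = tuple[str, ...]
ParalogGenotype = tuple[tuple[str, ...], ...]


def allele_key(allele: str) -> tuple[int, str]:
    """Canonical sort key for alleles: by length, then lexicographically."""
    return (len(allele), allele)


def sort_alleles(alleles: Sequence[str]) -> list[str]:
    """Distinct alleles in canonical order."""
    return sorted(set(alleles), key=allele_key)


def multiplicity(allele: str, genotype: Sequence[str]) -> int:
    """Number of occurrences of ``allele`` in the genotype multiset (mu)."""
    return sum(1 for a in genotype if a == allele)


def canonical_genotype(alleles: Sequence[str]) -> AggregateGenotype:
    """Sort a multiset of alleles into canonical tuple form."""
    return tuple(sorted(alleles, key=allele_key))


def enumerate_aggregate_genotypes(
    alleles: Sequence[str], agcn: int
) -> list[AggregateGenotype]:
    """All multisets of ``agcn`` alleles drawn from ``alleles``.

    The number of genotypes is the multiset coefficient
    ``C(agcn + |A| - 1, |A| - 1)``.  Output order is deterministic:
    lexicographic over indices into the canonically sorted allele list.
    """
    if agcn <= 0:
        raise ValueError(f"aggregate copy number must be >= 1, got {agcn}")
    distinct = sort_alleles(alleles)
    if not distinct:
        raise ValueError("allele set must be non-empty")
    k = len(distinct)
    out: list[AggregateGenotype] = []

    def rec(idx: int, remaining: int, acc: list[str]) -> None:
        if idx == k - 1:
            out.append(tuple(acc + [distinct[idx]] * remaining))
            return
        for take in range(remaining + 1):
            rec(idx + 1, remaining - take, acc + [distinct[idx]] * take)

    rec(0, agcn, [])
    assert len(out) == comb(agcn + k - 1, k - 1)
    return out


def _compositions(total: int, caps: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All ways to split ``total`` into len(caps) parts with part i <= caps[i]."""
    n = len(caps)

    def rec(i: int, left: int, acc: list[int]) -> Iterator[tuple[int, ...]]:
        if i == n - 1:
            if left <= caps[i]:
                yield tuple(acc + [left])
            return
        for take in range(min(left, caps[i]) + 1):
            yield from rec(i + 1, left - take, acc + [take])

    yield from rec(0, total, [])


def enumerate_paralog_genotypes(
    aggregate: Sequence[str], pscn: Sequence[int]
) -> list[ParalogGenotype]:
    """All distinct distributions of an aggregate genotype over repeat copies.

    Copy ``i`` receives a multiset of exactly ``pscn[i]`` alleles; the
    per-copy multisets flatten back to the aggregate.  Enumeration walks
    allele counts per copy, so permutations of equal alleles are never
    produced twice.
    """
    aggregate = canonical_genotype(aggregate)
    if len(aggregate) != sum(pscn):
        raise ValueError(
            f"aggregate size {len(aggregate)} != sum(pscn) {sum(pscn)}"
        )
    distinct = sort_alleles(aggregate)
    counts = [multiplicity(a, aggregate) for a in distinct]
    n = len(pscn)
    out: list[ParalogGenotype] = []

    def rec(copy_idx: int, remaining: list[int], acc: list[tuple[str, ...]]) -> None:
        if copy_idx == n:
            if all(c == 0 for c in remaining):
                out.append(tuple(acc))
            return
        cap = pscn[copy_idx]
        for split in _compositions(cap, remaining):
            copy_gt = tuple(
                a for a, m in zip(distinct, split) for _ in range(m)
            )
            rec(
                copy_idx + 1,
                [r - m for r, m in zip(remaining, split)],
                acc + [copy_gt],
            )

    rec(0, counts, [])
    return out


def flatten_paralog_genotype(genotype: ParalogGenotype) -> AggregateGenotype:
    """Combine per-copy multisets into the associated aggregate genotype."""
    return canonical_genotype([a for copy in genotype for a in copy])


def reference_compatible(
    genotype: ParalogGenotype, ref_alleles: Sequence[str]
) -> bool:
    """True iff every copy's multiset contains only that copy's reference allele."""
    return all(
        all(a == ref for a in copy_gt)
        for copy_gt, ref in zip(genotype, ref_alleles)
    )


def reference_paralog_genotype(
    ref_alleles: Sequence[str], pscn: Sequence[int]
) -> ParalogGenotype:
    """The unique reference-compatible paralog genotype for given copy numbers."""
    return tuple(
        (ref,) * c for ref, c in zip(ref_alleles, pscn)
    )


@dataclass(frozen=True)
class ParalogousSite:
    """A jointly-called site: one position and reference allele per repeat copy.

    ``copy_positions[i]`` is ``(copy_id, contig, 0-based position)`` for the
    i-th copy; ``ref_alleles[i]`` is that copy's reference allele.  The site
    is a PSV iff the copies' reference alleles are not all equal.
    """

    copy_positions: tuple[tuple[str, str, int], ...]
    ref_alleles: tuple[str, ...]
    allele_set: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if len(self.copy_positions) != len(self.ref_alleles):
            raise ValueError("copy_positions and ref_alleles length mismatch")
        if len(self.copy_positions) < 2:
            raise ValueError("a paralogous site needs >= 2 repeat copies")
        alleles = self.allele_set or tuple(sort_alleles(self.ref_alleles))
        object.__setattr__(self, "allele_set", tuple(sort_alleles(
            list(alleles) + list(self.ref_alleles)
        )))

    @property
    def n_copies(self) -> int:
        return len(self.copy_positions)

    @property
    def is_psv(self) -> bool:
        return len(set(self.ref_alleles)) > 1

    @property
    def rep_position(self) -> int:
        """Position on the representative (first) copy."""
        return self.copy_positions[0][2]


@dataclass(frozen=True)
class PSVRecord:
    """A PSV together with per-copy population reference-allele frequencies.

    ``freqs[i]`` is the population frequency of ``site.ref_alleles[i]`` on
    copy i; it is strictly inside (0, 1) because a PSV that is absolutely
    fixed would be encoded arbitrarily close to 1 (e.g. 0.9999) rather than
    exactly 1.  ``min_freq`` (f-tilde) is the minimum over copies and is the
    PSV's weight in the conflict-graph pruning step.
    """

    site: ParalogousSite
    freqs: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.site.is_psv:
            raise ValueError("PSVRecord requires a site whose copies differ")
        if len(self.freqs) != self.site.n_copies:
            raise ValueError("one frequency per repeat copy required")
        if not all(0.0 < f < 1.0 for f in self.freqs):
            raise ValueError(f"frequencies must lie in (0, 1): {self.freqs}")

    @property
    def min_freq(self) -> float:
        return min(self.freqs)


@dataclass(frozen=True)
class CopyNumberProfile:
    """Per-sample copy numbers for one locus.

    ``pscn[i]`` counts occurrences of repeat copy i in the sample's genome
    (``None`` when unknown); ``agcn`` is the total over all copies.
    """

    sample_id: str
    pscn: tuple[int | None, ...]
    agcn: int

    def __post_init__(self) -> None:
        known = [c for c in self.pscn if c is not None]
        if any(c < 0 for c in known):
            raise ValueError("paralog-specific copy numbers must be >= 0")
        if None not in self.pscn and self.agcn != sum(known):
            raise ValueError(
                f"agcn {self.agcn} != sum(pscn) {sum(known)}"
            )
        if self.agcn < 1:
            raise ValueError("aggregate copy number must be >= 1")

    @property
    def fully_known(self) -> bool:
        return None not in self.pscn

    @property
    def known_pscn(self) -> tuple[int, ...]:
        if not self.fully_known:
            raise ValueError("paralog-specific copy number partially unknown")
        return self.pscn  # type: ignore[return-value]
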