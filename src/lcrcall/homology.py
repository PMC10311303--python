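"""Homology map between repeat copies of an LCR locus.

The map is derived from a multiple sequence alignment (MSA) of the
copies' reference sequences.  Each alignment column records the aligned
position of every copy (or a gap), which lets reads aligned to any copy
be projected onto the *representative* copy (copy 0) for pooled calling,
and lets PSV candidate columns (differing residues) be extracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ParalogousSite

__all__ = ["CopyInterval", "HomologyMap", "build_homology_map", "psv_sites_from_msa"]

GAP = -1


@dataclass(frozen=True)
class CopyInterval:
    """Genomic interval of one repeat copy (0-based half-open)."""

    copy_id: str
    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval for copy {self.copy_id}")
        if self.strand != "+":
            raise NotImplementedError(
                "reverse-strand repeat copies are not supported; flip the "
                "copy's reference sequence before building the map"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class HomologyMap:
    """Column table aligning every copy position to the representative copy.

    ``columns`` has shape ``(n_columns, n_copies)``; entry ``(k, i)`` is
    the contig position of copy i in alignment column k, or -1 for a gap.
    Positions within each copy are strictly increasing over non-gap
    columns and cover the copy's interval exactly.
    """

    def __init__(self, copies: list[CopyInterval], columns: np.ndarray):
        columns = np.asarray(columns, dtype=np.int64)
        if columns.ndim != 2 or columns.shape[1] != len(copies):
            raise ValueError("columns must be (n_columns, n_copies)")
        if len(copies) < 2:
            raise ValueError("a homology map needs >= 2 copies")
        self.copies = list(copies)
        self.columns = columns
        self._pos2col: list[np.ndarray] = []
        for i, cp in enumerate(self.copies):
            col_pos = columns[:, i]
            nongap = col_pos != GAP
            pos = col_pos[nongap]
            if pos.size != cp.length or not np.array_equal(
                pos, np.arange(cp.start, cp.end)
            ):
                raise ValueError(
                    f"copy {cp.copy_id}: column positions must cover "
                    f"[{cp.start}, {cp.end}) in increasing order"
                )
            lut = np.full(cp.length, GAP, dtype=np.int64)
            lut[pos - cp.start] = np.nonzero(nongap)[0]
            self._pos2col.append(lut)
        # Gap-free identity fast path (all copies same length, no gaps).
        self.is_gapless = bool((columns != GAP).all())

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    @property
    def representative(self) -> CopyInterval:
        return self.copies[0]

    def copy_index(self, copy_id: str) -> int:
        for i, cp in enumerate(self.copies):
            if cp.copy_id == copy_id:
                return i
        raise KeyError(copy_id)

    def column_of(self, copy: int, positions: np.ndarray) -> np.ndarray:
        """Alignment column of each position of a copy (-1 outside interval)."""
        cp = self.copies[copy]
        positions = np.asarray(positions, dtype=np.int64)
        off = positions - cp.start
        inside = (off >= 0) & (off < cp.length)
        out = np.full(positions.shape, GAP, dtype=np.int64)
        out[inside] = self._pos2col[copy][off[inside]]
        return out

    def project(self, copy: int, positions, to_copy: int = 0) -> np.ndarray:
        """Positions of ``copy`` translated to ``to_copy`` (-1 where gapped)."""
        cols = self.column_of(copy, positions)
        out = np.full(cols.shape, GAP, dtype=np.int64)
        ok = cols != GAP
        out[ok] = self.columns[cols[ok], to_copy]
        return out

    # -- serialisation ----------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the map as a self-describing tab-separated table."""
        with open(path, "w") as fh:
            fh.write("##lcrcall homology map\n")
            fh.write("#copy\tcopy_id\tcontig\tstart\tend\tstrand\n")
            for cp in self.copies:
                fh.write(
                    f"copy\t{cp.copy_id}\t{cp.contig}\t{cp.start}\t{cp.end}\t{cp.strand}\n"
                )
            fh.write(
                "#column\t" + "\t".join(cp.copy_id for cp in self.copies) + "\n"
            )
            for row in self.columns:
                fh.write("column\t" + "\t".join(map(str, row)) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "HomologyMap":
        copies: list[CopyInterval] = []
        rows: list[list[int]] = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if parts[0] == "copy":
                    try:
                        copies.append(
                            CopyInterval(
                                parts[1], parts[2], int(parts[3]), int(parts[4]),
                                parts[5] if len(parts) > 5 else "+",
                            )
                        )
                    except (IndexError, ValueError) as exc:
                        raise ValueError(f"{path}:{ln}: bad copy line") from exc
                elif parts[0] == "column":
                    try:
                        rows.append([int(x) for x in parts[1:]])
                    except ValueError as exc:
                        raise ValueError(f"{path}:{ln}: bad column line") from exc
                else:
                    raise ValueError(f"{path}:{ln}: unknown record {parts[0]!r}")
        if not copies or not rows:
            raise ValueError(f"{path}: no copies or columns found")
        return cls(copies, np.array(rows, dtype=np.int64))


def build_homology_map(
    aligned: list[tuple[str, str]],
    contigs: list[str] | None = None,
    starts: list[int] | None = None,
) -> HomologyMap:
    """Build a homology map from an MSA of the copies' reference sequences.

    ``aligned`` is a list of ``(copy_id, aligned_sequence)`` rows of equal
    length ('-' marks gaps); the first row is the representative copy.
    ``contigs``/``starts`` default to the copy ids and 0.
    """
    if len(aligned) < 2:
        raise ValueError("need >= 2 aligned sequences")
    width = len(aligned[0][1])
    if any(len(seq) != width for _, seq in aligned):
        raise ValueError("ragged alignment: rows differ in length")
    contigs = contigs or [cid for cid, _ in aligned]
    starts = starts or [0] * len(aligned)
    n = len(aligned)
    columns = np.full((width, n), GAP, dtype=np.int64)
    cursors = list(starts)
    for k in range(width):
        for i, (_, seq) in enumerate(aligned):
            if seq[k] != "-":
                columns[k, i] = cursors[i]
                cursors[i] += 1
    copies = [
        CopyInterval(cid, contigs[i], starts[i], cursors[i])
        for i, (cid, _) in enumerate(aligned)
    ]
    return HomologyMap(copies, columns)


def psv_sites_from_msa(
    aligned: list[tuple[str, str]],
    hmap: HomologyMap | None = None,
) -> list[ParalogousSite]:
    """PSV candidate columns of an MSA: ungapped columns whose residues differ.

    Columns where any copy is gapped are skipped (indel paralog
    differences are better handled by dedicated indel-PSV records); the
    remaining differing columns become substitution PSV sites.
    """
    hmap = hmap or build_homology_map(aligned)
    sites: list[ParalogousSite] = []
    for k, row in enumerate(hmap.columns):
        if (row == GAP).any():
            continue
        residues = [seq[k].upper() for _, seq in aligned]
        if len(set(residues)) > 1:
            sites.append(
                ParalogousSite(
                    copy_positions=tuple(
                        (cp.copy_id, cp.contig, int(row[i]))
                        for i, cp in enumerate(hmap.copies)
                    ),
                    ref_alleles=tuple(residues),
                )
            )
    return sites
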