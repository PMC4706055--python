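"""Genomic intervals, read extraction and the standard text formats.

All coordinates are handled internally as 0-based half-open intervals;
user-facing reports (region tables, log messages) convert to 1-based
inclusive at the presentation layer.  The conversion helpers
:func:`to_one_based` / :func:`from_one_based` are the single point where
that happens.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(f"require 0 <= start < end, got [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


def to_one_based(iv: GenomicInterval) -> tuple[str, int, int]:
    """0-based half-open -> 1-based inclusive (for display)."""
    return iv.chrom, iv.start + 1, iv.end


def from_one_based(chrom: str, start1: int, end1: int, strand: str = ".") -> GenomicInterval:
    """1-based inclusive -> internal 0-based half-open."""
    return GenomicInterval(chrom, start1 - 1, end1, strand)


@dataclass(frozen=True)
class AlignedRead:
    """Minimal alignment record: a 5' position plus orientation.

    ``pos5`` is the 0-based position of the 5' end: the leftmost aligned
    base for forward-strand reads, the rightmost for reverse-strand reads.
    """

    chrom: str
    pos5: int
    length: int
    strand: str
    mapq: int
    is_dup: bool = False

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be + or -")


class _BlacklistIndex:
    """Sorted per-chromosome interval arrays for point-membership queries."""

    def __init__(self, intervals: Iterable[GenomicInterval]):
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for iv in intervals:
            by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
        self._index: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            # merge overlapping intervals so searchsorted is sound
            merged: list[list[int]] = []
            for s, e in ivs:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            starts = np.array([m[0] for m in merged], dtype=np.int64)
            ends = np.array([m[1] for m in merged], dtype=np.int64)
            self._index[chrom] = (starts, ends)

    def contains(self, chrom: str, pos: int) -> bool:
        entry = self._index.get(chrom)
        if entry is None:
            return False
        starts, ends = entry
        i = int(np.searchsorted(starts, pos, side="right")) - 1
        return i >= 0 and pos < ends[i]

    def contains_many(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        entry = self._index.get(chrom)
        if entry is None:
            return np.zeros(len(pos), dtype=bool)
        starts, ends = entry
        i = np.searchsorted(starts, pos, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(pos), dtype=bool)
        out[ok] = pos[ok] < ends[i[ok]]
        return out


@dataclass
class ReadFilter:
    """Read-extraction policy shared by every counting step.

    A read is used iff its MAPQ is at least ``minq``, its 5' position does
    not fall inside a blacklisted interval, its chromosome is in
    ``restrict`` (when given), and it is not a flagged duplicate unless
    ``use_dups``.  Duplicates are kept by default because the workflow
    only excludes them when estimating the fragment length.
    """

    minq: int = 50
    blacklist: Sequence[GenomicInterval] = field(default_factory=tuple)
    restrict: frozenset[str] | None = None
    use_dups: bool = True

    def __post_init__(self) -> None:
        if self.minq < 0:
            raise ValueError("minq must be >= 0")
        if self.restrict is not None:
            self.restrict = frozenset(self.restrict)
        self._bl = _BlacklistIndex(self.blacklist)

    def without_duplicates(self) -> "ReadFilter":
        return replace(self, use_dups=False)

    def keeps(self, read: AlignedRead) -> bool:
        if read.mapq < self.minq:
            return False
        if read.is_dup and not self.use_dups:
            return False
        if self.restrict is not None and read.chrom not in self.restrict:
            return False
        return not self._bl.contains(read.chrom, read.pos5)

    def chromosomes(self, bam_path: str) -> list[tuple[str, int]]:
        """Chromosomes (name, length) to process for one BAM, respecting restrict."""
        with pysam.AlignmentFile(str(bam_path), "rb") as bam:
            chroms = list(zip(bam.references, bam.lengths))
        if self.restrict is None:
            return chroms
        known = {c for c, _ in chroms}
        for name in sorted(self.restrict - known):
            warnings.warn(f"restricted chromosome {name!r} absent from BAM, skipped")
        return [(c, l) for c, l in chroms if c in self.restrict]


def _read_from_alignment(aln: pysam.AlignedSegment) -> AlignedRead:
    if aln.is_reverse:
        pos5 = aln.reference_end - 1
        strand = "-"
    else:
        pos5 = aln.reference_start
        strand = "+"
    return AlignedRead(
        chrom=aln.reference_name,
        pos5=pos5,
        length=aln.query_length or aln.infer_query_length() or 0,
        strand=strand,
        mapq=aln.mapping_quality,
        is_dup=aln.is_duplicate,
    )


def load_reads(
    bam_path: str,
    region: GenomicInterval | None = None,
    filter: ReadFilter | None = None,
) -> Iterator[AlignedRead]:
    """Stream filtered reads from a coordinate-sorted, indexed BAM.

    Unmapped, secondary and supplementary alignments are always skipped.
    The blacklist discard rule tests the read's 5' position against the
    blacklisted intervals.
    """
    rf = filter if filter is not None else ReadFilter(minq=0)
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        if region is not None:
            if not bam.has_index():
                raise FileNotFoundError(f"BAM index required for region queries: {bam_path}")
            it = bam.fetch(region.chrom, region.start, region.end)
        else:
            it = bam.fetch() if bam.has_index() else bam
        for aln in it:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            read = _read_from_alignment(aln)
            if region is not None and not (region.start <= read.pos5 < region.end):
                # fetch() returns any-overlap; the 5' convention decides membership
                continue
            if rf.keeps(read):
                yield read


# ---------------------------------------------------------------------------
# BED / bedGraph


def read_bed(path: str) -> list[GenomicInterval]:
    """Read intervals from a BED3+ file (0-based half-open, as BED defines)."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            strand = parts[5] if len(parts) > 5 and parts[5] in VALID_STRANDS else "."
            out.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2]), strand))
    return out


def write_bed(
    path: str,
    regions: Sequence[GenomicInterval],
    names: Sequence[str] | None = None,
    scores: Sequence[float] | None = None,
) -> None:
    """Write BED6.  Regions must be sortable; scores must be finite."""
    regions = list(regions)
    if scores is not None:
        scores = list(scores)
        if any(s is not None and not np.isfinite(s) for s in scores):
            raise ValueError("scores must be finite")
    order = sorted(range(len(regions)), key=lambda i: (regions[i].chrom, regions[i].start))
    with open(path, "w") as fh:
        for rank, i in enumerate(order):
            iv = regions[i]
            name = names[i] if names is not None else f"region{rank + 1}"
            score = f"{scores[i]:g}" if scores is not None else "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models


@dataclass
class GeneModel:
    """A gene as a strand, a TSS and a merged, 5'->3' ordered exon list."""

    gene_id: str
    symbol: str
    strand: str
    exons: list[GenomicInterval]
    tss: int

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def start(self) -> int:
        return min(e.start for e in self.exons)

    @property
    def end(self) -> int:
        return max(e.end for e in self.exons)


def _parse_gtf_attributes(attr: str, lineno: int) -> dict[str, str]:
    out: dict[str, str] = {}
    attr = attr.strip()
    if "=" in attr.split(";")[0] and '"' not in attr:  # GFF3 style key=value
        for item in attr.split(";"):
            if not item.strip():
                continue
            try:
                key, value = item.strip().split("=", 1)
            except ValueError:
                raise ValueError(f"malformed attribute column at line {lineno}: {item!r}")
            out[key.strip()] = value.strip()
        return out
    for item in attr.split(";"):  # GTF style key "value"
        item = item.strip()
        if not item:
            continue
        try:
            key, value = item.split(None, 1)
        except ValueError:
            raise ValueError(f"malformed attribute column at line {lineno}: {item!r}")
        out[key] = value.strip().strip('"')
    return out


def read_gene_models(gtf_path: str) -> list[GeneModel]:
    """Parse exon features from GTF/GFF3 into per-gene merged exon models.

    The TSS is the leftmost exon base for + strand genes and the rightmost
    for - strand genes; overlapping exon records of one gene are merged.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}  # gene_id -> (symbol, strand)
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"malformed GTF line {lineno}: expected 9 columns")
            chrom, _, feature, start1, end1, _, strand, _, attr = fields[:9]
            if feature != "exon":
                continue
            attrs = _parse_gtf_attributes(attr, lineno)
            gene_id = attrs.get("gene_id") or attrs.get("ID")
            if gene_id is None:
                raise ValueError(f"missing gene_id at line {lineno}")
            symbol = attrs.get("gene_name") or attrs.get("Name") or gene_id
            exons.setdefault(gene_id, []).append(
                GenomicInterval(chrom, int(start1) - 1, int(end1), strand)
            )
            meta[gene_id] = (symbol, strand)

    genes: list[GeneModel] = []
    for gene_id, ivs in exons.items():
        symbol, strand = meta[gene_id]
        ivs.sort(key=lambda iv: iv.start)
        merged: list[GenomicInterval] = []
        for iv in ivs:
            if merged and iv.start <= merged[-1].end:
                last = merged.pop()
                merged.append(
                    GenomicInterval(last.chrom, last.start, max(last.end, iv.end), strand)
                )
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end, strand))
        if strand == "-":
            tss = merged[-1].end - 1  # rightmost base, 0-based
            ordered = merged[::-1]
        else:
            tss = merged[0].start
            ordered = merged
        genes.append(GeneModel(gene_id, symbol, strand, ordered, tss))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes
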