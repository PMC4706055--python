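"""Counting directionally extended reads into sliding windows and bins.

Windows tile each chromosome from position 0 with a fixed spacing between
start positions; an extended fragment contributes one count to every
window it overlaps by at least one base.  Bins are the disjoint special
case (spacing == width) where each fragment is instead assigned exactly
once, to the bin containing its midpoint, so that bin counts are
conserved (column sums equal filtered read counts).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genomic_io import GenomicInterval, AlignedRead, ReadFilter, load_reads


@dataclass(frozen=True)
class CountingParams:
    width: int = 150
    spacing: int = 50
    ext: int = 100
    min_total: int = 10
    bin_mode: bool = False

    def __post_init__(self) -> None:
        if self.width < 1 or self.spacing < 1 or self.ext < 1:
            raise ValueError("width, spacing and ext must all be >= 1")
        if self.bin_mode and self.spacing != self.width:
            raise ValueError("bins require spacing == width")


@dataclass
class WindowCountMatrix:
    """Counts for windows x libraries plus per-library filtered totals."""

    windows: list[GenomicInterval]
    counts: np.ndarray
    totals: np.ndarray
    params: CountingParams
    bam_paths: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        if self.counts.shape != (len(self.windows), len(self.totals)):
            raise ValueError("counts shape must be (n_windows, n_libraries)")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_libraries(self) -> int:
        return len(self.totals)

    def subset(self, mask: np.ndarray) -> "WindowCountMatrix":
        idx = np.flatnonzero(np.asarray(mask))
        return WindowCountMatrix(
            [self.windows[i] for i in idx],
            self.counts[idx],
            self.totals,
            self.params,
            self.bam_paths,
        )

    # -- persistence (TSV + JSON sidecar) so counting need not be re-run --

    def to_tsv(self, path: str) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            cols = "\t".join(f"count.{i + 1}" for i in range(self.n_libraries))
            fh.write(f"chrom\tstart\tend\t{cols}\n")
            for iv, row in zip(self.windows, self.counts):
                vals = "\t".join(str(int(v)) for v in row)
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{vals}\n")
        meta = {
            "totals": [int(t) for t in self.totals],
            "params": {
                "width": self.params.width,
                "spacing": self.params.spacing,
                "ext": self.params.ext,
                "min_total": self.params.min_total,
                "bin_mode": self.params.bin_mode,
            },
            "bam_paths": list(self.bam_paths),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_tsv(cls, path: str) -> "WindowCountMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        windows: list[GenomicInterval] = []
        rows: list[list[int]] = []
        with open(path) as fh:
            next(fh)
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                windows.append(GenomicInterval(parts[0], int(parts[1]), int(parts[2])))
                rows.append([int(v) for v in parts[3:]])
        counts = np.array(rows, dtype=np.int64) if rows else np.zeros((0, len(meta["totals"])), dtype=np.int64)
        return cls(
            windows,
            counts,
            np.array(meta["totals"], dtype=np.int64),
            CountingParams(**meta["params"]),
            meta.get("bam_paths", []),
        )


def extend_read(read: AlignedRead, ext: int, chrom_len: int | None = None) -> GenomicInterval:
    """Directionally extend a read to ``ext`` bp from its 5' end.

    Forward reads span [pos5, pos5+ext); reverse reads span the mirror
    image [pos5-ext+1, pos5+1).  Coordinates are clipped to the
    chromosome when its length is known.
    """
    if ext < 1:
        raise ValueError("ext must be >= 1")
    if read.strand == "+":
        start, end = read.pos5, read.pos5 + ext
    else:
        start, end = read.pos5 - ext + 1, read.pos5 + 1
    start = max(start, 0)
    if chrom_len is not None:
        end = min(end, chrom_len)
        start = min(start, chrom_len - 1)
    return GenomicInterval(read.chrom, start, max(end, start + 1))


def _fragments_on_chrom(
    bam_path: str, chrom: str, chrom_len: int, rf: ReadFilter, ext: int
) -> tuple[np.ndarray, np.ndarray]:
    """Extended-fragment (start, end) arrays for filtered reads on one chromosome."""
    starts: list[int] = []
    ends: list[int] = []
    region = GenomicInterval(chrom, 0, chrom_len)
    for read in load_reads(bam_path, region=region, filter=rf):
        frag = extend_read(read, ext, chrom_len)
        starts.append(frag.start)
        ends.append(frag.end)
    return np.asarray(starts, dtype=np.int64), np.asarray(ends, dtype=np.int64)


def _tile_windows(chrom: str, chrom_len: int, width: int, spacing: int) -> list[GenomicInterval]:
    n_win = (chrom_len - 1) // spacing + 1
    return [
        GenomicInterval(chrom, s, min(s + width, chrom_len))
        for s in range(0, n_win * spacing, spacing)
    ]


def count_windows(
    bam_paths: Sequence[str],
    filter: ReadFilter | None = None,
    params: CountingParams | None = None,
) -> WindowCountMatrix:
    """Count extended reads into sliding windows across all libraries.

    A fragment increments every window it overlaps; windows whose count
    sum across libraries falls below ``params.min_total`` are dropped
    (``min_total=0`` keeps everything).  ``totals`` are genome-wide
    filtered read counts per library, computed before any window filter.
    """
    if not bam_paths:
        raise ValueError("at least one BAM is required")
    rf = filter if filter is not None else ReadFilter(minq=0)
    params = params if params is not None else CountingParams()
    chroms = rf.chromosomes(bam_paths[0])

    all_windows: list[GenomicInterval] = []
    blocks: list[np.ndarray] = []
    totals = np.zeros(len(bam_paths), dtype=np.int64)

    for chrom, chrom_len in chroms:
        windows = _tile_windows(chrom, chrom_len, params.width, params.spacing)
        n_win = len(windows)
        block = np.zeros((n_win, len(bam_paths)), dtype=np.int64)
        for j, bam in enumerate(bam_paths):
            starts, ends = _fragments_on_chrom(bam, chrom, chrom_len, rf, params.ext)
            totals[j] += len(starts)
            if len(starts) == 0:
                continue
            # window i covers [i*spacing, i*spacing+width); fragment [s, e)
            # overlaps windows with ceil((s-width+1)/spacing) <= i <= (e-1)//spacing
            lo = np.maximum(-(-(starts - params.width + 1) // params.spacing), 0)
            hi = np.minimum((ends - 1) // params.spacing, n_win - 1)
            ok = lo <= hi
            delta = np.zeros(n_win + 1, dtype=np.int64)
            np.add.at(delta, lo[ok], 1)
            np.add.at(delta, hi[ok] + 1, -1)
            block[:, j] = np.cumsum(delta[:-1])
        all_windows.extend(windows)
        blocks.append(block)

    counts = np.vstack(blocks) if blocks else np.zeros((0, len(bam_paths)), dtype=np.int64)
    if params.min_total > 0:
        keep = counts.sum(axis=1) >= params.min_total
        counts = counts[keep]
        all_windows = [w for w, k in zip(all_windows, keep) if k]
    return WindowCountMatrix(all_windows, counts, totals, params, list(map(str, bam_paths)))


def count_bins(
    bam_paths: Sequence[str],
    filter: ReadFilter | None = None,
    bin_width: int = 2000,
    ext: int = 100,
) -> WindowCountMatrix:
    """Count each read exactly once into disjoint bins.

    The bin is the one containing the midpoint of the extended fragment,
    so per-chromosome column sums equal the filtered read count there.
    No preliminary abundance filter is applied.
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    if not bam_paths:
        raise ValueError("at least one BAM is required")
    rf = filter if filter is not None else ReadFilter(minq=0)
    chroms = rf.chromosomes(bam_paths[0])

    all_bins: list[GenomicInterval] = []
    blocks: list[np.ndarray] = []
    totals = np.zeros(len(bam_paths), dtype=np.int64)

    for chrom, chrom_len in chroms:
        n_bins = -(-chrom_len // bin_width)
        bins = [
            GenomicInterval(chrom, s, min(s + bin_width, chrom_len))
            for s in range(0, n_bins * bin_width, bin_width)
        ]
        block = np.zeros((n_bins, len(bam_paths)), dtype=np.int64)
        for j, bam in enumerate(bam_paths):
            starts, ends = _fragments_on_chrom(bam, chrom, chrom_len, rf, ext)
            totals[j] += len(starts)
            if len(starts) == 0:
                continue
            mid = (starts + ends) // 2
            idx = np.clip(mid // bin_width, 0, n_bins - 1)
            block[:, j] = np.bincount(idx, minlength=n_bins)
        all_bins.extend(bins)
        blocks.append(block)

    counts = np.vstack(blocks) if blocks else np.zeros((0, len(bam_paths)), dtype=np.int64)
    params = CountingParams(width=bin_width, spacing=bin_width, ext=ext, min_total=0, bin_mode=True)
    return WindowCountMatrix(all_bins, counts, totals, params, list(map(str, bam_paths)))
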