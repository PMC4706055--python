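"""Depth-normalized coverage tracks over a region, for browser export.

Coverage is the pileup of directionally extended fragments, reported per
million filtered reads so that libraries of different depths are
comparable; tracks can be restricted to one strand to show the forward/
reverse bimodality around binding sites.
"""

from __future__ import annotations

import numpy as np

from .counting import extend_read
from .genomic_io import GenomicInterval, ReadFilter, load_reads


def region_coverage(
    bam_path: str,
    region: GenomicInterval,
    filter: ReadFilter | None = None,
    ext: int = 100,
    per_million_total: float | None = None,
    strand: str = "both",
) -> list[tuple[GenomicInterval, float]]:
    """Per-base pileup of extended fragments as a step function.

    Returns (interval, value) steps covering the region, with value in
    reads-per-million given the library total ``per_million_total``
    (pass the genome-wide filtered read count; required for comparable
    tracks).  ``strand`` restricts which reads contribute.
    """
    if strand not in ("both", "+", "-"):
        raise ValueError("strand must be 'both', '+' or '-'")
    rf = filter if filter is not None else ReadFilter(minq=0)
    chrom_lens = dict(rf.chromosomes(bam_path))
    chrom_len = chrom_lens.get(region.chrom)
    if chrom_len is None:
        return []

    # fetch a margin so fragments whose read lies outside still pile up inside
    query = GenomicInterval(
        region.chrom, max(0, region.start - ext), min(chrom_len, region.end + ext)
    )
    n = region.end - region.start
    delta = np.zeros(n + 1, dtype=np.float64)
    for read in load_reads(bam_path, region=query, filter=rf):
        if strand != "both" and read.strand != strand:
            continue
        frag = extend_read(read, ext, chrom_len)
        lo = max(frag.start, region.start) - region.start
        hi = min(frag.end, region.end) - region.start
        if hi > lo:
            delta[lo] += 1
            delta[hi] -= 1
    depth = np.cumsum(delta[:-1])
    if per_million_total is not None:
        if per_million_total <= 0:
            raise ValueError("per_million_total must be positive")
        depth = depth / (per_million_total / 1e6)

    steps: list[tuple[GenomicInterval, float]] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or depth[i] != depth[start]:
            steps.append(
                (
                    GenomicInterval(region.chrom, region.start + start, region.start + i),
                    float(depth[start]),
                )
            )
            start = i
    return steps


def write_bedgraph(path: str, steps: list[tuple[GenomicInterval, float]]) -> None:
    with open(path, "w") as fh:
        for iv, value in steps:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value:g}\n")


def read_bedgraph(path: str) -> list[tuple[GenomicInterval, float]]:
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split("\t")
            out.append((GenomicInterval(chrom, int(start), int(end)), float(value)))
    return out
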