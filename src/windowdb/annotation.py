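"""Compact gene-centric annotation strings for regions.

Each gene touching a region is reported as ``SYMBOL|EXONS|STRAND`` where
EXONS is a compressed list of the overlapped features: ``0`` denotes the
promoter, ``I`` the intron (at most once per gene), and positive integers
denote exons numbered 5'->3' in gene orientation.  Flanking genes within
a distance limit but fully outside the region are reported to the left
and right with the gap distance appended as ``[DISTANCE]``.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genomic_io import GeneModel, GenomicInterval


@dataclass
class AnnotationString:
    overlap: str
    left: str
    right: str


def promoter_set(
    genes: list[GeneModel],
    promoter: tuple[int, int] = (3000, 1000),
) -> list[GenomicInterval]:
    """Promoter intervals: ``promoter[0]`` bp upstream to ``promoter[1]`` bp
    downstream of each TSS, in gene orientation, clipped at zero."""
    up, down = promoter
    out = []
    for g in genes:
        if g.strand == "-":
            start, end = g.tss - down, g.tss + up
        else:
            start, end = g.tss - up, g.tss + down
        out.append(GenomicInterval(g.chrom, max(0, start), max(1, end), g.strand))
    return out


def _compress_indices(indices: list) -> str:
    """Compress feature markers: [0,1] -> '0-1'; [0,2] -> '0,2'; 'I' appended."""
    nums = sorted({i for i in indices if isinstance(i, int)})
    parts: list[str] = []
    i = 0
    while i < len(nums):
        j = i
        while j + 1 < len(nums) and nums[j + 1] == nums[j] + 1:
            j += 1
        parts.append(str(nums[i]) if i == j else f"{nums[i]}-{nums[j]}")
        i = j + 1
    if "I" in indices:
        parts.append("I")
    return ",".join(parts)


def _gene_features(
    gene: GeneModel, promoter: tuple[int, int]
) -> list[tuple[GenomicInterval, object]]:
    """(interval, marker) pairs: promoter=0, exons=1.., introns='I'."""
    feats: list[tuple[GenomicInterval, object]] = []
    prom = promoter_set([gene], promoter)[0]
    feats.append((prom, 0))
    for k, exon in enumerate(gene.exons, start=1):
        feats.append((exon, k))
    by_pos = sorted(gene.exons, key=lambda e: e.start)
    for a, b in zip(by_pos, by_pos[1:]):
        if b.start > a.end:
            feats.append((GenomicInterval(gene.chrom, a.end, b.start, gene.strand), "I"))
    return feats


def _descriptor(gene: GeneModel, markers: list) -> str:
    return f"{gene.symbol}|{_compress_indices(markers)}|{gene.strand}"


def annotate_regions(
    regions: list[GenomicInterval],
    genes: list[GeneModel],
    flank: int = 5000,
    promoter: tuple[int, int] = (3000, 1000),
) -> list[AnnotationString]:
    """Overlap and flanking annotation strings for each region.

    ``overlap`` lists genes with any feature intersecting the region;
    ``left``/``right`` list promoter/exon features lying fully outside the
    region within ``flank`` bp, with the intervening distance to the
    nearest one appended.  A gene may appear in both (e.g. a region inside
    an intron has the neighbouring exons as flanking features).
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)

    out: list[AnnotationString] = []
    for region in regions:
        over_parts: list[str] = []
        left_parts: list[str] = []
        right_parts: list[str] = []
        for gene in by_chrom.get(region.chrom, []):
            feats = _gene_features(gene, promoter)
            over = [m for iv, m in feats if iv.overlaps(region)]
            if over:
                over_parts.append(_descriptor(gene, over))
            side = [(iv, m) for iv, m in feats if m != "I"]  # introns never flank
            left_feats = [
                (m, region.start - iv.end)
                for iv, m in side
                if iv.end <= region.start and region.start - iv.end <= flank
            ]
            if left_feats:
                dist = min(d for _, d in left_feats)
                left_parts.append(_descriptor(gene, [m for m, _ in left_feats]) + f"[{dist}]")
            right_feats = [
                (m, iv.start - region.end)
                for iv, m in side
                if iv.start >= region.end and iv.start - region.end <= flank
            ]
            if right_feats:
                dist = min(d for _, d in right_feats)
                right_parts.append(_descriptor(gene, [m for m, _ in right_feats]) + f"[{dist}]")
        out.append(
            AnnotationString(
                overlap=",".join(over_parts),
                left=",".join(left_parts),
                right=",".join(right_parts),
            )
        )
    return out
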