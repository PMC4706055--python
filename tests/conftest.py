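import numpy as np
import pytest

from windowdb.genomic_io import GenomicInterval
from windowdb.simulate import write_synthetic_bam


@pytest.fixture
def make_bam(tmp_path):
    """Factory writing (chrom, pos5, strand, is_dup[, mapq]) records to BAM."""

    counter = {"n": 0}

    def _make(reads, chrom_sizes=None, read_len=36):
        chrom_sizes = chrom_sizes or {"chrT": 100_000}
        counter["n"] += 1
        return write_synthetic_bam(
            tmp_path / f"fixture_{counter['n']}.bam", chrom_sizes, reads, read_len=read_len
        )

    return _make


@pytest.fixture
def toy_gtf(tmp_path):
    """Three-gene GTF: two + strand genes and one - strand gene with
    overlapping exon records that must be merged."""
    lines = [
        # geneA (+): exons [1000,1200) and [1500,1800), tss=1000
        'chrT\ttest\texon\t1001\t1200\t.\t+\t.\tgene_id "geneA"; gene_name "Alpha";',
        'chrT\ttest\texon\t1501\t1800\t.\t+\t.\tgene_id "geneA"; gene_name "Alpha";',
        # geneB (-): exons [5000,5300) and [6000,6400), tss=6399
        'chrT\ttest\texon\t5001\t5300\t.\t-\t.\tgene_id "geneB"; gene_name "Beta";',
        'chrT\ttest\texon\t6001\t6400\t.\t-\t.\tgene_id "geneB"; gene_name "Beta";',
        # geneC (+): two overlapping exon records -> one exon [9000,9500)
        'chrT\ttest\texon\t9001\t9300\t.\t+\t.\tgene_id "geneC"; gene_name "Gamma";',
        'chrT\ttest\texon\t9101\t9500\t.\t+\t.\tgene_id "geneC"; gene_name "Gamma";',
    ]
    path = tmp_path / "genes.gtf"
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def brute_force_window_counts(frags, chrom_len, width, spacing):
    """Quadratic-time oracle: count each fragment into every overlapping window."""
    n_win = (chrom_len - 1) // spacing + 1
    windows = [(s, min(s + width, chrom_len)) for s in range(0, n_win * spacing, spacing)]
    counts = np.zeros(n_win, dtype=int)
    for fs, fe in frags:
        for i, (ws, we) in enumerate(windows):
            if fs < we and ws < fe:
                counts[i] += 1
    return windows, counts


def random_intervals(rng, n, chrom="chrT", max_pos=10_000):
    out = []
    for _ in range(n):
        s = int(rng.integers(0, max_pos - 2))
        e = int(rng.integers(s + 1, min(s + 500, max_pos)))
        out.append(GenomicInterval(chrom, s, e))
    return out
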