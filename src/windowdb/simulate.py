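"""Synthetic ChIP-seq data with known ground truth.

Two generators cover the two halves of the pipeline:

* :func:`simulate_reads` writes sorted, indexed BAM files with uniform
  background reads plus strand-bimodal reads around binding sites whose
  per-condition enrichment is specified, along with a truth BED of the
  genuinely differential sites.  Replicate variability of the site read
  counts is negative-binomial.
* :func:`simulate_counts` draws window-level NB count matrices directly
  from the model assumed downstream (log-linear means, gamma-mixed
  dispersions), for testing the statistical machinery at scale.

All randomness flows through one seeded generator per call: background
reads first (per library, chromosome order), then site reads in list
order, then duplicates.  Appending new draw types keeps earlier streams
stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from .counting import CountingParams, WindowCountMatrix
from .genomic_io import GenomicInterval

LN2 = np.log(2.0)


@dataclass
class BindingSite:
    chrom: str
    position: int
    enrichment: dict[str, float]  # condition -> expected reads per unit depth
    width: int = 50


@dataclass
class SimulationSpec:
    """Parameters of a synthetic two-condition ChIP-seq experiment.

    ``background_rate`` is in reads per bp per unit depth;
    ``library_depths`` are relative depth factors; ``composition_bias``
    multiplies site reads per library (background untouched), and
    ``trended_bias`` log2-amplitudes tilt site yields with site strength,
    emulating the abundance-dependent biases the normalization removes.
    """

    chrom_sizes: dict[str, int]
    binding_sites: list[BindingSite]
    conditions: list[str]
    frag_len: int = 148
    read_len: int = 36
    background_rate: float = 0.03
    library_depths: list[float] = field(default_factory=list)
    composition_bias: list[float] | None = None
    trended_bias: list[float] | None = None
    batch_offsets: list[float] | None = None
    dup_rate: float = 0.0
    phi: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.library_depths:
            self.library_depths = [1.0] * len(self.conditions)
        if len(self.library_depths) != len(self.conditions):
            raise ValueError("library_depths must match conditions")
        if self.background_rate < 0 or self.dup_rate < 0 or self.phi < 0:
            raise ValueError("rates must be >= 0")

    @property
    def n_libraries(self) -> int:
        return len(self.conditions)


def default_spec(
    seed: int = 0,
    n_db_sites: int = 50,
    n_stable_sites: int = 40,
    site_reads: float = 220.0,
    db_fold: float = 8.0,
    chrom_size: int = 500_000,
    background_rate: float = 0.03,
    conditions: tuple[str, ...] = ("A", "A", "B", "B"),
) -> SimulationSpec:
    """The study conditions used throughout testing: two 500 kbp toy
    chromosomes, four libraries in two conditions, 90 binding sites of
    which 50 are differential (balanced up/down so trended normalization
    assumptions hold)."""
    rng = np.random.default_rng(seed)
    chroms = {"chrTA": chrom_size, "chrTB": chrom_size}
    n_sites = n_db_sites + n_stable_sites
    margin = 5000
    per_chrom = -(-n_sites // len(chroms))
    positions = []
    for chrom in chroms:
        slots = np.linspace(margin, chrom_size - margin, per_chrom).astype(int)
        positions.extend((chrom, int(p)) for p in slots)
    positions = positions[:n_sites]
    rng.shuffle(positions)

    sites = []
    for k, (chrom, pos) in enumerate(positions):
        if k < n_db_sites:  # alternate direction to balance DB
            hi, lo = site_reads, site_reads / db_fold
            enr = {"A": hi, "B": lo} if k % 2 == 0 else {"A": lo, "B": hi}
        else:
            enr = {"A": site_reads, "B": site_reads}
        sites.append(BindingSite(chrom=chrom, position=pos, enrichment=enr))
    return SimulationSpec(
        chrom_sizes=chroms,
        binding_sites=sites,
        conditions=list(conditions),
        background_rate=background_rate,
        seed=seed,
    )


def truth_regions(spec: SimulationSpec) -> list[GenomicInterval]:
    """Intervals around sites whose enrichment differs between conditions."""
    out = []
    for s in spec.binding_sites:
        values = list(s.enrichment.values())
        if max(values) > min(values):
            half = s.width // 2 + spec.frag_len
            out.append(
                GenomicInterval(
                    s.chrom,
                    max(0, s.position - half),
                    min(spec.chrom_sizes[s.chrom], s.position + half),
                )
            )
    return out


def _nb_draw(rng: np.random.Generator, mean: float, phi: float) -> int:
    if mean <= 0:
        return 0
    if phi <= 0:
        return int(rng.poisson(mean))
    lam = rng.gamma(1.0 / phi, phi * mean)
    return int(rng.poisson(lam))


def write_synthetic_bam(
    path,
    chrom_sizes: dict[str, int],
    reads: list[tuple],
    read_len: int = 36,
    default_mapq: int = 60,
) -> str:
    """Write read records as a sorted, indexed BAM.

    Each record is (chrom, pos5, strand, is_dup) or, with an explicit
    mapping quality, (chrom, pos5, strand, is_dup, mapq).
    """
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": l} for c, l in chrom_sizes.items()],
    }
    tids = {c: i for i, c in enumerate(chrom_sizes)}
    unsorted = path.with_suffix(".unsorted.bam")
    with pysam.AlignmentFile(str(unsorted), "wb", header=header) as bam:
        for k, rec in enumerate(reads):
            chrom, pos5, strand, is_dup = rec[:4]
            size = chrom_sizes[chrom]
            a = pysam.AlignedSegment()
            a.query_name = f"read{k}"
            a.query_sequence = "A" * read_len
            a.query_qualities = pysam.qualitystring_to_array("I" * read_len)
            a.reference_id = tids[chrom]
            a.mapping_quality = rec[4] if len(rec) > 4 else default_mapq
            a.cigar = [(0, read_len)]
            if strand == "-":
                a.is_reverse = True
                start = pos5 - read_len + 1
            else:
                start = pos5
            a.reference_start = int(np.clip(start, 0, size - read_len))
            a.is_duplicate = is_dup
            bam.write(a)
    pysam.sort("-o", str(path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(path))
    return str(path)


def simulate_reads(
    spec: SimulationSpec, outdir: str
) -> tuple[list[str], list[GenomicInterval]]:
    """Generate one sorted+indexed BAM per library and the truth regions.

    Background fragments are uniform; site fragments are bimodal: forward
    5' ends centre on position - frag_len/2 and reverse 5' ends on
    position + frag_len/2, jittered with SD frag_len/10 plus a uniform
    shift within the site width.  Duplicate records are resampled
    existing reads with the duplicate flag set.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    jitter_sd = spec.frag_len / 10.0
    comp = spec.composition_bias or [1.0] * spec.n_libraries
    trend = spec.trended_bias or [0.0] * spec.n_libraries
    batch = spec.batch_offsets or [0.0] * spec.n_libraries

    strengths = np.array(
        [np.mean(list(s.enrichment.values())) for s in spec.binding_sites] or [1.0]
    )
    logs = np.log2(np.maximum(strengths, 1e-9))
    z = (logs - logs.mean()) / (logs.std() if logs.std() > 0 else 1.0)

    bam_paths: list[str] = []
    for i, cond in enumerate(spec.conditions):
        depth = spec.library_depths[i] * 2.0 ** batch[i]
        reads: list[tuple[str, int, str, bool]] = []
        for chrom, size in spec.chrom_sizes.items():
            n_bg = rng.poisson(spec.background_rate * size * depth)
            starts = rng.integers(0, max(1, size - spec.frag_len), size=n_bg)
            strands = rng.random(n_bg) < 0.5
            for s, fwd in zip(starts, strands):
                pos5 = int(s) if fwd else int(s) + spec.frag_len - 1
                reads.append((chrom, pos5, "+" if fwd else "-", False))
        for k, site in enumerate(spec.binding_sites):
            mean = site.enrichment.get(cond, 0.0) * depth * comp[i] * 2.0 ** (trend[i] * z[k])
            n = _nb_draw(rng, mean, spec.phi)
            size = spec.chrom_sizes[site.chrom]
            centers = site.position + rng.uniform(-site.width / 2, site.width / 2, size=n)
            fwd = rng.random(n) < 0.5
            offsets = rng.normal(0.0, jitter_sd, size=n)
            for c, f, o in zip(centers, fwd, offsets):
                if f:
                    pos5 = int(round(c - spec.frag_len / 2 + o))
                else:
                    pos5 = int(round(c + spec.frag_len / 2 + o))
                pos5 = int(np.clip(pos5, 0, size - 1))
                reads.append((site.chrom, pos5, "+" if f else "-", False))
        if spec.dup_rate > 0 and reads:
            n_dup = rng.binomial(len(reads), spec.dup_rate)
            for idx in rng.integers(0, len(reads), size=n_dup):
                chrom, pos5, strand, _ = reads[idx]
                reads.append((chrom, pos5, strand, True))
        path = outdir / f"library_{i + 1}.bam"
        write_synthetic_bam(path, spec.chrom_sizes, reads, read_len=spec.read_len)
        bam_paths.append(str(path))
    return bam_paths, truth_regions(spec)


def simulate_counts(
    n_windows: int,
    design: np.ndarray,
    true_logfc,
    phi: float = 0.05,
    df_prior_true: float = np.inf,
    depths=None,
    seed: int = 0,
    cluster_size: int = 1,
    base_range: tuple[float, float] = (np.log(30.0), np.log(300.0)),
) -> tuple[WindowCountMatrix, np.ndarray]:
    """NB count matrix for windows with known per-window log2 fold changes.

    Means are exp(base + log depth), with ``true_logfc`` (log2, scalar or
    per-window) added to libraries loading on the last design column.
    Per-window dispersions are phi scaled by df0/chi2(df0) draws when
    ``df_prior_true`` is finite, mimicking QL variability around the
    trend.  Windows are laid out in clusters of ``cluster_size`` adjacent
    sliding windows separated by large gaps, so region-level aggregation
    can be exercised on the result.  Returns the matrix and the
    per-window true log2 fold change.
    """
    rng = np.random.default_rng(seed)
    X = np.asarray(design, dtype=float)
    L = X.shape[0]
    depths = np.asarray(depths if depths is not None else [1e6] * L, dtype=float)
    lfc = np.broadcast_to(np.asarray(true_logfc, dtype=float), (n_windows,)).copy()

    n_clusters = -(-n_windows // cluster_size)
    base_cluster = rng.uniform(base_range[0], base_range[1], size=n_clusters)
    base = np.repeat(base_cluster, cluster_size)[:n_windows]

    rel_depth = depths / depths.mean()
    in_last = X[:, -1] > 0
    log_mu = (
        base[:, None]
        + np.log(rel_depth)[None, :]
        + np.where(in_last[None, :], lfc[:, None] * LN2, 0.0)
    )
    mu = np.exp(log_mu)

    if df_prior_true is not None and np.isfinite(df_prior_true):
        s2 = df_prior_true / rng.chisquare(df_prior_true, size=n_windows)
        phi_g = phi * s2
    else:
        phi_g = np.full(n_windows, phi)

    if phi <= 0:
        counts = rng.poisson(mu)
    else:
        lam = rng.gamma(1.0 / phi_g[:, None], phi_g[:, None] * mu)
        counts = rng.poisson(lam)

    windows = []
    width, spacing, gap = 150, 50, 10_000
    for g in range(n_windows):
        c, j = divmod(g, cluster_size)
        start = c * gap + j * spacing
        windows.append(GenomicInterval("sim", start, start + width))
    params = CountingParams(width=width, spacing=spacing, ext=100, min_total=0)
    m = WindowCountMatrix(windows, counts.astype(np.int64), depths.astype(np.int64), params)
    return m, lfc
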