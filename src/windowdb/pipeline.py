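"""End-to-end differential binding pipeline with checkpointed intermediates.

The configuration is a YAML/dict with the libraries, their groups, the
contrast and a preset: ``histone`` (150 bp windows, loess normalization,
2 kbp background bins) for broad marks, or ``tf`` (10 bp windows, binned
TMM on 10 kbp bins) for sharp transcription-factor binding.  Every stage
persists its output as TSV so the expensive counting steps never need to
be re-run; rerunning with identical inputs reproduces results exactly.
"""

from __future__ import annotations

import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abundance_filter import apply_filter, global_filter
from .annotation import annotate_regions
from .counting import CountingParams, WindowCountMatrix, count_bins, count_windows
from .fraglen import cross_correlation, estimate_fragment_length, write_profile_tsv
from .genomic_io import GenomicInterval, ReadFilter, read_bed, read_gene_models, write_bed
from .nbql import contrast_vector, design_from_groups, estimate_dispersion_trend, ql_f_test, ql_fit
from .normalization import effective_offsets, loess_offsets, tmm_factors
from .regions import merge_windows, region_table

logger = logging.getLogger("windowdb")

PRESETS = {
    "histone": {
        "width": 150,
        "spacing": 50,
        "bin_width": 2000,
        "min_fc": 3.0,
        "normalization": "loess",
        "tol": 100,
        "max_width": 5000,
        "min_total": 10,
    },
    "tf": {
        "width": 10,
        "spacing": 50,
        "bin_width": 10000,
        "min_fc": 3.0,
        "normalization": "tmm",
        "tol": 100,
        "max_width": 5000,
        "min_total": 10,
    },
}

MAX_BED_SCORE = 3000.0  # -10*log10(FDR) cap for FDR values at numerical zero


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "windowdb.log")):
        handler.setFormatter(fmt)
        logger.addHandler(handler)


def write_region_tsv(df: pd.DataFrame, path: str) -> None:
    """Region table as TSV with 1-based inclusive coordinates for display."""
    out = df.copy()
    out["start"] = out["start"] + 1
    if "best.pos" in out:
        out["best.pos"] = out["best.pos"] + 1
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_significant(
    regions: pd.DataFrame,
    path: str,
    fdr_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Write significant regions as BED6 scored by -10*log10(FDR)."""
    sig = regions[regions["FDR"] <= fdr_cutoff]
    score = -10.0 * np.log10(np.maximum(sig["FDR"].to_numpy(), 10 ** (-MAX_BED_SCORE / 10)))
    ivs = [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(sig["chrom"], sig["start"], sig["end"])
    ]
    write_bed(path, ivs, names=[f"region{i + 1}" for i in range(len(ivs))], scores=list(score))
    return sig


def load_config(path: str) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def run_pipeline(config: dict | str) -> dict:
    """Run fraglen -> count -> filter -> normalize -> test -> regions -> export.

    Returns a dict of result objects and output paths.  Any stage failure
    raises with the stage name; everything persisted up to that point is
    left on disk for inspection and restart.
    """
    if isinstance(config, (str, Path)):
        config = load_config(config)
    preset = dict(PRESETS[config.get("preset", "histone")])
    preset.update({k: config[k] for k in preset if k in config})

    outdir = Path(config.get("outdir", "windowdb_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)

    bam_paths = [str(b) for b in config["bams"]]
    groups = list(config["groups"])
    if len(groups) != len(bam_paths):
        raise ValueError("groups must match bams")
    blacklist = read_bed(config["blacklist"]) if config.get("blacklist") else ()
    restrict = frozenset(config["restrict"]) if config.get("restrict") else None
    rf = ReadFilter(minq=int(config.get("minq", 50)), blacklist=blacklist, restrict=restrict)
    fdr_cutoff = float(config.get("fdr", 0.05))
    stage = "setup"

    try:
        stage = "fraglen"
        if "ext" in config:
            frag_len = int(config["ext"])
            logger.info("fragment length fixed by config: %d bp", frag_len)
        else:
            profile = cross_correlation(bam_paths, rf, max_delay=int(config.get("max_delay", 1000)))
            write_profile_tsv(profile, outdir / "ccf_profile.tsv")
            frag_len = estimate_fragment_length(profile)
            logger.info("estimated fragment length: %d bp", frag_len)

        stage = "count"
        win_path = outdir / "window_counts.tsv"
        params = CountingParams(
            width=preset["width"],
            spacing=preset["spacing"],
            ext=frag_len,
            min_total=preset["min_total"],
        )
        if win_path.exists():
            windows = WindowCountMatrix.from_tsv(win_path)
            logger.info("reusing persisted window counts (%d windows)", windows.n_windows)
        else:
            windows = count_windows(bam_paths, rf, params)
            windows.to_tsv(win_path)
        bin_path = outdir / "bin_counts.tsv"
        if bin_path.exists():
            bins = WindowCountMatrix.from_tsv(bin_path)
        else:
            bins = count_bins(bam_paths, rf, bin_width=preset["bin_width"], ext=frag_len)
            bins.to_tsv(bin_path)
        for i, (bam, tot) in enumerate(zip(bam_paths, windows.totals)):
            logger.info("library %d (%s): %d filtered reads", i + 1, bam, tot)

        stage = "filter"
        filt = global_filter(windows, bins)
        keep = apply_filter(filt, min_fc=preset["min_fc"])
        logger.info(
            "abundance filter: kept %d / %d windows (background %.3f log2-CPM)",
            int(keep.sum()), windows.n_windows, filt.back_abundance,
        )
        filtered = windows.subset(keep)
        filtered.to_tsv(outdir / "filtered_counts.tsv")
        if filtered.n_windows == 0:
            raise ValueError("no windows pass the abundance filter")

        stage = "normalize"
        if preset["normalization"] == "loess":
            norm = loess_offsets(filtered)
            np.savetxt(outdir / "offsets.tsv", norm.offsets, delimiter="\t")
        else:
            norm = tmm_factors(bins)
            np.savetxt(outdir / "factors.tsv", norm.factors[None, :], delimiter="\t")
            logger.info("TMM factors: %s", np.array2string(norm.factors, precision=4))
        offsets = effective_offsets(filtered, norm)

        stage = "test"
        design, labels = design_from_groups(groups)
        contrast_expr = config.get("contrast") or f"{labels[-1]}-{labels[0]}"
        contrast = contrast_vector(labels, contrast_expr)
        disp = estimate_dispersion_trend(filtered, design, offsets)
        logger.info("common NB dispersion: %.4f (BCV %.3f)", disp.common, np.sqrt(disp.common))
        fit = ql_fit(filtered, design, offsets, disp, robust=bool(config.get("robust", True)))
        d0 = np.atleast_1d(np.asarray(fit.df_prior, dtype=float))
        logger.info("QL prior df: median %.4g", float(np.median(d0)))
        res = ql_f_test(fit, contrast)
        pd.DataFrame(
            {
                "chrom": [w.chrom for w in filtered.windows],
                "start": [w.start + 1 for w in filtered.windows],
                "end": [w.end for w in filtered.windows],
                "logFC": res.logFC,
                "logCPM": res.logCPM,
                "F": res.F,
                "PValue": res.p_value,
            }
        ).to_csv(outdir / "window_tests.tsv", sep="\t", index=False, float_format="%.6g")

        stage = "regions"
        assign = merge_windows(filtered.windows, tol=preset["tol"], max_width=preset["max_width"])
        table = region_table(assign, res, filtered.windows)
        write_region_tsv(table, outdir / "regions.tsv")
        logger.info(
            "%d regions, %d at FDR <= %.3g",
            len(table), int((table["FDR"] <= fdr_cutoff).sum()), fdr_cutoff,
        )

        stage = "annotate"
        if config.get("gtf"):
            genes = read_gene_models(config["gtf"])
            regions = [
                GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(table["chrom"], table["start"], table["end"])
            ]
            anno = annotate_regions(regions, genes)
            table["overlap"] = [a.overlap for a in anno]
            table["left"] = [a.left for a in anno]
            table["right"] = [a.right for a in anno]
            write_region_tsv(table, outdir / "regions_annotated.tsv")

        stage = "export"
        sig = export_significant(table, outdir / "significant.bed", fdr_cutoff)
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    return {
        "frag_len": frag_len,
        "windows": windows,
        "filtered": filtered,
        "normalization": norm,
        "dispersion": disp,
        "fit": fit,
        "window_results": res,
        "regions": table,
        "significant": sig,
        "outdir": str(outdir),
    }
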