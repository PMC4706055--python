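"""Aggregating window results into regions with region-level FDR control.

Applying BH directly to window p-values does not control the FDR across
binding events, because a single event spans many correlated windows.
Instead adjacent windows are merged into clusters, a combined p-value is
computed per cluster with Simes' method (valid under the positive
dependence typical of overlapping windows), and BH is applied to the
cluster-level p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .genomic_io import GenomicInterval
from .nbql import WindowTestResult


@dataclass
class ClusterAssignment:
    cluster_id: np.ndarray  # per window
    regions: list[GenomicInterval]  # per cluster: span of member windows

    @property
    def n_clusters(self) -> int:
        return len(self.regions)


def merge_windows(
    windows: list[GenomicInterval],
    tol: int = 100,
    max_width: int = 5000,
) -> ClusterAssignment:
    """Cluster sorted windows whose gap is below ``tol``; split giant clusters.

    Windows w_i, w_{i+1} on one chromosome join a cluster when
    start_{i+1} - end_i < tol (half-open coordinates: fewer than ``tol``
    intervening bases); clustering is the transitive closure.  A cluster
    spanning more than ``max_width`` bp is split into ceil(span/max_width)
    contiguous subclusters of near-equal span, windows assigned by
    midpoint, to prevent chaining from producing uninterpretably large
    regions.
    """
    if tol < 0:
        raise ValueError("tol must be >= 0")
    order = sorted(range(len(windows)), key=lambda i: (windows[i].chrom, windows[i].start))
    cluster_of = np.full(len(windows), -1, dtype=np.int64)
    regions: list[GenomicInterval] = []

    run: list[int] = []

    def flush(run: list[int]) -> None:
        if not run:
            return
        chrom = windows[run[0]].chrom
        span_start = min(windows[i].start for i in run)
        span_end = max(windows[i].end for i in run)
        span = span_end - span_start
        k = max(1, -(-span // max_width)) if max_width > 0 else 1
        if k == 1:
            cid = len(regions)
            for i in run:
                cluster_of[i] = cid
            regions.append(GenomicInterval(chrom, span_start, span_end))
            return
        sub_members: list[list[int]] = [[] for _ in range(k)]
        for i in run:
            mid = windows[i].midpoint
            j = min(int((mid - span_start) * k // span), k - 1)
            sub_members[j].append(i)
        for members in sub_members:
            if not members:
                continue
            cid = len(regions)
            for i in members:
                cluster_of[i] = cid
            regions.append(
                GenomicInterval(
                    chrom,
                    min(windows[i].start for i in members),
                    max(windows[i].end for i in members),
                )
            )

    prev = None
    for i in order:
        w = windows[i]
        if prev is None or w.chrom != prev.chrom or w.start - run_end >= tol:
            flush(run)
            run = [i]
            run_end = w.end
        else:
            run.append(i)
            run_end = max(run_end, w.end)
        prev = w
    flush(run)
    return ClusterAssignment(cluster_id=cluster_of, regions=regions)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _simes(p: np.ndarray) -> float:
    p_sorted = np.sort(p)
    m = len(p_sorted)
    return float(min(1.0, (m * p_sorted / np.arange(1, m + 1)).min()))


def combine_simes(
    assign: ClusterAssignment,
    res: WindowTestResult,
    fc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster Simes combined p-values with direction summaries.

    For each cluster with sorted member p-values p_(1) <= ... <= p_(m),
    the combined p-value is min_i(m p_(i) / i); logFC.up / logFC.down
    count member windows with log2 fold change beyond +/- fc_threshold;
    FDR is BH over cluster p-values.
    """
    n_clusters = assign.n_clusters
    p_comb = np.ones(n_clusters)
    n_win = np.zeros(n_clusters, dtype=np.int64)
    up = np.zeros(n_clusters, dtype=np.int64)
    down = np.zeros(n_clusters, dtype=np.int64)
    for cid in range(n_clusters):
        members = np.flatnonzero(assign.cluster_id == cid)
        if len(members) == 0:
            raise ValueError(f"cluster {cid} has no member windows")
        p_comb[cid] = _simes(res.p_value[members])
        n_win[cid] = len(members)
        up[cid] = int(np.sum(res.logFC[members] > fc_threshold))
        down[cid] = int(np.sum(res.logFC[members] < -fc_threshold))
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in assign.regions],
            "start": [r.start for r in assign.regions],
            "end": [r.end for r in assign.regions],
            "nWindows": n_win,
            "logFC.up": up,
            "logFC.down": down,
            "PValue": p_comb,
            "FDR": bh_adjust(p_comb),
        }
    )


def best_window(
    assign: ClusterAssignment,
    res: WindowTestResult,
    windows: list[GenomicInterval] | None = None,
) -> pd.DataFrame:
    """Most significant window per cluster, Bonferroni-adjusted within cluster.

    The best window's log-fold change proxies the direction and size of
    the change for the whole cluster; its p-value is min(1, m * p_best).
    Ties go to the leftmost member window.
    """
    n_clusters = assign.n_clusters
    best_idx = np.zeros(n_clusters, dtype=np.int64)
    best_p = np.ones(n_clusters)
    best_fc = np.zeros(n_clusters)
    best_pos = np.zeros(n_clusters, dtype=np.int64)
    for cid in range(n_clusters):
        members = np.flatnonzero(assign.cluster_id == cid)
        m = len(members)
        j = members[int(np.argmin(res.p_value[members]))]  # argmin -> leftmost tie
        best_idx[cid] = j
        best_p[cid] = min(1.0, m * float(res.p_value[j]))
        best_fc[cid] = float(res.logFC[j])
        if windows is not None:
            best_pos[cid] = windows[j].midpoint
    out = pd.DataFrame(
        {
            "best.index": best_idx,
            "PValue": best_p,
            "best.logFC": best_fc,
            "FDR": bh_adjust(best_p),
        }
    )
    if windows is not None:
        out["best.pos"] = best_pos
    return out


def combine_by_feature(
    features: list[GenomicInterval],
    windows: list[GenomicInterval],
    res: WindowTestResult,
    fc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Simes combination over the windows overlapping each feature.

    Features (e.g. promoters) may overlap each other and share windows;
    each feature gets its own combination over its own member set.
    Features with no overlapping windows get NA statistics.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)
    starts = {c: np.array([windows[i].start for i in idx]) for c, idx in by_chrom.items()}
    ends = {c: np.array([windows[i].end for i in idx]) for c, idx in by_chrom.items()}

    rows = []
    pvals = []
    for feat in features:
        idx = by_chrom.get(feat.chrom)
        if idx is None:
            members = np.array([], dtype=int)
        else:
            hit = (starts[feat.chrom] < feat.end) & (ends[feat.chrom] > feat.start)
            members = np.asarray(idx)[hit]
        if len(members) == 0:
            rows.append((0, 0, 0, np.nan))
            pvals.append(np.nan)
        else:
            p = _simes(res.p_value[members])
            rows.append(
                (
                    len(members),
                    int(np.sum(res.logFC[members] > fc_threshold)),
                    int(np.sum(res.logFC[members] < -fc_threshold)),
                    p,
                )
            )
            pvals.append(p)
    pvals = np.asarray(pvals)
    fdr = np.full(len(pvals), np.nan)
    ok = ~np.isnan(pvals)
    if ok.any():
        fdr[ok] = bh_adjust(pvals[ok])
    df = pd.DataFrame(rows, columns=["nWindows", "logFC.up", "logFC.down", "PValue"])
    df.insert(0, "chrom", [f.chrom for f in features])
    df.insert(1, "start", [f.start for f in features])
    df.insert(2, "end", [f.end for f in features])
    df["FDR"] = fdr
    return df


def region_table(
    assign: ClusterAssignment,
    res: WindowTestResult,
    windows: list[GenomicInterval],
    fc_threshold: float = 0.5,
) -> pd.DataFrame:
    """Full region result table: Simes columns plus best-window columns."""
    combined = combine_simes(assign, res, fc_threshold)
    best = best_window(assign, res, windows)
    combined["best.pos"] = best["best.pos"]
    combined["best.logFC"] = best["best.logFC"]
    return combined[
        [
            "chrom",
            "start",
            "end",
            "nWindows",
            "logFC.up",
            "logFC.down",
            "PValue",
            "FDR",
            "best.pos",
            "best.logFC",
        ]
    ]
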