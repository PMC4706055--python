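"""Abundance computation and global background filtering.

Most of the genome is unbound background; the filter estimates the
background abundance as the median average log-CPM of large disjoint
bins (rescaled for the bin/window width difference) and keeps only
windows whose abundance exceeds it by more than log2 of a fold-change
threshold (default 3-fold).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counting import WindowCountMatrix


@dataclass
class FilterResult:
    abundances: np.ndarray  # per-window average abundance, log2 CPM
    back_abundance: float  # background abundance on the window scale
    filter_stat: np.ndarray  # abundances - back_abundance

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.filter_stat = np.asarray(self.filter_stat, dtype=float)


def ave_log_cpm(m: WindowCountMatrix, prior_count: float = 2.0) -> np.ndarray:
    """Average log2 counts-per-million per window.

    The prior count is specified per million reads and scaled to each
    library's size (prior_i = prior_count * total_i / 1e6), making the
    statistic monotone in counts and exactly invariant to rescaling any
    library's counts together with its total:

        abundance_g = log2( 1e6 * mean_i( (count_gi + prior_i) / total_i ) )
    """
    totals = m.totals.astype(float)
    if np.any(totals <= 0):
        raise ValueError("all library totals must be positive")
    prior = prior_count * totals / 1e6
    cpm = (m.counts + prior[None, :]) / totals[None, :]
    return np.log2(cpm.mean(axis=1) * 1e6)


def global_filter(
    windows: WindowCountMatrix,
    bins: WindowCountMatrix,
    prior_count: float = 2.0,
    effective_widths: bool = False,
) -> FilterResult:
    """Filter statistic of each window over the global background.

    The background abundance is the median bin abundance minus
    log2(bin width / window width).  With ``effective_widths`` the ratio
    instead uses width + ext - 1 for both, accounting for the span over
    which an extended fragment can touch an interval; the difference is a
    constant offset of the statistic.
    """
    if windows.n_libraries != bins.n_libraries:
        raise ValueError("window and bin matrices must come from the same libraries")
    ab_win = ave_log_cpm(windows, prior_count)
    ab_bin = ave_log_cpm(bins, prior_count)
    if effective_widths:
        bw = bins.params.width + bins.params.ext - 1
        ww = windows.params.width + windows.params.ext - 1
    else:
        bw = bins.params.width
        ww = windows.params.width
    back = float(np.median(ab_bin)) - np.log2(bw / ww)
    return FilterResult(abundances=ab_win, back_abundance=back, filter_stat=ab_win - back)


def apply_filter(result: FilterResult, min_fc: float = 3.0) -> np.ndarray:
    """Boolean keep-mask: filter statistic strictly above log2(min_fc)."""
    if min_fc <= 0:
        raise ValueError("min_fc must be positive")
    return result.filter_stat > np.log2(min_fc)
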