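"""Normalization: loess offsets for trended bias, TMM factors for composition bias.

Two mutually exclusive schemes, as appropriate for the data at hand:

* ``loess_offsets`` removes library-specific, abundance-dependent
  (trended) biases by fitting a loess curve to each library's M-values
  against average abundance on the filtered windows, yielding a full
  offset matrix for the GLM.
* ``tmm_factors`` removes composition bias with the trimmed mean of
  M-values computed on large disjoint bins, where most of the genome is
  background and unbound regions dominate the trimmed mean.

``effective_offsets`` converts either representation into the natural-log
offset matrix consumed by the GLM fitting routines.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.nonparametric.smoothers_lowess import lowess

from .abundance_filter import ave_log_cpm
from .counting import WindowCountMatrix

LN2 = np.log(2.0)


@dataclass
class NormalizationResult:
    mode: str  # "offsets" or "factors"
    offsets: np.ndarray | None = None  # windows x libraries, natural log
    factors: np.ndarray | None = None  # per-library positive scalars

    def __post_init__(self) -> None:
        if self.mode not in ("offsets", "factors"):
            raise ValueError("mode must be 'offsets' or 'factors'")
        if self.mode == "offsets":
            if self.offsets is None or self.factors is not None:
                raise ValueError("offsets mode requires offsets only")
            self.offsets = np.asarray(self.offsets, dtype=float)
        else:
            if self.factors is None or self.offsets is not None:
                raise ValueError("factors mode requires factors only")
            self.factors = np.asarray(self.factors, dtype=float)
            if np.any(self.factors <= 0):
                raise ValueError("factors must be positive")


def loess_offsets(
    m: WindowCountMatrix,
    span: float = 0.3,
    prior_count: float = 0.5,
    iterations: int = 3,
) -> NormalizationResult:
    """Fast-loess offsets removing abundance-dependent trends between libraries.

    For each library, M = log2(count + 0.5) minus the per-window mean of
    the same quantity is smoothed against average abundance A; the fitted
    curve (converted to natural log, rows re-centred to mean zero) becomes
    that library's offset column.  Requires abundance-filtered input: the
    trend is meaningless if background windows dominate.
    """
    if m.n_libraries < 2:
        raise ValueError("at least two libraries are required")
    n = m.n_windows
    if n < 10 or n * span < 2:
        raise ValueError("too few windows for the requested span")
    adjc = np.log2(m.counts + prior_count)
    rowmean = adjc.mean(axis=1)
    abundance = ave_log_cpm(m)
    delta = 0.01 * (abundance.max() - abundance.min())
    offsets = np.empty((n, m.n_libraries))
    for i in range(m.n_libraries):
        mvals = adjc[:, i] - rowmean
        fitted = lowess(
            mvals,
            abundance,
            frac=span,
            it=iterations,
            delta=delta,
            return_sorted=False,
        )
        offsets[:, i] = fitted * LN2
    offsets -= offsets.mean(axis=1, keepdims=True)
    return NormalizationResult(mode="offsets", offsets=offsets)


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    logratio_trim: float,
    sum_trim: float,
) -> float:
    """log2 TMM factor of one library against the reference."""
    keep = (obs > 0) & (ref > 0)
    obs = obs[keep].astype(float)
    ref = ref[keep].astype(float)
    if len(obs) == 0:
        return 0.0
    log_r = np.log2((obs / n_obs) / (ref / n_ref))
    abs_e = 0.5 * (np.log2(obs / n_obs) + np.log2(ref / n_ref))
    # inverse asymptotic variance of each M-value (delta method, binomial)
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)

    n = len(log_r)
    lo_l = np.floor(n * logratio_trim) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * sum_trim) + 1
    hi_s = n + 1 - lo_s
    rank_r = np.argsort(np.argsort(log_r, kind="stable"), kind="stable") + 1
    rank_e = np.argsort(np.argsort(abs_e, kind="stable"), kind="stable") + 1
    keep2 = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if not keep2.any():
        return 0.0
    f = np.sum(log_r[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    bins: WindowCountMatrix,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> NormalizationResult:
    """Trimmed-mean-of-M-values factors from bin counts.

    The reference library is the one whose upper-quartile CPM is closest
    to the mean upper quartile; bins zero in either library of a pair are
    dropped, the stated fractions are trimmed by M and by A, and the
    remaining M-values are averaged with inverse-approximate-variance
    weights.  Factors are rescaled to geometric mean one.
    """
    if bins.n_libraries < 2:
        raise ValueError("at least two libraries are required")
    counts = bins.counts.astype(float)
    totals = bins.totals.astype(float)
    if np.any(counts.sum(axis=0) == 0):
        raise ValueError("a library has all-zero bin counts")

    uq = np.array(
        [np.percentile(counts[counts[:, i] > 0, i] / totals[i], 75) for i in range(bins.n_libraries)]
    )
    ref = int(np.argmin(np.abs(uq - uq.mean())))

    logf = np.zeros(bins.n_libraries)
    for i in range(bins.n_libraries):
        if i == ref:
            continue
        logf[i] = _tmm_pair(
            counts[:, i], counts[:, ref], totals[i], totals[ref], logratio_trim, sum_trim
        )
    factors = 2.0**logf
    factors /= np.exp(np.mean(np.log(factors)))
    return NormalizationResult(mode="factors", factors=factors)


def effective_offsets(m: WindowCountMatrix, norm: NormalizationResult) -> np.ndarray:
    """Natural-log GLM offset matrix combining library sizes and normalization.

    o[g, i] = log(total_i) + offsets[g, i]           (offsets mode)
            = log(total_i) + log(factor_i)           (factors mode)
    """
    log_tot = np.log(m.totals.astype(float))
    if norm.mode == "offsets":
        if norm.offsets.shape != (m.n_windows, m.n_libraries):
            raise ValueError("offset matrix shape mismatch")
        return log_tot[None, :] + norm.offsets
    return np.broadcast_to(
        log_tot + np.log(norm.factors), (m.n_windows, m.n_libraries)
    ).copy()
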