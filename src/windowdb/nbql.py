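"""Negative-binomial quasi-likelihood modelling of window counts.

Counts for each window are modelled as NB-distributed with a log link and
per-observation offsets.  Biological variability enters twice: an
abundance-dependent NB dispersion trend shared across windows, and a
per-window quasi-likelihood (QL) dispersion that scales the residual
deviance.  Raw QL dispersions are shrunk towards their own abundance
trend by empirical Bayes; the strength of shrinkage is governed by the
prior degrees of freedom estimated by moment-matching a scaled
F-distribution to the raw/trend ratios.  Differences between conditions
are tested per window with QL F-tests on GLM deviances.

All fitting is vectorized across windows: one design matrix, count and
offset matrices of shape (windows, libraries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special, stats
from scipy.linalg import null_space
from statsmodels.nonparametric.smoothers_lowess import lowess

LN2 = np.log(2.0)
_MIN_P = np.nextafter(0.0, 1.0)


# ---------------------------------------------------------------------------
# design helpers


def design_from_groups(groups) -> tuple[np.ndarray, list[str]]:
    """One-hot (no intercept) design matrix from group labels."""
    labels = sorted(set(groups))
    X = np.zeros((len(groups), len(labels)))
    for i, g in enumerate(groups):
        X[i, labels.index(g)] = 1.0
    return X, labels


def contrast_vector(labels: list[str], expr: str) -> np.ndarray:
    """Parse a simple two-group contrast like ``"proB-matureB"``."""
    try:
        plus, minus = expr.split("-")
    except ValueError:
        raise ValueError(f"contrast must look like 'groupA-groupB', got {expr!r}")
    c = np.zeros(len(labels))
    c[labels.index(plus.strip())] = 1.0
    c[labels.index(minus.strip())] = -1.0
    return c


# ---------------------------------------------------------------------------
# NB likelihood pieces


def nb_deviance(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-window residual deviance, summed over libraries.

    2 * sum[ y log(y/mu) - (y + 1/phi) log((y + 1/phi)/(mu + 1/phi)) ],
    with the y = 0 and phi = 0 (Poisson) limits handled analytically.
    """
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi = np.asarray(phi, dtype=float)
    if phi.ndim == 1:
        phi = phi[:, None]
    if phi.ndim:
        phi = np.broadcast_to(phi, y.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        ylogy = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
    if np.ndim(phi) == 0:
        if phi == 0:
            unit = ylogy - (y - mu)
        else:
            r = 1.0 / phi
            unit = ylogy - (y + r) * np.log((y + r) / (mu + r))
    else:
        r = np.where(phi > 0, 1.0 / np.maximum(phi, 1e-300), np.inf)
        with np.errstate(invalid="ignore"):
            nb_part = np.where(
                phi > 0,
                (y + r) * np.log(np.where(phi > 0, (y + r) / (mu + r), 1.0)),
                y - mu,
            )
        unit = ylogy - nb_part
    return 2.0 * unit.sum(axis=-1)


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi) -> np.ndarray:
    """Per-window NB log-likelihood (Poisson at phi == 0), summed over libraries."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-10)
    phi_arr = np.asarray(phi, dtype=float)
    if np.ndim(phi_arr) == 0 and phi_arr == 0:
        ll = y * np.log(mu) - mu - special.gammaln(y + 1)
        return ll.sum(axis=-1)
    if phi_arr.ndim == 1:
        phi_arr = phi_arr[:, None]
    phi_b = np.broadcast_to(phi_arr, y.shape) if phi_arr.ndim else np.full_like(y, phi_arr)
    pois = y * np.log(mu) - mu - special.gammaln(y + 1)
    phi_s = np.maximum(phi_b, 1e-300)
    r = 1.0 / phi_s
    nb = (
        special.gammaln(y + r)
        - special.gammaln(r)
        - special.gammaln(y + 1)
        + y * np.log(mu)
        - (y + r) * np.log1p(phi_s * mu)
        + y * np.log(phi_s)
    )
    ll = np.where(phi_b > 0, nb, pois)
    return ll.sum(axis=-1)


# ---------------------------------------------------------------------------
# vectorized damped IRLS


def _irls(
    y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi,
    beta0: np.ndarray | None = None,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit NB GLMs for all windows at once.

    Returns (beta, mu, deviance, converged).  Step-halving is applied
    per window whenever an update increases the deviance.
    """
    y = np.asarray(y, dtype=float)
    G, L = y.shape
    p = X.shape[1]
    phi_col = np.asarray(phi, dtype=float)
    phi_col = phi_col.reshape(-1, 1) if phi_col.ndim == 1 else phi_col

    if beta0 is None:
        z0 = np.log(y + 0.5) - offset
        beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    else:
        beta = beta0.copy()

    def mu_of(b):
        eta = offset + b @ X.T
        return np.exp(np.clip(eta, -700, 700))

    mu = mu_of(beta)
    dev = nb_deviance(y, mu, phi_col if np.ndim(phi) else phi)
    converged = np.zeros(G, dtype=bool)
    ridge = 1e-8 * np.eye(p)

    for _ in range(max_iter):
        denom = 1.0 + phi_col * mu
        w = mu / denom
        score_resid = (y - mu) / denom  # = W * (y-mu)/mu
        grad = np.einsum("gl,lp->gp", score_resid, X)
        gnorm = np.abs(grad).max(axis=1)
        converged = gnorm < tol
        if converged.all():
            break
        eta_work = (offset + beta @ X.T) - offset  # X beta
        rhs = np.einsum("gl,lp->gp", w * eta_work, X) + grad
        XtWX = np.einsum("gl,lp,lq->gpq", w, X, X) + ridge
        beta_new = np.linalg.solve(XtWX, rhs[..., None])[..., 0]

        step = beta_new - beta
        cand = beta + step
        mu_c = mu_of(cand)
        dev_c = nb_deviance(y, mu_c, phi_col if np.ndim(phi) else phi)
        for _half in range(15):
            worse = (dev_c > dev + 1e-8) & ~converged
            if not worse.any():
                break
            step[worse] *= 0.5
            cand[worse] = beta[worse] + step[worse]
            mu_c = mu_of(cand)
            dev_c = nb_deviance(y, mu_c, phi_col if np.ndim(phi) else phi)
        upd = ~converged
        beta[upd] = cand[upd]
        mu = mu_of(beta)
        dev = nb_deviance(y, mu, phi_col if np.ndim(phi) else phi)
    return beta, mu, dev, converged


def fit_nb_glm(
    counts_row: np.ndarray,
    design: np.ndarray,
    offsets_row: np.ndarray,
    phi: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit one window's NB GLM; returns (coef, fitted means, deviance).

    Thin wrapper over the vectorized fitter.  Non-convergence returns the
    last iterate (the deviance is still valid as an upper bound).
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    X = np.asarray(design, dtype=float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix must have full column rank")
    y = np.asarray(counts_row, dtype=float)[None, :]
    off = np.asarray(offsets_row, dtype=float)[None, :]
    beta, mu, dev, _ = _irls(y, X, off, float(phi))
    return beta[0], mu[0], float(dev[0])


# ---------------------------------------------------------------------------
# dispersion estimation


@dataclass
class DispersionFit:
    trended: np.ndarray  # per-window NB dispersion from the abundance trend
    common: float  # scalar diagnostic dispersion

    def __post_init__(self) -> None:
        self.trended = np.asarray(self.trended, dtype=float)
        if np.any(self.trended <= 0) or self.common <= 0:
            raise ValueError("dispersions must be positive")


def _interp_max(logphi: np.ndarray, values: np.ndarray) -> float:
    """Quadratic interpolation of the grid maximum, in log-dispersion."""
    j = int(np.argmax(values))
    if j == 0 or j == len(values) - 1:
        return float(logphi[j])
    x0, x1, x2 = logphi[j - 1 : j + 2]
    y0, y1, y2 = values[j - 1 : j + 2]
    denom = (y0 - y1) * (x2 - x1) + (y2 - y1) * (x1 - x0)
    if denom >= 0:  # degenerate / flat
        return float(x1)
    vertex = x1 + 0.5 * ((y0 - y1) * (x2 - x1) ** 2 - (y2 - y1) * (x1 - x0) ** 2) / denom
    return float(np.clip(vertex, x0, x2))


def estimate_dispersion_trend(
    m,
    design: np.ndarray,
    offsets: np.ndarray,
    grid_min: float = 1e-4,
    grid_max: float = 1.0,
    grid_points: int = 41,
    n_bins: int = 20,
    span: float = 0.5,
) -> DispersionFit:
    """Abundance-dependent NB dispersion trend via Cox-Reid profile likelihood.

    For each dispersion on a log-spaced grid the GLMs are refitted (warm
    started from the previous grid point) and the Cox-Reid adjusted
    profile likelihood (APL) evaluated per window.  Windows are pooled
    into abundance bins; each bin's APL-maximizing dispersion is smoothed
    by loess against bin abundance and interpolated back to the windows.
    """
    from .abundance_filter import ave_log_cpm

    X = np.asarray(design, dtype=float)
    y = np.asarray(m.counts, dtype=float)
    df_res = y.shape[1] - X.shape[1]
    if df_res < 1:
        raise ValueError("no replication: residual degrees of freedom is zero")

    A = ave_log_cpm(m)
    logphi = np.linspace(np.log(grid_min), np.log(grid_max), grid_points)
    apl = np.empty((grid_points, y.shape[0]))
    beta = None
    for k, lp in enumerate(logphi):
        phi = float(np.exp(lp))
        beta, mu, _, _ = _irls(y, X, offsets, phi, beta0=beta)
        w = mu / (1.0 + phi * mu)
        XtWX = np.einsum("gl,lp,lq->gpq", w, X, X)
        _, logdet = np.linalg.slogdet(XtWX + 1e-12 * np.eye(X.shape[1]))
        apl[k] = nb_loglik(y, mu, phi) - 0.5 * logdet

    common = float(np.exp(_interp_max(logphi, apl.sum(axis=1))))

    n_bins_eff = min(n_bins, max(1, y.shape[0] // 50))
    edges = np.quantile(A, np.linspace(0, 1, n_bins_eff + 1))
    edges = np.unique(edges)
    bin_idx = np.clip(np.digitize(A, edges[1:-1]), 0, len(edges) - 2)
    bin_ab, bin_lp = [], []
    for b in range(len(edges) - 1):
        members = bin_idx == b
        if not members.any():
            continue
        bin_ab.append(float(A[members].mean()))
        bin_lp.append(_interp_max(logphi, apl[:, members].sum(axis=1)))
    bin_ab = np.asarray(bin_ab)
    bin_lp = np.asarray(bin_lp)

    if len(bin_ab) >= 4:
        smoothed = lowess(bin_lp, bin_ab, frac=min(1.0, max(span, 4 / len(bin_ab))),
                          it=3, return_sorted=False)
    else:
        smoothed = np.full_like(bin_lp, bin_lp.mean())
    order = np.argsort(bin_ab)
    trended = np.exp(np.interp(A, bin_ab[order], smoothed[order]))
    return DispersionFit(trended=trended, common=common)


# ---------------------------------------------------------------------------
# QL dispersions and empirical Bayes


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _winsorized_logf_var(df1: float, df2: float, p_lo: float, p_hi: float) -> float:
    """Variance of log F(df1, df2) winsorized at its own (p_lo, p_hi) quantiles."""
    dist = stats.f(df1, df2)
    q_lo, q_hi = np.log(dist.ppf(p_lo)), np.log(dist.ppf(p_hi))
    # E[g(Z)] by probability-integral quadrature
    u = np.linspace(1e-6, 1 - 1e-6, 4001)
    z = np.clip(np.log(dist.ppf(u)), q_lo, q_hi)
    mean = np.trapezoid(z, u)
    return float(np.trapezoid((z - mean) ** 2, u))


def _fit_f_dist(
    s2: np.ndarray,
    df1: float,
    covariate: np.ndarray,
    robust: bool,
    span: float = 0.4,
    winsor: tuple[float, float] = (0.05, 0.95),
) -> tuple[np.ndarray, float, np.ndarray | float]:
    """Moment-match s2 ~ s2_trend(covariate) * F(df1, df_prior).

    Returns (s2_trend per window, global df_prior, per-window df_prior).
    The per-window value differs from the global one only when robust
    estimation flags a window as an outlier, in which case its prior df
    is reduced so the outlier is not over-shrunk towards the trend.
    """
    # exact-zero deviances (identical counts within groups) are atoms the
    # continuous log-chi-squared theory does not cover; replace them by the
    # smallest positive value instead of letting the log explode
    pos = s2[s2 > 0]
    if len(pos) == 0:
        raise ValueError("all raw quasi-dispersions are zero")
    z = np.log(np.maximum(s2, float(pos.min())))
    if len(z) >= 20:
        delta = 0.01 * (covariate.max() - covariate.min())
        # it=0: the left skew of log-chi-squared is expected, not outliers;
        # robustness iterations would bias the conditional-mean trend upward
        ztrend = lowess(z, covariate, frac=span, it=0, delta=delta, return_sorted=False)
    else:
        ztrend = np.full_like(z, z.mean())
    resid = z - ztrend

    e_chisq = special.digamma(df1 / 2) - np.log(df1 / 2)  # E[log(chi2_df1/df1)]
    var_chisq = special.polygamma(1, df1 / 2)

    if not robust:
        evar = float(np.var(resid, ddof=1)) - var_chisq
        if evar > 0:
            df2 = 2.0 * _trigamma_inverse(evar)
        else:
            df2 = np.inf
        df_prior_window: np.ndarray | float = df2
    else:
        lo, hi = np.quantile(resid, winsor)
        wvar = float(np.var(np.clip(resid, lo, hi), ddof=1))

        def gap(log_df2: float) -> float:
            return _winsorized_logf_var(df1, np.exp(log_df2), *winsor) - wvar

        # variance of winsorized log-F decreases towards the chi-squared
        # limit as df2 grows; no crossing means effectively infinite prior df
        if gap(np.log(1e6)) >= 0:
            df2 = np.inf
        elif gap(np.log(0.1)) <= 0:
            df2 = 0.1
        else:
            df2 = float(np.exp(optimize.brentq(gap, np.log(0.1), np.log(1e6), xtol=1e-4)))

        df_prior_window = np.full(len(z), df2)
        if np.isfinite(df2):
            e_logf = e_chisq - (special.digamma(df2 / 2) - np.log(df2 / 2))
            target_sf = float(stats.f(df1, df2).sf(np.exp(hi - e_logf)))
            outliers = np.flatnonzero(resid > hi)
            for g in outliers:
                fstat = np.exp(resid[g] - e_logf)

                def tail_gap(log_d: float) -> float:
                    return stats.f(df1, np.exp(log_d)).sf(fstat) - target_sf

                if tail_gap(np.log(df2)) >= 0:
                    continue
                if tail_gap(np.log(1e-3)) <= 0:
                    df_prior_window[g] = 1e-3
                else:
                    df_prior_window[g] = float(
                        np.exp(optimize.brentq(tail_gap, np.log(1e-3), np.log(df2), xtol=1e-3))
                    )

    if np.isfinite(df2):
        e_logf = e_chisq - (special.digamma(df2 / 2) - np.log(df2 / 2))
    else:
        e_logf = e_chisq
    s2_trend = np.exp(ztrend - e_logf)
    return s2_trend, float(df2), df_prior_window


@dataclass
class QLFit:
    """NB GLM fits plus raw, trended and shrunken QL dispersions."""

    coef: np.ndarray  # windows x coefficients, natural log scale
    mu: np.ndarray  # fitted means
    df_residual: float
    s2_raw: np.ndarray
    s2_trend: np.ndarray
    s2_post: np.ndarray
    df_prior: float | np.ndarray  # scalar, or per-window when robust
    counts: np.ndarray
    design: np.ndarray
    offsets: np.ndarray
    phi: np.ndarray
    abundance: np.ndarray


def ql_fit(
    m,
    design: np.ndarray,
    offsets: np.ndarray,
    disp: DispersionFit,
    robust: bool = False,
) -> QLFit:
    """Fit per-window GLMs at the trended NB dispersion and shrink QL dispersions.

    Raw quasi-dispersions are residual deviances over residual df; they
    are squeezed towards their abundance trend with empirical-Bayes
    weights given by the estimated prior degrees of freedom.
    """
    from .abundance_filter import ave_log_cpm

    X = np.asarray(design, dtype=float)
    y = np.asarray(m.counts, dtype=float)
    df_res = y.shape[1] - X.shape[1]
    if df_res < 1:
        raise ValueError("no replication: residual degrees of freedom is zero")
    phi = np.asarray(disp.trended, dtype=float)
    beta, mu, dev, _ = _irls(y, X, offsets, phi)
    s2_raw = dev / df_res
    A = ave_log_cpm(m)

    if np.allclose(s2_raw, s2_raw[0]):
        s2_trend = np.full_like(s2_raw, s2_raw.mean())
        df_prior: float | np.ndarray = np.inf
    else:
        s2_trend, df2, df_prior = _fit_f_dist(s2_raw, df_res, A, robust)
        if not robust:
            df_prior = df2

    d0 = np.asarray(df_prior, dtype=float)
    with np.errstate(invalid="ignore"):
        s2_post = np.where(
            np.isinf(d0),
            s2_trend,
            (d0 * s2_trend + df_res * s2_raw) / (d0 + df_res),
        )
    return QLFit(
        coef=beta,
        mu=mu,
        df_residual=float(df_res),
        s2_raw=s2_raw,
        s2_trend=s2_trend,
        s2_post=s2_post,
        df_prior=df_prior,
        counts=y,
        design=X,
        offsets=np.asarray(offsets, dtype=float),
        phi=phi,
        abundance=A,
    )


@dataclass
class WindowTestResult:
    logFC: np.ndarray  # log2 fold change of the contrast
    logCPM: np.ndarray
    F: np.ndarray
    p_value: np.ndarray

    def __len__(self) -> int:
        return len(self.p_value)


def ql_f_test(fit: QLFit, contrast: np.ndarray) -> WindowTestResult:
    """Quasi-likelihood F-test of a contrast for every window.

    The test statistic is the deviance difference between the full fit
    and a fit with the contrast constrained to zero, divided by the
    contrast rank and the shrunken QL dispersion; the reference
    distribution is F with (rank, prior df + residual df), degenerating
    to scaled chi-squared when the prior df is infinite.
    """
    c = np.asarray(contrast, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != fit.design.shape[1]:
        raise ValueError("contrast dimension does not match design columns")
    if not c.any():
        raise ValueError("contrast must not be all zero")
    df_test = np.linalg.matrix_rank(c)

    N = null_space(c.T)  # basis of the null-constrained coefficient space
    dev_full = nb_deviance(fit.counts, fit.mu, fit.phi)
    if N.shape[1] == 0:
        X_null = np.zeros((fit.design.shape[0], 0))
        mu0 = np.exp(np.clip(fit.offsets, -700, 700))
        dev_null = nb_deviance(fit.counts, mu0, fit.phi)
    else:
        X_null = fit.design @ N
        _, _, dev_null, _ = _irls(fit.counts, X_null, fit.offsets, fit.phi)

    devdiff = np.maximum(dev_null - dev_full, 0.0)
    s2 = np.maximum(fit.s2_post, 1e-10)
    F = (devdiff / df_test) / s2

    d0 = np.asarray(fit.df_prior, dtype=float)
    df_total = d0 + fit.df_residual
    if np.ndim(df_total) == 0:
        df_total = np.full(len(F), float(df_total))
    p = np.empty(len(F))
    inf_mask = np.isinf(df_total)
    if inf_mask.any():
        p[inf_mask] = stats.chi2.sf(F[inf_mask] * df_test, df_test)
    if (~inf_mask).any():
        p[~inf_mask] = stats.f.sf(F[~inf_mask], df_test, df_total[~inf_mask])
    p = np.clip(p, _MIN_P, 1.0)

    logfc = (fit.coef @ c[:, 0]) / LN2
    return WindowTestResult(logFC=logfc, logCPM=fit.abundance, F=F, p_value=p)


# ---------------------------------------------------------------------------
# diagnostics


def mds_distances(adjusted_logcounts: np.ndarray, top: int = 500) -> np.ndarray:
    """Pairwise library distances: RMS of the `top` largest |log-fold changes|.

    The distance between two libraries summarizes their overall log2
    difference on the most discrepant windows, the quantity plotted on
    multi-dimensional scaling diagnostics.
    """
    Y = np.asarray(adjusted_logcounts, dtype=float)
    if Y.shape[1] < 2:
        raise ValueError("at least two libraries are required")
    L = Y.shape[1]
    k = min(top, Y.shape[0])
    D = np.zeros((L, L))
    for i in range(L):
        for j in range(i + 1, L):
            m = np.abs(Y[:, i] - Y[:, j])
            largest = np.partition(m, len(m) - k)[len(m) - k :] if k < len(m) else m
            D[i, j] = D[j, i] = float(np.sqrt(np.mean(largest**2)))
    return D
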