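"""Bayesian logistic adaptive-spline risk curves with measurement-error averaging.

The risk of spontaneous preterm birth (sPTB) as a function of a taxon's
log10 relative abundance is modelled nonparametrically:

    y_i ~ Bernoulli(expit(theta_{b(i)}))

with one latent value theta per (binned) covariate position and a
locally-adaptive shrinkage prior on second differences of theta — a
horseshoe trend-filtering prior, giving piecewise-smooth curves that can
still jump where the data demand it and behave well at the extremes of the
covariate range. Only samples in which the taxon was detected enter a fit.

Posterior computation is an exact blocked Gibbs sampler: the logistic
likelihood is augmented with Polya-Gamma variables (one per bin, summed
over that bin's observations), the horseshoe local/global scales use the
inverse-gamma auxiliary parameterisation, and the latent curve update is a
single multivariate-normal draw with banded precision.

Measurement error is propagated by refitting on ``n_resamples`` (default 5)
perturbed covariate vectors drawn from the replicate-error model and
averaging the resulting posterior-mean curves; effect size, threshold and
association evidence are computed from the averaged curve, credible bands
from the pooled posterior draws. Because the perturbation is widest at low
abundance, the averaged curve relaxes toward the baseline risk (the sPTB
proportion among detected samples) where measurement error is large.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

__all__ = [
    "SplineConfig",
    "SplinePosterior",
    "RiskSplineFit",
    "fit_adaptive_spline",
    "fit_with_measurement_error",
    "fit_absolute_abundance_risk",
    "effect_size",
    "signed_effect_size",
    "risk_threshold",
    "threshold_from_curve",
    "association_significance",
    "summary_table",
]


@dataclass
class SplineConfig:
    """MCMC and model settings for the adaptive-spline risk model."""

    seed: int
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    #: covariate positions are quantile-binned when unique values exceed this
    max_bins: int = 100
    #: minimum detected samples for a fit
    min_n: int = 50
    #: global horseshoe scale; None = 1/sqrt(n) heuristic
    tau0: float | None = None
    #: weakly-informative prior scales for the level and slope (logit units)
    level_scale: float = 3.0
    slope_scale: float = 2.0
    #: truncation of the Polya-Gamma sum-of-gammas representation
    pg_trunc: int = 128
    rhat_threshold: float = 1.05
    #: taxa with |effect size| below this are excluded from threshold calling
    effect_floor: float = 0.10


@dataclass
class SplinePosterior:
    """Posterior of a single adaptive-spline fit."""

    x_grid: np.ndarray  # bin centres (ordered)
    f: np.ndarray  # posterior mean risk per bin
    band_lo: np.ndarray
    band_hi: np.ndarray
    theta_draws: np.ndarray | None  # (chains, draws, bins)
    n: int
    baseline: float
    degenerate: bool = False
    converged: bool = True
    rhat_max: float = np.nan

    @property
    def risk_draws(self) -> np.ndarray | None:
        """Pooled posterior draws of the risk curve, (total draws, bins)."""
        if self.theta_draws is None:
            return None
        c, d, b = self.theta_draws.shape
        return expit(self.theta_draws.reshape(c * d, b))


@dataclass
class RiskSplineFit:
    """Averaged measurement-error-aware risk-curve fit for one taxon."""

    taxon: str
    x_grid: np.ndarray
    f: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    g_eff: float
    threshold: float | None
    baseline: float
    p_assoc: float
    n_detected: int
    q_value: float | None = None
    resample_curves: list = field(default_factory=list)
    degenerate: bool = False
    converged: bool = True
    pooled_draws: np.ndarray | None = None

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "taxon": self.taxon,
                    "x_grid": self.x_grid.tolist(),
                    "f": self.f.tolist(),
                    "band_lo": self.band_lo.tolist(),
                    "band_hi": self.band_hi.tolist(),
                    "g_eff": self.g_eff,
                    "threshold": self.threshold,
                    "baseline": self.baseline,
                    "p_assoc": self.p_assoc,
                    "q_value": self.q_value,
                    "n_detected": self.n_detected,
                    "degenerate": self.degenerate,
                    "converged": self.converged,
                },
                fh,
                indent=2,
            )


# ---------------------------------------------------------------------------
# Polya-Gamma draws
# ---------------------------------------------------------------------------

def _sample_pg(b: np.ndarray, c: np.ndarray, rng: np.random.Generator, trunc: int = 128):
    """Draw PG(b_j, c_j) elementwise via the truncated sum-of-gammas series.

    X = (1/2 pi^2) sum_k g_k / ((k-1/2)^2 + a^2), g_k ~ Gamma(b, 1),
    a = c/(2 pi); the truncated tail is replaced by its expectation.
    """
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    a2 = (c / (2.0 * np.pi)) ** 2
    k = np.arange(1, trunc + 1) - 0.5
    denom = k[None, :] ** 2 + a2[:, None]  # (m, trunc)
    g = rng.gamma(np.broadcast_to(b[:, None], denom.shape), 1.0)
    x = (g / denom).sum(axis=1)
    # tail expectation: b * sum_{k>K} 1/((k-1/2)^2+a^2) ~ b * int_K^inf du/(u^2+a^2)
    a = np.sqrt(a2)
    with np.errstate(divide="ignore", invalid="ignore"):
        tail = np.where(a > 0, (np.pi / 2 - np.arctan(trunc / np.maximum(a, 1e-300))) / np.maximum(a, 1e-300), 1.0 / trunc)
    x = x + b * tail
    return x / (2.0 * np.pi**2)


def _inv_gamma(rng, shape, scale):
    """Draw from InverseGamma(shape, scale); scale is the IG scale parameter."""
    return scale / rng.gamma(shape, 1.0, size=np.shape(scale) or None)


# ---------------------------------------------------------------------------
# binning and diagnostics
# ---------------------------------------------------------------------------

def _make_bins(x: np.ndarray, max_bins: int):
    """Bin covariate positions: unique values, or quantile bins above max_bins.

    Returns (grid of bin centres, bin index per observation).
    """
    ux = np.unique(x)
    if ux.size <= max_bins:
        idx = np.searchsorted(ux, x)
        return ux, idx
    qs = np.quantile(x, np.linspace(0, 1, max_bins + 1))
    edges = np.unique(qs)[1:-1]
    idx = np.searchsorted(edges, x, side="right")
    nb = idx.max() + 1
    centres = np.array([x[idx == j].mean() for j in range(nb)])
    # centres are increasing by construction of the quantile edges
    return centres, idx


def _split_rhat(draws: np.ndarray) -> float:
    """Max split-Rhat over bins; draws has shape (chains, ndraws, bins)."""
    c, n, b = draws.shape
    half = n // 2
    if half < 2:
        return np.nan
    seqs = np.concatenate([draws[:, :half, :], draws[:, half : 2 * half, :]], axis=0)
    m, n2, _ = seqs.shape
    mean_j = seqs.mean(axis=1)  # (m, b)
    var_j = seqs.var(axis=1, ddof=1)
    W = var_j.mean(axis=0)
    B = n2 * mean_j.var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (n2 - 1) / n2 * W + B / n2
        rhat = np.sqrt(var_hat / W)
    rhat = rhat[np.isfinite(rhat)]
    return float(rhat.max()) if rhat.size else np.nan


# ---------------------------------------------------------------------------
# the Gibbs sampler
# ---------------------------------------------------------------------------

def fit_adaptive_spline(x, y, config: SplineConfig) -> SplinePosterior:
    """Fit the horseshoe trend-filtering logistic model to (x, y).

    ``x`` are log10 abundances of *detected* samples (finite), ``y`` binary
    outcomes (1 = sPTB). All-0 or all-1 outcomes yield a degenerate flat
    fit at the observed proportion rather than an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    if not np.all(np.isfinite(x)):
        raise ValueError("x must be finite (detected samples only)")
    n = x.size
    if n < config.min_n:
        raise ValueError(f"n={n} below min_n={config.min_n}")
    baseline = float(y.mean())
    grid, idx = _make_bins(x, config.max_bins)
    B = grid.size
    if baseline in (0.0, 1.0):
        f = np.full(B, baseline)
        return SplinePosterior(grid, f, f.copy(), f.copy(), None, n, baseline, degenerate=True)

    nb = np.bincount(idx, minlength=B).astype(float)
    ysum = np.bincount(idx, weights=y, minlength=B)
    kappa = ysum - nb / 2.0

    m = max(B - 2, 0)
    D = np.zeros((m, B))
    for j in range(m):
        D[j, j : j + 3] = (1.0, -2.0, 1.0)

    tau0 = config.tau0 if config.tau0 is not None else 1.0 / np.sqrt(n)
    m0 = float(np.clip(logit(baseline), -5, 5))
    P0 = np.zeros((B, B))
    P0[0, 0] += 1.0 / config.level_scale**2
    if B >= 2:
        s1 = 1.0 / config.slope_scale**2
        P0[:2, :2] += s1 * np.array([[1.0, -1.0], [-1.0, 1.0]])
    b0 = np.zeros(B)
    b0[0] = m0 / config.level_scale**2

    ss = np.random.SeedSequence(config.seed)
    chain_seeds = ss.spawn(config.chains)
    keep = np.empty((config.chains, config.draws, B))
    for ch in range(config.chains):
        rng = np.random.default_rng(chain_seeds[ch])
        theta = np.full(B, m0) + 0.1 * rng.standard_normal(B)
        lam2 = np.ones(m)
        nu = np.ones(m)
        tau2 = tau0**2
        xi = 1.0
        for it in range(config.warmup + config.draws):
            omega = _sample_pg(nb, np.abs(theta), rng, config.pg_trunc)
            if m > 0:
                d = D @ theta
                lam2 = np.clip(_inv_gamma(rng, 1.0, 1.0 / nu + d**2 / (2 * tau2)), 1e-12, 1e12)
                nu = _inv_gamma(rng, 1.0, 1.0 + 1.0 / lam2)
                tau2 = float(
                    np.clip(
                        _inv_gamma(rng, (m + 1) / 2.0, 1.0 / xi + float((d**2 / (2 * lam2)).sum())),
                        1e-14,
                        1e10,
                    )
                )
                xi = float(_inv_gamma(rng, 1.0, 1.0 / tau0**2 + 1.0 / tau2))
                w = np.clip(1.0 / (tau2 * lam2), 1e-12, 1e12)
                Q = (D.T * w) @ D
            else:
                Q = np.zeros((B, B))
            Q += P0
            Q[np.diag_indices(B)] += omega + 1e-9
            L = np.linalg.cholesky(Q)
            mu = np.linalg.solve(L.T, np.linalg.solve(L, kappa + b0))
            z = rng.standard_normal(B)
            theta = mu + np.linalg.solve(L.T, z)
            if it >= config.warmup:
                keep[ch, it - config.warmup] = theta

    rhat = _split_rhat(keep)
    converged = not (np.isfinite(rhat) and rhat > config.rhat_threshold)
    if not converged:
        warnings.warn(f"split-Rhat {rhat:.3f} exceeds {config.rhat_threshold}", stacklevel=2)
    p_draws = expit(keep.reshape(-1, B))
    return SplinePosterior(
        x_grid=grid,
        f=p_draws.mean(axis=0),
        band_lo=np.quantile(p_draws, 0.025, axis=0),
        band_hi=np.quantile(p_draws, 0.975, axis=0),
        theta_draws=keep,
        n=n,
        baseline=baseline,
        converged=converged,
        rhat_max=rhat,
    )


# ---------------------------------------------------------------------------
# effect size, threshold, significance
# ---------------------------------------------------------------------------

def signed_effect_size(x_grid, f) -> float:
    """max(f) - min(f), signed positive when the maximum sits at larger x
    than the minimum (risk rising with abundance); ties break leftmost."""
    f = np.asarray(f, dtype=float)
    imin = int(np.argmin(f))
    imax = int(np.argmax(f))
    mag = float(f[imax] - f[imin])
    if mag == 0.0:
        return 0.0
    return mag if imax > imin else -mag


def effect_size(fit: RiskSplineFit) -> float:
    return signed_effect_size(fit.x_grid, fit.f)


def threshold_from_curve(x_grid, f, g_eff: float, effect_floor: float = 0.10):
    """Abundance threshold: crossing of f with y* = min(f) + 0.1|gEff|.

    Absent when |gEff| < ``effect_floor``. For a positive association the
    leftmost crossing to the right of the global argmin is taken (mirror
    image for a negative association), with linear interpolation between
    grid points.
    """
    f = np.asarray(f, dtype=float)
    x = np.asarray(x_grid, dtype=float)
    if abs(g_eff) < effect_floor or f.size < 2:
        return None
    ystar = float(f.min()) + 0.1 * abs(g_eff)
    i0 = int(np.argmin(f))  # leftmost by argmin convention
    if g_eff > 0:
        for k in range(i0 + 1, f.size):
            if f[k] >= ystar:
                x0, x1, f0, f1 = x[k - 1], x[k], f[k - 1], f[k]
                if f1 == f0:
                    return float(x1)
                return float(x0 + (ystar - f0) / (f1 - f0) * (x1 - x0))
    else:
        for k in range(i0 - 1, -1, -1):
            if f[k] >= ystar:
                x0, x1, f0, f1 = x[k], x[k + 1], f[k], f[k + 1]
                if f0 == f1:
                    return float(x0)
                return float(x1 + (ystar - f1) / (f0 - f1) * (x0 - x1))
    return None


def risk_threshold(fit: RiskSplineFit, effect_floor: float = 0.10):
    return threshold_from_curve(fit.x_grid, fit.f, fit.g_eff, effect_floor)


def association_significance(fits: list[RiskSplineFit], alpha: float = 0.05,
                             effect_floor: float = 0.10):
    """Benjamini-Hochberg FDR across taxa; updates each fit's q_value.

    A fit is called significant when q < alpha AND |gEff| >= effect_floor.
    Returns a summary DataFrame.
    """
    import pandas as pd
    from statsmodels.stats.multitest import multipletests

    testable = [f for f in fits if not f.degenerate]
    if testable:
        ps = np.array([f.p_assoc for f in testable])
        _, qs, _, _ = multipletests(ps, alpha=alpha, method="fdr_bh")
        for f, q in zip(testable, qs):
            f.q_value = float(q)
    rows = []
    for f in fits:
        rows.append(
            {
                "taxon": f.taxon,
                "n_detected": f.n_detected,
                "baseline": f.baseline,
                "g_eff": f.g_eff,
                "threshold": f.threshold,
                "p_assoc": None if f.degenerate else f.p_assoc,
                "q_value": f.q_value,
                "significant": (
                    f.q_value is not None
                    and f.q_value < alpha
                    and abs(f.g_eff) >= effect_floor
                ),
            }
        )
    return pd.DataFrame(rows)


def summary_table(fits: list[RiskSplineFit], alpha: float = 0.05):
    """Taxon-level summary (effect size, q-value, threshold) as a DataFrame."""
    return association_significance(fits, alpha=alpha)


# ---------------------------------------------------------------------------
# measurement-error averaging
# ---------------------------------------------------------------------------

def fit_with_measurement_error(
    x,
    y,
    em,
    config: SplineConfig,
    n_resamples: int = 5,
    taxon: str = "",
    offset=None,
) -> RiskSplineFit:
    """Average ``n_resamples`` fits on measurement-error-perturbed covariates.

    For each resample a new covariate vector is drawn from the replicate
    error model (Normal around the observed log10 RA with
    abundance-dependent sd), the spline is refitted, and the posterior-mean
    curves are averaged on the grid of the unperturbed covariate. The
    credible region comes from the pooled posterior draws of all component
    fits; effect size, threshold and association evidence are computed from
    the averaged curve/pooled draws.

    ``offset`` (optional, per-sample) is added to the covariate *after*
    perturbation — used for absolute-abundance fits where the measurement
    error lives on the relative-abundance scale.
    """
    from .error_model import perturb_abundances

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    off = np.zeros_like(x) if offset is None else np.asarray(offset, dtype=float)
    grid, _ = _make_bins(x + off, config.max_bins)
    baseline = float(y.mean())
    n = x.size
    if baseline in (0.0, 1.0):
        f = np.full(grid.size, baseline)
        return RiskSplineFit(
            taxon=taxon, x_grid=grid, f=f, band_lo=f.copy(), band_hi=f.copy(),
            g_eff=0.0, threshold=None, baseline=baseline, p_assoc=1.0,
            n_detected=n, degenerate=True,
        )

    ss = np.random.SeedSequence(config.seed)
    sub = ss.spawn(n_resamples)
    curves, pooled, converged = [], [], True
    for r in range(n_resamples):
        perturb_seed, fit_seed = sub[r].spawn(2)
        xr = perturb_abundances(x, em, np.random.default_rng(perturb_seed)) + off
        cfg_r = replace(config, seed=int(fit_seed.generate_state(1)[0] % (2**31)))
        post = fit_adaptive_spline(xr, y, cfg_r)
        if post.degenerate:
            warnings.warn(f"resample {r} degenerate; excluded from average", stacklevel=2)
            continue
        converged &= post.converged
        curves.append(np.interp(grid, post.x_grid, post.f))
        rd = post.risk_draws
        pooled.append(
            np.array([np.interp(grid, post.x_grid, row) for row in rd])
        )
    if not curves:
        f = np.full(grid.size, baseline)
        return RiskSplineFit(
            taxon=taxon, x_grid=grid, f=f, band_lo=f.copy(), band_hi=f.copy(),
            g_eff=0.0, threshold=None, baseline=baseline, p_assoc=1.0,
            n_detected=n, degenerate=True,
        )
    f_avg = np.mean(curves, axis=0)
    pooled_mat = np.concatenate(pooled, axis=0)
    band_lo = np.minimum(np.quantile(pooled_mat, 0.025, axis=0), f_avg)
    band_hi = np.maximum(np.quantile(pooled_mat, 0.975, axis=0), f_avg)
    g = signed_effect_size(grid, f_avg)
    thr = threshold_from_curve(grid, f_avg, g, config.effect_floor)
    p_hi = float(np.mean(pooled_mat[:, -1] > pooled_mat[:, 0]))
    p_assoc = float(np.clip(2.0 * min(p_hi, 1.0 - p_hi), 1.0 / pooled_mat.shape[0], 1.0))
    return RiskSplineFit(
        taxon=taxon,
        x_grid=grid,
        f=f_avg,
        band_lo=band_lo,
        band_hi=band_hi,
        g_eff=g,
        threshold=thr,
        baseline=baseline,
        p_assoc=p_assoc,
        n_detected=n,
        resample_curves=curves,
        converged=converged,
        pooled_draws=pooled_mat,
    )


def fit_absolute_abundance_risk(
    rel_x,
    log10_totals,
    y,
    em,
    config: SplineConfig,
    n_resamples: int = 5,
    taxon: str = "",
) -> RiskSplineFit:
    """Risk fit on log10 absolute abundance (log10 totals + log10 RA).

    Measurement error is applied on the relative-abundance component (the
    error model's domain) and the qPCR total added afterwards, preserving
    abs = total + RA elementwise in log10 units.
    """
    return fit_with_measurement_error(
        rel_x, y, em, config, n_resamples=n_resamples, taxon=taxon, offset=log10_totals
    )
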