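"""Cumulative-Gaussian psychometric fits of proportion correct vs contrast.

Performance is first scaled by the observed maximum (performance ceilings
well below 100% are the norm for trace agreement), then fitted with

    p̂(x) = γ + (1 − γ − λ) · Φ((x − μ)/σ)

by penalized maximum likelihood on effective trial counts, with γ = 0 and a
small free lapse λ. Pixel counts are not independent Bernoulli trials, so
the raw pixel totals are rescaled to a configurable effective trial count;
the fit is invariant to uniform rescaling of the input weights.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize
from scipy.stats import norm, pearsonr

_EPS = 1e-9


@dataclass
class PsychometricData:
    """Proportion correct per contrast level with effective weights.

    Contrasts are sorted ascending on construction; weights default to one
    per level.
    """

    contrasts: np.ndarray
    p_values: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.contrasts, dtype=float)
        p = np.asarray(self.p_values, dtype=float)
        if c.ndim != 1 or c.shape != p.shape:
            raise ValueError("contrasts and p_values must be 1-D and equal length")
        if np.any(c <= 0):
            raise ValueError("contrasts must be strictly positive")
        if np.any((p < 0) | (p > 1)):
            raise ValueError("p_values must lie in [0, 1]")
        w = np.ones_like(c) if self.weights is None else np.asarray(self.weights, dtype=float)
        if w.shape != c.shape or np.any(w <= 0):
            raise ValueError("weights must be positive and match the contrasts")
        order = np.argsort(c)
        self.contrasts, self.p_values, self.weights = c[order], p[order], w[order]

    def __len__(self) -> int:
        return len(self.contrasts)


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters and derived threshold."""

    mu: float
    sigma: float
    lapse: float
    guess: float
    pmax: float
    threshold: float
    gof: float  # deviance against the saturated model
    converged: bool


def scale_by_max(data: PsychometricData, robust_quantile: float | None = None) -> tuple[PsychometricData, float]:
    """Divide performance by its maximum; returns (scaled data, pmax).

    ``robust_quantile`` (e.g. 0.9) uses that quantile of the p-values as the
    ceiling instead of the raw maximum; scaled values are capped at 1.
    """
    if len(data) == 0:
        raise ValueError("empty data")
    p = data.p_values
    pmax = float(np.max(p) if robust_quantile is None else np.quantile(p, robust_quantile))
    if pmax <= 0:
        raise ValueError("all-zero performance cannot be scaled")
    scaled = np.minimum(p / pmax, 1.0)
    if np.ptp(p) == 0:
        warnings.warn("constant performance: scaled data are degenerate", stacklevel=2)
    return PsychometricData(data.contrasts.copy(), scaled, data.weights.copy()), pmax


def _curve(x: np.ndarray, mu: float, sigma: float, lapse: float, guess: float) -> np.ndarray:
    return guess + (1.0 - guess - lapse) * norm.cdf((x - mu) / sigma)


def _neg_loglik(params, x, k, n, guess, lapse_max):
    mu, log_sigma, lapse = params
    pred = np.clip(_curve(x, mu, np.exp(log_sigma), lapse, guess), _EPS, 1 - _EPS)
    ll = np.sum(k * np.log(pred) + (n - k) * np.log1p(-pred))
    # mild penalty keeps the lapse from absorbing mid-range misfit
    penalty = 4.0 * (lapse / max(lapse_max, _EPS)) ** 2 if lapse_max > 0 else 0.0
    return -(ll) + penalty


def fit_cumulative_gaussian(
    data: PsychometricData,
    guess: float = 0.0,
    lapse_max: float = 0.05,
    n_eff: float = 100.0,
    criterion: float = 0.5,
) -> PsychometricFit:
    """Penalized-MLE fit of a cumulative Gaussian to (scaled) performance.

    Weights are normalized to a mean effective trial count of ``n_eff`` per
    level, so the fit is invariant to uniform weight rescaling. Optimization
    is a deterministic multi-start (grid over μ and σ) refined with
    L-BFGS-B. Degenerate data never raise: the best local fit is returned
    with ``converged=False``.
    """
    if len(np.unique(data.contrasts)) < 3:
        raise ValueError("need at least 3 distinct contrast levels")
    x = data.contrasts
    n = data.weights / data.weights.mean() * n_eff
    k = data.p_values * n

    span = max(x.max() - x.min(), _EPS)
    mu_grid = np.linspace(x.min(), x.max(), 5)
    sigma_grid = span * np.array([0.05, 0.2, 0.8])
    bounds = [
        (x.min() - 2 * span, x.max() + 2 * span),
        (np.log(span * 1e-3), np.log(span * 10)),
        (0.0, lapse_max),
    ]

    best = None
    for mu0 in mu_grid:
        for s0 in sigma_grid:
            res = optimize.minimize(
                _neg_loglik,
                x0=np.array([mu0, np.log(s0), 0.01 if lapse_max > 0 else 0.0]),
                args=(x, k, n, guess, lapse_max),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    mu, log_sigma, lapse = best.x
    sigma = float(np.exp(log_sigma))

    pred = np.clip(_curve(x, mu, sigma, lapse, guess), _EPS, 1 - _EPS)
    p_obs = np.clip(data.p_values, _EPS, 1 - _EPS)
    deviance = float(
        2.0
        * np.sum(
            k * (np.log(p_obs) - np.log(pred))
            + (n - k) * (np.log1p(-p_obs) - np.log1p(-pred))
        )
    )
    fit = PsychometricFit(
        mu=float(mu),
        sigma=sigma,
        lapse=float(lapse),
        guess=guess,
        pmax=1.0,
        threshold=np.nan,
        gof=deviance,
        converged=bool(best.success),
    )
    return replace(fit, threshold=threshold_at(fit, criterion))


def threshold_at(fit: PsychometricFit, criterion: float = 0.5) -> float:
    """Contrast at which the scaled curve crosses ``criterion`` of its range.

    The criterion is a fraction of the Φ range between the asymptotes, so
    0.5 returns μ exactly and 0.841345 returns μ + σ.
    """
    if not 0.0 < criterion < 1.0:
        raise ValueError("criterion must lie strictly in (0, 1)")
    return float(fit.mu + fit.sigma * norm.ppf(criterion))


def correlate_patterns(a: np.ndarray, b: np.ndarray) -> float:
    """Pearson correlation between two equally long threshold patterns."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("patterns must be 1-D, equal length, and of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("correlation undefined for a zero-variance pattern")
    return float(pearsonr(a, b).statistic)


def bootstrap_threshold(
    contrasts: np.ndarray,
    per_observer_p: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
    criterion: float = 0.5,
    interval: float = 0.68,
    **fit_kwargs,
) -> tuple[float, float]:
    """Nonparametric bootstrap CI of the threshold over observers.

    ``per_observer_p`` is (n_observers, n_levels). Observers are resampled
    with replacement, each resample averaged, scaled by its maximum and
    fitted; returns the central ``interval`` quantile range of thresholds.
    """
    rng = np.random.default_rng(seed)
    per_observer_p = np.asarray(per_observer_p, dtype=float)
    n_obs = per_observer_p.shape[0]
    thresholds = []
    for _ in range(n_boot):
        idx = rng.integers(0, n_obs, size=n_obs)
        mean_p = per_observer_p[idx].mean(axis=0)
        try:
            scaled, _ = scale_by_max(PsychometricData(contrasts, mean_p))
            fit = fit_cumulative_gaussian(scaled, criterion=criterion, **fit_kwargs)
            thresholds.append(fit.threshold)
        except ValueError:
            continue
    lo = float(np.quantile(thresholds, (1 - interval) / 2))
    hi = float(np.quantile(thresholds, 1 - (1 - interval) / 2))
    return lo, hi
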