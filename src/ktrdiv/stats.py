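"""Statistical analysis of single-cell division fates and kinase dynamics.

Windowed per-cell medians, right-tailed rank-sum comparison of dividing
versus non-dividing cells, logistic regression of division on ERK/Akt
medians, pooled ERK-Akt Pearson correlation with a multivariate-normal
resampling band, and the 2-node perturbation crosstalk statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

__all__ = [
    "WindowSpec",
    "FeatureRow",
    "RankSumResult",
    "LogitFit",
    "CorrelationNullSpec",
    "CorrelationResult",
    "EffectResult",
    "window_median",
    "ranksum_right",
    "fit_division_logit",
    "pooled_pearson",
    "correlation_null_band",
    "crosstalk_effect",
]


@dataclass
class WindowSpec:
    """Analysis window in hours post growth factor, inclusive both ends."""

    t_lo_h: float = 8.5
    t_hi_h: float = 40.0

    def __post_init__(self) -> None:
        if not self.t_lo_h < self.t_hi_h:
            raise ValueError("window must satisfy t_lo_h < t_hi_h")

    def contains(self, times_h: np.ndarray) -> np.ndarray:
        t = np.asarray(times_h, dtype=float)
        return (t >= self.t_lo_h - 1e-9) & (t <= self.t_hi_h + 1e-9)


@dataclass
class FeatureRow:
    cell_id: int
    median_erk: float | None
    median_akt: float | None
    divided: bool


@dataclass
class RankSumResult:
    statistic: float     # rank-sum W of the first sample
    p_value: float
    n_x: int
    n_y: int
    tail: str = "right"
    method: str = "exact"


@dataclass
class LogitFit:
    params: dict[str, float]
    bse: dict[str, float]
    zvalues: dict[str, float]
    pvalues: dict[str, float]
    converged: bool


@dataclass
class CorrelationNullSpec:
    mu: np.ndarray
    cov: np.ndarray
    reps: int = 1000
    percentiles: tuple[float, float] = (5.0, 95.0)
    round_step: float = 0.01
    round_mode: str = "ceil"   # "ceil" (round band ends up) or "half_up"

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float).reshape(2)
        self.cov = np.asarray(self.cov, dtype=float).reshape(2, 2)
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-10:
            raise ValueError("covariance must be positive semidefinite")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass
class CorrelationResult:
    r: float
    n_points: int
    class_label: str
    band: tuple[float, float] | None = None


@dataclass
class EffectResult:
    effect: float
    ci: tuple[float, float]
    edge_present: bool
    floor: float = 0.0


def window_median(trace: np.ndarray, times_h: np.ndarray,
                  window: WindowSpec | None = None,
                  min_points: int = 10) -> float | None:
    """Median C/N over in-window frames of a (possibly truncated) trace.

    Returns None when fewer than ``min_points`` frames fall inside the
    window — a truncated trace may not reach it at all.
    """
    window = window or WindowSpec()
    trace = np.asarray(trace, dtype=float)
    times_h = np.asarray(times_h, dtype=float)[: trace.size]
    trace = trace[: times_h.size]
    sel = window.contains(times_h) & np.isfinite(trace)
    if sel.sum() < min_points:
        return None
    return float(np.median(trace[sel]))


def ranksum_right(x, y) -> RankSumResult:
    """Right-tailed Wilcoxon rank-sum test (x stochastically greater than y).

    Exact enumeration when n_x + n_y <= 12 with no ties; otherwise the
    normal approximation with tie and continuity corrections.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="greater", method=method,
                           use_continuity=True)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return RankSumResult(statistic=w, p_value=float(res.pvalue),
                         n_x=int(x.size), n_y=int(y.size), method=method)


def _irls_ridge(X: np.ndarray, y: np.ndarray, ridge: float = 1e-6,
                maxiter: int = 50) -> np.ndarray:
    """Minimal ridge-stabilised IRLS, used only to report diverging fits."""
    beta = np.zeros(X.shape[1])
    for _ in range(maxiter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = np.clip(p * (1 - p), 1e-10, None)
        z = eta + (y - p) / w
        A = X.T @ (w[:, None] * X) + ridge * np.eye(X.shape[1])
        beta = np.linalg.solve(A, X.T @ (w * z))
    return beta


def fit_division_logit(features: pd.DataFrame) -> LogitFit:
    """Binomial GLM with logit link: division ~ median_erk + median_akt.

    Fitted by IRLS; Wald standard errors, z and p per coefficient.
    Quasi-separation or non-convergence is reported through the
    ``converged`` flag (with the diverging coefficients still shown), not
    raised.
    """
    req = {"median_erk", "median_akt", "divided"}
    if not req <= set(features.columns):
        raise ValueError(f"features must have columns {sorted(req)}")
    df = features.dropna(subset=["median_erk", "median_akt"])
    y = df["divided"].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("both outcome classes must be present")
    X = sm.add_constant(df[["median_erk", "median_akt"]].to_numpy())
    names = ["intercept", "erk", "akt"]
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(
                maxiter=100, tol=1e-8)
            params = np.asarray(res.params, dtype=float)
            bse = np.asarray(res.bse, dtype=float)
            separated = any("PerfectSeparation" in w.category.__name__
                            for w in caught)
            converged = bool(res.converged) and np.all(np.isfinite(bse)) \
                and np.abs(params).max() < 1e3 and not separated
        except Exception:
            converged = False
            params = _irls_ridge(X, y)
            bse = np.full(X.shape[1], np.nan)
    if not converged and not np.all(np.isfinite(bse)):
        zv = np.full(X.shape[1], np.nan)
        pv = np.full(X.shape[1], np.nan)
    else:
        zv = params / bse
        pv = 2 * sps.norm.sf(np.abs(zv))
    return LogitFit(
        params=dict(zip(names, map(float, params))),
        bse=dict(zip(names, map(float, bse))),
        zvalues=dict(zip(names, map(float, zv))),
        pvalues=dict(zip(names, map(float, pv))),
        converged=converged,
    )


def pooled_pearson(erk_points, akt_points, class_label: str = "") -> CorrelationResult:
    """Pearson r over pooled (cell x timepoint) ERK/Akt pairs of one class."""
    x = np.asarray(erk_points, dtype=float)
    y = np.asarray(akt_points, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 pooled points")
    r = float(sps.pearsonr(x, y).statistic)
    return CorrelationResult(r=r, n_points=int(x.size), class_label=class_label)


def _round_band(v: float, step: float, mode: str) -> float:
    scaled = v / step
    # shave float fuzz so e.g. 0.60000000001 does not ceil to 0.61
    scaled = round(scaled, 9)
    if mode == "ceil":
        return round(math.ceil(scaled) * step, 10)
    if mode == "half_up":
        return round(math.floor(scaled + 0.5) * step, 10)
    raise ValueError(f"unknown round_mode {mode!r}")


def correlation_null_band(
    spec: CorrelationNullSpec, n_points: int,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Resampling band for a pooled correlation coefficient.

    Draws ``n_points`` paired samples from MVN(mu, cov), computes Pearson
    r, repeats ``reps`` times; the (5th, 95th) percentiles of the r
    distribution are reported, each rounded up to the nearest 0.01 by
    default.
    """
    if n_points < 3:
        raise ValueError("n_points must be >= 3")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    w, V = np.linalg.eigh(spec.cov)
    factor = V * np.sqrt(np.clip(w, 0.0, None))
    z = rng.standard_normal((spec.reps, n_points, 2))
    samples = z @ factor.T + spec.mu
    xc = samples[..., 0] - samples[..., 0].mean(axis=1, keepdims=True)
    yc = samples[..., 1] - samples[..., 1].mean(axis=1, keepdims=True)
    denom = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rs = (xc * yc).sum(axis=1) / denom
    # a degenerate (perfectly correlated) covariance yields 0/0; the limit
    # of the correlation is the sign of the off-diagonal
    if np.any(~np.isfinite(rs)):
        rho_sign = np.sign(spec.cov[0, 1]) if spec.cov[0, 1] != 0 else 1.0
        rs = np.where(np.isfinite(rs), rs, rho_sign)
    rs = np.clip(rs, -1.0, 1.0)
    lo, hi = np.percentile(rs, spec.percentiles)
    return (_round_band(float(lo), spec.round_step, spec.round_mode),
            _round_band(float(hi), spec.round_step, spec.round_mode))


def crosstalk_effect(
    control: np.ndarray,
    perturbed: np.ndarray,
    times_h: np.ndarray,
    window: WindowSpec | None = None,
    n_boot: int = 1000,
    floor: float | None = None,
    floor_frac_of_range: float = 0.10,
    seed: int | np.random.Generator = 0,
) -> EffectResult:
    """Perturbation effect on one node of the 2-node network.

    ``control`` and ``perturbed`` are (cells x frames) C/N arrays of the
    read-out node on a shared time grid. The effect is the in-window time
    average of the difference of per-timepoint population medians
    (perturbed - control); the CI is a cell-level percentile bootstrap. An
    edge is declared only when the CI excludes zero AND the effect clears a
    practical-significance floor (default 10% of the control trajectory's
    dynamic range).
    """
    window = window or WindowSpec()
    ctrl = np.asarray(control, dtype=float)
    pert = np.asarray(perturbed, dtype=float)
    times_h = np.asarray(times_h, dtype=float)
    if ctrl.ndim != 2 or pert.ndim != 2 or ctrl.shape[1] != pert.shape[1] \
            or ctrl.shape[1] != times_h.size:
        raise ValueError("conditions must share the time grid")
    sel = window.contains(times_h)
    if not sel.any():
        raise ValueError("window contains no timepoints")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    ctrl_med = np.median(ctrl, axis=0)
    pert_med = np.median(pert, axis=0)
    effect = float(np.mean(pert_med[sel] - ctrl_med[sel]))
    if floor is None:
        floor = floor_frac_of_range * float(np.ptp(ctrl_med))

    idx_c = rng.integers(0, ctrl.shape[0], size=(n_boot, ctrl.shape[0]))
    idx_p = rng.integers(0, pert.shape[0], size=(n_boot, pert.shape[0]))
    boot = np.empty(n_boot)
    cw, pw = ctrl[:, sel], pert[:, sel]
    for b in range(n_boot):
        boot[b] = np.mean(np.median(pw[idx_p[b]], axis=0)
                          - np.median(cw[idx_c[b]], axis=0))
    lo, hi = np.percentile(boot, [2.5, 97.5])
    edge = bool((lo > 0 or hi < 0) and abs(effect) >= floor)
    return EffectResult(effect=effect, ci=(float(lo), float(hi)),
                        edge_present=edge, floor=float(floor))
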