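"""Drift-diffusion model of two-alternative food choice.

Evidence accumulates from a starting point ``bias * boundary_sep`` with drift
``drift`` (unit diffusion coefficient) until it hits 0 (unhealthy choice) or
``boundary_sep`` (healthy choice); the observed response time adds a
non-decision component. This module provides the first-passage-time density
(dual small-time/large-time series), the analytic absorption probability, an
Euler-Maruyama sampler with Brownian-bridge boundary-crossing correction, and
per-condition maximum-likelihood fitting with multi-start Nelder-Mead.

Conventions: diffusion coefficient fixed to 1; the upper boundary is the
healthy choice; ``bias`` is the relative start point in (0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "DDMParams",
    "FitResult",
    "FitSettings",
    "wiener_pdf",
    "wiener_cdf_grid",
    "wiener_loglik",
    "hit_probability",
    "mean_decision_time",
    "sample_wiener",
    "simulate_choices",
    "fit_ddm",
    "fit_all_conditions",
]

_SERIES_ERR = 1e-10
_DENSITY_FLOOR = 1e-300
_LOGLIK_GUARD = -1e12  # stands in for -inf when rt <= non_decision
PARAM_NAMES = ("alpha", "tau", "beta", "delta")


@dataclass(frozen=True)
class DDMParams:
    """Parameters of one participant x condition diffusion process.

    boundary_sep : evidence units (alpha > 0)
    non_decision : seconds (tau >= 0)
    bias         : relative start point in (0, 1); 0.5 = unbiased
    drift        : evidence units / s; positive drifts toward healthy
    """

    boundary_sep: float
    non_decision: float
    bias: float
    drift: float

    def __post_init__(self) -> None:
        vals = (self.boundary_sep, self.non_decision, self.bias, self.drift)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError(f"DDM parameters must be finite, got {vals}")
        if self.boundary_sep <= 0:
            raise ValueError(f"boundary_sep must be > 0, got {self.boundary_sep}")
        if self.non_decision < 0:
            raise ValueError(f"non_decision must be >= 0, got {self.non_decision}")
        if not 0.0 < self.bias < 1.0:
            raise ValueError(f"bias must lie in (0, 1), got {self.bias}")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.boundary_sep, self.non_decision, self.bias, self.drift], float
        )

    @classmethod
    def from_array(cls, arr: Sequence[float]) -> "DDMParams":
        a, t, b, d = (float(v) for v in arr)
        return cls(boundary_sep=a, non_decision=t, bias=b, drift=d)


def _fpt_density_unit(tau: np.ndarray, w: float, err: float = _SERIES_ERR) -> np.ndarray:
    """First-passage density at the lower barrier for a driftless diffusion on
    (0, 1) started at ``w``, at rescaled time ``tau``.

    Dual infinite-series representation; per element the branch needing fewer
    terms (small-time vs large-time) is used, truncated to absolute error
    ``err``.
    """
    tau = np.asarray(tau, float)
    out = np.zeros_like(tau)
    pos = tau > 0
    if not pos.any():
        return out
    t = tau[pos]
    with np.errstate(divide="ignore", invalid="ignore"):
        ks = 2.0 + np.sqrt(-2.0 * t * np.log(2.0 * err * np.sqrt(2.0 * np.pi * t)))
        ks = np.where(
            2.0 * np.sqrt(2.0 * np.pi * t) * err < 1.0,
            np.maximum(ks, np.sqrt(t) + 1.0),
            2.0,
        )
        kl = np.sqrt(-2.0 * np.log(np.pi * t * err) / (np.pi**2 * t))
        kl = np.where(
            np.pi * t * err < 1.0,
            np.maximum(kl, 1.0 / (np.pi * np.sqrt(t))),
            1.0 / (np.pi * np.sqrt(t)),
        )
    use_small = ks < kl
    dens = np.empty_like(t)
    if use_small.any():
        ts = t[use_small]
        K = int(np.ceil(ks[use_small].max()))
        k = np.arange(-(K // 2 + 1), K // 2 + 2)
        wk = w + 2.0 * k[None, :]
        dens[use_small] = (
            (wk * np.exp(-(wk**2) / (2.0 * ts[:, None]))).sum(axis=1)
            / np.sqrt(2.0 * np.pi * ts**3)
        )
    if (~use_small).any():
        tl = t[~use_small]
        K = int(min(np.ceil(kl[~use_small].max()), 100_000))
        k = np.arange(1, K + 1)
        dens[~use_small] = np.pi * (
            k[None, :]
            * np.exp(-(k[None, :] ** 2) * np.pi**2 * tl[:, None] / 2.0)
            * np.sin(k[None, :] * np.pi * w)
        ).sum(axis=1)
    out[pos] = np.maximum(dens, 0.0)
    return out


def wiener_pdf(t, boundary: str, params: DDMParams):
    """First-passage-time density (1/s) at the given boundary.

    ``boundary`` is ``"upper"`` (healthy) or ``"lower"`` (unhealthy). Zero for
    ``t <= non_decision``.
    """
    if boundary not in ("upper", "lower"):
        raise ValueError(f"boundary must be 'upper' or 'lower', got {boundary!r}")
    scalar = np.isscalar(t)
    t_arr = np.atleast_1d(np.asarray(t, float))
    a = params.boundary_sep
    if boundary == "upper":
        v, w = -params.drift, 1.0 - params.bias
    else:
        v, w = params.drift, params.bias
    td = t_arr - params.non_decision
    dens = np.zeros_like(td)
    m = td > 0
    if m.any():
        tt = td[m]
        # guard exp underflow for long t at large |v|
        with np.errstate(under="ignore"):
            dens[m] = (
                np.exp(-v * a * w - v * v * tt / 2.0)
                / a**2
                * _fpt_density_unit(tt / a**2, w)
            )
    return float(dens[0]) if scalar else dens


def wiener_cdf_grid(params: DDMParams, t_grid: np.ndarray) -> np.ndarray:
    """CDF of the observed RT (either boundary) on a time grid, by cumulative
    trapezoidal integration of the two defective densities."""
    from scipy.integrate import cumulative_trapezoid

    t_grid = np.asarray(t_grid, float)
    dens = wiener_pdf(t_grid, "upper", params) + wiener_pdf(t_grid, "lower", params)
    cdf = np.concatenate([[0.0], cumulative_trapezoid(dens, t_grid)])
    return np.clip(cdf, 0.0, 1.0)


def _hit_prob_arrays(alpha, beta, delta):
    """Vectorized P(absorb at upper boundary) for unit diffusion."""
    alpha, beta, delta = np.broadcast_arrays(
        np.asarray(alpha, float), np.asarray(beta, float), np.asarray(delta, float)
    )
    x = 2.0 * delta * alpha
    out = np.empty_like(x)
    tiny = np.abs(x) < 1e-9
    out[tiny] = beta[tiny]
    big_neg = x < -500.0  # exp overflow; use asymptotic form
    rest = ~tiny & ~big_neg
    with np.errstate(over="ignore", under="ignore"):
        out[rest] = np.expm1(-x[rest] * beta[rest]) / np.expm1(-x[rest])
        out[big_neg] = np.exp(x[big_neg] * (1.0 - beta[big_neg]))
    return np.clip(out, 0.0, 1.0)


def hit_probability(params: DDMParams) -> float:
    """Probability of absorbing at the upper (healthy) boundary.

    Closed form ``(1 - exp(-2*delta*alpha*beta)) / (1 - exp(-2*delta*alpha))``
    with unit diffusion; equals ``bias`` in the zero-drift limit.
    """
    return float(
        _hit_prob_arrays(params.boundary_sep, params.bias, params.drift)
    )


def mean_decision_time(params: DDMParams) -> float:
    """Unconditional mean first-passage (decision) time, excluding the
    non-decision component. From the optional-stopping identity
    ``E[T] = (alpha * P_upper - alpha * beta) / drift`` (zero drift:
    ``alpha^2 * beta * (1 - beta)``)."""
    a, b, d = params.boundary_sep, params.bias, params.drift
    if abs(d) < 1e-9:
        return a * a * b * (1.0 - b)
    return (a * hit_probability(params) - a * b) / d


def sample_wiener(
    alpha,
    tau,
    beta,
    delta,
    n: int | None = None,
    rng: np.random.Generator | None = None,
    timeout: float | None = None,
    dt: float = 1e-3,
    max_decision_time: float = 20.0,
):
    """Simulate first-passage trials by Euler-Maruyama with a Brownian-bridge
    crossing test each step (removes the O(sqrt(dt)) boundary bias of the
    plain scheme).

    Parameters may be scalars or arrays of a common length; ``n`` replicates
    scalar parameters. Trials whose decision has not completed by
    ``timeout - tau`` (or ``max_decision_time``) are censored, not dropped.

    Returns ``(rt, upper, censored)``: rt is NaN where censored.
    """
    rng = np.random.default_rng() if rng is None else rng
    alpha, tau, beta, delta = np.broadcast_arrays(
        np.asarray(alpha, float),
        np.asarray(tau, float),
        np.asarray(beta, float),
        np.asarray(delta, float),
    )
    if alpha.ndim == 0:
        if n is None:
            n = 1
        alpha, tau, beta, delta = (
            np.full(n, float(v)) for v in (alpha, tau, beta, delta)
        )
    else:
        if n is not None and n != alpha.shape[0]:
            raise ValueError("n conflicts with parameter array length")
        n = alpha.shape[0]
    if np.any(alpha <= 0) or np.any((beta <= 0) | (beta >= 1)) or np.any(tau < 0):
        raise ValueError("invalid diffusion parameters")
    if timeout is None:
        limit = np.full(n, max_decision_time)
    else:
        limit = np.maximum(float(timeout) - tau, 0.0)

    x = beta * alpha
    rt_dec = np.full(n, np.nan)
    upper = np.zeros(n, bool)
    censored = np.zeros(n, bool)
    active = np.arange(n)
    sqrt_dt = np.sqrt(dt)
    t = 0.0
    # pre-censor trials with zero decision-time budget
    zero = limit[active] <= 0
    censored[active[zero]] = True
    active = active[~zero]
    while active.size:
        t += dt
        xa = x[active]
        aa = alpha[active]
        x1 = xa + delta[active] * dt + sqrt_dt * rng.standard_normal(active.size)
        with np.errstate(over="ignore", under="ignore"):
            pu = np.where(x1 >= aa, 1.0, np.exp(-2.0 * (aa - xa) * np.maximum(aa - x1, 0.0) / dt))
            pl = np.where(x1 <= 0.0, 1.0, np.exp(-2.0 * xa * np.maximum(x1, 0.0) / dt))
        hit_up = rng.random(active.size) < pu
        hit_lo = ~hit_up & (rng.random(active.size) < pl)
        done = hit_up | hit_lo
        over = t >= limit[active]
        decided = done & ~over
        idx_dec = active[decided]
        rt_dec[idx_dec] = t
        upper[idx_dec] = hit_up[decided]
        censored[active[over & ~done]] = True
        # trials that finished in the same step the deadline passed: censored
        censored[active[over & done]] = True
        keep = ~decided & ~over
        x[active[keep]] = x1[keep]
        active = active[keep]
    rt = tau + rt_dec
    rt[censored] = np.nan
    return rt, upper, censored


def simulate_choices(params: DDMParams, n: int, rng, timeout: float | None = None, dt: float = 1e-3):
    """Convenience wrapper: ``n`` iid trials from one parameter set."""
    return sample_wiener(
        params.boundary_sep,
        params.non_decision,
        params.bias,
        params.drift,
        n=n,
        rng=rng,
        timeout=timeout,
        dt=dt,
    )


def wiener_loglik(rts, upper, params: DDMParams) -> float:
    """Joint log-likelihood (nats) of (rt, boundary) observations.

    Returns a large negative guard value instead of -inf when any rt falls at
    or below the non-decision time.
    """
    rts = np.asarray(rts, float)
    upper = np.asarray(upper, bool)
    if rts.size == 0:
        raise ValueError("wiener_loglik requires at least one trial")
    if rts.shape != upper.shape:
        raise ValueError("rts and upper must have matching shapes")
    if np.any(rts <= params.non_decision):
        return _LOGLIK_GUARD * float(np.mean(rts <= params.non_decision))
    ll = 0.0
    if upper.any():
        ll += np.log(
            np.maximum(wiener_pdf(rts[upper], "upper", params), _DENSITY_FLOOR)
        ).sum()
    if (~upper).any():
        ll += np.log(
            np.maximum(wiener_pdf(rts[~upper], "lower", params), _DENSITY_FLOOR)
        ).sum()
    return float(ll)


@dataclass
class FitSettings:
    """Knobs of the per-condition maximum-likelihood fit."""

    n_restarts: int = 5
    min_trials: int = 20
    alpha_bounds: tuple[float, float] = (0.2, 6.0)
    beta_bounds: tuple[float, float] = (0.02, 0.98)
    delta_bounds: tuple[float, float] = (-8.0, 8.0)
    tau_margin: float = 1e-3  # tau upper bound is min(rt) - margin
    maxiter: int = 1200
    xatol: float = 1e-5
    fatol: float = 1e-7


@dataclass
class FitResult:
    params: DDMParams
    log_likelihood: float
    n_trials: int
    converged: bool
    n_restarts_used: int
    at_bound: bool = False
    condition: tuple | None = None


def _start_points(rts, upper, bounds, n_restarts, rng):
    min_rt = float(np.min(rts))
    p = float(np.clip(np.mean(upper), 0.05, 0.95))
    base = np.array(
        [1.4, 0.7 * min_rt, 0.5 + 0.5 * (p - 0.5), 2.0 * (p - 0.5)]
    )
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    starts = [np.clip(base, lo + 1e-4, hi - 1e-4)]
    for _ in range(n_restarts - 1):
        jitter = rng.uniform(0.15, 0.85, size=4)
        pt = lo + jitter * (hi - lo)
        # keep the data-driven beta/tau flavour half the time
        if rng.random() < 0.5:
            pt[1] = np.clip(rng.uniform(0.3, 0.95) * min_rt, lo[1], hi[1])
            pt[2] = np.clip(p + rng.normal(0, 0.1), lo[2] + 1e-4, hi[2] - 1e-4)
        starts.append(np.clip(pt, lo + 1e-4, hi - 1e-4))
    return starts


def fit_ddm(
    rts,
    upper,
    settings: FitSettings | None = None,
    rng: np.random.Generator | None = None,
    init: DDMParams | None = None,
) -> FitResult:
    """Maximum-likelihood fit of (alpha, tau, beta, delta) to one condition.

    Bounded Nelder-Mead from ``n_restarts`` dispersed initial points (the
    first is data-driven); ``init`` replaces the multi-start with a single
    start at the given parameters. ``tau`` is upper-bounded just below the
    minimum observed RT so the likelihood stays finite.
    """
    settings = settings or FitSettings()
    rng = np.random.default_rng(0) if rng is None else rng
    rts = np.asarray(rts, float)
    upper = np.asarray(upper, bool)
    if rts.size < settings.min_trials:
        raise ValueError(
            f"fit_ddm needs at least {settings.min_trials} trials, got {rts.size}"
        )
    if np.any(rts <= 0):
        raise ValueError("all rts must be positive")
    min_rt = float(np.min(rts))
    tau_hi = max(1e-4, min_rt - settings.tau_margin)
    bounds = [
        settings.alpha_bounds,
        (0.0, tau_hi),
        settings.beta_bounds,
        settings.delta_bounds,
    ]

    def neg_ll(theta):
        try:
            p = DDMParams.from_array(theta)
        except ValueError:
            return 1e12
        return -wiener_loglik(rts, upper, p)

    if init is not None:
        starts = [np.clip(init.as_array(), [b[0] for b in bounds], [b[1] for b in bounds])]
    else:
        starts = _start_points(rts, upper, bounds, settings.n_restarts, rng)

    best = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        res = minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            bounds=bounds,
            options={
                "maxiter": settings.maxiter,
                "xatol": settings.xatol,
                "fatol": settings.fatol,
            },
        )
        if best is None or res.fun < best.fun:
            best = res
    assert best is not None
    theta = np.clip(best.x, [b[0] for b in bounds], [b[1] for b in bounds])
    # never report tau >= min rt even after clipping noise
    theta[1] = min(theta[1], tau_hi)
    params = DDMParams.from_array(theta)
    tol = 1e-3
    at_bound = any(
        min(theta[i] - bounds[i][0], bounds[i][1] - theta[i]) < tol
        for i in (0, 2, 3)
    )
    return FitResult(
        params=params,
        log_likelihood=-float(best.fun),
        n_trials=int(rts.size),
        converged=bool(best.success and np.isfinite(best.fun)),
        n_restarts_used=n_used,
        at_bound=at_bound,
    )


def fit_all_conditions(
    trials: pd.DataFrame,
    settings: FitSettings | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit one DDM per participant x context x label condition.

    Healthy choices map to the upper boundary. Censored (timeout) trials are
    excluded from the likelihood with their count logged per condition.
    Conditions with fewer than ``min_trials`` usable trials are flagged
    (``insufficient_trials``), not dropped.
    """
    from ._rng import rng_for

    settings = settings or FitSettings()
    required = {"participant_id", "context", "nwl_shown", "rt_s", "healthy_choice"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    censored = (
        trials["censored"].astype(bool)
        if "censored" in trials.columns
        else pd.Series(False, index=trials.index)
    )
    rows = []
    for (pid, ctx, nwl), grp in trials.groupby(
        ["participant_id", "context", "nwl_shown"], sort=True
    ):
        cmask = censored.loc[grp.index].to_numpy()
        use = grp.loc[~cmask]
        n_censored = int(cmask.sum())
        rec = {
            "participant_id": pid,
            "context": ctx,
            "nwl_shown": bool(nwl),
            "n_trials": int(len(use)),
            "n_censored": n_censored,
        }
        if len(use) < settings.min_trials:
            rec.update(
                alpha=np.nan, tau=np.nan, beta=np.nan, delta=np.nan,
                loglik=np.nan, converged=False, at_bound=False,
                insufficient_trials=True,
            )
        else:
            fit = fit_ddm(
                use["rt_s"].to_numpy(),
                use["healthy_choice"].to_numpy(bool),
                settings=settings,
                rng=rng_for(seed, "fit", pid, ctx, bool(nwl)),
            )
            rec.update(
                alpha=fit.params.boundary_sep,
                tau=fit.params.non_decision,
                beta=fit.params.bias,
                delta=fit.params.drift,
                loglik=fit.log_likelihood,
                converged=fit.converged,
                at_bound=fit.at_bound,
                insufficient_trials=False,
            )
        rows.append(rec)
    return pd.DataFrame(rows)
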