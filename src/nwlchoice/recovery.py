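"""Monte-Carlo parameter-recovery validation of the diffusion fits.

For each condition: estimate the mean vector and covariance of the
individual fitted parameter sets (alpha, tau, beta, delta); draw parameter
sets from the corresponding multivariate normal; simulate a fixed number of
trials from each draw; refit with the same settings as the empirical fits;
then (a) flag empirical fits falling outside the central 95% of the
recovered marginals, and (b) report the Pearson correlation between
generating draws and their refits per parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ddm import FitSettings, PARAM_NAMES, fit_ddm, sample_wiener

__all__ = [
    "ParamPopulation",
    "RecoveryResult",
    "fit_param_population",
    "run_recovery",
    "flag_outlier_params",
    "recovery_correlation",
]

_MIN_SOURCE_FITS = 5
_EIG_FLOOR = 1e-10
# clamp box for draws that land outside the valid parameter region
_CLAMP_LO = np.array([0.05, 0.0, 0.02, -10.0])
_CLAMP_HI = np.array([10.0, 5.0, 0.98, 10.0])


@dataclass
class ParamPopulation:
    """Normal population of fitted parameter vectors for one condition."""

    condition: tuple | str | None
    mean_vec: np.ndarray  # (4,) order alpha, tau, beta, delta
    cov: np.ndarray       # (4, 4), PSD (eigenvalue-clipped if needed)
    n_source: int
    degenerate: bool = False  # zero/near-zero covariance or clipping applied


@dataclass
class RecoveryResult:
    condition: tuple | str | None
    draws: np.ndarray            # (n_sets, 4) generating parameters (post-clamp)
    refits: np.ndarray           # (n_sets, 4), NaN rows where the refit failed
    valid: np.ndarray            # (n_sets,) bool
    n_clamped: int
    n_failed: int
    quantile_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    pearson_r: dict[str, float] = field(default_factory=dict)
    warning: str | None = None


def fit_param_population(
    fits: pd.DataFrame | np.ndarray,
    condition=None,
) -> ParamPopulation:
    """Sample mean and covariance over converged fits of one condition.

    Accepts a fits table with columns alpha/tau/beta/delta (rows with
    ``converged == False`` are ignored when the column exists) or a plain
    (n, 4) array. Requires at least 5 usable fits. A covariance that is not
    positive semi-definite is repaired by clipping eigenvalues at 1e-10 and
    the population is marked degenerate.
    """
    if isinstance(fits, pd.DataFrame):
        use = fits
        if "converged" in use.columns:
            use = use.loc[use["converged"].astype(bool)]
        arr = use[list(PARAM_NAMES)].to_numpy(float)
    else:
        arr = np.asarray(fits, float)
    arr = arr[np.isfinite(arr).all(axis=1)]
    if arr.shape[0] < _MIN_SOURCE_FITS:
        raise ValueError(
            f"need at least {_MIN_SOURCE_FITS} converged fits, got {arr.shape[0]}"
        )
    mean = arr.mean(axis=0)
    cov = np.cov(arr, rowvar=False)
    w, v = np.linalg.eigh((cov + cov.T) / 2.0)
    degenerate = bool(np.any(w < _EIG_FLOOR))
    w = np.maximum(w, _EIG_FLOOR)
    cov_psd = (v * w) @ v.T
    return ParamPopulation(
        condition=condition,
        mean_vec=mean,
        cov=cov_psd,
        n_source=int(arr.shape[0]),
        degenerate=degenerate,
    )


def _clamp_draws(draws: np.ndarray) -> tuple[np.ndarray, int]:
    clamped = np.clip(draws, _CLAMP_LO, _CLAMP_HI)
    n = int(np.any(clamped != draws, axis=1).sum())
    return clamped, n


def run_recovery(
    pop: ParamPopulation,
    n_sets: int = 1000,
    n_rt: int = 128,
    rng: np.random.Generator | None = None,
    fit_settings: FitSettings | None = None,
    timeout: float | None = None,
    q: float = 0.05,
) -> RecoveryResult:
    """Draw -> simulate ``n_rt`` trials -> refit, ``n_sets`` times.

    Draws outside the valid region are clamped to the boundary (counted, not
    redrawn, preserving the draw count); failed refits are flagged and kept
    as NaN rows. Emits a warning-level note when more than half the refits
    fail. Quantile bounds (central 1-q mass) and draw-vs-refit Pearson
    correlations are attached to the result.
    """
    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    fit_settings = fit_settings or FitSettings(min_trials=min(20, n_rt))
    raw = rng.multivariate_normal(pop.mean_vec, pop.cov, size=n_sets)
    draws, n_clamped = _clamp_draws(raw)
    refits = np.full((n_sets, 4), np.nan)
    valid = np.zeros(n_sets, bool)
    for i in range(n_sets):
        a, t, b, d = draws[i]
        rt, upper, censored = sample_wiener(
            a, t, b, d, n=n_rt, rng=rng, timeout=timeout
        )
        keep = ~censored
        if keep.sum() < fit_settings.min_trials:
            continue
        try:
            fit = fit_ddm(rt[keep], upper[keep], settings=fit_settings, rng=rng)
        except ValueError:
            continue
        if np.isfinite(fit.log_likelihood):
            refits[i] = fit.params.as_array()
            valid[i] = True
    n_failed = int(n_sets - valid.sum())
    result = RecoveryResult(
        condition=pop.condition,
        draws=draws,
        refits=refits,
        valid=valid,
        n_clamped=n_clamped,
        n_failed=n_failed,
    )
    rec = refits[valid]
    if rec.shape[0]:
        lo_q, hi_q = q / 2.0, 1.0 - q / 2.0
        for j, name in enumerate(PARAM_NAMES):
            lo, hi = np.quantile(rec[:, j], [lo_q, hi_q])
            result.quantile_bounds[name] = (float(lo), float(hi))
    result.pearson_r = recovery_correlation(draws, refits, valid)
    if n_failed > n_sets / 2:
        result.warning = f"{n_failed}/{n_sets} refits failed"
    return result


def flag_outlier_params(
    source_fits: pd.DataFrame | np.ndarray,
    recovered: np.ndarray,
    q: float = 0.05,
    mode: str = "two-sided",
) -> pd.DataFrame:
    """Flag empirical parameters lying in the tails of the recovered
    distribution.

    Default two-sided reading: a value is flagged when below the q/2 or above
    the 1-q/2 empirical quantile of the recovered marginal (linear
    interpolation). ``mode`` may also be ``"lower"`` or ``"upper"`` for the
    one-sided readings (tail mass q on that side).
    """
    if isinstance(source_fits, pd.DataFrame):
        arr = source_fits[list(PARAM_NAMES)].to_numpy(float)
    else:
        arr = np.atleast_2d(np.asarray(source_fits, float))
    recovered = np.asarray(recovered, float)
    recovered = recovered[np.isfinite(recovered).all(axis=1)]
    if recovered.shape[0] == 0:
        raise ValueError("recovered distribution is empty")
    flags = np.zeros_like(arr, dtype=bool)
    for j in range(4):
        col = recovered[:, j]
        if mode == "two-sided":
            lo, hi = np.quantile(col, [q / 2.0, 1.0 - q / 2.0])
            flags[:, j] = (arr[:, j] < lo) | (arr[:, j] > hi)
        elif mode == "lower":
            flags[:, j] = arr[:, j] < np.quantile(col, q)
        elif mode == "upper":
            flags[:, j] = arr[:, j] > np.quantile(col, 1.0 - q)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    out = pd.DataFrame(flags, columns=[f"flag_{n}" for n in PARAM_NAMES])
    out["flag_any"] = flags.any(axis=1)
    return out


def recovery_correlation(
    draws: np.ndarray,
    refits: np.ndarray,
    valid: np.ndarray | None = None,
) -> dict[str, float]:
    """Pearson r between generating draws and refits, per parameter.

    Pairs with failed refits are excluded (their count is implicit in the
    RecoveryResult). A parameter with zero variance on either side comes
    back as NaN. Requires at least 3 valid pairs.
    """
    draws = np.asarray(draws, float)
    refits = np.asarray(refits, float)
    if valid is None:
        valid = np.isfinite(refits).all(axis=1)
    d = draws[valid]
    r = refits[valid]
    out: dict[str, float] = {}
    if d.shape[0] < 3:
        return {name: float("nan") for name in PARAM_NAMES}
    for j, name in enumerate(PARAM_NAMES):
        sx = np.std(d[:, j])
        sy = np.std(r[:, j])
        if sx < 1e-12 or sy < 1e-12:
            out[name] = float("nan")
        else:
            out[name] = float(np.corrcoef(d[:, j], r[:, j])[0, 1])
    return out
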