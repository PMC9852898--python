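"""Per-trial mouse-path metrics.

Paths live in a normalized screen space: the start button at the origin, the
two response images at (-1, 1.5) and (+1, 1.5). For each trial this module
computes the sampling rate, initiation time, response time, the signed area
between the path and the straight start-to-end line (AUC, the conflict
proxy: deviation away from the chosen side counts positive), and the number
of crossings of the vertical axis through the start position (vacillation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Geometry",
    "DEFAULT_GEOMETRY",
    "estimate_sampling_rate",
    "normalize_trajectory",
    "compute_auc",
    "count_y_crossings",
    "compute_times",
    "compute_trial_metrics",
]


@dataclass(frozen=True)
class Geometry:
    start: tuple[float, float] = (0.0, 0.0)
    target_left: tuple[float, float] = (-1.0, 1.5)
    target_right: tuple[float, float] = (1.0, 1.5)
    movement_threshold: float = 0.02  # normalized units; initiation detector


DEFAULT_GEOMETRY = Geometry()


def estimate_sampling_rate(t: np.ndarray) -> float:
    """Average sampling rate (n-1) / span in Hz from sample timestamps."""
    t = np.asarray(t, float)
    if t.size < 2:
        raise ValueError("need at least 2 samples to estimate a sampling rate")
    span = float(t[-1] - t[0])
    if span <= 0:
        raise ValueError("zero or negative time span")
    return (t.size - 1) / span


def normalize_trajectory(
    x: np.ndarray,
    y: np.ndarray,
    chosen_side: str,
    geometry: Geometry = DEFAULT_GEOMETRY,
):
    """Anchor the path at the origin and reflect right-choice paths about the
    vertical axis so every path heads for the left target.

    The reflection is an involution and leaves the AUC magnitude/sign
    convention side-invariant.
    """
    if chosen_side not in ("left", "right"):
        raise ValueError(f"chosen_side must be 'left' or 'right', got {chosen_side!r}")
    x = np.asarray(x, float) - geometry.start[0]
    y = np.asarray(y, float) - geometry.start[1]
    if chosen_side == "right":
        x = -x
    return x, y


def compute_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Signed area between the piecewise-linear path and the straight line
    from its first to its last sample.

    Computed by trapezoidal integration of the perpendicular deviation over
    the along-chord coordinate (equivalent to the shoelace area of the closed
    path-plus-chord polygon). Deviation to the right of the chord direction
    counts positive; for a normalized path (chosen target on the left) that
    is deviation away from the chosen side.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2:
        raise ValueError("need at least 2 samples to compute an AUC")
    p0 = np.array([x[0], y[0]])
    p1 = np.array([x[-1], y[-1]])
    chord = p1 - p0
    norm = np.hypot(*chord)
    if norm == 0:
        raise ValueError("degenerate path: start equals end")
    u = chord / norm
    n = np.array([u[1], -u[0]])  # right-hand perpendicular
    dx = x - p0[0]
    dy = y - p0[1]
    s = dx * u[0] + dy * u[1]
    d = dx * n[0] + dy * n[1]
    return float(np.trapezoid(d, s))


def count_y_crossings(x: np.ndarray, start_x: float = 0.0) -> int:
    """Number of strict sign changes of x(t) about the start abscissa.

    Samples exactly on the axis are bridged (the previous sign carries
    through), so grazing the axis does not count as two crossings.
    """
    rel = np.asarray(x, float) - start_x
    signs = np.sign(rel)
    signs = signs[signs != 0]
    if signs.size < 2:
        return 0
    return int(np.count_nonzero(np.diff(signs) != 0))


def compute_times(
    t: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    start_press_t: float,
    click_t: float,
    geometry: Geometry = DEFAULT_GEOMETRY,
):
    """(initiation time, response time, no_movement flag) for one trial.

    RT is click minus start press; initiation is the time of the first sample
    whose displacement from the first sample exceeds the movement threshold.
    A path that never moves past the threshold gets initiation = RT and a
    flag instead of an error.
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if click_t < start_press_t:
        raise ValueError("click before start press")
    rt = float(click_t - start_press_t)
    disp = np.hypot(x - x[0], y - y[0])
    moved = np.nonzero(disp > geometry.movement_threshold)[0]
    if moved.size == 0:
        return rt, rt, True
    init = float(t[moved[0]] - start_press_t)
    return init, rt, False


def compute_trial_metrics(
    trials: pd.DataFrame,
    paths: pd.DataFrame,
    geometry: Geometry = DEFAULT_GEOMETRY,
    signed_auc: bool = True,
) -> pd.DataFrame:
    """Per-trial metrics table for all non-censored trials.

    ``trials`` carries trial metadata (trial_id, participant_id, context,
    nwl_shown, pair_id, chosen_side, healthy_choice, rt_s, ...); ``paths``
    holds the samples (trial_id, t_s, x, y). Censored trials (no click) are
    skipped. Set ``signed_auc=False`` for the absolute-area reading.
    """
    for col in ("trial_id", "t_s", "x", "y"):
        if col not in paths.columns:
            raise ValueError(f"paths table missing column {col!r}")
    t_all = paths["t_s"].to_numpy(float)
    x_all = paths["x"].to_numpy(float)
    y_all = paths["y"].to_numpy(float)
    groups = paths.groupby("trial_id", sort=False).indices

    meta = trials.set_index("trial_id")
    rows = []
    for trial_id, idx in groups.items():
        if trial_id not in meta.index:
            continue
        info = meta.loc[trial_id]
        t = t_all[idx]
        x = x_all[idx]
        y = y_all[idx]
        rate = estimate_sampling_rate(t)
        xn, yn = normalize_trajectory(x, y, str(info["chosen_side"]), geometry)
        auc = compute_auc(xn, yn)
        if not signed_auc:
            auc = abs(auc)
        # crossings are counted from the first movement sample on, about the
        # start abscissa; pre-initiation jitter is not vacillation
        disp = np.hypot(xn - xn[0], yn - yn[0])
        moved_idx = np.nonzero(disp > geometry.movement_threshold)[0]
        if moved_idx.size:
            crossings = count_y_crossings(xn[moved_idx[0]:], start_x=float(xn[0]))
        else:
            crossings = 0
        rt_click = float(info["rt_s"]) if "rt_s" in info else float(t[-1])
        init, rt, no_move = compute_times(t, x, y, 0.0, rt_click, geometry)
        rows.append(
            {
                "trial_id": trial_id,
                "auc": auc,
                "y_crossings": crossings,
                "rt_s": rt,
                "init_time_s": init,
                "no_movement": no_move,
                "sampling_rate_hz": rate,
            }
        )
    metrics = pd.DataFrame(rows)
    carry = [
        c
        for c in (
            "participant_id", "context", "nwl_shown", "pair_id", "position",
            "left_image", "right_image", "nwl_left", "nwl_right", "delta_nwl",
            "chosen_side", "healthy_choice", "censored",
            "recognized_left", "recognized_right",
            "contam_low_resolution", "contam_multicross",
            "contam_rt_outlier", "contam_unrecognized",
        )
        if c in trials.columns
    ]
    return metrics.merge(
        trials[["trial_id", *carry]], on="trial_id", how="left", validate="1:1"
    )
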