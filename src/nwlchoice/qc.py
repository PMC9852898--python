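"""Trial-level quality filters.

A trial is excluded when any rule fires: mouse-tracking resolution below
10 Hz; initiation time, AUC, or RT more than 3 SD above the participant's
mean (means/SDs computed per participant over that participant's
resolution-passing trials); three or more crossings of the vertical axis; or
fewer than both pair images recognized. Rules are applied conjunctively in a
single pass with thresholds from the unfiltered (resolution-passing) base
set, so the outcome is order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FilterParams",
    "ExclusionReport",
    "RULE_ORDER",
    "recognition_pair_check",
    "participant_baselines",
    "apply_trial_filters",
]

# reporting order mirrors the study's data-preparation narrative
RULE_ORDER = (
    "low_resolution",
    "init_time",
    "auc",
    "rt",
    "y_crossings",
    "recognition",
)


@dataclass(frozen=True)
class FilterParams:
    min_rate_hz: float = 10.0       # exclude when rate < this (strict)
    sd_mult: float = 3.0            # exclude when value > mean + sd_mult * SD (strict)
    max_crossings: int = 3          # exclude when crossings >= this
    require_both_recognized: bool = True

    def __post_init__(self) -> None:
        if self.min_rate_hz <= 0:
            raise ValueError("min_rate_hz must be > 0")
        if self.sd_mult <= 0:
            raise ValueError("sd_mult must be > 0")


@dataclass
class ExclusionReport:
    n_total: int
    n_retained: int
    per_rule_counts: dict[str, int]
    per_rule_fractions: dict[str, float]
    tags: pd.DataFrame  # one bool column per rule, indexed like the input
    n_sd_undefined: int = 0

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_retained": self.n_retained,
            "n_excluded": self.n_total - self.n_retained,
            "per_rule_counts": dict(self.per_rule_counts),
            "per_rule_fractions": dict(self.per_rule_fractions),
            "n_sd_undefined": self.n_sd_undefined,
        }


def recognition_pair_check(left_flag, right_flag) -> str:
    """'both', 'one', or 'none' recognized images in a pair; a missing flag
    counts as unrecognized."""
    flags = []
    for f in (left_flag, right_flag):
        if f is None or (isinstance(f, float) and np.isnan(f)):
            flags.append(False)
        else:
            flags.append(bool(f))
    n = sum(flags)
    return {2: "both", 1: "one", 0: "none"}[n]


def participant_baselines(
    metrics: pd.DataFrame, params: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Per-participant mean/SD of initiation time, AUC, and RT over
    resolution-passing trials (the threshold base set)."""
    base = metrics.loc[metrics["sampling_rate_hz"] >= params.min_rate_hz]
    stats = base.groupby("participant_id")[["init_time_s", "auc", "rt_s"]].agg(
        ["mean", "std", "count"]
    )
    stats.columns = ["_".join(c) for c in stats.columns]
    return stats


def apply_trial_filters(
    metrics: pd.DataFrame,
    params: FilterParams = FilterParams(),
    recognition: pd.DataFrame | None = None,
    baselines: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply all exclusion rules to a metrics table.

    ``recognition`` (participant_id, image_id, recognized) overrides the
    recognized_left/right columns when given. ``baselines`` allows re-running
    the filter with thresholds computed on a previous base set (for
    idempotence checks / per-context policies); by default they are computed
    from ``metrics`` itself. Participants with fewer than 2 resolution-passing
    trials have undefined SDs: their trials are retained by the 3-SD rules
    and counted in ``n_sd_undefined``.
    """
    df = metrics
    n = len(df)
    tags = pd.DataFrame(index=df.index)

    tags["low_resolution"] = df["sampling_rate_hz"].to_numpy() < params.min_rate_hz

    if baselines is None:
        baselines = participant_baselines(df, params)
    stats = baselines.reindex(df["participant_id"])
    n_sd_undefined = 0
    for rule, col in (("init_time", "init_time_s"), ("auc", "auc"), ("rt", "rt_s")):
        mean = stats[f"{col}_mean"].to_numpy()
        sd = stats[f"{col}_std"].to_numpy()
        thr = mean + params.sd_mult * sd
        fired = df[col].to_numpy() > thr
        undef = ~np.isfinite(thr)
        fired[undef] = False
        tags[rule] = fired
    n_sd_undefined = int((~np.isfinite(stats["rt_s_std"].to_numpy())).sum())

    tags["y_crossings"] = df["y_crossings"].to_numpy() >= params.max_crossings

    if params.require_both_recognized:
        if recognition is not None:
            rec = recognition.set_index(["participant_id", "image_id"])["recognized"]
            left = [
                rec.get((p, i), None)
                for p, i in zip(df["participant_id"], df["left_image"])
            ]
            right = [
                rec.get((p, i), None)
                for p, i in zip(df["participant_id"], df["right_image"])
            ]
        else:
            left = df.get("recognized_left")
            right = df.get("recognized_right")
            left = [None] * n if left is None else list(left)
            right = [None] * n if right is None else list(right)
        tags["recognition"] = [
            recognition_pair_check(l, r) != "both" for l, r in zip(left, right)
        ]
    else:
        tags["recognition"] = np.zeros(n, bool)

    excluded = tags[list(RULE_ORDER)].any(axis=1)
    retained = df.loc[~excluded].copy()
    counts = {rule: int(tags[rule].sum()) for rule in RULE_ORDER}
    fractions = {rule: (counts[rule] / n if n else 0.0) for rule in RULE_ORDER}
    report = ExclusionReport(
        n_total=n,
        n_retained=int(len(retained)),
        per_rule_counts=counts,
        per_rule_fractions=fractions,
        tags=tags,
        n_sd_undefined=n_sd_undefined,
    )
    return retained, report
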