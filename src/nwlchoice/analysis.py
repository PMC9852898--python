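"""Behavioral estimates with participant-cluster bootstrap uncertainty.

The design shows every pair twice — first without, then with nutrient
warning labels (NWL) — which defines four decision paths per pair: HH, HU,
UH, UU (first letter = choice without labels, H = healthy). Quantities
computed here: healthy-choice probabilities by context and label condition,
reversal probability P(healthy with labels | unhealthy without), label-caused
changes in path curvature and response time (ΔAUC, ΔRT; negative = reduction
caused by the labels) adjusted for their no-label baseline, and the
dose-response of healthy-choice probability in the within-pair label-count
difference (ΔNWL 1-3).

Uncertainty is a seeded percentile bootstrap resampling participants
(clusters) with replacement — a deliberate replacement for mixed-effects
machinery that targets the same marginal estimands.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._rng import rng_for

__all__ = [
    "DECISION_PATHS",
    "label_healthy_choice",
    "build_paired_trials",
    "classify_decision_path",
    "path_census",
    "healthy_choice_prob",
    "reversal_probability",
    "compute_deltas",
    "delta_summary",
    "delta_nwl_effect",
]

DECISION_PATHS = ("HH", "HU", "UH", "UU")
DEFAULT_N_BOOT = 2000


def label_healthy_choice(chosen_nwl, other_nwl):
    """True iff the chosen image carries strictly fewer warning labels.

    Equal counts violate the design (every pair differs in NWL) and raise.
    """
    chosen = np.asarray(chosen_nwl)
    other = np.asarray(other_nwl)
    if np.any(chosen == other):
        raise ValueError("design violation: pair members share an NWL count")
    out = chosen < other
    return bool(out) if out.ndim == 0 else out


def classify_decision_path(first_healthy, second_healthy):
    """'HH'/'HU'/'UH'/'UU' from the without-label and with-label choices."""
    f = np.asarray(first_healthy, bool)
    s = np.asarray(second_healthy, bool)
    letters_f = np.where(f, "H", "U")
    letters_s = np.where(s, "H", "U")
    out = np.char.add(letters_f, letters_s)
    return str(out) if out.ndim == 0 else out


def build_paired_trials(trials: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Join each pair's two label-block records into one row.

    Pairs missing either block (e.g. one trial filtered or censored) are
    dropped; the count of dropped pairs is returned alongside.
    """
    key = ["participant_id", "context", "pair_id"]
    cols = ["healthy_choice", "auc", "rt_s", "delta_nwl"]
    have = [c for c in cols if c in trials.columns]
    wide = trials.pivot_table(
        index=key, columns="nwl_shown", values=have, aggfunc="first", observed=True
    )
    n_pairs = len(wide)
    needed = [("healthy_choice", False), ("healthy_choice", True)]
    complete = wide[needed].notna().all(axis=1)
    wide = wide.loc[complete]
    out = pd.DataFrame(index=wide.index)
    out["choice_no_nwl"] = wide[("healthy_choice", False)].astype(bool)
    out["choice_nwl"] = wide[("healthy_choice", True)].astype(bool)
    for name, col in (("auc", "auc"), ("rt", "rt_s")):
        if col in have:
            out[f"{name}_no_nwl"] = wide[(col, False)]
            out[f"{name}_nwl"] = wide[(col, True)]
    if "delta_nwl" in have:
        out["delta_nwl"] = wide[("delta_nwl", False)].astype("Int64")
    out = out.reset_index()
    out["decision_path"] = classify_decision_path(
        out["choice_no_nwl"].to_numpy(), out["choice_nwl"].to_numpy()
    )
    return out, int(n_pairs - complete.sum())


def path_census(paired: pd.DataFrame, by=("context",)) -> pd.DataFrame:
    """Counts of the four decision paths per group."""
    tab = (
        paired.groupby([*by, "decision_path"], observed=True)
        .size()
        .unstack("decision_path", fill_value=0)
    )
    for p in DECISION_PATHS:
        if p not in tab.columns:
            tab[p] = 0
    return tab[list(DECISION_PATHS)].reset_index()


def _bootstrap_ratio(
    num: np.ndarray,
    den: np.ndarray,
    n_boot: int,
    rng: np.random.Generator,
    level: float = 0.95,
):
    """Percentile CI for sum(num)/sum(den) under cluster (row) resampling."""
    P = len(num)
    if P == 0:
        return np.nan, np.nan
    idx = rng.integers(0, P, size=(n_boot, P))
    nums = num[idx].sum(axis=1)
    dens = den[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stats = np.where(dens > 0, nums / np.maximum(dens, 1), np.nan)
    lo, hi = np.nanpercentile(stats, [(1 - level) / 2 * 100, (1 + level) / 2 * 100])
    return float(lo), float(hi)


def _grouped_proportion(
    df: pd.DataFrame,
    success: pd.Series,
    by: list[str],
    n_boot: int,
    seed: int,
    stream: str,
) -> pd.DataFrame:
    rows = []
    for keys, grp in df.groupby(by, observed=True, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        s = success.loc[grp.index]
        per = pd.DataFrame(
            {"k": s.astype(float), "n": 1.0, "pid": grp["participant_id"]}
        ).groupby("pid").sum()
        k = per["k"].to_numpy()
        m = per["n"].to_numpy()
        est = k.sum() / m.sum()
        lo, hi = _bootstrap_ratio(
            k, m, n_boot, rng_for(seed, stream, *keys)
        )
        rows.append(
            dict(zip(by, keys))
            | {
                "estimate": est,
                "ci_lo": lo,
                "ci_hi": hi,
                "n_trials": int(m.sum()),
                "n_participants": len(per),
            }
        )
    return pd.DataFrame(rows)


def healthy_choice_prob(
    trials: pd.DataFrame,
    by=("context",),
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """P(healthy choice) per group, with 95% cluster-bootstrap CIs."""
    if len(trials) == 0:
        raise ValueError("no trials")
    return _grouped_proportion(
        trials, trials["healthy_choice"].astype(bool), list(by), n_boot, seed, "p_healthy"
    )


def reversal_probability(
    paired: pd.DataFrame,
    by=("context",),
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """P(healthy with labels | unhealthy without labels) per group.

    The denominator (pairs whose first choice was unhealthy) is reported;
    groups with an empty denominator come back as missing with count 0.
    """
    rows = []
    for keys, grp in paired.groupby(list(by), observed=True, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        ufirst = grp.loc[~grp["choice_no_nwl"].astype(bool)]
        if len(ufirst) == 0:
            rows.append(
                dict(zip(by, keys))
                | {"estimate": np.nan, "ci_lo": np.nan, "ci_hi": np.nan,
                   "n_u_first": 0, "n_participants": 0}
            )
            continue
        per = pd.DataFrame(
            {
                "k": ufirst["choice_nwl"].astype(float),
                "n": 1.0,
                "pid": ufirst["participant_id"],
            }
        ).groupby("pid").sum()
        k = per["k"].to_numpy()
        m = per["n"].to_numpy()
        lo, hi = _bootstrap_ratio(k, m, n_boot, rng_for(seed, "reversal", *keys))
        rows.append(
            dict(zip(by, keys))
            | {
                "estimate": k.sum() / m.sum(),
                "ci_lo": lo,
                "ci_hi": hi,
                "n_u_first": int(m.sum()),
                "n_participants": len(per),
            }
        )
    return pd.DataFrame(rows)


def compute_deltas(paired: pd.DataFrame) -> pd.DataFrame:
    """Label-caused change per pair: Δ = value with labels − value without.

    Negative values mean the labels reduced path curvature (ΔAUC) or sped up
    the response (ΔRT). The no-label baseline is carried for covariate
    adjustment in `delta_summary`.
    """
    out = paired.copy()
    out["delta_auc"] = out["auc_nwl"] - out["auc_no_nwl"]
    out["delta_rt"] = out["rt_nwl"] - out["rt_no_nwl"]
    out["baseline_auc"] = out["auc_no_nwl"]
    out["baseline_rt"] = out["rt_no_nwl"]
    return out


def _adjusted_mean(y: np.ndarray, xc: np.ndarray):
    """Intercept of OLS of y on a (globally) centered baseline; falls back to
    the raw mean when the baseline is constant."""
    var = np.var(xc)
    if var < 1e-12:
        return float(np.mean(y)), True
    slope = np.cov(xc, y, bias=True)[0, 1] / var
    return float(np.mean(y) - slope * np.mean(xc)), False


def delta_summary(
    deltas: pd.DataFrame,
    by=("context", "decision_path"),
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """Baseline-adjusted mean ΔAUC / ΔRT per cell with bootstrap CIs.

    Baselines are centered at their grand mean; each cell's adjusted mean is
    the intercept of an in-cell regression of Δ on the centered baseline.
    Cells whose 95% CI excludes zero are flagged.
    """
    rows = []
    for metric in ("auc", "rt"):
        dcol, bcol = f"delta_{metric}", f"baseline_{metric}"
        grand = deltas[bcol].mean()
        for keys, grp in deltas.groupby(list(by), observed=True, sort=True):
            keys = keys if isinstance(keys, tuple) else (keys,)
            if len(grp) < 2:
                continue
            y = grp[dcol].to_numpy(float)
            xc = grp[bcol].to_numpy(float) - grand
            est, degenerate = _adjusted_mean(y, xc)
            pids = grp["participant_id"].to_numpy()
            uniq = np.unique(pids)
            rng = rng_for(seed, "delta", metric, *keys)
            stats = []
            groups = {p: np.nonzero(pids == p)[0] for p in uniq}
            for _ in range(n_boot):
                take = rng.integers(0, len(uniq), len(uniq))
                sel = np.concatenate([groups[uniq[i]] for i in take])
                stats.append(_adjusted_mean(y[sel], xc[sel])[0])
            lo, hi = np.percentile(stats, [2.5, 97.5])
            rows.append(
                dict(zip(by, keys))
                | {
                    "metric": metric,
                    "adjusted_mean": est,
                    "ci_lo": float(lo),
                    "ci_hi": float(hi),
                    "excludes_zero": bool(lo > 0 or hi < 0),
                    "baseline_degenerate": degenerate,
                    "n_pairs": int(len(grp)),
                }
            )
    return pd.DataFrame(rows)


def delta_nwl_effect(
    trials: pd.DataFrame,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> pd.DataFrame:
    """P(healthy choice) by within-pair label-count difference (1, 2, 3) per
    context, over trials shown with labels."""
    shown = trials.loc[trials["nwl_shown"].astype(bool)]
    if len(shown) == 0:
        raise ValueError("no label-shown trials")
    out = _grouped_proportion(
        shown,
        shown["healthy_choice"].astype(bool),
        ["context", "delta_nwl"],
        n_boot,
        seed,
        "dnwl",
    )
    for ctx in shown["context"].unique():
        for lvl in (1, 2, 3):
            if not ((out["context"] == ctx) & (out["delta_nwl"] == lvl)).any():
                out.loc[len(out)] = {
                    "context": ctx, "delta_nwl": lvl, "estimate": np.nan,
                    "ci_lo": np.nan, "ci_hi": np.nan, "n_trials": 0,
                    "n_participants": 0,
                }
    return out.sort_values(["context", "delta_nwl"]).reset_index(drop=True)
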