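"""Synthetic food-choice studies with known ground truth.

Emulates the study design end-to-end: 94 food images split into three
context inventories stratified by nutrient-warning-label (NWL) count;
per-participant VAS ratings whose health means fall and like/want means are
U-shaped in NWL count; constrained 90-pair choice sequences per context,
shown once without and once with labels; choices and response times from a
drift-diffusion process whose parameters depend on context and label
condition (plus pair-level drift heterogeneity shared across the two label
blocks and a drift increment per unit NWL difference); curved mouse paths
whose deviation scales with decision conflict; a 4-second response deadline;
and tagged contaminant trials (low sampling rate, multi-crossing paths, RT
outliers, unrecognized images) that exercise every downstream filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import rng_for
from .ddm import DDMParams, _hit_prob_arrays, sample_wiener
from .stimuli import (
    DEFAULT_STRATA,
    ContextInventory,
    build_inventories,
    generate_pair_sequence,
)
from .trajectory import DEFAULT_GEOMETRY, Geometry

__all__ = [
    "CONTEXTS",
    "RatingModel",
    "ContaminationRates",
    "StudyConfig",
    "SyntheticStudy",
    "ConfigError",
    "default_ddm_truth",
    "make_image_table",
    "simulate_ratings",
    "simulate_trial",
    "simulate_trajectory",
    "inject_contaminants",
    "simulate_study",
]

CONTEXTS = ("healthy", "typical", "unrestricted")

_CATEGORIES = (
    "fruit", "vegetables", "salads", "seeds_nuts", "bread", "pasta",
    "prepared_meals", "soups_stews", "breakfast_food", "cheese", "snacks",
    "pizza", "pastries", "cookies", "cake", "dessert_treats",
)


class ConfigError(ValueError):
    """Invalid study configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.field = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass
class RatingModel:
    """VAS rating structure by NWL count (0..3).

    Health means decrease with NWL count; like/want means are U-shaped
    (lowest at 2 NWL). Draws are Gaussian, clamped to [0, 100].
    """

    health_means: tuple[float, float, float, float] = (78.0, 58.0, 38.0, 24.0)
    like_means: tuple[float, float, float, float] = (68.0, 56.0, 50.0, 63.0)
    want_means: tuple[float, float, float, float] = (64.0, 53.0, 47.0, 60.0)
    rating_sd: float = 12.0
    recognition_prob: float = 0.91

    def validate(self) -> None:
        for name in ("health_means", "like_means", "want_means"):
            means = getattr(self, name)
            if len(means) != 4 or any(not 0 <= m <= 100 for m in means):
                raise ConfigError(name, "needs 4 means inside [0, 100]")
        if self.rating_sd <= 0:
            raise ConfigError("rating_sd", "must be > 0")
        if not 0 <= self.recognition_prob <= 1:
            raise ConfigError("recognition_prob", "must be a probability")


@dataclass
class ContaminationRates:
    """Per-trial probabilities of each contaminant type."""

    low_resolution_rate: float = 0.036
    multicross_rate: float = 0.024
    rt_outlier_rate: float = 0.02
    unrecognized_pair_rate: float = 0.0

    def validate(self) -> None:
        for name, v in asdict(self).items():
            if not 0.0 <= v <= 0.5:
                raise ConfigError(name, "must lie in [0, 0.5]")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def default_ddm_truth() -> dict[tuple[str, bool], DDMParams]:
    """Ground-truth diffusion parameters per (context, labels shown).

    Chosen once to mirror the study's qualitative structure: the healthy
    context has the largest bias and drift toward the healthy option and the
    shortest non-decision time, the unrestricted context the opposite;
    showing labels raises drift in every context and shortens non-decision
    time, but raises bias only in the healthy and typical contexts.
    """
    return {
        ("healthy", False): DDMParams(1.6, 0.35, 0.62, 0.90),
        ("healthy", True): DDMParams(1.6, 0.29, 0.67, 1.70),
        ("typical", False): DDMParams(1.6, 0.40, 0.57, 0.60),
        ("typical", True): DDMParams(1.6, 0.36, 0.62, 1.15),
        ("unrestricted", False): DDMParams(1.6, 0.42, 0.52, 0.35),
        ("unrestricted", True): DDMParams(1.6, 0.38, 0.52, 1.30),
    }


@dataclass
class StudyConfig:
    """Everything needed to generate one synthetic study."""

    n_participants: int = 128
    contexts: tuple[str, str, str] = CONTEXTS
    pairs_per_combo: int = 15
    timeout: float = 4.0
    ddm_truth: dict[tuple[str, bool], DDMParams] = field(default_factory=default_ddm_truth)
    rating_model: RatingModel = field(default_factory=RatingModel)
    contamination: ContaminationRates = field(default_factory=ContaminationRates)
    sampling_rate_mean: float = 60.0
    sampling_rate_sd: float = 8.0
    pair_drift_sd: float = 0.4      # pair-level drift heterogeneity, shared across blocks
    dnwl_drift_slope: float = 0.15  # drift increment per unit NWL difference (centered at 2)
    conflict_gain: float = 0.8      # path curvature per unit conflict
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants", "must be >= 1")
        if len(self.contexts) != 3 or len(set(self.contexts)) != 3:
            raise ConfigError("contexts", "needs 3 distinct context labels")
        if self.pairs_per_combo < 1:
            raise ConfigError("pairs_per_combo", "must be >= 1")
        if self.timeout <= 0:
            raise ConfigError("timeout", "must be > 0")
        expected = {(c, s) for c in self.contexts for s in (False, True)}
        if set(self.ddm_truth) != expected:
            raise ConfigError(
                "ddm_truth",
                f"needs exactly 6 entries keyed by context x nwl_shown, got {sorted(self.ddm_truth)}",
            )
        if self.sampling_rate_mean <= 0 or self.sampling_rate_sd < 0:
            raise ConfigError("sampling_rate", "mean must be > 0 and sd >= 0")
        self.rating_model.validate()
        self.contamination.validate()


@dataclass
class SyntheticStudy:
    trials: pd.DataFrame
    paths: pd.DataFrame
    ratings: pd.DataFrame
    participants: pd.DataFrame
    inventories: dict[str, ContextInventory]
    truth: dict
    config: StudyConfig


def make_image_table(rng: np.random.Generator, extra_per_stratum: int = 0) -> pd.DataFrame:
    """Synthetic stand-in for the study's 94-image inventory table.

    Generates exactly the pooled stratum sizes the three contexts require
    (plus ``extra_per_stratum``), with nutrient values drawn from ranges that
    rise with the label count.
    """
    needed = {c: 0 for c in (0, 1, 2, 3)}
    for spec in DEFAULT_STRATA.values():
        for c, n in spec.items():
            needed[c] += n
    rows = []
    k = 0
    for c, n in needed.items():
        for _ in range(n + extra_per_stratum):
            rows.append(
                {
                    "image_id": f"img{k:03d}",
                    "category": _CATEGORIES[int(rng.integers(len(_CATEGORIES)))],
                    "nwl_count": c,
                    "kcal": float(np.round(rng.uniform(40 + 90 * c, 140 + 110 * c), 1)),
                    "sat_fat_g": float(np.round(rng.uniform(0.1 + 2 * c, 1.5 + 4 * c), 2)),
                    "sugar_g": float(np.round(rng.uniform(1 + 5 * c, 8 + 8 * c), 1)),
                    "sodium_mg": float(np.round(rng.uniform(10 + 120 * c, 120 + 260 * c), 0)),
                }
            )
            k += 1
    return pd.DataFrame(rows)


def simulate_ratings(
    model: RatingModel,
    images: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-image health/like/want VAS ratings and recognition flags for one
    participant."""
    model.validate()
    if len(images) == 0:
        raise ValueError("image inventory is empty")
    nwl = images["nwl_count"].to_numpy(int)
    out = {"image_id": images["image_id"].to_numpy(), "nwl_count": nwl}
    for name, means in (
        ("health", model.health_means),
        ("like", model.like_means),
        ("want", model.want_means),
    ):
        mu = np.asarray(means, float)[nwl]
        out[name] = np.clip(mu + model.rating_sd * rng.standard_normal(len(nwl)), 0.0, 100.0)
    out["recognized"] = rng.random(len(nwl)) < model.recognition_prob
    return pd.DataFrame(out)


def simulate_trial(
    params: DDMParams,
    timeout: float,
    rng: np.random.Generator,
    dt: float = 1e-3,
):
    """One diffusion trial: ('healthy'|'unhealthy', rt seconds, censored)."""
    rt, upper, censored = sample_wiener(
        params.boundary_sep, params.non_decision, params.bias, params.drift,
        n=1, rng=rng, timeout=timeout, dt=dt,
    )
    choice = "healthy" if upper[0] else "unhealthy"
    return choice, float(rt[0]), bool(censored[0])


def _smoothstep(s: np.ndarray) -> np.ndarray:
    return s * s * (3.0 - 2.0 * s)


def simulate_trajectory(
    choice_side: str,
    rt: float,
    conflict: float,
    rate: float,
    rng: np.random.Generator,
    geometry: Geometry = DEFAULT_GEOMETRY,
    hold_s: float = 0.2,
    noise_sd: float = 0.008,
    wander: float = 0.0,
):
    """Mouse path for one trial: hold at the start, then a quadratic Bezier
    sweep to the chosen corner whose control point is pulled toward the
    unchosen side in proportion to ``conflict``.

    ``wander`` adds a damped horizontal oscillation (used by the
    multi-crossing contaminant). Returns (t, x, y) arrays sampled at ``rate``.
    """
    if rt <= 0:
        raise ValueError("rt must be > 0")
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if conflict < 0:
        raise ValueError("conflict must be >= 0")
    n = max(2, int(round(rate * rt)) + 1)
    t = np.linspace(0.0, rt, n)
    p0 = np.asarray(geometry.start, float)
    p2 = np.asarray(
        geometry.target_left if choice_side == "left" else geometry.target_right, float
    )
    away = 1.0 if choice_side == "left" else -1.0  # toward the unchosen side
    p1 = 0.5 * (p0 + p2)
    p1 = p1 + np.array([away * conflict, 0.0])
    hold = min(hold_s, 0.5 * rt)
    s = np.clip((t - hold) / max(rt - hold, 1e-9), 0.0, 1.0)
    s = _smoothstep(s)
    x = (1 - s) ** 2 * p0[0] + 2 * s * (1 - s) * p1[0] + s**2 * p2[0]
    y = (1 - s) ** 2 * p0[1] + 2 * s * (1 - s) * p1[1] + s**2 * p2[1]
    if wander > 0:
        x = x + wander * np.sin(8.0 * np.pi * s) * np.exp(-2.5 * s)
    if noise_sd > 0:
        # smoothed jitter: real cursor noise is correlated between samples,
        # and white noise about the axis would fabricate crossings
        kernel = np.array([0.25, 0.5, 0.25])
        nx = rng.standard_normal(n)
        ny = rng.standard_normal(n)
        if n >= 3:
            for _ in range(2):
                nx = np.convolve(nx, kernel, mode="same")
                ny = np.convolve(ny, kernel, mode="same")
        x = x + noise_sd * nx
        y = y + noise_sd * ny
    x[0], y[0] = p0
    x[-1], y[-1] = p2
    return t, x, y


def _make_participants(n: int, rng: np.random.Generator) -> pd.DataFrame:
    sex = np.where(np.arange(n) % 2 == 0, "female", "male")
    return pd.DataFrame(
        {
            "participant_id": [f"p{i:03d}" for i in range(n)],
            "age": rng.integers(18, 46, n),
            "sex": sex[rng.permutation(n)],
            "bmi": np.round(np.clip(rng.normal(25.0, 3.0, n), 20.0, 35.0), 1),
            "appetite_vas": np.round(np.clip(rng.normal(50, 18, n), 0, 100), 1),
            "sss_score": rng.integers(1, 8, n),
            "aebq_score": np.round(np.clip(rng.normal(3.0, 0.6, n), 1.0, 5.0), 2),
            "exercise": rng.random(n) < 0.5,
        }
    )


def simulate_study(config: StudyConfig) -> SyntheticStudy:
    """Generate a complete synthetic study (trials, paths, ratings,
    participants, ground truth), reproducible from ``config.rng_seed``."""
    config.validate()
    seed = config.rng_seed

    image_table = make_image_table(rng_for(seed, "images"))
    inventories = build_inventories(image_table, DEFAULT_STRATA, rng_for(seed, "inventories"))
    # inventories are keyed by DEFAULT_STRATA's context names; remap if the
    # config uses different labels (order-preserving)
    if tuple(inventories) != tuple(config.contexts):
        inventories = {
            ctx: ContextInventory(context=ctx, images=inv.images)
            for ctx, inv in zip(config.contexts, inventories.values())
        }

    participants = _make_participants(config.n_participants, rng_for(seed, "participants"))
    pids = participants["participant_id"].tolist()

    all_images = pd.concat(
        [
            pd.DataFrame(
                {
                    "image_id": [i.image_id for i in inv.images],
                    "nwl_count": [i.nwl_count for i in inv.images],
                    "context": ctx,
                }
            )
            for ctx, inv in inventories.items()
        ],
        ignore_index=True,
    )

    ratings_frames = []
    rec_lookup: dict[tuple[str, str], bool] = {}
    for pid in pids:
        r = simulate_ratings(config.rating_model, all_images, rng_for(seed, "ratings", pid))
        r.insert(0, "participant_id", pid)
        ratings_frames.append(r)
        for img, flag in zip(r["image_id"], r["recognized"]):
            rec_lookup[(pid, img)] = bool(flag)
    ratings = pd.concat(ratings_frames, ignore_index=True)

    # --- trial skeleton -------------------------------------------------
    rows = []
    for pid in pids:
        for ctx in config.contexts:
            inv = inventories[ctx]
            seq = generate_pair_sequence(
                inv, config.pairs_per_combo, rng_for(seed, "sequence", pid, ctx)
            )
            pair_rng = rng_for(seed, "pair_effects", pid, ctx)
            pair_effects = config.pair_drift_sd * pair_rng.standard_normal(len(seq))
            for block, nwl_shown in enumerate((False, True)):
                for spec, pair_eff in zip(seq, pair_effects):
                    rows.append(
                        {
                            "trial_id": f"{pid}:{ctx}:{block}:{spec.position:03d}",
                            "participant_id": pid,
                            "context": ctx,
                            "nwl_shown": nwl_shown,
                            "block": block,
                            "position": spec.position,
                            "pair_id": f"{ctx}:{spec.position:03d}",
                            "left_image": spec.left_image,
                            "right_image": spec.right_image,
                            "nwl_left": spec.nwl_left,
                            "nwl_right": spec.nwl_right,
                            "pair_drift_effect": pair_eff,
                        }
                    )
    trials = pd.DataFrame(rows)
    trials["delta_nwl"] = (trials["nwl_left"] - trials["nwl_right"]).abs()

    # --- ground-truth parameters per trial ------------------------------
    base = np.array(
        [
            config.ddm_truth[(ctx, shown)].as_array()
            for ctx, shown in zip(trials["context"], trials["nwl_shown"])
        ]
    )
    alpha = base[:, 0]
    tau = base[:, 1]
    beta = base[:, 2]
    delta = (
        base[:, 3]
        + trials["pair_drift_effect"].to_numpy()
        + config.dnwl_drift_slope * (trials["delta_nwl"].to_numpy() - 2.0)
    )
    trials["true_drift"] = delta

    rt, upper, censored = sample_wiener(
        alpha, tau, beta, delta, rng=rng_for(seed, "choices"), timeout=config.timeout
    )
    trials["healthy_choice"] = upper
    trials["rt_s"] = rt
    trials["censored"] = censored
    healthy_side = np.where(
        trials["nwl_left"].to_numpy() < trials["nwl_right"].to_numpy(), "left", "right"
    )
    other_side = np.where(healthy_side == "left", "right", "left")
    trials["chosen_side"] = np.where(upper, healthy_side, other_side)

    p_up = _hit_prob_arrays(alpha, beta, delta)
    trials["conflict"] = config.conflict_gain * (1.0 - np.abs(2.0 * p_up - 1.0))

    rate_rng = rng_for(seed, "rates")
    trials["sampling_rate_hz"] = np.clip(
        rate_rng.normal(config.sampling_rate_mean, config.sampling_rate_sd, len(trials)),
        20.0,
        None,
    )

    trials["recognized_left"] = [
        rec_lookup[(p, i)] for p, i in zip(trials["participant_id"], trials["left_image"])
    ]
    trials["recognized_right"] = [
        rec_lookup[(p, i)] for p, i in zip(trials["participant_id"], trials["right_image"])
    ]

    # --- mouse paths ----------------------------------------------------
    path_rng = rng_for(seed, "paths")
    tau_holds = 0.4 * tau
    frames = {"trial_id": [], "t_s": [], "x": [], "y": []}
    for i, trial_id in enumerate(trials["trial_id"]):
        if censored[i]:
            continue
        t, x, y = simulate_trajectory(
            str(trials["chosen_side"].iloc[i]),
            float(rt[i]),
            float(trials["conflict"].iloc[i]),
            float(trials["sampling_rate_hz"].iloc[i]),
            path_rng,
            hold_s=float(tau_holds[i]),
        )
        frames["trial_id"].append(np.repeat(trial_id, len(t)))
        frames["t_s"].append(t)
        frames["x"].append(x)
        frames["y"].append(y)
    paths = pd.DataFrame(
        {k: np.concatenate(v) if v else np.array([]) for k, v in frames.items()}
    )

    study = SyntheticStudy(
        trials=trials,
        paths=paths,
        ratings=ratings,
        participants=participants,
        inventories=inventories,
        truth={
            "ddm_truth": {
                f"{ctx}|{'nwl' if shown else 'no_nwl'}": list(p.as_array())
                for (ctx, shown), p in config.ddm_truth.items()
            },
            "pair_drift_sd": config.pair_drift_sd,
            "dnwl_drift_slope": config.dnwl_drift_slope,
            "conflict_gain": config.conflict_gain,
            "rng_seed": seed,
        },
        config=config,
    )
    return inject_contaminants(study, config.contamination, rng_for(seed, "contaminants"))


def inject_contaminants(
    study: SyntheticStudy,
    rates: ContaminationRates,
    rng: np.random.Generator,
) -> SyntheticStudy:
    """Tag and corrupt a random subset of trials, one independent Bernoulli
    draw per contaminant type per trial.

    Low-resolution trials are resampled at 4-9 Hz; multi-crossing trials get
    a damped horizontal oscillation strong enough to cross the vertical axis
    at least three times; RT outliers have their response slowed far past the
    participant's typical range (path timestamps stretched to match); the
    unrecognized contaminant flips one pair image's recognition flag. Tags
    record the ground truth so filter recall/precision is computable.
    """
    rates.validate()
    trials = study.trials.copy()
    paths = study.paths
    n = len(trials)
    for col in ("contam_low_resolution", "contam_multicross", "contam_rt_outlier", "contam_unrecognized"):
        if col not in trials.columns:
            trials[col] = False

    active = ~trials["censored"].to_numpy(bool)
    draw = lambda rate: (rng.random(n) < rate) & active  # noqa: E731

    low_res = draw(rates.low_resolution_rate)
    multi = draw(rates.multicross_rate)
    rt_out = draw(rates.rt_outlier_rate)
    unrec = (rng.random(n) < rates.unrecognized_pair_rate)  # recognition needs no path

    trials.loc[low_res, "contam_low_resolution"] = True
    trials.loc[multi, "contam_multicross"] = True
    trials.loc[rt_out, "contam_rt_outlier"] = True
    trials.loc[unrec, "contam_unrecognized"] = True
    trials.loc[unrec, "recognized_left"] = False

    touched = low_res | multi | rt_out
    if not touched.any() or len(paths) == 0:
        study.trials = trials
        return study

    keep = ~paths["trial_id"].isin(trials.loc[touched, "trial_id"])
    kept_paths = paths.loc[keep]
    rebuilt = {"trial_id": [], "t_s": [], "x": [], "y": []}
    timeout = study.config.timeout if study.config is not None else None
    for i in np.nonzero(touched)[0]:
        row = trials.iloc[i]
        rt = float(row["rt_s"])
        if rt_out[i]:
            rt = min(0.97 * (timeout or 4.0), max(3.2, 2.5 * rt))
            trials.iloc[i, trials.columns.get_loc("rt_s")] = rt
        rate = float(row["sampling_rate_hz"])
        if low_res[i]:
            rate = float(rng.uniform(4.0, 9.0))
            trials.iloc[i, trials.columns.get_loc("sampling_rate_hz")] = rate
        t, x, y = simulate_trajectory(
            str(row["chosen_side"]),
            rt,
            float(row["conflict"]),
            rate,
            rng,
            wander=0.35 if multi[i] else 0.0,
            noise_sd=0.004 if multi[i] else 0.008,
        )
        rebuilt["trial_id"].append(np.repeat(row["trial_id"], len(t)))
        rebuilt["t_s"].append(t)
        rebuilt["x"].append(x)
        rebuilt["y"].append(y)
    new_paths = pd.DataFrame({k: np.concatenate(v) for k, v in rebuilt.items()})
    study.paths = pd.concat([kept_paths, new_paths], ignore_index=True)
    study.trials = trials
    return study
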