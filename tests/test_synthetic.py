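"""Synthetic study generator: design arithmetic, ratings, trials, paths,
contaminants, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nwlchoice._rng import rng_for
from nwlchoice.ddm import DDMParams, hit_probability
from nwlchoice.synthetic import (
    ConfigError,
    ContaminationRates,
    RatingModel,
    StudyConfig,
    inject_contaminants,
    make_image_table,
    simulate_ratings,
    simulate_study,
    simulate_trajectory,
    simulate_trial,
)
from nwlchoice.trajectory import compute_auc


def test_config_rejects_empty_study():
    with pytest.raises(ConfigError, match="n_participants"):
        StudyConfig(n_participants=0).validate()


def test_config_rejects_bad_truth_map():
    cfg = StudyConfig()
    cfg.ddm_truth = {("healthy", False): DDMParams(1.5, 0.3, 0.5, 1.0)}
    with pytest.raises(ConfigError, match="ddm_truth"):
        cfg.validate()


def test_trials_per_participant(small_study):
    per = small_study.trials.groupby("participant_id").size()
    assert (per == 540).all()  # 6 combos x 15 pairs x 3 contexts x 2 blocks
    # same pairs repeat across the two label blocks of a context
    first = small_study.trials.query("participant_id=='p000' and context=='healthy'")
    blocks = first.pivot_table(
        index="pair_id", columns="nwl_shown", values="left_image", aggfunc="first"
    )
    assert (blocks[False] == blocks[True]).all()


def test_same_seed_reproduces_identical_tables():
    cfg = StudyConfig(n_participants=2, rng_seed=123)
    a = simulate_study(cfg)
    b = simulate_study(StudyConfig(n_participants=2, rng_seed=123))
    pd.testing.assert_frame_equal(a.trials, b.trials)
    pd.testing.assert_frame_equal(a.paths, b.paths)
    pd.testing.assert_frame_equal(a.ratings, b.ratings)


def test_ground_truth_closure(small_study):
    keys = set(
        zip(small_study.trials["context"], small_study.trials["nwl_shown"])
    )
    assert keys == set(small_study.config.ddm_truth)


def _images():
    return make_image_table(rng_for(0, "images"))


def test_ratings_degenerate_noise_equals_means():
    model = RatingModel(
        health_means=(80, 60, 40, 25), rating_sd=1e-9, recognition_prob=1.0
    )
    r = simulate_ratings(model, _images(), np.random.default_rng(0))
    for c in (0, 1, 2, 3):
        sub = r.loc[r.nwl_count == c, "health"]
        np.testing.assert_allclose(sub, model.health_means[c], atol=1e-6)
    assert r.recognized.all()


def test_ratings_clamped_and_validated():
    with pytest.raises(ConfigError):
        simulate_ratings(
            RatingModel(health_means=(120, 60, 40, 25)),
            _images(),
            np.random.default_rng(0),
        )
    r = simulate_ratings(RatingModel(rating_sd=40.0), _images(), np.random.default_rng(1))
    assert r[["health", "like", "want"]].to_numpy().min() >= 0
    assert r[["health", "like", "want"]].to_numpy().max() <= 100


def test_ratings_health_declines_with_nwl():
    """Welch test on 10^4 draws: mean health at 0 NWL > at 3 NWL."""
    model = RatingModel()
    rng = np.random.default_rng(2)
    frames = [simulate_ratings(model, _images(), rng) for _ in range(110)]
    r = pd.concat(frames)
    assert len(r) >= 10_000
    a = r.loc[r.nwl_count == 0, "health"]
    b = r.loc[r.nwl_count == 3, "health"]
    t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    assert p < 0.01


def test_simulate_trial_contract():
    params = DDMParams(1.5, 0.3, 0.5, 0.8)
    rng = np.random.default_rng(0)
    rts = []
    for _ in range(50):
        choice, rt, censored = simulate_trial(params, 4.0, rng)
        assert choice in ("healthy", "unhealthy")
        if not censored:
            assert rt > 0.3
            rts.append(rt)
    assert min(rts) >= 0.3


def test_simulate_trial_matches_hit_probability():
    # biased start, zero drift: healthy fraction tracks the closed form
    params = DDMParams(1.6, 0.2, 0.9, 0.0)
    rng = np.random.default_rng(4)
    from nwlchoice.ddm import simulate_choices

    rt, up, cen = simulate_choices(params, 20_000, rng, dt=5e-4)
    p = hit_probability(params)
    sd = np.sqrt(p * (1 - p) / up.size)
    assert abs(up.mean() - p) < 3 * sd
    assert p == pytest.approx(0.9)


def test_trajectory_sample_count_and_straightness():
    rng = np.random.default_rng(0)
    t, x, y = simulate_trajectory("left", 2.0, 0.0, 60.0, rng)
    assert abs(len(t) - 120) <= 1
    assert t[0] == 0 and t[-1] == pytest.approx(2.0)
    assert (np.diff(t) > 0).all()
    # conflict 0: essentially straight, AUC near zero
    aucs = [
        abs(compute_auc(*simulate_trajectory("left", 1.5, 0.0, 60.0, rng)[1:]))
        for _ in range(50)
    ]
    assert np.mean(aucs) < 0.02


def test_trajectory_auc_increases_with_conflict():
    rng = np.random.default_rng(1)

    def mean_auc(conflict, reps=200):
        vals = []
        for _ in range(reps):
            _, x, y = simulate_trajectory("left", 1.5, conflict, 60.0, rng)
            vals.append(compute_auc(x, y))
        return np.mean(vals)

    low, mid, high = mean_auc(0.1), mean_auc(0.4), mean_auc(0.8)
    assert low < mid < high


def test_trajectory_ends_in_chosen_corner():
    rng = np.random.default_rng(2)
    _, x, y = simulate_trajectory("right", 1.0, 0.3, 60.0, rng)
    assert x[-1] == pytest.approx(1.0)
    assert y[-1] == pytest.approx(1.5)
    with pytest.raises(ValueError):
        simulate_trajectory("left", 1.0, 0.3, -5.0, rng)


def test_contaminants_zero_rates_leave_study_unchanged():
    study = simulate_study(StudyConfig(n_participants=1, rng_seed=3))
    before_trials = study.trials.copy()
    before_paths = study.paths.copy()
    out = inject_contaminants(study, ContaminationRates(0, 0, 0, 0), np.random.default_rng(0))
    pd.testing.assert_frame_equal(
        out.trials.drop(columns=[c for c in out.trials if c.startswith("contam_")]),
        before_trials.drop(columns=[c for c in before_trials if c.startswith("contam_")]),
    )
    pd.testing.assert_frame_equal(out.paths, before_paths)


def test_contamination_fractions_within_three_binomial_sd(small_study):
    rates = small_study.config.contamination
    trials = small_study.trials
    n = len(trials)
    for col, rate in (
        ("contam_low_resolution", rates.low_resolution_rate),
        ("contam_multicross", rates.multicross_rate),
        ("contam_rt_outlier", rates.rt_outlier_rate),
    ):
        k = trials[col].sum()
        sd = np.sqrt(n * rate * (1 - rate))
        assert abs(k - n * rate) <= 3 * sd + 1


def test_low_resolution_contaminants_resampled_below_10hz(small_study):
    from nwlchoice.trajectory import estimate_sampling_rate

    tagged = small_study.trials.loc[small_study.trials.contam_low_resolution, "trial_id"]
    paths = small_study.paths
    for trial_id in tagged.head(20):
        t = paths.loc[paths.trial_id == trial_id, "t_s"].to_numpy()
        assert estimate_sampling_rate(t) < 10.0


def test_unrecognized_rate_one_hits_every_trial():
    study = simulate_study(StudyConfig(n_participants=1, rng_seed=5))
    out = inject_contaminants(
        study, ContaminationRates(0, 0, 0, 0.5), np.random.default_rng(1)
    )
    hit = out.trials.contam_unrecognized
    assert (~out.trials.loc[hit, "recognized_left"]).all()
    # rate 0.5 is the config ceiling; every tagged trial has >=1 unrecognized image
    assert hit.sum() > 0
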