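"""Decision paths, choice probabilities, reversal, and delta estimates."""

import numpy as np
import pandas as pd
import pytest

from nwlchoice.analysis import (
    build_paired_trials,
    classify_decision_path,
    compute_deltas,
    delta_nwl_effect,
    delta_summary,
    healthy_choice_prob,
    label_healthy_choice,
    path_census,
    reversal_probability,
)


def test_label_healthy_choice():
    assert label_healthy_choice(0, 3) is True
    assert label_healthy_choice(2, 1) is False
    with pytest.raises(ValueError, match="design violation"):
        label_healthy_choice(2, 2)
    out = label_healthy_choice([0, 2], [3, 1])
    np.testing.assert_array_equal(out, [True, False])


def test_classify_decision_path_covers_all_four():
    first = [True, True, False, False]
    second = [True, False, True, False]
    np.testing.assert_array_equal(
        classify_decision_path(first, second), ["HH", "HU", "UH", "UU"]
    )
    assert classify_decision_path(False, True) == "UH"


def _paired_fixture():
    # one participant, four pairs covering every decision path
    return pd.DataFrame(
        {
            "participant_id": "p0",
            "context": "typical",
            "pair_id": [f"t{i}" for i in range(4)],
            "choice_no_nwl": [True, True, False, False],
            "choice_nwl": [True, False, True, False],
            "decision_path": ["HH", "HU", "UH", "UU"],
            "auc_no_nwl": [0.4, 0.2, 0.5, 0.3],
            "auc_nwl": [0.3, 0.3, 0.4, 0.5],
            "rt_no_nwl": [1.0, 1.2, 1.1, 0.9],
            "rt_nwl": [1.4, 1.0, 1.0, 1.2],
        }
    )


def test_path_census_fixture():
    census = path_census(_paired_fixture())
    row = census.iloc[0]
    assert (row[["HH", "HU", "UH", "UU"]] == 1).all()


def test_healthy_choice_prob_fixtures():
    trials = pd.DataFrame(
        {
            "participant_id": ["p0"] * 10,
            "context": "typical",
            "healthy_choice": [True] * 6 + [False] * 4,
        }
    )
    out = healthy_choice_prob(trials, n_boot=100, seed=0)
    assert out.estimate.iloc[0] == pytest.approx(0.6)
    all_h = trials.assign(healthy_choice=True)
    out2 = healthy_choice_prob(all_h, n_boot=100, seed=0)
    assert out2.estimate.iloc[0] == 1.0
    assert out2.ci_lo.iloc[0] == 1.0 and out2.ci_hi.iloc[0] == 1.0


def test_reversal_probability_fixture():
    rows = []
    for i in range(10):
        rows.append(
            {
                "participant_id": "p0",
                "context": "typical",
                "pair_id": f"t{i}",
                "choice_no_nwl": False,
                "choice_nwl": i < 8,
            }
        )
    paired = pd.DataFrame(rows)
    out = reversal_probability(paired, n_boot=100, seed=0)
    assert out.estimate.iloc[0] == pytest.approx(0.8)
    assert out.n_u_first.iloc[0] == 10
    # no unhealthy-first trials -> missing with zero denominator
    none = paired.assign(choice_no_nwl=True)
    out2 = reversal_probability(none, n_boot=100, seed=0)
    assert np.isnan(out2.estimate.iloc[0])
    assert out2.n_u_first.iloc[0] == 0


def test_compute_deltas_sign_convention():
    d = compute_deltas(_paired_fixture())
    # labels reduced the HH pair's AUC from 0.4 to 0.3 -> negative delta
    assert d.loc[d.decision_path == "HH", "delta_auc"].iloc[0] == pytest.approx(-0.1)
    assert d.loc[d.decision_path == "HU", "delta_auc"].iloc[0] == pytest.approx(0.1)
    assert d.loc[d.decision_path == "UU", "delta_rt"].iloc[0] == pytest.approx(0.3)


def test_delta_summary_zero_deltas_not_flagged():
    paired = _paired_fixture()
    paired = pd.concat([paired] * 3, ignore_index=True)
    paired["participant_id"] = np.repeat(["p0", "p1", "p2"], 4)
    paired["auc_nwl"] = paired["auc_no_nwl"]
    paired["rt_nwl"] = paired["rt_no_nwl"]
    d = compute_deltas(paired)
    out = delta_summary(d, n_boot=100, seed=0)
    assert np.allclose(out.adjusted_mean, 0.0, atol=1e-12)
    assert not out.excludes_zero.any()


def test_delta_summary_perfect_baseline_adjustment():
    # delta entirely explained by a zero-centered baseline: adjusted mean ~ 0
    rng = np.random.default_rng(0)
    base = rng.normal(0, 0.2, 60)
    base -= base.mean()
    paired = pd.DataFrame(
        {
            "participant_id": np.repeat([f"p{i}" for i in range(6)], 10),
            "context": "typical",
            "decision_path": "HH",
            "auc_no_nwl": base,
            "auc_nwl": 0.0,
            "rt_no_nwl": 1.0,
            "rt_nwl": 1.0,
        }
    )
    paired["auc_nwl"] = paired["auc_no_nwl"] - paired["auc_no_nwl"]  # delta = -baseline
    d = compute_deltas(paired)
    out = delta_summary(d, n_boot=50, seed=0)
    auc_row = out[out.metric == "auc"].iloc[0]
    assert auc_row.adjusted_mean == pytest.approx(0.0, abs=1e-9)


def test_delta_summary_degenerate_baseline_falls_back():
    paired = _paired_fixture()
    paired["auc_no_nwl"] = 0.4  # constant baseline
    d = compute_deltas(paired)
    out = delta_summary(d, by=("context",), n_boot=50, seed=0)
    auc_row = out[out.metric == "auc"].iloc[0]
    assert auc_row.baseline_degenerate
    assert auc_row.adjusted_mean == pytest.approx(d.delta_auc.mean())


def test_delta_nwl_profiles():
    rows = []
    for lvl, p in ((1, 0.5), (2, 0.6), (3, 0.7)):
        for i in range(10):
            rows.append(
                {
                    "participant_id": "p0",
                    "context": "typical",
                    "nwl_shown": True,
                    "delta_nwl": lvl,
                    "healthy_choice": i < round(10 * p),
                }
            )
    out = delta_nwl_effect(pd.DataFrame(rows), n_boot=100, seed=0)
    est = out.sort_values("delta_nwl").estimate.to_numpy()
    np.testing.assert_allclose(est, [0.5, 0.6, 0.7])


def test_paired_identities_on_synthetic_study(small_metrics):
    from nwlchoice.qc import apply_trial_filters

    retained, _ = apply_trial_filters(small_metrics)
    paired, n_dropped = build_paired_trials(retained)
    census = path_census(paired, by=("context",))
    totals = census[["HH", "HU", "UH", "UU"]].sum(axis=1)
    per_ctx = paired.groupby("context").size()
    # census conservation
    for _, row in census.iterrows():
        assert row[["HH", "HU", "UH", "UU"]].sum() == per_ctx[row["context"]]
    # reversal identity: P = |UH| / (|UH| + |UU|) exactly
    rev = reversal_probability(paired, n_boot=10, seed=0).set_index("context")
    for _, row in census.iterrows():
        ctx = row["context"]
        expected = row["UH"] / (row["UH"] + row["UU"])
        assert rev.loc[ctx, "estimate"] == pytest.approx(expected, abs=1e-12)
    # consistency: P(healthy | labels) over paired trials = P(HH or UH)
    for ctx, grp in paired.groupby("context"):
        lhs = grp["choice_nwl"].mean()
        rhs = grp["decision_path"].isin(["HH", "UH"]).mean()
        assert lhs == pytest.approx(rhs, abs=1e-12)
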