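import itertools
import warnings

import numpy as np
import pandas as pd
import pytest

from suddengains.matching import (MatchingConfig, balance_diagnostics,
                                  estimate_propensity, match_gainers)


def make_byperson(ages, gainer, pregain=5, **extra_cols):
    n = len(ages)
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "age": ages,
        "gainer": gainer,
        "pregain_session": [pregain if g else np.nan for g in gainer],
    })
    for k, v in extra_cols.items():
        df[k] = v
    return df


def test_identical_covariates_give_intercept_only_propensity():
    df = make_byperson([40.0] * 10, [True] * 3 + [False] * 7)
    scores, dropped = estimate_propensity(df, ["age"])
    assert dropped == []
    assert np.allclose(scores["ps"], 0.3)


def test_binary_covariate_recovers_closed_form_odds_ratio():
    # 2x2 table: level 1 has 20 gainers / 80 controls, level 0 has 10 / 90
    x = [1] * 100 + [0] * 100
    y = [True] * 20 + [False] * 80 + [True] * 10 + [False] * 90
    df = make_byperson([40.0] * 200, y, x=x)
    scores, _ = estimate_propensity(df, ["x"])
    lp1 = scores.loc[df.index[df["x"] == 1], "lp"].iloc[0]
    lp0 = scores.loc[df.index[df["x"] == 0], "lp"].iloc[0]
    assert np.exp(lp1 - lp0) == pytest.approx((20 * 90) / (80 * 10),
                                              rel=1e-4)


def test_propensities_in_unit_interval_with_mean_gain_fraction():
    rng = np.random.default_rng(5)
    df = make_byperson(rng.normal(40, 10, 120),
                       list(rng.random(120) < 0.3),
                       x=rng.normal(size=120))
    scores, _ = estimate_propensity(df, ["age", "x"])
    assert ((scores["ps"] > 0) & (scores["ps"] < 1)).all()
    assert scores["ps"].mean() == pytest.approx(df["gainer"].mean(),
                                                abs=1e-6)


def test_rows_with_missing_covariates_are_excluded():
    ages = [40.0, np.nan, 35.0, 30.0, 45.0, 50.0]
    df = make_byperson(ages, [True, False, True, False, False, False])
    scores, dropped = estimate_propensity(df, ["age"])
    assert len(dropped) == 1 and len(scores) == 5


def brute_force_best_pairing(dist, gainer_ids, control_ids):
    """Exhaustive minimum-total-distance 1:1 assignment."""
    best, best_cost = None, np.inf
    for perm in itertools.permutations(control_ids, len(gainer_ids)):
        cost = sum(dist[g][c] for g, c in zip(gainer_ids, perm))
        if cost < best_cost:
            best, best_cost = dict(zip(gainer_ids, perm)), cost
    return best


def _twin_cohort(n_gainers, n_decoys=1, seed=0):
    """Each gainer has an exact covariate twin among the controls."""
    rng = np.random.default_rng(seed)
    ages = list(rng.normal(40, 8, n_gainers))
    xs = list(rng.normal(0, 1, n_gainers))
    extra_age = list(rng.normal(60, 2, n_decoys))  # distant decoys
    extra_x = list(rng.normal(4, 0.5, n_decoys))
    df = make_byperson(
        ages + ages + extra_age,
        [True] * n_gainers + [False] * (n_gainers + n_decoys),
        x=xs + xs + extra_x)
    return df


def _hand_distances(df, covariate_names):
    """Mahalanobis distances recomputed from scratch with numpy."""
    X = df[list(covariate_names)].to_numpy(float)
    vi = np.linalg.inv(np.cov(X, rowvar=False, ddof=1))
    ids = df["patient_id"].tolist()
    gainers = [i for i, g in zip(ids, df["gainer"]) if g]
    controls = [i for i, g in zip(ids, df["gainer"]) if not g]
    idx = {pid: k for k, pid in enumerate(ids)}
    return {g: {c: float(np.sqrt((X[idx[g]] - X[idx[c]]) @ vi
                                 @ (X[idx[g]] - X[idx[c]])))
                for c in controls} for g in gainers}, gainers, controls


@pytest.mark.parametrize("n_gainers", [3, 6, 8])
def test_matching_recovers_exact_twins(n_gainers):
    df = _twin_cohort(n_gainers, seed=n_gainers)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs, unmatched = match_gainers(
            df, MatchingConfig(covariate_names=("age", "x"), seed=1))
    assert unmatched == []
    assert len(pairs) == n_gainers
    for p in pairs:
        g = int(p.gainer_id[1:])
        assert int(p.control_id[1:]) == g + n_gainers  # the twin
        assert p.mahalanobis_distance == pytest.approx(0.0, abs=1e-9)
        assert p.matched_session == 5
    # exhaustive minimum-distance assignment agrees with the greedy result
    dist, gainers, controls = _hand_distances(df, ("age", "x"))
    best = brute_force_best_pairing(dist, gainers, controls)
    assert {p.gainer_id: p.control_id for p in pairs} == best


def test_single_covariate_distance_is_standardized_difference():
    ages = [40.0, 42.0, 55.0, 30.0, 35.0, 50.0]
    df = make_byperson(ages, [True, False, False, False, False, False])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs, _ = match_gainers(df, MatchingConfig(
            covariate_names=("age",), caliper_width=1e6, seed=0))
    sd = np.std(ages, ddof=1)
    assert len(pairs) == 1
    assert pairs[0].control_id == "p1"  # nearest age
    assert pairs[0].mahalanobis_distance == pytest.approx(2.0 / sd)


def test_no_control_reused_and_caliper_respected():
    rng = np.random.default_rng(9)
    n = 120
    df = make_byperson(rng.normal(40, 10, n), list(rng.random(n) < 0.4),
                       x=rng.normal(size=n))
    config = MatchingConfig(covariate_names=("age", "x"), seed=2)
    pairs, unmatched = match_gainers(df, config)
    controls = [p.control_id for p in pairs]
    assert len(controls) == len(set(controls))
    lps = {**{p.gainer_id: p.lp_gainer for p in pairs},
           **{p.control_id: p.lp_control for p in pairs}}
    scores, _ = estimate_propensity(df.set_index("patient_id", drop=False),
                                    ("age", "x"))
    caliper = 0.25 * scores["lp"].std(ddof=1)
    for p in pairs:
        assert abs(p.lp_gainer - p.lp_control) <= caliper + 1e-12
    n_gainers = df["gainer"].sum()
    assert len(pairs) + len(unmatched) == n_gainers
    # removing the caliper can only increase the number of pairs
    wide, _ = match_gainers(df, MatchingConfig(
        covariate_names=("age", "x"), caliper_width=1e6, seed=2))
    assert len(wide) >= len(pairs)


def test_balance_zero_for_exact_copies():
    df = _twin_cohort(5, seed=7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pairs, _ = match_gainers(
            df, MatchingConfig(covariate_names=("age", "x"), seed=1))
    bal = balance_diagnostics(pairs, df, ("age", "x"))
    assert np.allclose(bal["mean_difference"], 0.0)
    assert not bal["flagged"].any()


def test_balance_hand_example():
    from suddengains.matching import MatchedPair

    df = make_byperson([30.0, 40.0, 31.0, 41.0],
                       [True, True, False, False])
    pairs = [MatchedPair("p0", "p2", 5, 0.1, 0.5, 0.5, 0.0, 0.0),
             MatchedPair("p1", "p3", 5, 0.1, 0.5, 0.5, 0.0, 0.0)]
    bal = balance_diagnostics(pairs, df, ("age",))
    assert abs(bal.loc[0, "mean_difference"]) == pytest.approx(1.0)


def test_matching_requires_controls():
    df = make_byperson([40.0, 41.0], [True, True])
    with pytest.raises(ValueError):
        match_gainers(df, MatchingConfig(covariate_names=("age",)))
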