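"""Reaction times, d-prime, focal classification, running split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import norm

from attnrun import behavior as beh
from attnrun.synthetic import AttentionProfile, generate_trials, simulate_behavior


def _trial_row(onset, licks, ttype="go", outcome=None, block_type="BR", block_index=1):
    if outcome is None:
        in_win = [t for t in licks if onset <= t <= onset + 1.6]
        outcome = "Hit" if in_win else "Miss"
    return {
        "trial": 0,
        "type": ttype,
        "block_index": block_index,
        "block_type": block_type,
        "grating_onset_s": onset,
        "lick_times": licks,
        "outcome": outcome,
    }


def test_reaction_time_subtraction():
    t = pd.DataFrame([_trial_row(10.0, [10.45])])
    out = beh.compute_reaction_times(t)
    assert np.isclose(out["reaction_time"].iloc[0], 0.45)
    assert not out["rt_excluded"].iloc[0]


def test_pre_onset_lick_excluded():
    t = pd.DataFrame([_trial_row(10.0, [9.9, 10.5])])
    out = beh.compute_reaction_times(t)
    assert out["rt_excluded"].iloc[0]


def test_fast_rt_excluded():
    t = pd.DataFrame([_trial_row(10.0, [10.1])])
    out = beh.compute_reaction_times(t)
    assert out["rt_excluded"].iloc[0]


def test_miss_contributes_fixed_rt_to_mean():
    t = pd.DataFrame([_trial_row(10.0, []), _trial_row(20.0, [20.4])])
    out = beh.compute_reaction_times(t)
    assert np.isnan(out["reaction_time"].iloc[0])
    assert np.isclose(out["rt_for_mean"].iloc[0], 1.6)
    assert np.isclose(out["rt_for_mean"].mean(), (1.6 + 0.4) / 2)


def test_dprime_matches_closed_form():
    d = beh.compute_dprime(80, 20, 20, 80)
    assert abs(d - (norm.ppf(0.8) - norm.ppf(0.2))) < 1e-6
    assert abs(d - 1.6832) < 1e-3


def test_dprime_symmetry_zero():
    assert abs(beh.compute_dprime(30, 70, 30, 70)) < 1e-12


def test_dprime_perfect_hit_correction():
    # 20 hits, 0 misses -> effective hit rate (20 - 0.5)/20 = 0.975
    d = beh.compute_dprime(20, 0, 10, 40)
    assert abs(d - (norm.ppf(0.975) - norm.ppf(0.2))) < 1e-9


def test_dprime_fa_guards_finite():
    assert np.isfinite(beh.compute_dprime(10, 10, 0, 50))
    assert np.isfinite(beh.compute_dprime(10, 10, 50, 0))
    with pytest.raises(ValueError):
        beh.compute_dprime(0, 0, 5, 5)


@given(
    h1=st.integers(1, 99),
    h2=st.integers(1, 99),
    f=st.integers(1, 99),
)
@settings(max_examples=50, deadline=None)
def test_dprime_monotone_in_hit_rate(h1, h2, f):
    if h1 == h2:
        return
    lo, hi = sorted((h1, h2))
    d_lo = beh.compute_dprime(lo, 100 - lo, f, 100 - f)
    d_hi = beh.compute_dprime(hi, 100 - hi, f, 100 - f)
    assert d_hi > d_lo


def _session_with_catches(catch_rts, go_rt_other=0.5, n_go=80, miss_catch=0):
    """Two-block toy session: BR block holds the catch trials, TL the reference."""
    rows = []
    t = 10.0
    rng = np.random.default_rng(0)
    for _ in range(n_go):
        rows.append(_trial_row(t, [t + go_rt_other + rng.normal(0, 0.05)],
                               block_type="TL", block_index=2))
        t += 5.0
    for rt in catch_rts:
        rows.append(_trial_row(t, [t + rt], ttype="catch", outcome="Hit",
                               block_type="BR", block_index=1))
        t += 5.0
    for _ in range(miss_catch):
        rows.append(_trial_row(t, [], ttype="catch", outcome="Miss",
                               block_type="BR", block_index=1))
        t += 5.0
    # a couple of BR go trials so the TL block has a reference too
    for _ in range(10):
        rows.append(_trial_row(t, [t + 0.5], block_type="BR", block_index=1))
        t += 5.0
    return pd.DataFrame(rows)


def test_all_catch_missed_is_focal():
    trials = _session_with_catches([], miss_catch=8)
    label = beh.classify_focal_blocks(trials)
    row = label.blocks[label.blocks["block_index"] == 1].iloc[0]
    assert row["focal"] is True or row["focal"] == True  # noqa: E712


def test_catch_rts_matching_go_rts_not_focal():
    trials = _session_with_catches([0.5] * 10)
    label = beh.classify_focal_blocks(trials)
    row = label.blocks[label.blocks["block_index"] == 1].iloc[0]
    assert not row["focal"]


def test_slow_catch_rts_focal():
    trials = _session_with_catches([1.1 + 0.05 * k for k in range(10)])
    label = beh.classify_focal_blocks(trials)
    row = label.blocks[label.blocks["block_index"] == 1].iloc[0]
    assert row["focal"]


def test_no_catch_trials_session_unusable():
    trials = generate_trials(60, catch_fraction=0.0, seed=1)
    trials, _ = simulate_behavior(trials, seed=2)
    label = beh.classify_focal_blocks(trials)
    assert not label.usable


def test_classification_invariant_to_inlier_go_trials():
    base = _session_with_catches([1.1] * 10)
    label0 = beh.classify_focal_blocks(base)
    extra = pd.DataFrame([_trial_row(1e4 + 5 * k, [1e4 + 5 * k + 0.5],
                                     block_type="TL", block_index=2) for k in range(20)])
    label1 = beh.classify_focal_blocks(pd.concat([base, extra], ignore_index=True))
    assert list(label0.blocks["focal"]) == list(label1.blocks["focal"])


def test_generated_focal_br_session_classified():
    trials = generate_trials(450, catch_fraction=0.05, seed=3)
    trials, _ = simulate_behavior(trials, AttentionProfile(), seed=4)
    label = beh.classify_focal_blocks(trials)
    assert label.usable and label.focal_type == "BR"


def test_split_by_running_all_stationary():
    trials = generate_trials(30, seed=5)
    trials, behavior = simulate_behavior(trials, seed=6)
    trials = beh.compute_reaction_times(trials)
    behavior["speed_cms"] = 0.0
    out = beh.split_performance_by_running(trials, behavior)
    assert out["running"].n_go == 0
    assert out["stationary"].n_go > 0
    assert np.isnan(out["running"].hit_rate)


def test_speed_exactly_one_counts_as_running():
    trials = generate_trials(30, seed=7)
    trials, behavior = simulate_behavior(trials, seed=8)
    trials = beh.compute_reaction_times(trials)
    behavior["speed_cms"] = 1.0
    out = beh.split_performance_by_running(trials, behavior)
    assert out["stationary"].n_go == 0
    assert out["running"].n_go > 0


def test_state_rates_sum_to_one():
    trials = generate_trials(400, seed=9)
    trials, behavior = simulate_behavior(trials, seed=10)
    trials = beh.compute_reaction_times(trials)
    from attnrun.traces import filter_running_speed

    behavior["speed_cms"] = filter_running_speed(behavior["raw_speed_cms"].to_numpy(), 12.85)
    out = beh.split_performance_by_running(trials, behavior)
    for s in out.values():
        if s.n_go:
            assert np.isclose(s.hit_rate + s.miss_rate, 1.0)
        if s.n_nogo:
            assert np.isclose(s.fa_rate + s.cr_rate, 1.0)
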