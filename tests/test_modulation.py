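"""Modulation indices, bootstrap significance, reliability splits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from attnrun import modulation as mod


def _samples(values, block_index, block_type=None, running=False, t0=0.0):
    n = len(values)
    bt = block_type or ["BR" if b in (1, 3) else "TL" for b in block_index]
    return pd.DataFrame(
        {
            "onset_s": t0 + np.arange(n, dtype=float),
            "row": 0,
            "col": 0,
            "value": values,
            "block_index": block_index,
            "block_type": bt,
            "running": running if np.iterable(running) else [running] * n,
        }
    )


def test_index_algebra():
    assert np.isclose(mod.modulation_index(2.0, 1.0), 1 / 3)
    assert mod.modulation_index(1.0, 1.0) == 0.0
    assert np.isclose(mod.modulation_index(3.0, 1.0), 0.5)
    assert np.isclose(mod.modulation_index(0.0, 2.0), -1.0)
    assert np.isnan(mod.modulation_index(-2.0, 1.0))  # non-positive denominator
    assert np.isnan(mod.modulation_index(2.0, 1.0, n_a=2))  # too few reps


@given(
    a=st.floats(0.01, 100),
    b=st.floats(0.01, 100),
    c=st.floats(0.01, 50),
)
@settings(max_examples=100, deadline=None)
def test_index_antisymmetry_and_scale_invariance(a, b, c):
    ab = mod.modulation_index(a, b)
    ba = mod.modulation_index(b, a)
    assert np.isclose(ab, -ba, atol=1e-12)
    assert np.isclose(mod.modulation_index(c * a, c * b), ab, atol=1e-9)


def test_injected_gain_index_identity():
    """Multiplicative gain g in one condition yields index (g-1)/(g+1)."""
    for g in (1.5, 2.0, 3.0):
        base = np.full(20, 2.0)
        s = pd.concat(
            [
                _samples(base * g, np.ones(20, int)),
                _samples(base, np.full(20, 2)),
            ],
            ignore_index=True,
        )
        assert np.isclose(mod.attention_index_a(s), (g - 1) / (g + 1))
        assert np.isclose(mod.attention_index_a(s, reverse=True), -(g - 1) / (g + 1))


def test_attention_index_b_values():
    assert np.isclose(mod.attention_index_b([3.0] * 6, [1.0] * 6), 0.5)
    assert np.isclose(mod.attention_index_b([0.0] * 6, [2.0] * 6), -1.0)


def test_running_index_from_labels():
    vals = np.r_[np.full(10, 4.0), np.full(10, 2.0)]
    s = _samples(vals, np.ones(20, int), running=np.r_[np.ones(10, bool), np.zeros(10, bool)])
    idx, _ = mod.running_index(s, with_p=False)
    assert np.isclose(idx, 1 / 3)


def test_bootstrap_p_identical_sets():
    a = np.arange(10, dtype=float)
    assert mod.bootstrap_modulation_p(a, a.copy(), n_boot=2000, seed=1) >= 0.9


def test_bootstrap_p_separated_sets():
    rng = np.random.default_rng(2)
    a = rng.normal(0, 1, 20)
    b = a + 10
    assert mod.bootstrap_modulation_p(b, a, n_boot=5000, seed=3) < 1e-3


def test_bootstrap_p_needs_three_samples():
    with pytest.raises(ValueError):
        mod.bootstrap_modulation_p([1.0, 2.0], [1.0, 2.0, 3.0])


def test_bootstrap_p_matches_exhaustive_enumeration():
    """For tiny discrete samples the violation probability can be enumerated
    exactly over all joint resamples; Monte-Carlo must converge to it."""
    a = np.array([1.0, 2.0, 4.0])
    b = np.array([0.5, 1.0, 1.5])
    obs = a.mean() - b.mean()
    viol = 0
    total = 0
    for ra in itertools.product(range(3), repeat=3):
        for rb in itertools.product(range(3), repeat=3):
            d = a[list(ra)].mean() - b[list(rb)].mean()
            viol += (d <= 0) if obs > 0 else (d >= 0)
            total += 1
    exact = min(1.0, 2 * viol / total)
    mc = mod.bootstrap_modulation_p(a, b, n_boot=40_000, seed=4)
    assert abs(mc - exact) < 0.02


def test_running_onset_activity_flat_trace():
    speed = np.r_[np.zeros(50), np.full(30, 5.0), np.zeros(50), np.full(30, 5.0),
                  np.zeros(50), np.full(30, 5.0)]
    act, p = mod.running_onset_activity(np.zeros(speed.size), speed, 12.85)
    assert act == 0.0 and p == 1.0


def test_running_onset_activity_recovers_transient():
    rng = np.random.default_rng(5)
    frame_rate = 12.85
    n = 4000
    speed = np.zeros(n)
    dff = rng.normal(0, 0.05, n)
    onsets = np.arange(200, n - 200, 300)
    for f in onsets:
        speed[f : f + 100] = 5.0
        dff[f : f + 10] += 0.5
    act, p = mod.running_onset_activity(dff, speed, frame_rate)
    assert abs(act - 0.5) / 0.5 < 0.2
    assert p < 0.01


def test_running_onset_activity_requires_onsets():
    act, p = mod.running_onset_activity(np.zeros(500), np.zeros(500), 12.85)
    assert np.isnan(act) and np.isnan(p)


def test_split_half_equal_counts_per_stimulus():
    vals = np.arange(14, dtype=float)
    s = _samples(vals, np.ones(14, int))
    s.loc[7:, "row"] = 1  # two stimuli, 7 reps each (odd)
    halves = mod.split_half_by_stimulus(s)
    for _, sub in s.groupby(["row", "col"]):
        h = halves[sub.index]
        assert (h == 1).sum() == 4 and (h == 2).sum() == 3


def test_within_block_reliability_equal_halves_for_constant_gain():
    s = pd.concat(
        [
            _samples(np.full(12, 3.0), np.ones(12, int)),
            _samples(np.full(12, 1.0), np.full(12, 2)),
            _samples(np.full(12, 3.0), np.full(12, 3)),
        ],
        ignore_index=True,
    )
    w = mod.within_block_reliability(s)
    assert np.isclose(w[1][0], w[1][1])
    assert np.isclose(w[1][0], 0.5)
    assert np.isclose(w[3][0], w[3][1])


def test_between_block_reliability_identical_gains():
    s = pd.concat(
        [
            _samples(np.full(12, 3.0), np.ones(12, int)),
            _samples(np.full(12, 1.0), np.full(12, 2)),
            _samples(np.full(12, 3.0), np.full(12, 3)),
        ],
        ignore_index=True,
    )
    b1, b3 = mod.between_block_reliability(s)
    assert np.isclose(b1, b3)
    assert np.isclose(b1, 0.5)


def test_reliability_null_when_gains_resampled_per_half():
    """Independently drawn per-half gains destroy the half-to-half correlation."""
    rng = np.random.default_rng(6)
    h1, h2 = [], []
    for _ in range(200):
        g1, g2 = rng.uniform(1.0, 3.0, 2)
        vals1 = np.r_[np.full(6, 2.0 * g1), np.full(6, 2.0 * g2)]
        s = pd.concat(
            [
                _samples(vals1, np.ones(12, int)),
                _samples(np.full(12, 2.0), np.full(12, 2)),
                _samples(np.full(12, 2.0), np.full(12, 3)),
            ],
            ignore_index=True,
        )
        w = mod.within_block_reliability(s)
        h1.append(w[1][0])
        h2.append(w[1][1])
    r = np.corrcoef(h1, h2)[0, 1]
    assert abs(r) < 2 / np.sqrt(len(h1) - 3)


def test_extract_samples_constant_trace_is_zero(small_session):
    from attnrun import rf as rfmod

    session = small_session
    events = session.stimuli.events
    mask = np.zeros((14, 22), bool)
    mask[7, 7] = True
    row, col = 7, 7
    events = events.copy()
    dff = np.zeros(session.fluo.dFF.shape[1])
    s = mod.extract_response_samples(
        dff,
        events,
        session.fluo.frame_times,
        mask,
        "white",
        session.behavior,
        session.blocks,
        peak_offset=1,
    )
    if len(s):
        assert np.allclose(s["value"], 0.0)
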