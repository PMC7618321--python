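"""Hierarchical bootstrap, paired shuffle test, BH adjustment, permutation r."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from attnrun import hstats


def _nested(values, animals):
    return hstats.NestedSample(values=np.asarray(values), animals=np.asarray(animals))


def test_constant_values_give_degenerate_ci():
    n = _nested([3.0] * 12, np.repeat([0, 1, 2], 4))
    res = hstats.hier_bootstrap(n, n_boot=500, seed=0)
    assert res.ci_95 == (3.0, 3.0)
    assert res.estimate == 3.0


def test_single_animal_rejected():
    with pytest.raises(ValueError):
        hstats.hier_bootstrap(_nested([1.0, 2.0], [0, 0]), n_boot=10)


def test_two_animals_one_value_matches_enumeration():
    """With 2 animals x 1 value the replicate distribution is exactly
    {va: 1/4, (va+vb)/2: 1/2, vb: 1/4}."""
    va, vb = 1.0, 5.0
    res = hstats.hier_bootstrap(_nested([va, vb], [0, 1]), n_boot=20_000, seed=1)
    reps = res.replicates
    freqs = {v: np.mean(np.isclose(reps, v)) for v in (va, (va + vb) / 2, vb)}
    assert abs(freqs[va] - 0.25) < 0.02
    assert abs(freqs[(va + vb) / 2] - 0.5) < 0.02
    assert abs(freqs[vb] - 0.25) < 0.02


def test_ci_width_shrinks_with_more_units():
    rng = np.random.default_rng(2)
    widths = []
    for m in (5, 50, 500):
        vals = rng.normal(0, 1, 4 * m)
        res = hstats.hier_bootstrap(
            _nested(vals, np.repeat(np.arange(4), m)), n_boot=800, seed=3
        )
        widths.append(res.ci_95[1] - res.ci_95[0])
    assert widths[0] > widths[1] > widths[2]


def test_paired_test_identical_pairs():
    vals = np.column_stack([np.arange(8.0), np.arange(8.0)])
    p = hstats.hier_bootstrap_paired_test(_nested(vals, np.repeat([0, 1], 4)), n_boot=200)
    assert p == 1.0


def test_paired_test_large_separation():
    rng = np.random.default_rng(4)
    a = rng.normal(0, 1, 16)
    vals = np.column_stack([a + 10, a])
    p = hstats.hier_bootstrap_paired_test(
        _nested(vals, np.repeat(np.arange(4), 4)), n_boot=2000, seed=5
    )
    assert p < 0.01


def test_paired_test_requires_pairs():
    with pytest.raises(ValueError):
        hstats.hier_bootstrap_paired_test(_nested([1.0, 2.0], [0, 1]))


def _bh_oracle(p):
    """Direct step-up: adj_(i) = min_{j>=i} m p_(j) / j, capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    best = np.inf
    for rank in range(m - 1, -1, -1):
        best = min(best, m * p[order[rank]] / (rank + 1))
        adj[order[rank]] = min(1.0, best)
    return adj


def test_bh_single_p_unchanged():
    adj, rej = hstats.bh_adjust([0.03])
    assert np.isclose(adj[0], 0.03)
    assert rej[0]


def test_bh_hand_computed_example():
    adj, _ = hstats.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])


def test_bh_empty_input():
    adj, rej = hstats.bh_adjust([])
    assert adj.size == 0 and rej.size == 0


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
@settings(max_examples=150, deadline=None)
def test_bh_matches_stepup_oracle(p):
    adj, rej = hstats.bh_adjust(p)
    assert np.allclose(adj, _bh_oracle(p), atol=1e-12)
    # BH rejections are a superset of Bonferroni rejections
    bonf = np.asarray(p) < 0.05 / len(p)
    assert np.all(rej[bonf])


def test_bh_monotone_in_raw_p():
    rng = np.random.default_rng(6)
    p = rng.uniform(size=10)
    adj, _ = hstats.bh_adjust(p)
    order = np.argsort(p)
    assert np.all(np.diff(adj[order]) >= -1e-12)


def test_randomization_perfect_correlation():
    x = np.arange(10.0)
    r, p = hstats.randomization_corr_test(x, x, n_perm=5000, seed=7)
    assert np.isclose(r, 1.0)
    assert p < 1e-3


def test_randomization_exhaustive_small_n():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    r, p = hstats.randomization_corr_test(x, y)
    # n = 5 engages exhaustive enumeration over 120 permutations
    import itertools

    robs = np.corrcoef(x, y)[0, 1]
    count = sum(
        abs(np.corrcoef(x, np.array(perm))[0, 1]) >= abs(robs) - 1e-12
        for perm in itertools.permutations(y)
    )
    assert np.isclose(p, count / 120)


def test_randomization_rejects_degenerate_input():
    with pytest.raises(ValueError):
        hstats.randomization_corr_test(np.ones(6), np.arange(6.0))
    with pytest.raises(ValueError):
        hstats.randomization_corr_test(np.arange(4.0), np.arange(4.0))


def test_all_routines_deterministic_per_seed():
    rng = np.random.default_rng(8)
    vals = rng.normal(size=(12, 2))
    nested = _nested(vals, np.repeat(np.arange(3), 4))
    p1 = hstats.hier_bootstrap_paired_test(nested, n_boot=300, seed=9)
    p2 = hstats.hier_bootstrap_paired_test(nested, n_boot=300, seed=9)
    assert p1 == p2
    x, y = rng.normal(size=20), rng.normal(size=20)
    assert hstats.randomization_corr_test(x, y, 500, seed=10) == \
        hstats.randomization_corr_test(x, y, 500, seed=10)
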