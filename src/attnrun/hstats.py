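"""Hierarchical bootstrap inference and multiple-testing utilities.

Data from several animals are never pooled directly: confidence intervals
and tests resample animals with replacement first, then the units (sessions
or neurons) within each drawn animal, so that the per-animal dependence
structure is respected.  Also provides the paired shuffle test on that
hierarchy, a permutation test for Pearson correlations, and the
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.multitest import multipletests


@dataclass
class NestedSample:
    """Values with a two-level (animal -> unit) nesting structure.

    ``values`` may be 1-D (one value per unit) or 2-D with shape
    (n_units, 2) for paired data.  ``animals`` holds one animal label
    per unit.
    """

    values: np.ndarray
    animals: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.animals = np.asarray(self.animals)
        if len(self.animals) != len(self.values):
            raise ValueError("values and animals must have one entry per unit")

    @property
    def animal_ids(self):
        return np.unique(self.animals)

    def by_animal(self):
        """Indices of the units belonging to each animal."""
        return {a: np.flatnonzero(self.animals == a) for a in self.animal_ids}


@dataclass
class HierBootstrapResult:
    estimate: float
    ci_90: tuple
    ci_95: tuple
    replicates: np.ndarray = field(repr=False)


def _resample_indices(groups, rng, n_units=None):
    """One hierarchical resample: animals with replacement, units within each."""
    keys = list(groups)
    drawn = rng.integers(0, len(keys), size=len(keys))
    idx = []
    for k in drawn:
        members = groups[keys[k]]
        m = len(members) if n_units is None else n_units
        idx.append(members[rng.integers(0, len(members), size=m)])
    return np.concatenate(idx)


def hier_bootstrap(nested, statistic=np.mean, n_boot=10_000, seed=0, n_units=None):
    """Hierarchical bootstrap confidence intervals for a statistic.

    Each replicate resamples animals with replacement and then, within each
    drawn animal, resamples its units with replacement (the same number of
    units as observed unless ``n_units`` overrides it), then applies
    ``statistic`` to the pooled resampled values.

    Returns a :class:`HierBootstrapResult` with percentile 90% and 95% CIs.
    """
    if len(nested.animal_ids) < 2:
        raise ValueError("hierarchical bootstrap requires at least 2 animals")
    groups = nested.by_animal()
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for i in range(n_boot):
        idx = _resample_indices(groups, rng, n_units)
        reps[i] = statistic(nested.values[idx])
    return HierBootstrapResult(
        estimate=float(statistic(nested.values)),
        ci_90=(float(np.percentile(reps, 5)), float(np.percentile(reps, 95))),
        ci_95=(float(np.percentile(reps, 2.5)), float(np.percentile(reps, 97.5))),
        replicates=reps,
    )


def hier_bootstrap_paired_test(nested, statistic=np.mean, n_boot=10_000, seed=0):
    """Hierarchical paired shuffle test.

    ``nested.values`` must be (n_units, 2) paired observations.  The observed
    statistic is ``statistic`` of the within-pair differences.  Each replicate
    hierarchically resamples the pairs and randomly flips the order of each
    drawn pair before computing the statistic of differences; the p-value is
    the fraction of shuffled replicates at least as extreme (two-sided, by
    absolute value) as the observed statistic.
    """
    vals = nested.values
    if vals.ndim != 2 or vals.shape[1] != 2:
        raise ValueError("paired test requires (n_units, 2) values")
    diffs = vals[:, 0] - vals[:, 1]
    observed = float(statistic(diffs))
    if np.all(diffs == 0):
        return 1.0
    groups = nested.by_animal()
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_boot):
        idx = _resample_indices(groups, rng)
        d = diffs[idx] * rng.choice([-1.0, 1.0], size=len(idx))
        if abs(statistic(d)) >= abs(observed):
            hits += 1
    return hits / n_boot


def bh_adjust(p_values, fdr=0.05):
    """Benjamini-Hochberg step-up adjustment.

    Returns ``(adjusted_p, reject)`` with monotone adjusted p-values and
    rejection flags at the given false-discovery rate.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, adj, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return adj, reject


def randomization_corr_test(x, y, n_perm=10_000, seed=0):
    """Pearson correlation with a permutation p-value.

    The p-value is the fraction of permutations of ``y`` whose absolute
    correlation with ``x`` is at least the observed absolute correlation.
    When the number of distinct permutations is small (n! <= 1e5) all
    permutations are enumerated instead of sampled.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("x and y must have equal length >= 5")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    n = len(x)
    xc = (x - x.mean()) / (x.std() * np.sqrt(n))
    yc = (y - y.mean()) / (y.std() * np.sqrt(n))
    r_obs = float(xc @ yc)
    if math.factorial(n) <= 100_000:
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = (yc[perms] @ xc)
        p = float(np.mean(np.abs(r_perm) >= abs(r_obs) - 1e-12))
    else:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            r = float(xc @ yc[rng.permutation(n)])
            if abs(r) >= abs(r_obs) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    return r_obs, p
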