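"""Behavioural performance: reaction times, d-prime, attention classification.

Implements the go/no-go performance metrics (hit/miss/FA/CR rates, the
behavioural d' = Phi^-1(hit rate) - Phi^-1(FA rate) with finite-rate
guards), reaction-time extraction with exclusion rules, the catch-trial
based classification of focally attending blocks, and performance split by
running state at grating onset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from attnrun.synthetic.neurons import RUN_SPEED_THRESHOLD

MISS_RT_S = 1.6  # reaction time assigned to Miss trials for mean RT only
RT_MIN_S = 0.16  # lower reaction-time cut-off
PRE_ONSET_WINDOW_S = 0.2
RESPONSE_WINDOW_S = 1.6


def compute_reaction_times(trials):
    """Fill reaction_time and exclusion flags from per-trial lick times.

    RT is the first lick after grating onset minus the onset.  A trial is
    excluded from RT analyses if any lick falls within 200 ms before the
    onset, or if its RT is below 160 ms.  Miss trials get RT = NaN but
    contribute 1.6 s to mean-RT computations (column ``rt_for_mean``).
    """
    trials = trials.copy()
    rts, excluded = [], []
    for _, tr in trials.iterrows():
        onset = tr["grating_onset_s"]
        licks = np.asarray(tr["lick_times"] if isinstance(tr["lick_times"], (list, np.ndarray)) else [])
        pre = np.any((licks >= onset - PRE_ONSET_WINDOW_S) & (licks < onset)) if licks.size else False
        post = licks[(licks >= onset) & (licks <= onset + RESPONSE_WINDOW_S)] if licks.size else np.array([])
        if post.size:
            rt = float(post[0] - onset)
            rts.append(rt)
            excluded.append(bool(pre or rt < RT_MIN_S))
        else:
            rts.append(np.nan)
            excluded.append(bool(pre))
    trials["reaction_time"] = rts
    trials["rt_excluded"] = excluded
    trials["rt_for_mean"] = np.where(
        trials["outcome"] == "Miss", MISS_RT_S, trials["reaction_time"]
    )
    return trials


def _guarded_rate(k, n):
    """Proportion k/n with half-count corrections at the boundaries."""
    if n < 1:
        raise ValueError("needs at least one trial")
    if k == n:
        return (n - 0.5) / n
    if k == 0:
        return 0.5 / n
    return k / n


def compute_dprime(n_hit, n_miss, n_fa, n_cr):
    """Behavioural d' = Phi^-1(hit rate) - Phi^-1(FA rate).

    A 100% hit rate is replaced by (n_hit - 0.5)/n_hit; the symmetric
    half-count guard is applied at the other boundaries so d' stays finite.
    """
    hit = _guarded_rate(n_hit, n_hit + n_miss)
    fa = _guarded_rate(n_fa, n_fa + n_cr)
    return float(norm.ppf(hit) - norm.ppf(fa))


@dataclass
class PerformanceSummary:
    n_go: int
    n_nogo: int
    hit_rate: float
    miss_rate: float
    fa_rate: float
    cr_rate: float
    d_prime: float
    mean_rt: float

    @classmethod
    def empty(cls):
        return cls(0, 0, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)


def performance_summary(trials):
    """Hit/miss/FA/CR rates, d' and mean RT over go and no-go trials.

    Catch trials are excluded from the go/no-go counts.  Mean RT pools hit
    RTs with 1.6 s substituted for misses, skipping RT-excluded trials.
    """
    go = trials[trials["type"] == "go"]
    nogo = trials[trials["type"] == "nogo"]
    if len(go) == 0 or len(nogo) == 0:
        return PerformanceSummary.empty()
    n_hit = int((go["outcome"] == "Hit").sum())
    n_miss = int((go["outcome"] == "Miss").sum())
    n_fa = int((nogo["outcome"] == "FA").sum())
    n_cr = int((nogo["outcome"] == "CR").sum())
    keep = go[~go.get("rt_excluded", pd.Series(False, index=go.index)).astype(bool)]
    mean_rt = float(keep["rt_for_mean"].mean()) if "rt_for_mean" in keep else np.nan
    return PerformanceSummary(
        n_go=len(go),
        n_nogo=len(nogo),
        hit_rate=n_hit / len(go),
        miss_rate=n_miss / len(go),
        fa_rate=n_fa / len(nogo),
        cr_rate=n_cr / len(nogo),
        d_prime=compute_dprime(n_hit, n_miss, n_fa, n_cr),
        mean_rt=mean_rt,
    )


@dataclass
class AttentionLabel:
    """Focal-attention classification of a session's blocks."""

    blocks: pd.DataFrame  # block_index, block_type, n_catch, frac_exceed, focal
    usable: bool
    focal_type: str | None


def classify_focal_blocks(trials):
    """Label each block focal/divided from catch-trial reaction times.

    For every block, the reference distribution is the go-trial RTs of the
    *other* block type (the go stimulus there appears at the same location
    as this block's catch stimulus); a block is focal when more than 50% of
    its catch trials have RTs exceeding the empirical 95% interval (above
    the 97.5th percentile), counting catch misses as exceeding.  The
    session is usable when focal blocks exist and occur in only one block
    type.
    """
    if "reaction_time" not in trials:
        trials = compute_reaction_times(trials)
    if int((trials["type"] == "catch").sum()) == 0:
        return AttentionLabel(blocks=pd.DataFrame(), usable=False, focal_type=None)

    rows = []
    for b, blk in trials.groupby("block_index"):
        bt = blk["block_type"].iloc[0]
        other = trials[(trials["block_type"] != bt) & (trials["type"] == "go")]
        ref = other[(other["outcome"] == "Hit") & ~other["rt_excluded"]]["reaction_time"].dropna()
        catch = blk[blk["type"] == "catch"]
        if len(catch) == 0 or len(ref) == 0:
            rows.append({"block_index": b, "block_type": bt, "n_catch": len(catch),
                         "frac_exceed": np.nan, "focal": None})
            continue
        upper = float(np.percentile(ref, 97.5))
        exceed = 0
        for _, tr in catch.iterrows():
            if tr["outcome"] == "Miss" or (
                np.isfinite(tr["reaction_time"]) and tr["reaction_time"] > upper
            ):
                exceed += 1
        frac = exceed / len(catch)
        rows.append({"block_index": b, "block_type": bt, "n_catch": len(catch),
                     "frac_exceed": frac, "focal": frac > 0.5})
    blocks = pd.DataFrame(rows)
    focal_blocks = blocks[blocks["focal"] == True]  # noqa: E712
    focal_types = set(focal_blocks["block_type"])
    usable = len(focal_blocks) > 0 and len(focal_types) == 1
    return AttentionLabel(
        blocks=blocks,
        usable=usable,
        focal_type=focal_types.pop() if usable else None,
    )


def split_performance_by_running(trials, behavior, speed_column="speed_cms"):
    """Performance summaries split by running state at grating onset.

    Each trial takes the running state (filtered speed >= 1 cm/s) at the
    frame nearest its grating onset.  Returns a dict with 'running' and
    'stationary' :class:`PerformanceSummary` entries; a state with no
    trials yields an empty-marked summary.
    """
    speed = behavior[speed_column].to_numpy()
    times = behavior["time_s"].to_numpy()
    idx = np.clip(np.searchsorted(times, trials["grating_onset_s"].to_numpy()), 0, len(times) - 1)
    running = speed[idx] >= RUN_SPEED_THRESHOLD
    out = {}
    for name, sel in (("running", running), ("stationary", ~running)):
        sub = trials[sel]
        out[name] = performance_summary(sub) if len(sub) else PerformanceSummary.empty()
    return out
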