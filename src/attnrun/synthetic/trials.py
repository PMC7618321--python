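"""Blocked go/no-go/catch trial structure and behavioural simulation.

Trials are organised into 2 or 3 contiguous blocks of alternating type
(BR, TL, BR).  Each trial is a delay period (3 s + Exponential(mean 9 s))
of ongoing sparse noise followed by a 1.6 s grating presentation.  A small
fraction of no-go trials are catch trials (the go stimulus shown at the
unattended location); each catch is separated from the previous one, and
from a block switch, by at least ten go trials.

``simulate_behavior`` fills outcomes and lick times from a per-block-type
attention profile (focal blocks miss catches more often and respond to
them with slower reaction times) and synthesises running and pupil streams
on the imaging frame clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

GRATING_DURATION_S = 1.6
RESPONSE_WINDOW_S = 1.6


@dataclass
class AttentionProfile:
    """Per-block-type behavioural state and rates.

    ``focal`` maps block type to whether attention is focused on that
    block's go/no-go location (True) or divided (False).  Catch trials in
    focal blocks are missed with probability ``catch_miss_focal`` and
    otherwise answered with reaction times slowed by ``catch_rt_shift_s``;
    in divided blocks catch trials behave like go trials apart from
    ``catch_miss_divided``.
    """

    focal: dict = field(default_factory=lambda: {"BR": True, "TL": False})
    hit_rate: float = 0.85
    fa_rate: float = 0.15
    catch_miss_focal: float = 0.55
    catch_miss_divided: float = 0.10
    go_rt_mean_s: float = 0.50
    go_rt_sd_s: float = 0.10
    catch_rt_shift_s: float = 0.60
    rt_min_s: float = 0.20
    rt_max_s: float = 1.55
    pre_onset_lick_rate: float = 0.02

    def validate(self):
        for name in ("hit_rate", "fa_rate", "catch_miss_focal", "catch_miss_divided"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


def generate_trials(
    n_trials,
    n_blocks=3,
    catch_fraction=0.023,
    delay_mean_s=9.0,
    delay_floor_s=3.0,
    go_fraction=0.7,
    post_trial_s=1.0,
    lead_in_s=5.0,
    seed=0,
):
    """Generate a trial table with blocked structure and shifted-exponential delays.

    Blocks alternate BR, TL, BR...  Catch trials are converted from no-go
    trials only after at least ten go trials since the previous catch or the
    block switch, targeting an overall ``catch_fraction`` of trials.
    """
    if n_blocks not in (2, 3):
        raise ValueError("n_blocks must be 2 or 3")
    if not 0.0 <= catch_fraction < 0.1:
        raise ValueError("catch_fraction must lie in [0, 0.1)")
    if catch_fraction > 0 and catch_fraction > go_fraction / 10.0:
        raise ValueError(
            f"catch_fraction {catch_fraction} incompatible with the >=10-go-trial "
            f"spacing rule at go_fraction {go_fraction}"
        )
    rng = np.random.default_rng(seed)
    block_types = ["BR", "TL", "BR"][:n_blocks]
    block_index = 1 + (np.arange(n_trials) * n_blocks) // n_trials
    is_go = rng.random(n_trials) < go_fraction
    trial_type = np.where(is_go, "go", "nogo").astype(object)

    # convert eligible no-go trials to catch
    if catch_fraction > 0:
        p_eligible = catch_fraction / max(1e-9, (1 - go_fraction) * 0.6)
        go_since = 0
        prev_block = 1
        for i in range(n_trials):
            if block_index[i] != prev_block:
                go_since = 0
                prev_block = block_index[i]
            if trial_type[i] == "go":
                go_since += 1
            elif go_since >= 10 and rng.random() < min(1.0, p_eligible):
                trial_type[i] = "catch"
                go_since = 0

    delays = delay_floor_s + rng.exponential(delay_mean_s, size=n_trials)
    starts = np.empty(n_trials)
    t = lead_in_s
    for i in range(n_trials):
        starts[i] = t
        t += delays[i] + GRATING_DURATION_S + post_trial_s
    onsets = starts + delays

    return pd.DataFrame(
        {
            "trial": np.arange(n_trials),
            "type": trial_type,
            "block_index": block_index,
            "block_type": [block_types[b - 1] for b in block_index],
            "start_s": starts,
            "delay_s": delays,
            "grating_onset_s": onsets,
            "grating_off_s": onsets + GRATING_DURATION_S,
        }
    )


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def simulate_behavior(
    trials,
    profile=None,
    duration_s=None,
    frame_rate=12.85,
    seed=0,
    stationary_mean_s=5.0,
    running_mean_s=8.0,
    running_speed_range=(2.0, 15.0),
    pupil_dev_sd_deg=1.5,
    artifact_rate=0.002,
):
    """Fill trial outcomes and lick times; synthesise behavioural time series.

    Returns ``(trials, behavior)`` where ``trials`` gains outcome /
    lick_times / reaction-time columns and ``behavior`` is a frame-indexed
    DataFrame with time_s, raw_speed_cms, pupil_area, pupil_az_dev_deg,
    pupil_el_dev_deg and eye_corr columns.

    Running is an alternating bout process: stationary epochs (mean 5 s,
    speed ~0) and running epochs (mean 8 s, constant bout speed drawn
    uniformly from 2-15 cm/s) with small additive jitter.
    """
    profile = profile or AttentionProfile()
    profile.validate()
    rng = np.random.default_rng(seed)
    trials = trials.copy()
    if duration_s is None:
        duration_s = float(trials["grating_off_s"].iloc[-1]) + 5.0

    outcomes = []
    lick_lists = []
    for _, tr in trials.iterrows():
        onset = tr["grating_onset_s"]
        focal = profile.focal.get(tr["block_type"], False)
        licks = []
        if rng.random() < profile.pre_onset_lick_rate:
            licks.append(onset - rng.uniform(0.01, 0.19))
        if tr["type"] == "go":
            if rng.random() < profile.hit_rate:
                rt = _truncnorm(rng, profile.go_rt_mean_s, profile.go_rt_sd_s,
                                profile.rt_min_s, profile.rt_max_s)
                licks.append(onset + rt)
                outcomes.append("Hit")
            else:
                outcomes.append("Miss")
        elif tr["type"] == "nogo":
            if rng.random() < profile.fa_rate:
                rt = _truncnorm(rng, profile.go_rt_mean_s, profile.go_rt_sd_s,
                                profile.rt_min_s, profile.rt_max_s)
                licks.append(onset + rt)
                outcomes.append("FA")
            else:
                outcomes.append("CR")
        else:  # catch: go stimulus at the unattended location
            miss_p = profile.catch_miss_focal if focal else profile.catch_miss_divided
            if rng.random() < miss_p:
                outcomes.append("Miss")
            else:
                shift = profile.catch_rt_shift_s if focal else 0.0
                rt = _truncnorm(rng, profile.go_rt_mean_s + shift, profile.go_rt_sd_s,
                                profile.rt_min_s, profile.rt_max_s)
                licks.append(onset + rt)
                outcomes.append("Hit")
        lick_lists.append(sorted(licks))
    trials["outcome"] = outcomes
    trials["lick_times"] = lick_lists

    # --- frame-clock behavioural streams ---
    n_frames = int(np.floor(duration_s * frame_rate)) + 1
    time_s = np.arange(n_frames) / frame_rate
    speed = np.zeros(n_frames)
    t = 0.0
    running = bool(rng.random() < 0.5)
    while t < duration_s:
        dur = rng.exponential(running_mean_s if running else stationary_mean_s)
        dur = max(dur, 0.4)
        sel = (time_s >= t) & (time_s < t + dur)
        if running:
            speed[sel] = rng.uniform(*running_speed_range) + rng.normal(0, 0.3, sel.sum())
        else:
            speed[sel] = np.abs(rng.normal(0, 0.15, sel.sum()))
        t += dur
        running = not running
    speed = np.clip(speed, 0.0, None)

    pupil_area = 500.0 + 40.0 * np.sin(2 * np.pi * time_s / 200.0) + rng.normal(0, 8.0, n_frames)
    # smoothed gaze jitter
    k = np.ones(13) / 13.0
    az_dev = np.convolve(rng.normal(0, pupil_dev_sd_deg * 3.6, n_frames), k, mode="same")
    el_dev = np.convolve(rng.normal(0, pupil_dev_sd_deg * 3.6, n_frames), k, mode="same")
    # occasional large saccades away from the monitor
    n_sac = rng.poisson(artifact_rate * n_frames)
    for f in rng.integers(0, max(1, n_frames - 14), size=n_sac):
        az_dev[f : f + 13] += rng.choice([-1, 1]) * rng.uniform(11, 20)
    eye_corr = rng.normal(0.95, 0.01, n_frames)
    n_close = rng.poisson(artifact_rate * n_frames)
    for f in rng.integers(0, max(1, n_frames - 7), size=n_close):
        eye_corr[f : f + 6] -= rng.uniform(0.1, 0.3)

    behavior = pd.DataFrame(
        {
            "time_s": time_s,
            "raw_speed_cms": speed,
            "pupil_area": pupil_area,
            "pupil_az_dev_deg": az_dev,
            "pupil_el_dev_deg": el_dev,
            "eye_corr": eye_corr,
        }
    )
    return trials, behavior
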