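"""Assembly of complete synthetic sessions.

A session is three task blocks (BR, TL, BR) of go/no-go/catch trials with
continuous sparse-noise stimulation, followed by a passive block in which
the same sparse-noise statistics continue with all attentional gains at 1,
plus behavioural streams and the simulated fluorescence matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from attnrun import grid
from attnrun.synthetic.neurons import FluorescenceSet, GroundTruth, simulate_neurons
from attnrun.synthetic.stimuli import StimulusFrameSet, generate_sparse_noise
from attnrun.synthetic.trials import AttentionProfile, generate_trials, simulate_behavior


@dataclass
class Session:
    stimuli: StimulusFrameSet
    trials: pd.DataFrame
    blocks: pd.DataFrame
    behavior: pd.DataFrame
    fluo: FluorescenceSet
    ground_truth: GroundTruth
    seed: int = 0
    params: dict = field(default_factory=dict)


def _block_table(trials, n_blocks, passive_s, post_trial_s=1.0):
    rows = []
    for b in range(1, n_blocks + 1):
        sel = trials[trials["block_index"] == b]
        rows.append(
            {
                "block_index": b,
                "block_type": sel["block_type"].iloc[0],
                "t_start": float(sel["start_s"].iloc[0]),
                "t_end": float(sel["grating_off_s"].iloc[-1]) + post_trial_s,
            }
        )
    if passive_s > 0:
        t0 = rows[-1]["t_end"]
        rows.append(
            {"block_index": 0, "block_type": "passive", "t_start": t0, "t_end": t0 + passive_s}
        )
    return pd.DataFrame(rows)


def make_session(
    n_neurons=50,
    n_trials_per_block=20,
    n_blocks=3,
    passive_s=150.0,
    seed=0,
    profile=None,
    frame_rate=grid.IMAGING_RATE_HZ,
    trial_kwargs=None,
    neuron_kwargs=None,
    behavior_kwargs=None,
):
    """Build a full task session with ground truth.

    Sub-generators receive independent child seeds derived from ``seed``,
    so the whole session is reproducible from a single integer.
    """
    ss = np.random.SeedSequence(seed)
    s_trials, s_stim, s_beh, s_gt, s_neu = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)
    ]
    profile = profile or AttentionProfile()
    trials = generate_trials(
        n_trials=n_trials_per_block * n_blocks,
        n_blocks=n_blocks,
        seed=s_trials,
        **(trial_kwargs or {}),
    )
    blocks = _block_table(trials, n_blocks, passive_s)
    duration = float(blocks["t_end"].max()) + 2.0
    stimuli = generate_sparse_noise(duration, seed=s_stim)
    trials, behavior = simulate_behavior(
        trials, profile, duration_s=duration, frame_rate=frame_rate, seed=s_beh,
        **(behavior_kwargs or {}),
    )
    task_blocks = blocks[blocks["block_index"] > 0]
    gt = GroundTruth.population(
        n_neurons,
        block_types=list(task_blocks["block_type"]),
        seed=s_gt,
        focal={bt: profile.focal.get(bt, False) for bt in set(task_blocks["block_type"])},
        **(neuron_kwargs or {}),
    )
    fluo = simulate_neurons(stimuli, task_blocks, behavior, gt, seed=s_neu, frame_rate=frame_rate)
    return Session(
        stimuli=stimuli,
        trials=trials,
        blocks=blocks,
        behavior=behavior,
        fluo=fluo,
        ground_truth=gt,
        seed=seed,
        params={
            "n_neurons": n_neurons,
            "n_trials_per_block": n_trials_per_block,
            "n_blocks": n_blocks,
            "passive_s": passive_s,
            "frame_rate": frame_rate,
        },
    )


def make_mapping_session(
    n_neurons=100,
    duration_s=600.0,
    seed=0,
    frame_rate=grid.IMAGING_RATE_HZ,
    neuron_kwargs=None,
):
    """Passive receptive-field-mapping session: sparse noise only, no task.

    All attentional gains are 1; running behaviour is still simulated so
    running-dependent analyses remain exercised when a running gain is set.
    """
    ss = np.random.SeedSequence(seed)
    s_stim, s_beh, s_gt, s_neu = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(4)]
    stimuli = generate_sparse_noise(duration_s, seed=s_stim)
    empty_trials = pd.DataFrame(
        columns=["trial", "type", "block_index", "block_type", "start_s", "delay_s",
                 "grating_onset_s", "grating_off_s"]
    )
    _, behavior = simulate_behavior(
        generate_trials(1, n_blocks=2, catch_fraction=0.0, seed=0),
        duration_s=duration_s + 1.0,
        frame_rate=frame_rate,
        seed=s_beh,
    )
    blocks = pd.DataFrame(
        [{"block_index": 0, "block_type": "passive", "t_start": 0.0, "t_end": duration_s}]
    )
    kwargs = dict(rf_location="uniform")
    kwargs.update(neuron_kwargs or {})
    gt = GroundTruth.population(n_neurons, block_types=[], seed=s_gt, **kwargs)
    gt.attn_gain_per_block = np.ones((n_neurons, 0))
    fluo = simulate_neurons(
        stimuli, blocks.iloc[0:0], behavior, gt, seed=s_neu, frame_rate=frame_rate
    )
    return Session(
        stimuli=stimuli,
        trials=empty_trials,
        blocks=blocks,
        behavior=behavior,
        fluo=fluo,
        ground_truth=gt,
        seed=seed,
        params={"n_neurons": n_neurons, "duration_s": duration_s, "frame_rate": frame_rate},
    )
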