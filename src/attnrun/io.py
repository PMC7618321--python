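"""Session-bundle persistence.

One directory per session: ``stimuli.csv``, ``trials.csv``, ``blocks.csv``,
``behavior.csv`` (frame-indexed), ``fluorescence.h5`` (datasets F,
frame_times, neuron_ids and, after trace processing, F0 and dFF),
``ground_truth.json`` and ``config.yaml``.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from attnrun.synthetic.neurons import FluorescenceSet, GroundTruth
from attnrun.synthetic.session import Session
from attnrun.synthetic.stimuli import StimulusFrameSet


def write_session(session, directory):
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    session.stimuli.events.to_csv(d / "stimuli.csv", index=False)
    trials = session.trials.copy()
    if "lick_times" in trials:
        trials["lick_times"] = [
            ";".join(f"{t:.4f}" for t in licks) for licks in trials["lick_times"]
        ]
    trials.to_csv(d / "trials.csv", index=False)
    session.blocks.to_csv(d / "blocks.csv", index=False)
    session.behavior.to_csv(d / "behavior.csv", index=False)
    with h5py.File(d / "fluorescence.h5", "w") as h5:
        h5.create_dataset("F", data=session.fluo.F)
        h5.create_dataset("frame_times", data=session.fluo.frame_times)
        h5.create_dataset("neuron_ids", data=session.fluo.neuron_ids)
        for name in ("F0", "dFF"):
            arr = getattr(session.fluo, name)
            if arr is not None:
                h5.create_dataset(name, data=arr)
        h5.attrs["frame_rate"] = session.fluo.frame_rate
    gt = dataclasses.asdict(session.ground_truth)
    gt = {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in gt.items()}
    (d / "ground_truth.json").write_text(json.dumps(gt))
    cfg = dict(session.params)
    cfg["seed"] = session.seed
    cfg["duration_s"] = float(session.stimuli.duration_s)
    (d / "config.yaml").write_text(yaml.safe_dump(cfg))


def read_session(directory):
    d = Path(directory)
    cfg = yaml.safe_load((d / "config.yaml").read_text())
    events = pd.read_csv(d / "stimuli.csv")
    stimuli = StimulusFrameSet(events=events, duration_s=float(cfg.get("duration_s", 0.0)))
    trials = pd.read_csv(d / "trials.csv")
    if "lick_times" in trials:
        trials["lick_times"] = [
            [float(x) for x in str(s).split(";") if x not in ("", "nan")]
            for s in trials["lick_times"].fillna("")
        ]
    blocks = pd.read_csv(d / "blocks.csv")
    behavior = pd.read_csv(d / "behavior.csv")
    with h5py.File(d / "fluorescence.h5", "r") as h5:
        fluo = FluorescenceSet(
            F=h5["F"][()],
            frame_times=h5["frame_times"][()],
            frame_rate=float(h5.attrs.get("frame_rate", 12.85)),
            neuron_ids=h5["neuron_ids"][()],
            F0=h5["F0"][()] if "F0" in h5 else None,
            dFF=h5["dFF"][()] if "dFF" in h5 else None,
        )
    gt_path = d / "ground_truth.json"
    gt = None
    if gt_path.exists():
        raw = json.loads(gt_path.read_text())
        fields = {f.name for f in dataclasses.fields(GroundTruth)}
        kwargs = {
            k: (np.asarray(v) if isinstance(v, list) else v)
            for k, v in raw.items()
            if k in fields
        }
        gt = GroundTruth(**kwargs)
    return Session(
        stimuli=stimuli,
        trials=trials,
        blocks=blocks,
        behavior=behavior,
        fluo=fluo,
        ground_truth=gt,
        seed=int(cfg.get("seed", 0)),
        params=cfg,
    )
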