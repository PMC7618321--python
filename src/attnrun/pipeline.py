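"""Session and cohort orchestration.

``run_session`` takes a configuration (or an already built/loaded session),
runs trace processing, behavioural metrics, RF mapping and modulation
analysis, and returns (optionally writes) the report tables.  ``run_cohort``
applies the focal-attention usability criterion across sessions and
correlates per-neuron modulation indices across days using the persistent
neuron identities.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from attnrun import behavior as beh
from attnrun import hstats, modulation as mod, rf, traces
from attnrun.synthetic import make_session
from attnrun.synthetic.trials import AttentionProfile


@dataclass
class SessionConfig:
    """All generator and analysis knobs for one session run."""

    n_neurons: int = 50
    n_trials_per_block: int = 20
    n_blocks: int = 3
    passive_s: float = 150.0
    seed: int = 0
    rf_location: str = "BR"
    attn_gain: float = 1.5
    run_gain: float = 1.0
    onset_amp: float = 0.0
    noise_sd: float = 0.08
    # analysis thresholds (defaults follow the experimental conventions)
    run_speed_threshold_cms: float = 1.0
    rt_min_s: float = 0.16
    eye_closure_sd: float = 5.5
    pupil_dev_limit_deg: float = 10.0
    f0_chunk_len: int = 2000
    f0_step: int = 500
    n_boot: int = 2000
    extra: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path):
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in data.items() if k in known}
        kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
        return cls(**kwargs)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))


@dataclass
class SessionResult:
    session: object
    behavior_summary: pd.DataFrame
    attention_label: object
    rf_map: object
    rf_fits: pd.DataFrame
    modulation: pd.DataFrame


def build_session(config):
    return make_session(
        n_neurons=config.n_neurons,
        n_trials_per_block=config.n_trials_per_block,
        n_blocks=config.n_blocks,
        passive_s=config.passive_s,
        seed=config.seed,
        profile=AttentionProfile(),
        neuron_kwargs={
            "rf_location": config.rf_location,
            "attn_gain": config.attn_gain,
            "run_gain": config.run_gain,
            "onset_amp": config.onset_amp,
            "noise_sd": config.noise_sd,
        },
    )


def process_traces(session, config=None):
    """Fill F0, dFF, filtered speed and validity columns in place."""
    cfg = config or SessionConfig()
    fluo = session.fluo
    n_frames = fluo.F.shape[1]
    chunk_len = min(cfg.f0_chunk_len, n_frames)
    fluo.F0 = traces.estimate_f0_matrix(fluo.F, chunk_len=chunk_len, step=cfg.f0_step)
    fluo.dFF = traces.compute_dff(fluo.F, fluo.F0)
    b = session.behavior
    b["speed_cms"] = traces.filter_running_speed(
        b["raw_speed_cms"].to_numpy(), fluo.frame_rate
    )
    validity = traces.build_frame_validity(
        b["eye_corr"].to_numpy(),
        b["pupil_az_dev_deg"].to_numpy(),
        b["pupil_el_dev_deg"].to_numpy(),
        closure_sd=cfg.eye_closure_sd,
        dev_limit=cfg.pupil_dev_limit_deg,
    )
    b["valid"] = validity.valid
    b["valid_rf"] = validity.valid_rf
    return session


def analyze_behavior(session):
    """Per-block-type and per-running-state performance tables."""
    trials = beh.compute_reaction_times(session.trials)
    session.trials = trials
    rows = []
    for bt, sub in trials.groupby("block_type"):
        s = beh.performance_summary(sub)
        rows.append({"scope": f"block_{bt}", **asdict(s)})
    rows.append({"scope": "all", **asdict(beh.performance_summary(trials))})
    if "speed_cms" in session.behavior:
        for state, s in beh.split_performance_by_running(trials, session.behavior).items():
            rows.append({"scope": state, **asdict(s)})
    label = beh.classify_focal_blocks(trials)
    return pd.DataFrame(rows), label


def map_rfs(session, config=None):
    cfg = config or SessionConfig()
    b = session.behavior
    events = rf.compensate_stimulus_positions(
        session.stimuli.events,
        session.fluo.frame_times,
        b["pupil_az_dev_deg"].to_numpy(),
        b["pupil_el_dev_deg"].to_numpy(),
        b["valid_rf"].to_numpy(),
    )
    rfmap = rf.reverse_correlate(session.fluo.dFF, events, session.fluo.frame_times)
    rf.detect_subfields(rfmap)
    fits = rf.fit_all_rfs(rfmap)
    return events, rfmap, fits


def analyze_modulation(session, events, rfmap, fits, config=None):
    """Per-neuron modulation table: indices, p-values, reliability pairs."""
    cfg = config or SessionConfig()
    rows = []
    ss = np.random.SeedSequence(session.seed + 1)
    child = ss.spawn(rfmap.n_neurons)
    for _, fit in fits.iterrows():
        i = int(fit["neuron"])
        if not fit["success"]:
            continue
        pol = fit["polarity"]
        mask = rfmap.mask[pol][i]
        seed_i = int(child[i].generate_state(1)[0] % (2**31))
        try:
            samples = mod.extract_response_samples(
                session.fluo.dFF[i],
                events,
                session.fluo.frame_times,
                mask,
                pol,
                session.behavior,
                session.blocks,
                valid=session.behavior["valid"].to_numpy(),
            )
        except ValueError:
            continue
        task = samples[samples["block_index"] > 0]
        a = task.loc[task["block_type"] == "BR", "value"].to_numpy()
        b = task.loc[task["block_type"] == "TL", "value"].to_numpy()
        attn_a = mod.attention_index_a(task)
        attn_p = (
            mod.bootstrap_modulation_p(a, b, n_boot=cfg.n_boot, seed=seed_i)
            if min(a.size, b.size) >= 3
            else np.nan
        )
        # attend-in vs attend-out (eq. b): defined for RFs overlapping one location
        overlaps_br = fit["d_br"] <= 0
        overlaps_tl = fit["d_tl"] <= 0
        attn_b = np.nan
        if overlaps_br != overlaps_tl:
            in_type = "BR" if overlaps_br else "TL"
            in_sel = task.loc[task["block_type"] == in_type, "value"].to_numpy()
            out_sel = task.loc[task["block_type"] != in_type, "value"].to_numpy()
            attn_b = mod.attention_index_b(in_sel, out_sel)
        # passive comparison (R_out = passive-block responses)
        passive = samples.loc[samples["block_type"] == "passive", "value"].to_numpy()
        attn_vs_passive = (
            mod.attention_index_b(a, passive) if passive.size else np.nan
        )
        run_idx, run_p = mod.running_index(task, n_boot=cfg.n_boot, seed=seed_i + 1)
        onset_act, onset_p = mod.running_onset_activity(
            session.fluo.dFF[i],
            session.behavior["speed_cms"].to_numpy(),
            session.fluo.frame_rate,
        )
        within = mod.within_block_reliability(task)
        between = mod.between_block_reliability(task)
        run_between = mod.running_between_block_reliability(task)
        rows.append(
            {
                "neuron": i,
                "polarity": pol,
                "n_samples": len(task),
                "attn_index_a": attn_a,
                "attn_p": attn_p,
                "attn_index_b": attn_b,
                "attn_index_vs_passive": attn_vs_passive,
                "run_index": run_idx,
                "run_p": run_p,
                "running_onset_activity": onset_act,
                "running_onset_p": onset_p,
                "within_b1_h1": within[1][0],
                "within_b1_h2": within[1][1],
                "within_b3_h1": within[3][0],
                "within_b3_h2": within[3][1],
                "between_b1": between[0],
                "between_b3": between[1],
                "run_between_b1": run_between[0],
                "run_between_b3": run_between[1],
                "d_br": fit["d_br"],
                "d_tl": fit["d_tl"],
            }
        )
    table = pd.DataFrame(rows)
    for col in ("attn_p", "run_p"):
        if len(table) and table[col].notna().any():
            sel = table[col].notna()
            adj, rej = hstats.bh_adjust(table.loc[sel, col].to_numpy())
            table.loc[sel, col + "_adj"] = adj
            table.loc[sel, col + "_reject"] = rej
    return table


def run_session(config=None, session=None, outdir=None):
    """Generate (or accept) a session and run the full analysis chain."""
    cfg = config or SessionConfig()
    if session is None:
        session = build_session(cfg)
    process_traces(session, cfg)
    behavior_summary, label = analyze_behavior(session)
    if session.fluo.F.shape[0] > 0:
        events, rfmap, fits = map_rfs(session, cfg)
        modulation_table = analyze_modulation(session, events, rfmap, fits, cfg)
    else:
        rfmap, fits = None, pd.DataFrame()
        modulation_table = pd.DataFrame()
    result = SessionResult(
        session=session,
        behavior_summary=behavior_summary,
        attention_label=label,
        rf_map=rfmap,
        rf_fits=fits,
        modulation=modulation_table,
    )
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        behavior_summary.to_csv(out / "behavior_metrics.csv", index=False)
        fits.to_csv(out / "rf_fits.csv", index=False)
        modulation_table.to_csv(out / "modulation.csv", index=False)
        if label.blocks is not None and len(label.blocks):
            label.blocks.to_csv(out / "attention_blocks.csv", index=False)
    return result


def run_cohort(results, require_usable=True):
    """Cross-day reliability over a list of per-session results.

    Sessions failing the focal-attention usability criterion are dropped
    (unless ``require_usable`` is False).  For every ordered session pair
    the per-neuron attention and running indices are correlated over
    shared neuron ids.
    """
    usable = [r for r in results if r.attention_label.usable or not require_usable]
    pair_rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i].modulation, usable[j].modulation
            if not len(a) or not len(b):
                continue
            merged = a.merge(b, on="neuron", suffixes=("_1", "_2"))
            row = {"day_i": i, "day_j": j, "n_neurons": len(merged)}
            for name in ("attn_index_a", "run_index"):
                x = merged[f"{name}_1"].to_numpy()
                y = merged[f"{name}_2"].to_numpy()
                ok = np.isfinite(x) & np.isfinite(y)
                row[f"r_{name}"] = (
                    float(np.corrcoef(x[ok], y[ok])[0, 1]) if ok.sum() >= 3 else np.nan
                )
                row[f"n_{name}"] = int(ok.sum())
            pair_rows.append(row)
    return {"n_usable": len(usable), "day_pairs": pd.DataFrame(pair_rows)}
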