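"""Ground-truth recovery experiments.

Each function builds synthetic sessions under stated conditions, runs the
full analysis chain on them, and reports how well the known generative
parameters are recovered.  These experiments double as the package's
end-to-end validation: the generator's defaults define the study
conditions and the analytic expectations (a multiplicative gain g yields a
modulation index of (g-1)/(g+1)) provide the targets.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from attnrun import behavior as beh
from attnrun import grid, hstats, modulation as mod, rf, traces
from attnrun.synthetic import (
    AttentionProfile,
    GroundTruth,
    generate_trials,
    make_mapping_session,
    make_session,
    simulate_behavior,
)


def _child_seeds(seed, n):
    return [int(c.generate_state(1)[0] % (2**31)) for c in np.random.SeedSequence(seed).spawn(n)]


def _analyze_session(session):
    """Trace processing + RF mapping; returns (events, rfmap, fits, dff)."""
    from attnrun.pipeline import SessionConfig, map_rfs, process_traces

    process_traces(session, SessionConfig())
    events, rfmap, fits = map_rfs(session, SessionConfig())
    return events, rfmap, fits


def _neuron_samples(session, events, rfmap, fit):
    i = int(fit["neuron"])
    return mod.extract_response_samples(
        session.fluo.dFF[i],
        events,
        session.fluo.frame_times,
        rfmap.mask[fit["polarity"]][i],
        fit["polarity"],
        session.behavior,
        session.blocks,
        valid=session.behavior["valid"].to_numpy(),
    )


def attention_gain_recovery(n_neurons=200, gain=1.5, seed=0, n_trials_per_block=18):
    """Median attention index of attended-location neurons vs the analytic value.

    Neurons with RFs at the BR location under a focal-BR profile and an
    attentional gain g in BR blocks should show attention index
    (g-1)/(g+1).
    """
    session = make_session(
        n_neurons=n_neurons,
        n_trials_per_block=n_trials_per_block,
        seed=seed,
        passive_s=60.0,
        neuron_kwargs={"rf_location": "BR", "attn_gain": gain, "run_gain": 1.0},
    )
    events, rfmap, fits = _analyze_session(session)
    indices = []
    for _, fit in fits[fits["success"]].iterrows():
        i = int(fit["neuron"])
        if session.ground_truth.attn_gain_per_block[i].max() <= 1.0:
            continue  # RF did not overlap the attended disk in truth
        samples = _neuron_samples(session, events, rfmap, fit)
        idx = mod.attention_index_a(samples[samples["block_index"] > 0])
        if np.isfinite(idx):
            indices.append(idx)
    indices = np.asarray(indices)
    return {
        "median_attn_index": float(np.median(indices)),
        "analytic": (gain - 1) / (gain + 1),
        "n": int(indices.size),
    }


def running_gain_recovery(n_neurons=200, gain=2.0, seed=0, n_trials_per_block=18):
    """Median running modulation index vs the analytic (g-1)/(g+1)."""
    session = make_session(
        n_neurons=n_neurons,
        n_trials_per_block=n_trials_per_block,
        seed=seed,
        passive_s=60.0,
        neuron_kwargs={"rf_location": "BR", "attn_gain": 1.0, "run_gain": gain},
    )
    events, rfmap, fits = _analyze_session(session)
    indices = []
    for _, fit in fits[fits["success"]].iterrows():
        samples = _neuron_samples(session, events, rfmap, fit)
        idx, _ = mod.running_index(samples[samples["block_index"] > 0], with_p=False)
        if np.isfinite(idx):
            indices.append(idx)
    indices = np.asarray(indices)
    return {
        "median_run_index": float(np.median(indices)),
        "analytic": (gain - 1) / (gain + 1),
        "n": int(indices.size),
    }


def rf_recovery(n_neurons=100, duration_s=600.0, seed=0):
    """RF-centre and sigma recovery on a passive mapping session."""
    session = make_mapping_session(n_neurons=n_neurons, duration_s=duration_s, seed=seed)
    _, rfmap, fits = _analyze_session(session)
    gt = session.ground_truth
    center_err, sigma_err = [], []
    for _, fit in fits[fits["success"]].iterrows():
        i = int(fit["neuron"])
        true_pol = "white" if gt.polarity[i] == "white" else "black"
        if ("on" if true_pol == "white" else "off") != rfmap.subfield_class[i]:
            continue
        center_err.append(
            float(np.hypot(fit["center_az"] - gt.center_az[i], fit["center_el"] - gt.center_el[i]))
        )
        sigma_err.append(abs(fit["sigma_major"] - gt.sigma_major[i]) / gt.sigma_major[i])
    return {
        "median_center_error_deg": float(np.median(center_err)),
        "median_sigma_error_frac": float(np.median(sigma_err)),
        "n": len(center_err),
    }


def subfield_null_fwer(n_null=500, duration_s=600.0, seed=0, noise_sd=0.08, batch=100):
    """Familywise false-positive rate of subfield detection on null neurons.

    Null neurons carry pure noise dF/F; any detected subfield is a
    familywise false positive.
    """
    from attnrun.synthetic import generate_sparse_noise

    s_stim, s_noise = _child_seeds(seed, 2)
    stimuli = generate_sparse_noise(duration_s, seed=s_stim)
    frame_times = np.arange(int(duration_s * grid.IMAGING_RATE_HZ)) / grid.IMAGING_RATE_HZ
    rng = np.random.default_rng(s_noise)
    false_any = 0
    done = 0
    while done < n_null:
        m = min(batch, n_null - done)
        dff = rng.normal(0.0, noise_sd, size=(m, frame_times.size))
        rfmap = rf.reverse_correlate(dff, stimuli.events, frame_times)
        rf.detect_subfields(rfmap)
        false_any += int(np.sum(rfmap.subfield_class != "none"))
        done += m
    return {"fwer": false_any / n_null, "n": n_null}


def geometry_oracle_check(n_cases=1000, seed=0):
    """Refined ellipse-disk distance vs the 1e4-point brute-force sampler."""
    from attnrun.geometry import ellipse_disk_distance, ellipse_disk_distance_bruteforce

    rng = np.random.default_rng(seed)
    max_err = 0.0
    for _ in range(n_cases):
        center = rng.uniform(-30, 120, 2)
        a = rng.uniform(2, 30)
        b = rng.uniform(1, a)
        ang = rng.uniform(-np.pi, np.pi)
        disk = rng.uniform(-30, 120, 2)
        r = rng.uniform(5, 25)
        d1 = ellipse_disk_distance(center, (a, b), ang, disk, r)
        d2 = ellipse_disk_distance_bruteforce(center, (a, b), ang, disk, r)
        max_err = max(max_err, abs(d1 - d2))
    return {"max_abs_error_deg": float(max_err), "n": n_cases}


def bootstrap_null_rejection(n_datasets=500, n=20, alpha=0.05, n_boot=2000, seed=0):
    """Type-I error of the bootstrap response-difference test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_datasets):
        a = rng.normal(1.0, 0.3, n)
        b = rng.normal(1.0, 0.3, n)
        p = mod.bootstrap_modulation_p(a, b, n_boot=n_boot, seed=seed + 17 * k + 1)
        if p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_datasets, "n": n_datasets}


def hier_paired_null_rejection(
    n_datasets=500, n_animals=4, n_units=8, alpha=0.05, n_boot=1000, seed=0
):
    """Type-I error of the hierarchical paired shuffle test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for k in range(n_datasets):
        vals = rng.normal(0.0, 1.0, size=(n_animals * n_units, 2))
        animals = np.repeat(np.arange(n_animals), n_units)
        nested = hstats.NestedSample(values=vals, animals=animals)
        p = hstats.hier_bootstrap_paired_test(nested, n_boot=n_boot, seed=seed + 31 * k + 1)
        if p < alpha:
            rejections += 1
    return {"rejection_rate": rejections / n_datasets, "n": n_datasets}


def randomization_null_uniformity(n_datasets=500, n=20, n_perm=2000, seed=0):
    """KS p-value for uniformity of randomisation-test p under independence."""
    from scipy.stats import kstest

    rng = np.random.default_rng(seed)
    ps = []
    for k in range(n_datasets):
        x = rng.normal(size=n)
        y = rng.normal(size=n)
        _, p = hstats.randomization_corr_test(x, y, n_perm=n_perm, seed=seed + 13 * k + 1)
        ps.append(p)
    return {"ks_p": float(kstest(ps, "uniform").pvalue), "n": n_datasets}


def focal_classification_rate(n_seeds=100, n_trials_per_block=150, seed=0):
    """Fraction of focal-BR synthetic sessions classified focal-BR.

    Sessions are sized so each block holds roughly ten catch trials, the
    regime the block classification is designed for.
    """
    correct = 0
    for s in _child_seeds(seed, n_seeds):
        trials = generate_trials(
            n_trials=3 * n_trials_per_block, n_blocks=3, catch_fraction=0.05, seed=s
        )
        trials, _ = simulate_behavior(trials, AttentionProfile(), seed=s + 1)
        label = beh.classify_focal_blocks(trials)
        if label.usable and label.focal_type == "BR":
            correct += 1
    return {"focal_br_rate": correct / n_seeds, "n": n_seeds}


def f0_recovery(n_traces=20, n_frames=8000, seed=0):
    """F0 estimation error on drifting traces with sparse calcium transients."""
    from attnrun.synthetic import simulate_drifting_trace

    rels = []
    for s in _child_seeds(seed, n_traces):
        F, true = simulate_drifting_trace(n_frames=n_frames, seed=s)
        f0 = traces.estimate_f0(F).f0
        rels.append(float(np.sqrt(np.mean((f0 - true) ** 2)) / true.mean()))
    return {"median_f0_rmse_frac": float(np.median(rels)), "n": n_traces}


def reliability_experiment(seed=0, n_neurons=200, n_trials_per_block=36, stable=True):
    """Within- and between-block reliability of modulation indices.

    With ``stable=True`` attention gains are drawn once per neuron
    (uniform 1.2-2.5) and shared by blocks 1 and 3; with ``stable=False``
    they are resampled independently per block.  Running gains
    (uniform 1.2-3) are always stable.  Returns pooled half/block index
    pairs and their Pearson correlations.
    """
    session = make_session(
        n_neurons=n_neurons,
        n_trials_per_block=n_trials_per_block,
        seed=seed,
        passive_s=60.0,
        neuron_kwargs={
            "rf_location": "BR",
            "attn_gain": (1.2, 2.5),
            "run_gain": (1.2, 3.0),
            "resample_attn_per_block": not stable,
        },
    )
    events, rfmap, fits = _analyze_session(session)
    within_pairs, between_pairs, run_pairs = [], [], []
    for _, fit in fits[fits["success"]].iterrows():
        i = int(fit["neuron"])
        if session.ground_truth.attn_gain_per_block[i].max() <= 1.0:
            continue
        samples = _neuron_samples(session, events, rfmap, fit)
        task = samples[samples["block_index"] > 0]
        w = mod.within_block_reliability(task)
        for blk in (1, 3):
            if np.isfinite(w[blk][0]) and np.isfinite(w[blk][1]):
                within_pairs.append(w[blk])
        b1, b3 = mod.between_block_reliability(task)
        if np.isfinite(b1) and np.isfinite(b3):
            between_pairs.append((b1, b3))
        r1, r3 = mod.running_between_block_reliability(task)
        if np.isfinite(r1) and np.isfinite(r3):
            run_pairs.append((r1, r3))

    def corr(pairs):
        arr = np.asarray(pairs)
        if len(arr) < 5:
            return np.nan, np.nan, 0
        r, p = hstats.randomization_corr_test(
            arr[:, 0], arr[:, 1], n_perm=2000, seed=seed + 99
        )
        return float(r), float(p), len(arr)

    rw, pw, nw = corr(within_pairs)
    rb, pb, nb = corr(between_pairs)
    rr, pr, nr = corr(run_pairs)
    between_arr = np.asarray(between_pairs) if between_pairs else np.empty((0, 2))
    return {
        "within_r": rw,
        "within_p": pw,
        "n_within": nw,
        "between_r": rb,
        "between_p": pb,
        "n_between": nb,
        "running_between_r": rr,
        "running_between_p": pr,
        "n_running": nr,
        "mean_between_b1": float(np.mean(between_arr[:, 0])) if len(between_arr) else np.nan,
        "mean_between_b3": float(np.mean(between_arr[:, 1])) if len(between_arr) else np.nan,
    }
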