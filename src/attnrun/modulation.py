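"""Attentional and running modulation of sparse-noise responses.

For one neuron with a detected RF, every presentation of a sparse-noise
square inside the RF mask yields one response sample: the dF/F summed over
a 7-frame window around the neuron's response peak (1 frame before to 5
frames after, ~0.5 s at 12.85 Hz) minus 7x the median dF/F over the ~470 ms
pre-onset baseline.  The peak frame offset is fixed per neuron from the
stimulus that drives the maximum response (the RF centre).  Samples carry
their block, block type and running state, from which the modulation
indices (R_A - R_B)/(R_A + R_B), their bootstrap significance, running
onset activity, and the within-/between-block reliability indices are
computed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import wilcoxon

from attnrun.rf import BASELINE_FRAMES, event_frames
from attnrun.synthetic.neurons import RUN_SPEED_THRESHOLD, running_onsets

PEAK_WINDOW = (-1, 5)  # frames around the peak, inclusive
MIN_REPS = 5  # minimum samples per condition for a defined index


def find_peak_offset(dff_neuron, events, frame_times, mask, polarity,
                     search_frames=7, baseline_frames=BASELINE_FRAMES):
    """Frame offset (0-based from onset) of the neuron's response peak.

    Uses the RF-centre stimulus: the masked location with the largest mean
    onset-aligned response; the peak is the offset of the maximum of that
    stimulus's mean baseline-subtracted response within ``search_frames``.
    """
    ev = events[(events["polarity"] == polarity)]
    f = event_frames(ev["onset_s"].to_numpy(), frame_times)
    ok = (f >= baseline_frames) & (f + search_frames <= dff_neuron.size)
    ev, f = ev[ok], f[ok]
    best = None
    for (r, c), sub in ev.groupby(["row", "col"]):
        if not mask[r, c]:
            continue
        fi = f[np.isin(ev.index, sub.index)]
        aligned = np.stack([dff_neuron[x : x + search_frames] for x in fi])
        base = np.median(
            np.stack([dff_neuron[x - baseline_frames : x] for x in fi]), axis=1
        )
        trace = (aligned - base[:, None]).mean(axis=0)
        if best is None or trace.max() > best[0]:
            best = (trace.max(), int(np.argmax(trace)))
    if best is None:
        raise ValueError("no RF events available to locate the peak")
    return best[1]


def extract_response_samples(
    dff_neuron,
    events,
    frame_times,
    mask,
    polarity,
    behavior,
    blocks,
    valid=None,
    peak_offset=None,
    speed_column="speed_cms",
    baseline_frames=BASELINE_FRAMES,
):
    """One response sample per RF-stimulus repetition for one neuron.

    Returns a DataFrame with columns onset_s, row, col, value (summed
    baseline-subtracted dF/F over the 7-frame peak window), block_index,
    block_type and running.
    """
    if peak_offset is None:
        peak_offset = find_peak_offset(dff_neuron, events, frame_times, mask, polarity)
    ev = events[events["polarity"] == polarity]
    in_mask = mask[ev["row"].to_numpy(), ev["col"].to_numpy()]
    ev = ev[in_mask]
    f = event_frames(ev["onset_s"].to_numpy(), frame_times)
    lo = f + peak_offset + PEAK_WINDOW[0]
    hi = f + peak_offset + PEAK_WINDOW[1] + 1
    ok = (f >= baseline_frames) & (lo >= 0) & (hi <= dff_neuron.size)
    if valid is not None:
        ok &= np.asarray(valid)[np.clip(f, 0, len(frame_times) - 1)]
    ev, f, lo, hi = ev[ok].reset_index(drop=True), f[ok], lo[ok], hi[ok]

    n_win = PEAK_WINDOW[1] - PEAK_WINDOW[0] + 1
    values = np.empty(len(ev))
    for i in range(len(ev)):
        base = np.median(dff_neuron[f[i] - baseline_frames : f[i]])
        values[i] = dff_neuron[lo[i] : hi[i]].sum() - n_win * base

    t = ev["onset_s"].to_numpy()
    block_index = np.zeros(len(ev), dtype=int)
    block_type = np.full(len(ev), "none", dtype=object)
    for _, b in blocks.iterrows():
        sel = (t >= b["t_start"]) & (t < b["t_end"])
        block_index[sel] = int(b["block_index"])
        block_type[sel] = b["block_type"]
    speed = behavior[speed_column].to_numpy()
    running = speed[np.clip(f, 0, len(speed) - 1)] >= RUN_SPEED_THRESHOLD

    return pd.DataFrame(
        {
            "onset_s": t,
            "row": ev["row"],
            "col": ev["col"],
            "value": values,
            "block_index": block_index,
            "block_type": block_type,
            "running": running,
        }
    )


def modulation_index(r_a, r_b, n_a=MIN_REPS, n_b=MIN_REPS):
    """(R_A - R_B)/(R_A + R_B); NaN when undefined.

    Undefined when either condition has fewer than MIN_REPS samples or the
    denominator is not positive (net-negative responses).
    """
    if n_a < MIN_REPS or n_b < MIN_REPS:
        return np.nan
    if not np.isfinite(r_a + r_b) or (r_a + r_b) <= 0:
        return np.nan
    return (r_a - r_b) / (r_a + r_b)


def attention_index_a(samples, reverse=False):
    """Attentional modulation of BR blocks relative to TL blocks.

    ``reverse`` flips the sign (assessing TL relative to BR).
    """
    a = samples.loc[samples["block_type"] == "BR", "value"]
    b = samples.loc[samples["block_type"] == "TL", "value"]
    idx = modulation_index(a.mean(), b.mean(), len(a), len(b))
    return -idx if reverse else idx


def attention_index_b(samples_in, samples_out):
    """Attend-in versus attend-out modulation (R_in vs R_out)."""
    a = np.asarray(samples_in, dtype=float)
    b = np.asarray(samples_out, dtype=float)
    return modulation_index(a.mean() if a.size else np.nan,
                            b.mean() if b.size else np.nan, a.size, b.size)


def bootstrap_modulation_p(samples_a, samples_b, n_boot=10_000, seed=0):
    """Bootstrap significance of a difference in mean responses.

    Both sides are resampled with replacement ``n_boot`` times; the
    one-sided p is the fraction of replicates whose mean ordering violates
    the observed ordering, reported two-sided as min(1, 2x).
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("needs >= 3 samples per side")
    obs = a.mean() - b.mean()
    if obs == 0 or (np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]):
        return 1.0
    rng = np.random.default_rng(seed)
    ma = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    mb = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diff = ma - mb
    violations = np.mean(diff <= 0) if obs > 0 else np.mean(diff >= 0)
    return float(min(1.0, 2.0 * violations))


def running_index(samples, n_boot=10_000, seed=0, with_p=True):
    """Running modulation index (running vs stationary) and bootstrap p."""
    a = samples.loc[samples["running"], "value"]
    b = samples.loc[~samples["running"], "value"]
    idx = modulation_index(a.mean() if len(a) else np.nan,
                           b.mean() if len(b) else np.nan, len(a), len(b))
    if not with_p:
        return idx, np.nan
    p = (
        bootstrap_modulation_p(a.to_numpy(), b.to_numpy(), n_boot=n_boot, seed=seed)
        if len(a) >= 3 and len(b) >= 3
        else np.nan
    )
    return idx, p


def running_onset_activity(dff_neuron, speed, frame_rate, n_frames=10, min_onsets=3):
    """Median running-onset response and its signed-rank significance.

    Onsets are transitions to running after at least 1 s of stillness;
    each contributes the mean dF/F over the next ``n_frames`` frames minus
    the median over the ``n_frames`` preceding frames.
    """
    onsets = running_onsets(speed, frame_rate)
    onsets = onsets[(onsets >= n_frames) & (onsets + n_frames <= dff_neuron.size)]
    if len(onsets) < min_onsets:
        return np.nan, np.nan
    deltas = np.array(
        [
            dff_neuron[f : f + n_frames].mean() - np.median(dff_neuron[f - n_frames : f])
            for f in onsets
        ]
    )
    if np.allclose(deltas, 0):
        return 0.0, 1.0
    stat = wilcoxon(deltas)
    return float(np.median(deltas)), float(stat.pvalue)


def split_half_by_stimulus(samples):
    """Half labels (1 or 2) such that each stimulus has equal onset counts.

    Within each (row, col) location, samples ordered by onset time are
    assigned alternately-sized halves: the first ceil(k/2) onsets to half 1
    (an odd repetition count puts the extra onset in the first half).
    """
    half = np.zeros(len(samples), dtype=int)
    order = samples.sort_values("onset_s").index
    s = samples.loc[order]
    for _, sub in s.groupby(["row", "col"], sort=False):
        k = len(sub)
        first = sub.index[: int(np.ceil(k / 2))]
        half[samples.index.get_indexer(first)] = 1
        half[samples.index.get_indexer(sub.index[int(np.ceil(k / 2)) :])] = 2
    return pd.Series(half, index=samples.index)


def _half_mean(samples, block, half_no):
    sub = samples[samples["block_index"] == block]
    if len(sub) == 0:
        return np.nan, 0
    halves = split_half_by_stimulus(sub)
    vals = sub.loc[halves == half_no, "value"]
    return (vals.mean() if len(vals) else np.nan), len(vals)


def within_block_reliability(samples):
    """Attend-in index pairs from the two halves of blocks 1 and 3.

    R_in is the mean response in each half of the block; R_out is the mean
    over the first half of block 2 (for block-1 halves) or the second half
    of block 2 (for block-3 halves).  Returns {block: (index_half1,
    index_half2)}.
    """
    out = {}
    for block, out_half in ((1, 1), (3, 2)):
        r_out, n_out = _half_mean(samples, 2, out_half)
        pair = []
        sub = samples[samples["block_index"] == block]
        halves = split_half_by_stimulus(sub) if len(sub) else None
        for h in (1, 2):
            vals = sub.loc[halves == h, "value"] if halves is not None else []
            pair.append(modulation_index(np.mean(vals) if len(vals) else np.nan,
                                         r_out, len(vals), n_out))
        out[block] = tuple(pair)
    return out


def between_block_reliability(samples):
    """Attend-in indices for block 1 versus block 3.

    R_in is the second half of block 1 and the first half of block 3;
    R_out is the first / second half of block 2 respectively.  Returns
    (index_block1, index_block3).
    """
    r_in1, n1 = _half_mean(samples, 1, 2)
    r_in3, n3 = _half_mean(samples, 3, 1)
    r_out1, m1 = _half_mean(samples, 2, 1)
    r_out3, m2 = _half_mean(samples, 2, 2)
    return (
        modulation_index(r_in1, r_out1, n1, m1),
        modulation_index(r_in3, r_out3, n3, m2),
    )


def running_between_block_reliability(samples, n_boot=0, seed=0):
    """Running modulation index computed separately in blocks 1 and 3."""
    i1, _ = running_index(samples[samples["block_index"] == 1], with_p=False)
    i3, _ = running_index(samples[samples["block_index"] == 3], with_p=False)
    return i1, i3
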