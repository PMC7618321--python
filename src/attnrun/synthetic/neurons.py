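"""Forward model: fluorescence from ground-truth receptive fields.

Each neuron has a rotated-Gaussian receptive field of one polarity.  Every
sparse-noise square matching the neuron's polarity contributes an impulse
of drive equal to the Gaussian evaluated at the square's centre, scaled
multiplicatively by the attentional gain of the task block the square falls
in and by the running gain when the animal is running (speed >= 1 cm/s) at
the onset.  The impulse train is convolved with a single-exponential
calcium kernel (GCaMP6f-like decay, 0.6 s; amplitude 1 dF/F per unit
drive), superimposed on a slowly drifting baseline, and corrupted with
additive Gaussian noise.  Running onsets can inject an additional
transient through the same kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

from attnrun import grid
from attnrun.geometry import ellipse_disk_distance

RUN_SPEED_THRESHOLD = 1.0  # cm/s


@dataclass
class GroundTruth:
    """Per-neuron generative parameters (arrays of length n_neurons)."""

    center_az: np.ndarray
    center_el: np.ndarray
    sigma_major: np.ndarray
    sigma_minor: np.ndarray
    rotation_rad: np.ndarray
    polarity: np.ndarray  # 'white' (ON) or 'black' (OFF)
    amplitude: np.ndarray  # peak dF/F per event at RF centre
    attn_gain_per_block: np.ndarray  # (n_neurons, n_blocks); passive periods use 1
    run_gain: np.ndarray
    onset_amp: np.ndarray  # running-onset transient amplitude (dF/F)
    noise_sd: np.ndarray  # additive noise SD in dF/F units
    f0_base: np.ndarray  # baseline fluorescence (a.u.)
    kernel_tau_s: float = 0.6
    drift_amp: float = 0.05
    drift_period_s: float = 600.0
    trend_amp: float = 0.06

    @property
    def n_neurons(self):
        return len(self.center_az)

    def rf_overlaps(self, location, radius=grid.TASK_DISK_RADIUS):
        """True where the neuron's two-sigma RF ellipse overlaps the disk."""
        out = np.zeros(self.n_neurons, dtype=bool)
        for i in range(self.n_neurons):
            d = ellipse_disk_distance(
                (self.center_az[i], self.center_el[i]),
                (2 * self.sigma_major[i], 2 * self.sigma_minor[i]),
                self.rotation_rad[i],
                location,
                radius,
            )
            out[i] = d <= 0
        return out

    @classmethod
    def population(
        cls,
        n_neurons,
        block_types,
        seed=0,
        rf_location="BR",
        rf_jitter_deg=5.0,
        attn_gain=1.0,
        run_gain=1.0,
        focal=None,
        resample_attn_per_block=False,
        amplitude=(0.4, 0.8),
        sigma_major=(5.0, 8.0),
        aspect=(1.0, 1.6),
        onset_amp=0.0,
        noise_sd=0.08,
        f0_base=(80.0, 120.0),
        **kwargs,
    ):
        """Draw a neuron population with RFs near a task location.

        ``rf_location`` is 'BR', 'TL' or 'uniform' (anywhere on the grid
        with a margin).  ``attn_gain`` and ``run_gain`` are either scalars
        or (lo, hi) ranges sampled per neuron.  The attentional gain is
        applied, in blocks whose type is focally attended (per ``focal``,
        default focal-BR), to neurons whose true two-sigma RF ellipse
        overlaps that block's attended disk; divided-attention blocks apply
        no gain.  With ``resample_attn_per_block`` the gain is drawn
        independently for every block (used for reliability null tests).
        """
        rng = np.random.default_rng(seed)
        focal = focal if focal is not None else {"BR": True, "TL": False}

        if rf_location == "uniform":
            az = rng.uniform(12.5, 97.5, n_neurons)
            el = rng.uniform(-22.5, 22.5, n_neurons)
        else:
            loc = grid.task_location(rf_location)
            az = loc[0] + rng.uniform(-rf_jitter_deg, rf_jitter_deg, n_neurons)
            el = loc[1] + rng.uniform(-rf_jitter_deg, rf_jitter_deg, n_neurons)

        def draw(spec, size=n_neurons):
            if np.isscalar(spec):
                return np.full(size, float(spec))
            return rng.uniform(spec[0], spec[1], size)

        smaj = draw(sigma_major)
        smin = smaj / draw(aspect)
        gt = cls(
            center_az=az,
            center_el=el,
            sigma_major=smaj,
            sigma_minor=smin,
            rotation_rad=rng.uniform(-np.pi / 2, np.pi / 2, n_neurons),
            polarity=rng.choice(["white", "black"], size=n_neurons),
            amplitude=draw(amplitude),
            attn_gain_per_block=np.ones((n_neurons, len(block_types))),
            run_gain=draw(run_gain),
            onset_amp=draw(onset_amp),
            noise_sd=draw(noise_sd),
            f0_base=draw(f0_base),
            **kwargs,
        )
        overlap = {
            bt: gt.rf_overlaps(grid.task_location(bt)) for bt in set(block_types)
        }
        g_shared = draw(attn_gain)
        for b, bt in enumerate(block_types):
            if not focal.get(bt, False):
                continue  # divided attention: no gain anywhere
            g = draw(attn_gain) if resample_attn_per_block else g_shared
            gt.attn_gain_per_block[:, b] = np.where(overlap[bt], g, 1.0)
        return gt


@dataclass
class FluorescenceSet:
    """Neurons x frames fluorescence with the imaging frame clock."""

    F: np.ndarray
    frame_times: np.ndarray
    frame_rate: float = grid.IMAGING_RATE_HZ
    neuron_ids: np.ndarray = None
    F0: np.ndarray = None
    dFF: np.ndarray = None
    true_f0: np.ndarray = field(default=None, repr=False)
    true_dff: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        if self.neuron_ids is None:
            self.neuron_ids = np.arange(self.F.shape[0])


def _gaussian_drive(gt, az, el):
    """(n_events, n_neurons) rotated-Gaussian drive, peak-normalised."""
    dx = az[:, None] - gt.center_az[None, :]
    dy = el[:, None] - gt.center_el[None, :]
    ca = np.cos(gt.rotation_rad)[None, :]
    sa = np.sin(gt.rotation_rad)[None, :]
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return np.exp(
        -0.5 * ((u / gt.sigma_major[None, :]) ** 2 + (v / gt.sigma_minor[None, :]) ** 2)
    )


def running_onsets(speed, frame_rate, threshold=RUN_SPEED_THRESHOLD, min_still_s=1.0):
    """Frame indices where running starts after >= min_still_s of stillness."""
    speed = np.asarray(speed)
    running = speed >= threshold
    min_still = int(np.ceil(min_still_s * frame_rate))
    onsets = []
    for f in range(min_still, len(speed)):
        if running[f] and not running[f - 1] and not running[f - min_still : f].any():
            onsets.append(f)
    return np.asarray(onsets, dtype=int)


def simulate_drifting_trace(
    n_frames=8000,
    frame_rate=grid.IMAGING_RATE_HZ,
    f0_start=100.0,
    f0_end=200.0,
    transient_rate_hz=0.2,
    transient_amp_dff=0.6,
    kernel_tau_s=0.6,
    noise_sd_dff=0.05,
    seed=0,
):
    """Single fluorescence trace with a drifting baseline and sparse transients.

    The baseline ramps linearly from ``f0_start`` to ``f0_end``; calcium
    transients arrive as a Poisson process with exponentially distributed
    amplitudes.  Returns ``(F, true_f0)``; used to characterise the chunked
    baseline estimator against known ground truth.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n_frames) / frame_rate
    true_f0 = f0_start + (f0_end - f0_start) * t / t[-1]
    impulses = np.zeros(n_frames)
    n_tr = rng.poisson(transient_rate_hz * t[-1])
    frames = rng.integers(0, n_frames, size=n_tr)
    np.add.at(impulses, frames, rng.exponential(transient_amp_dff, size=n_tr))
    rho = np.exp(-1.0 / (frame_rate * kernel_tau_s))
    dff = lfilter([1.0], [1.0, -rho], impulses)
    F = true_f0 * (1.0 + dff) + rng.normal(0, noise_sd_dff * true_f0.mean(), n_frames)
    return np.clip(F, 0.0, None), true_f0


def simulate_neurons(
    stimuli,
    blocks,
    behavior,
    ground_truth,
    seed=0,
    frame_rate=grid.IMAGING_RATE_HZ,
    chunk=4000,
):
    """Simulate the fluorescence matrix for a session.

    ``blocks`` is a DataFrame with block_index, block_type, t_start, t_end
    (task blocks only; events outside all task blocks, e.g. the passive
    block, see attentional gain 1).  ``behavior`` must share the frame
    clock with the output.
    """
    gt = ground_truth
    time_s = behavior["time_s"].to_numpy()
    n_frames = len(time_s)
    n = gt.n_neurons
    dt = 1.0 / frame_rate
    events = stimuli.events
    if len(events) and events["onset_s"].max() > time_s[-1] + dt:
        raise ValueError("stimulus clock extends beyond the behavior frame clock")

    # event -> frame (first frame at/after onset), block column, running state
    ev_t = events["onset_s"].to_numpy()
    ev_frame = np.searchsorted(time_s, ev_t - 1e-9, side="left")
    ev_frame = np.clip(ev_frame, 0, n_frames - 1)
    ev_block = np.zeros(len(events), dtype=int)  # 0 = outside task blocks
    for _, b in blocks.iterrows():
        sel = (ev_t >= b["t_start"]) & (ev_t < b["t_end"])
        ev_block[sel] = int(b["block_index"])
    speed = behavior["raw_speed_cms"].to_numpy()
    ev_running = speed[ev_frame] >= RUN_SPEED_THRESHOLD

    impulses = np.zeros((n_frames, n))
    ev_az = events["azimuth_deg"].to_numpy()
    ev_el = events["elevation_deg"].to_numpy()
    ev_pol = events["polarity"].to_numpy()
    gains = np.hstack([np.ones((n, 1)), gt.attn_gain_per_block])  # column 0: outside blocks
    for s in range(0, len(events), chunk):
        sl = slice(s, s + chunk)
        w = _gaussian_drive(gt, ev_az[sl], ev_el[sl])
        w *= (ev_pol[sl][:, None] == gt.polarity[None, :])
        w *= gt.amplitude[None, :]
        w *= gains.T[ev_block[sl]]  # (chunk, n)
        w *= np.where(ev_running[sl][:, None], gt.run_gain[None, :], 1.0)
        np.add.at(impulses, ev_frame[sl], w)

    if np.any(gt.onset_amp > 0):
        for f in running_onsets(speed, frame_rate):
            impulses[f] += gt.onset_amp

    # exponential calcium kernel, amplitude 1 at the onset frame
    rho = np.exp(-dt / gt.kernel_tau_s)
    dff_signal = lfilter([1.0], [1.0, -rho], impulses, axis=0)

    total = time_s[-1] if time_s[-1] > 0 else 1.0
    drift = (
        1.0
        + gt.drift_amp * np.sin(2 * np.pi * time_s / gt.drift_period_s)
        + gt.trend_amp * (time_s / total - 0.5)
    )
    true_f0 = gt.f0_base[None, :] * drift[:, None]
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((n_frames, n)) * (gt.noise_sd * gt.f0_base)[None, :]
    F = true_f0 * (1.0 + dff_signal) + noise
    F = np.clip(F, 0.0, None)

    return FluorescenceSet(
        F=F.T,
        frame_times=time_s,
        frame_rate=frame_rate,
        true_f0=true_f0.T,
        true_dff=dff_signal.T,
    )
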