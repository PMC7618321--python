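import numpy as np
import pandas as pd
import pytest

from attnrun.pipeline import SessionConfig, process_traces
from attnrun.synthetic import make_session


@pytest.fixture(scope="session")
def small_session():
    """A small but complete processed task session shared across tests."""
    session = make_session(
        n_neurons=8,
        n_trials_per_block=6,
        passive_s=60.0,
        seed=7,
        neuron_kwargs={"rf_location": "BR", "attn_gain": 1.5, "run_gain": 1.0},
    )
    process_traces(session, SessionConfig())
    return session


def make_single_event_session(
    amplitude=0.5,
    event_az=36.0,
    event_el=-18.0,
    rf_az=36.0,
    rf_el=-18.0,
    sigma=7.0,
    polarity="white",
    run_gain=1.0,
    speed_value=0.0,
    noise_sd=0.0,
    duration_s=20.0,
    frame_rate=12.85,
):
    """Minimal hand-built stimulus/behavior/ground-truth trio for oracle tests."""
    from attnrun.synthetic.neurons import GroundTruth, simulate_neurons
    from attnrun.synthetic.stimuli import StimulusFrameSet

    events = pd.DataFrame(
        {
            "onset_s": [6.0],
            "row": [0],
            "col": [0],
            "azimuth_deg": [event_az],
            "elevation_deg": [event_el],
            "polarity": [polarity],
        }
    )
    stimuli = StimulusFrameSet(events=events, duration_s=duration_s)
    n_frames = int(duration_s * frame_rate) + 1
    behavior = pd.DataFrame(
        {
            "time_s": np.arange(n_frames) / frame_rate,
            "raw_speed_cms": np.full(n_frames, speed_value),
        }
    )
    gt = GroundTruth(
        center_az=np.array([rf_az]),
        center_el=np.array([rf_el]),
        sigma_major=np.array([sigma]),
        sigma_minor=np.array([sigma]),
        rotation_rad=np.array([0.0]),
        polarity=np.array([polarity]),
        amplitude=np.array([amplitude]),
        attn_gain_per_block=np.ones((1, 0)),
        run_gain=np.array([run_gain]),
        onset_amp=np.array([0.0]),
        noise_sd=np.array([noise_sd]),
        f0_base=np.array([100.0]),
        drift_amp=0.0,
        trend_amp=0.0,
    )
    blocks = pd.DataFrame(columns=["block_index", "block_type", "t_start", "t_end"])
    fluo = simulate_neurons(stimuli, blocks, behavior, gt, seed=0, frame_rate=frame_rate)
    return stimuli, behavior, gt, fluo
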