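import numpy as np
import pandas as pd
import pytest

from crossmodal_eeg.design import generate_design
from crossmodal_eeg.montage import ChannelLayout
from crossmodal_eeg.pipeline import RunConfig, participant_seeds, run_participant
from crossmodal_eeg.preprocess import EpochSet
from crossmodal_eeg.simulate import (
    BlinkConfig,
    CouplingConfig,
    SimulationConfig,
)


@pytest.fixture(scope="session")
def layout():
    return ChannelLayout()


@pytest.fixture(scope="session")
def tiny_design():
    return generate_design(n_trials_per_block=50, seed=7)


@pytest.fixture(scope="session")
def silent_sim():
    """No noise, no blinks, no oscillations: pure evoked forward model."""
    return SimulationConfig(
        pink_noise_uv=0.0,
        white_noise_uv=0.0,
        blink=BlinkConfig(probability=0.0),
        coupling=CouplingConfig(amplitude_uv=0.0),
        subject_sd=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_participant(silent_sim):
    """One participant through the full pipeline with the forward model only."""
    cfg = RunConfig(
        n_participants=1, n_trials_per_block=50, sim=silent_sim,
        run_connectivity=False,
    )
    return run_participant(cfg, 0, participant_seeds(cfg)[0])


@pytest.fixture(name="make_epochs", scope="session")
def make_epochs_fixture():
    return make_epochs


def make_epochs(data, layout, sfreq=500.0, t0_ms=-200.0, events=None):
    """Build an EpochSet directly from an array (trials x channels x time)."""
    n, _, n_t = data.shape
    times = t0_ms + np.arange(n_t) / sfreq * 1000.0
    if events is None:
        events = pd.DataFrame(
            {
                "trial_index": np.arange(n),
                "modality": "A",
                "attended_side": "left",
                "stimulus_side": "left",
                "is_target": False,
                "attention": "attended",
                "condition": "A_att",
            }
        )
    return EpochSet(
        data=np.asarray(data, dtype=float),
        times_ms=times,
        events=events,
        layout=layout,
        sfreq=sfreq,
    )
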