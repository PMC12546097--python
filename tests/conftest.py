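import numpy as np
import pytest

import eegflavor as ef
from eegflavor.dataset import (
    assemble_dataset,
    demographics_frame,
    extract_panel_features,
    ratings_frame,
)


@pytest.fixture(scope="session")
def panel15():
    """The study-scale virtual panel (15 subjects, default conditions),
    simulated and feature-extracted once per test session."""
    config = ef.PanelConfig(n_subjects=15, seed=1)
    subjects, sessions = ef.simulate_panel(config)
    records = extract_panel_features(subjects, sessions)
    demographics = demographics_frame(subjects)
    ratings = ratings_frame(sessions)
    tables = {
        tag: assemble_dataset(records, demographics, ratings, tag)
        for tag in ("Be", "Co", "BeCo")
    }
    return {
        "config": config,
        "subjects": subjects,
        "sessions": sessions,
        "records": records,
        "demographics": demographics,
        "ratings": ratings,
        "tables": tables,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_sine_epoch(freq=10.0, fs=512.0, duration=10.0, amplitude=1.0,
                    channels=("O1", "Oz", "O2")):
    t = np.arange(int(duration * fs)) / fs
    wave = amplitude * np.sin(2 * np.pi * freq * t)
    return ef.Epoch(
        data=np.tile(wave, (len(channels), 1)),
        fs=fs,
        channel_names=list(channels),
        task="BSL",
    )
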