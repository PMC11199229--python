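"""Shared fixtures: small planted worlds reused across test modules."""

import numpy as np
import pytest

from microrest.eegio import segment_conditions
from microrest.simulate import (
    SimulationConfig,
    make_templates,
    render_eeg,
    sample_label_sequence,
)


@pytest.fixture(scope="session")
def small_world():
    """Noiseless 4-class planted world: maps, label plan, recording, datasets.

    16 channels, two (EO + EC) pairs of 10 s blocks at 250 Hz, snr infinite,
    segmented without trimming so planted labels align sample-for-sample.
    """
    config = SimulationConfig(
        n_channels=16,
        k_classes=4,
        block_plan=[("EO", 10.0), ("EC", 10.0)] * 2,
        snr=np.inf,
        seed=5,
    )
    maps = make_templates(16, 4, seed=5)
    blocks, per_condition = sample_label_sequence(config, seed=7)
    recording = render_eeg(blocks, maps, config)
    datasets = segment_conditions(recording, trim=0.0)
    return {
        "config": config,
        "maps": maps,
        "blocks": blocks,
        "per_condition": per_condition,
        "recording": recording,
        "datasets": datasets,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20260929)
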