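import dataclasses

import pytest

from moonwalk import StimulusSpec, generate_sequence


@pytest.fixture(scope="session")
def small_spec() -> StimulusSpec:
    """Desk-scale spec: 96x96 frame, 3-deg center, 0.8 s (60 frames)."""
    return StimulusSpec(
        frame_size_px=(96, 96),
        stimulus_diameter_deg=3.0,
        duration_s=0.8,
        rng_seed=11,
    )


@pytest.fixture(scope="session")
def small_seq(small_spec):
    return generate_sequence(small_spec)


@pytest.fixture(scope="session")
def small_seq_flicker(small_spec):
    return generate_sequence(
        dataclasses.replace(small_spec, surround_temporal_coherence=0.5)
    )
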