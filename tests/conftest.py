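import numpy as np
import pytest

from ratabr.abr_features import ABRRecording
from ratabr.synthetic_data import (
    DEFAULT_FREQUENCIES,
    DEFAULT_TEMPLATES,
    AgeEffect,
    CohortDesign,
    FieldDesign,
)


@pytest.fixture
def templates():
    return DEFAULT_TEMPLATES


@pytest.fixture
def young():
    return AgeEffect.young()


@pytest.fixture
def old():
    return AgeEffect.old()


@pytest.fixture
def small_noiseless_design():
    """Three groups × 2 subjects × 3 frequencies, no noise: fast but complete."""
    freqs = (0.5, 4, 32)
    return CohortDesign(
        groups=[(AgeEffect.young(freqs), 2), (AgeEffect.middle(freqs), 2),
                (AgeEffect.old(freqs), 2)],
        frequencies=freqs,
        noise_sd=0.0,
        seed=7,
    )


@pytest.fixture
def small_field_design():
    return FieldDesign(image_size=(128, 128), n_rings=4, n_puncta=40,
                       background_mean=40, background_sd=8, signal_gain=120)


def make_recording(samples, sampling_rate=25_000.0, onset_index=125,
                   freq_khz=4.0, intensity_db=80.0, subject="s1", group="young"):
    return ABRRecording(
        samples=np.asarray(samples, dtype=float),
        sampling_rate=sampling_rate,
        onset_index=onset_index,
        freq_khz=freq_khz,
        intensity_db=intensity_db,
        subject=subject,
        group=group,
    )


@pytest.fixture
def flat_recording():
    return make_recording(np.zeros(375))
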