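import pytest

from steerecg.core import Recording
from steerecg.simulate import SubjectParams, generate_clean_ecg, generate_noisy_wheel

make_noisy_wheel = generate_noisy_wheel


@pytest.fixture
def subject():
    return SubjectParams("T01", base_hr=70.0, hr_sd=1.2, r_amplitude_ref=1.0,
                         wheel_attenuation=0.5)


@pytest.fixture
def clean_recording(subject):
    """60 s clean reference-channel ECG at 500 Hz with its truth peaks."""
    wave, peaks = generate_clean_ecg(subject, 60.0, 500.0, seed=11)
    rec = Recording(wave, 500.0, "reference", "rest", subject.subject_id)
    return rec, peaks
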