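import numpy as np
import pytest

from gaitsm.io import SENSOR_CONFIGURATIONS, TrialRecording, segment_cycles
from gaitsm.synthetic import SubjectProfile, generate_subject


@pytest.fixture(scope="session")
def lower_cfg():
    return SENSOR_CONFIGURATIONS["lower_legs"]


@pytest.fixture(scope="session")
def pelvis_cfg():
    return SENSOR_CONFIGURATIONS["pelvis"]


@pytest.fixture(scope="session")
def control_recording():
    prof = SubjectProfile.draw("AB01", "AB", 0.0, seed=11, prosthetic_side="none")
    return generate_subject(prof, 14, seed=21)


@pytest.fixture(scope="session")
def patient_recording():
    prof = SubjectProfile.draw("TT01", "TT", 0.6, seed=12, prosthetic_side="left")
    return generate_subject(prof, 20, seed=22)


@pytest.fixture(scope="session")
def patient_cycles(patient_recording, lower_cfg):
    return segment_cycles(patient_recording, "prosthetic", lower_cfg)


def toy_recording(contacts_per_pass, cycle_samples=50, rate=100.0):
    """Minimal single-sensor recording with left contacts laid out per pass.

    Each pass holds the given number of same-side (left) contacts spaced
    ``cycle_samples`` apart; a right contact sits midway between them.
    """
    passes, events = [], []
    cursor = 0
    for n_contacts in contacts_per_pass:
        length = (n_contacts - 1) * cycle_samples + 20
        for k in range(n_contacts):
            idx = cursor + k * cycle_samples
            events.append((idx, "left"))
            if k < n_contacts - 1:
                events.append((idx + cycle_samples // 2, "right"))
        passes.append((cursor, cursor + length))
        cursor += length + 30
    T = cursor
    rng = np.random.default_rng(0)
    rec = TrialRecording(
        participant_id="TOY",
        group="AB",
        rate=rate,
        sensors={"pelvis": rng.normal(0, 1, (6, T))},
        events=sorted(events),
        passes=passes,
        prosthetic_side="none",
    )
    return rec.validate()
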