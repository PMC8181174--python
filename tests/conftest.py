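import numpy as np
import pytest

from advbeat.mitdb import BeatAnnotation, EcgRecord
from advbeat.synthetic import CLASS_EFFECTS, generate_record, sample_subject


@pytest.fixture(scope="session")
def subject_profile():
    return sample_subject(seed=11, subject_id=1)


@pytest.fixture(scope="session")
def small_record(subject_profile):
    """A 30-beat synthetic record with a mixed class sequence."""
    seq = list("N" * 10 + "S" + "N" * 5 + "V" + "N" * 13)
    return generate_record(subject_profile, len(seq), seed=11,
                           class_sequence=seq)


@pytest.fixture
def constant_rr_annotations():
    """R peaks every 300 samples, all normal beats."""
    return [BeatAnnotation(300 * i, "N") for i in range(12)]


@pytest.fixture
def flat_record():
    """A constant-signal record for segmentation arithmetic tests."""
    sig = np.full((5000, 2), 0.25)
    return EcgRecord("flat", 360.0, sig, ("a", "b"))


@pytest.fixture(scope="session")
def class_effects():
    return CLASS_EFFECTS
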