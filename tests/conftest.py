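import numpy as np
import pytest

from thymitrace.study_ingest import CohortConfig, NormalizedSample


@pytest.fixture
def config() -> CohortConfig:
    return CohortConfig()


def make_normalized(times, values, patient_id="P1", dose_index=1):
    """Wrap parallel arrays as normalized samples for the kinetics layer."""
    return [
        NormalizedSample(
            patient_id=patient_id,
            dose_index=dose_index,
            time_since_dose=float(t),
            atom_percent=float(v),
        )
        for t, v in zip(times, values)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
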