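import numpy as np
import pytest

from suddengains.cohort import PatientRecord


def make_record(symptom, patient_id="p0", **kwargs):
    """PatientRecord with a given symptom series and flat other series."""
    s = np.asarray(symptom, dtype=float)
    n = len(s)
    defaults = dict(
        patient_id=patient_id, age=40.0, gender="female",
        months_since_trauma=24.0, trauma_type="interpersonal",
        comorbid_depression=False,
        symptom_series=s,
        process_appraisal_series=np.full(n, 80.0),
        process_memory_series=np.full(n, 50.0),
        depression_series=np.full(n, 20.0),
        anxiety_series=np.full(n, 20.0),
    )
    defaults.update(kwargs)
    return PatientRecord(**defaults)


@pytest.fixture
def step_record():
    """Noiseless flat series with a 12-point step after session 5."""
    series = np.array([30.0] * 6 + [18.0] * 7)
    return make_record(series)
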