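"""Measurement scales used throughout the package.

Each weekly series is a bounded questionnaire total. The symptom scale
emulates a 17-item PTSD questionnaire scored 0-51; the appraisal scale a
short negative trauma-related cognitions inventory (item scores 1-7, so a
22-item total spans 22-154); the memory scale 0-100 intrusion ratings; the
depression and anxiety scales 21-item inventories scored 0-63.
"""

from __future__ import annotations

from typing import NamedTuple


class Scale(NamedTuple):
    lower: float
    upper: float
    integer: bool


#: measure key -> scale bounds
SCALES: dict[str, Scale] = {
    "pds": Scale(0.0, 51.0, True),
    "ptci": Scale(22.0, 154.0, False),
    "mem": Scale(0.0, 100.0, False),
    "dep": Scale(0.0, 63.0, False),
    "anx": Scale(0.0, 63.0, False),
}

#: measure key -> PatientRecord attribute holding its weekly series
MEASURE_ATTR: dict[str, str] = {
    "pds": "symptom_series",
    "ptci": "process_appraisal_series",
    "mem": "process_memory_series",
    "dep": "depression_series",
    "anx": "anxiety_series",
}

#: measures for which a follow-up score exists
FOLLOWUP_MEASURES = ("pds", "dep", "anx")
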