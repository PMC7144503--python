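"""Synthetic cohort generation for sudden-gains analyses.

Generates per-patient weekly symptom trajectories (baseline plus weekly
sessions), coupled cognitive-process series, baseline covariates drawn from
distributions typical of trauma-clinic samples, missingness and dropout.
A configurable fraction of patients carries an embedded step improvement
("true" sudden gain) whose session and magnitude are recorded as ground
truth, so that detection, matching and modelling stages can be validated
against a known data-generating process.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .scales import SCALES, MEASURE_ATTR

#: default absolute-magnitude cutoff for a reliable between-session change
DEFAULT_GAIN_CUTOFF = 6.15

# Baseline symptom severity of the simulated clinic population: moderate to
# severe presentations, kept away from the scale floor/ceiling so embedded
# step changes are never erased by clipping.
BASELINE_MEAN = 34.0
BASELINE_SD = 8.7
BASELINE_RANGE = (15.0, 45.0)

TRAUMA_TYPES = ("interpersonal", "accident_disaster", "harm_to_others", "other")
TRAUMA_TYPE_P = (0.60, 0.20, 0.11, 0.09)

# process-series calibration: intercept and noise multiplier per measure;
# the slope is config.process_coupling (appraisals/memory) or a fixed weak
# coupling (depression/anxiety secondary outcomes, no lead).
PROCESS_PARAMS = {
    "ptci": {"intercept": 28.0, "noise_mult": 2.0},
    "mem": {"intercept": 2.0, "noise_mult": 2.0},
    "dep": {"intercept": 2.0, "noise_mult": 1.2, "coupling": 0.7, "lead": 0},
    "anx": {"intercept": 2.0, "noise_mult": 1.2, "coupling": 0.65, "lead": 0},
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic data-generating process.

    Scores are points on the 0-51 symptom scale unless noted. ``seed``
    drives four documented substreams in fixed order: covariates,
    trajectories, missingness, follow-up.
    """

    n_patients: int
    n_sessions: int = 12
    gain_fraction: float = 0.31
    gain_magnitude_mean: float = 12.3
    gain_magnitude_sd: float = 4.4
    gain_session_range: tuple[int, int] = (2, 10)
    trend_slope_mean: float = 1.2
    trend_slope_sd: float = 0.4
    noise_sd: float = 2.5
    process_coupling: float = 2.0
    process_lead_sessions: int = 1
    missing_rate: float = 0.05
    dropout_hazard: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        for name in ("gain_fraction", "missing_rate", "dropout_hazard"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("gain_magnitude_mean", "gain_magnitude_sd",
                     "trend_slope_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.gain_session_range
        if not (1 <= lo <= hi):
            raise ValueError("gain_session_range must satisfy 1 <= lo <= hi")
        if self.n_sessions < hi + 2:
            raise ValueError(
                "n_sessions must be >= max(gain_session_range) + 2")
        if self.process_lead_sessions < 0:
            raise ValueError("process_lead_sessions must be >= 0")


@dataclass
class PatientRecord:
    """One patient: baseline covariates plus aligned per-session series.

    Series are float arrays of length ``n_sessions + 1`` indexed by session
    (0 = baseline); NaN marks a missing assessment. ``true_gain_session``
    is simulation-only ground truth (the pregain session of the embedded
    step), None for observed data and non-gainers.
    """

    patient_id: str
    age: float
    gender: str
    months_since_trauma: float
    trauma_type: str
    comorbid_depression: bool
    symptom_series: np.ndarray
    process_appraisal_series: np.ndarray
    process_memory_series: np.ndarray
    depression_series: np.ndarray
    anxiety_series: np.ndarray
    followup_symptom: float = np.nan
    followup_depression: float = np.nan
    followup_anxiety: float = np.nan
    true_gain_session: int | None = None
    true_gain_magnitude: float | None = None

    @property
    def n_sessions(self) -> int:
        return len(self.symptom_series) - 1

    def series(self, measure: str) -> np.ndarray:
        return getattr(self, MEASURE_ATTR[measure])

    def validate(self) -> None:
        n = len(self.symptom_series)
        for measure, attr in MEASURE_ATTR.items():
            arr = getattr(self, attr)
            if len(arr) != n:
                raise ValueError(
                    f"{self.patient_id}: {attr} length {len(arr)} != {n}")
            lo, hi = SCALES[measure].lower, SCALES[measure].upper
            vals = arr[np.isfinite(arr)]
            if vals.size and (vals.min() < lo or vals.max() > hi):
                raise ValueError(
                    f"{self.patient_id}: {measure} score outside "
                    f"[{lo}, {hi}]")
        if not np.isfinite(self.symptom_series[0]):
            raise ValueError(f"{self.patient_id}: baseline symptom missing")


def _clip(series: np.ndarray, bounds: tuple[float, float]) -> np.ndarray:
    return np.clip(series, bounds[0], bounds[1])


def embed_gain(series: np.ndarray, pregain_session: int,
               magnitude: float, bounds: tuple[float, float] = (0.0, 51.0),
               ) -> np.ndarray:
    """Lower all scores after ``pregain_session`` by ``magnitude``.

    Scores at sessions <= pregain_session are unchanged; later scores are
    reduced and clipped to the scale bounds.
    """
    series = np.asarray(series, dtype=float)
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if not 0 <= pregain_session < len(series) - 1:
        raise ValueError(
            f"pregain_session {pregain_session} out of range for series of "
            f"length {len(series)}")
    out = series.copy()
    out[pregain_session + 1:] = _clip(out[pregain_session + 1:] - magnitude,
                                      bounds)
    return out


def generate_process_series(symptom_series: np.ndarray, coupling: float,
                            lead: int, noise_sd: float,
                            bounds: tuple[float, float],
                            seed: int | np.random.Generator = 0,
                            intercept: float = 0.0) -> np.ndarray:
    """Process score at t = intercept + coupling * symptom(t + lead) + noise.

    With ``lead`` = 1 a symptom step between sessions N and N+1 appears in
    the process series one session earlier (between N-1 and N), encoding
    temporal precedence of process change. Beyond the end of the symptom
    series the last symptom score is held; missing symptom values propagate.
    """
    if lead < 0:
        raise ValueError("lead must be >= 0")
    if bounds[0] >= bounds[1]:
        raise ValueError("bounds must satisfy lower < upper")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    s = np.asarray(symptom_series, dtype=float)
    n = len(s)
    shifted = s[np.minimum(np.arange(n) + lead, n - 1)]
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    out = intercept + coupling * shifted + noise
    out = np.where(np.isfinite(shifted), _clip(out, bounds), np.nan)
    return out


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate a cohort under ``config``; deterministic given the seed.

    Exactly round(n_patients * gain_fraction) records carry an embedded
    step gain. The symptom trajectory is baseline - cumulative trend -
    step + noise, clipped to the scale and rounded to integer totals.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_cov, rng_traj, rng_miss, rng_fu = (
        np.random.default_rng(s) for s in ss.spawn(4))
    n = config.n_patients
    nsess = config.n_sessions

    # --- covariates (substream 1) ---
    a, b = (18.0 - 38.9) / 11.2, (80.0 - 38.9) / 11.2
    age = stats.truncnorm.rvs(a, b, loc=38.9, scale=11.2, size=n,
                              random_state=rng_cov)
    female = rng_cov.random(n) < 0.43
    months = np.clip(rng_cov.lognormal(np.log(20.0), 1.0, size=n), 1.0, 480.0)
    trauma = rng_cov.choice(TRAUMA_TYPES, size=n, p=TRAUMA_TYPE_P)
    depressed = rng_cov.random(n) < 0.51
    lo_b = (BASELINE_RANGE[0] - BASELINE_MEAN) / BASELINE_SD
    hi_b = (BASELINE_RANGE[1] - BASELINE_MEAN) / BASELINE_SD
    baseline = stats.truncnorm.rvs(lo_b, hi_b, loc=BASELINE_MEAN,
                                   scale=BASELINE_SD, size=n,
                                   random_state=rng_cov)
    n_gain = round(n * config.gain_fraction)
    gain_ids = rng_cov.choice(n, size=n_gain, replace=False)
    lo_s, hi_s = config.gain_session_range
    gain_sessions = rng_cov.integers(lo_s, hi_s + 1, size=n_gain)
    if config.gain_magnitude_sd > 0:
        # embedded events are true sudden gains: magnitudes truncated at the
        # detection cutoff
        a_m = (DEFAULT_GAIN_CUTOFF - config.gain_magnitude_mean) \
            / config.gain_magnitude_sd
        magnitudes = stats.truncnorm.rvs(
            a_m, np.inf, loc=config.gain_magnitude_mean,
            scale=config.gain_magnitude_sd, size=n_gain,
            random_state=rng_cov)
    else:
        magnitudes = np.full(n_gain, float(config.gain_magnitude_mean))
    gain_map = {int(i): (int(s), float(m))
                for i, s, m in zip(gain_ids, gain_sessions, magnitudes)}

    # --- trajectories (substream 2) ---
    records: list[PatientRecord] = []
    pds_bounds = (SCALES["pds"].lower, SCALES["pds"].upper)
    for i in range(n):
        slope = max(0.0, rng_traj.normal(config.trend_slope_mean,
                                         config.trend_slope_sd))
        gain = gain_map.get(i)
        # cap the slope so the noiseless trajectory stays on-scale through
        # the last session (no floor clipping that would erase the step)
        headroom = baseline[i] - 1.0 - (gain[1] if gain else 0.0)
        if headroom > 0:
            slope = min(slope, headroom / nsess)
        else:
            slope = 0.0
        t = np.arange(nsess + 1, dtype=float)
        pds = baseline[i] - slope * t
        if gain is not None:
            pds = embed_gain(pds, gain[0], gain[1], pds_bounds)
        if config.noise_sd > 0:
            noise = rng_traj.normal(0.0, config.noise_sd, size=nsess + 1)
            noise[0] = 0.0  # baseline is the drawn severity
            pds = pds + noise
        pds = np.round(_clip(pds, pds_bounds))

        series = {}
        for measure in ("ptci", "mem", "dep", "anx"):
            p = PROCESS_PARAMS[measure]
            coupling = p.get("coupling", config.process_coupling)
            lead = p.get("lead", config.process_lead_sessions)
            series[measure] = generate_process_series(
                pds, coupling, lead,
                config.noise_sd * p["noise_mult"],
                (SCALES[measure].lower, SCALES[measure].upper),
                seed=rng_traj, intercept=p["intercept"])

        records.append(PatientRecord(
            patient_id=f"p{i:04d}",
            age=float(age[i]),
            gender="female" if female[i] else "male",
            months_since_trauma=float(months[i]),
            trauma_type=str(trauma[i]),
            comorbid_depression=bool(depressed[i]),
            symptom_series=pds,
            process_appraisal_series=series["ptci"],
            process_memory_series=series["mem"],
            depression_series=series["dep"],
            anxiety_series=series["anx"],
            true_gain_session=gain[0] if gain else None,
            true_gain_magnitude=gain[1] if gain else None,
        ))

    # --- missingness (substream 3) ---
    records = apply_missingness(records, config.missing_rate,
                                config.dropout_hazard, rng_miss)

    # --- follow-up (substream 4): collected only from treatment completers
    # (patients observed at the final weekly session) ---
    for rec in records:
        for measure, attr in (("pds", "followup_symptom"),
                              ("dep", "followup_depression"),
                              ("anx", "followup_anxiety")):
            s = rec.series(measure)
            if not np.isfinite(s[-1]):
                setattr(rec, attr, np.nan)
                continue
            fu = s[-1] + rng_fu.normal(0.0, config.noise_sd)
            scale = SCALES[measure]
            fu = float(np.clip(fu, scale.lower, scale.upper))
            if scale.integer:
                fu = float(round(fu))
            setattr(rec, attr, fu)
    return records


def apply_missingness(cohort: list[PatientRecord], missing_rate: float,
                      dropout_hazard: float,
                      seed: int | np.random.Generator = 0,
                      ) -> list[PatientRecord]:
    """Apply MCAR deletion and dropout to post-baseline assessments.

    A missed assessment removes that session's scores on every measure
    (patients skip whole sessions, not single questionnaires); after a
    dropout event every later session is missing. Baseline is never
    removed. Deterministic given the seed.
    """
    for name, rate in (("missing_rate", missing_rate),
                       ("dropout_hazard", dropout_hazard)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    out = []
    for rec in cohort:
        rec = copy.deepcopy(rec)
        nsess = rec.n_sessions
        missing = np.zeros(nsess + 1, dtype=bool)
        for s in range(1, nsess + 1):
            if dropout_hazard > 0 and rng.random() < dropout_hazard:
                missing[s:] = True
                break
        mcar = rng.random(nsess + 1) < missing_rate
        mcar[0] = False
        missing |= mcar
        for attr in MEASURE_ATTR.values():
            arr = getattr(rec, attr).copy()
            arr[missing] = np.nan
            setattr(rec, attr, arr)
        out.append(rec)
    return out


__all__ = [
    "CohortConfig", "PatientRecord", "DEFAULT_GAIN_CUTOFF",
    "generate_cohort", "embed_gain", "generate_process_series",
    "apply_missingness",
]
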