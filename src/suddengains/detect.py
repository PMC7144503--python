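"""Sudden-gain and sudden-loss identification in weekly symptom series.

A sudden gain between consecutive sessions N (pregain) and N+1 (postgain)
must satisfy three joint criteria:

1. absolute magnitude: score_N - score_{N+1} >= cutoff (default 6.15,
   the standard error of the difference from the reliable change index);
2. relative magnitude: the drop is at least 25% of the pregain score;
3. stability: the mean of up to three pre-gain scores (N-2, N-1, N)
   exceeds the mean of up to three post-gain scores (N+1, N+2, N+3) by
   more than t_crit(df) * pooled SD of the two windows, with the critical
   value adjusted for missingness via the two-sample t test
   (df 4 -> 2.776, df 3 -> 3.182, df 2 -> 4.303).

Sudden losses are the mirror events (large stable increases). A gain is
*reversed* if at least 50% of its magnitude is lost later in treatment,
and a reversal is *stable* when it itself meets sudden-loss criteria.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .cohort import DEFAULT_GAIN_CUTOFF, PatientRecord


def _default_critical_values() -> dict[int, float]:
    return {4: 2.776, 3: 3.182, 2: 4.303}


@dataclass(frozen=True)
class GainCriteriaConfig:
    """Tunable parameters of the three detection criteria."""

    cutoff: float = DEFAULT_GAIN_CUTOFF
    relative_fraction: float = 0.25
    critical_values: dict[int, float] = field(
        default_factory=_default_critical_values)
    window_pre: int = 3
    window_post: int = 3
    min_present: int = 2
    candidate_pregain_sessions: tuple[int, int] = (2, 10)

    def validate(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be > 0")
        if not 0.0 < self.relative_fraction < 1.0:
            raise ValueError("relative_fraction must be in (0, 1)")
        if self.min_present < 2:
            raise ValueError("min_present must be >= 2")
        if self.min_present > min(self.window_pre, self.window_post):
            raise ValueError("min_present cannot exceed the window size")
        dfs = sorted(self.critical_values)
        vals = [self.critical_values[d] for d in dfs]
        if any(v <= 0 for v in vals):
            raise ValueError("critical values must be positive")
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ValueError("critical values must decrease with df")

    def critical_value(self, df: int) -> float:
        """Upper 97.5% t quantile for the given window df."""
        if df in self.critical_values:
            return self.critical_values[df]
        return float(sps.t.ppf(0.975, df))


def compute_rci_cutoff(baseline_sd: float, reliability: float) -> float:
    """Standard error of the difference score from the reliable change index.

    s_diff = sd * sqrt(2 * (1 - r)); the packaged default cutoff when no
    parameters are supplied is the constant 6.15 on the 0-51 symptom scale.
    """
    if baseline_sd <= 0:
        raise ValueError("baseline_sd must be > 0")
    if not 0.0 <= reliability <= 1.0:
        raise ValueError("reliability must be in [0, 1]")
    return float(baseline_sd * np.sqrt(2.0 * (1.0 - reliability)))


@dataclass(frozen=True)
class CriteriaResult:
    """Outcome of evaluating the three criteria at one interval."""

    eligible: bool
    c1: bool
    c2: bool
    c3: bool
    df_used: int | None = None
    pooled_sd: float | None = None
    mean_pre: float | None = None
    mean_post: float | None = None
    magnitude: float | None = None

    @property
    def all_met(self) -> bool:
        return self.eligible and self.c1 and self.c2 and self.c3


@dataclass
class SuddenGain:
    """One detected sudden gain (or, sign-flipped, a sudden loss)."""

    patient_id: str
    pregain_session: int
    postgain_session: int
    magnitude: float
    pre_scores: tuple[float, ...]
    post_scores: tuple[float, ...]
    criterion1: bool
    criterion2: bool
    criterion3: bool
    reversed: bool = False
    stable_reversal: bool = False
    regained_by_end: bool = True
    is_primary: bool = False


@dataclass
class SuddenLoss:
    """One detected sudden loss; magnitude is the symptom increase (> 0)."""

    patient_id: str
    pregain_session: int
    postgain_session: int
    magnitude: float
    criterion1: bool
    criterion2: bool
    criterion3: bool


def _windows(series: np.ndarray, n: int, config: GainCriteriaConfig):
    pre = series[max(0, n - config.window_pre + 1): n + 1]
    post = series[n + 1: n + 1 + config.window_post]
    return pre[np.isfinite(pre)], post[np.isfinite(post)]


def _evaluate(series: np.ndarray, n: int, config: GainCriteriaConfig,
              direction: int, scale_max: float = 51.0) -> CriteriaResult:
    """Evaluate the criteria at interval (n, n+1).

    ``direction`` +1 scores decreases (gains), -1 increases (losses).
    Losses are the criteria applied to the reflected series
    (scale_max - score), so their relative criterion compares the rise
    against the reflected pregain score.
    """
    s = np.asarray(series, dtype=float)
    if not (np.isfinite(s[n]) and np.isfinite(s[n + 1])):
        return CriteriaResult(eligible=False, c1=False, c2=False, c3=False)
    pre, post = _windows(s, n, config)
    if len(pre) < config.min_present or len(post) < config.min_present:
        return CriteriaResult(eligible=False, c1=False, c2=False, c3=False)
    drop = direction * (s[n] - s[n + 1])
    c1 = drop >= config.cutoff
    if direction > 0:
        c2 = drop >= config.relative_fraction * s[n]
    else:
        c2 = drop >= config.relative_fraction * (scale_max - s[n])
    mean_pre, mean_post = float(pre.mean()), float(post.mean())
    sd_pre = float(pre.std(ddof=1))
    sd_post = float(post.std(ddof=1))
    pooled_sd = float(np.sqrt((sd_pre ** 2 + sd_post ** 2) / 2.0))
    df = len(pre) + len(post) - 2
    gap = direction * (mean_pre - mean_post)
    if pooled_sd == 0.0:
        c3 = gap > 0.0  # limit of the inequality as pooled_sd -> 0
    else:
        c3 = gap > config.critical_value(df) * pooled_sd
    return CriteriaResult(eligible=True, c1=bool(c1), c2=bool(c2),
                          c3=bool(c3), df_used=df, pooled_sd=pooled_sd,
                          mean_pre=mean_pre, mean_post=mean_post,
                          magnitude=float(drop))


def evaluate_criteria(series: np.ndarray, pregain_session: int,
                      config: GainCriteriaConfig | None = None,
                      ) -> CriteriaResult:
    """Evaluate the three gain criteria at one candidate interval."""
    config = config or GainCriteriaConfig()
    lo, hi = config.candidate_pregain_sessions
    if not lo <= pregain_session <= hi:
        raise ValueError(
            f"pregain_session {pregain_session} outside candidate range "
            f"[{lo}, {hi}]")
    if pregain_session + 1 >= len(series):
        raise ValueError("pregain_session + 1 beyond end of series")
    return _evaluate(series, pregain_session, config, direction=+1)


def identify_sudden_gains(record: PatientRecord,
                          config: GainCriteriaConfig | None = None,
                          ) -> list[SuddenGain]:
    """Scan all candidate pregain sessions and return detected gains.

    The earliest gain is flagged ``is_primary``; reversal status is
    classified for every gain.
    """
    config = config or GainCriteriaConfig()
    config.validate()
    s = np.asarray(record.symptom_series, dtype=float)
    lo, hi = config.candidate_pregain_sessions
    gains: list[SuddenGain] = []
    for n in range(lo, min(hi, len(s) - 2) + 1):
        res = _evaluate(s, n, config, direction=+1)
        if res.all_met:
            pre, post = _windows(s, n, config)
            gains.append(SuddenGain(
                patient_id=record.patient_id,
                pregain_session=n, postgain_session=n + 1,
                magnitude=float(s[n] - s[n + 1]),
                pre_scores=tuple(pre), post_scores=tuple(post),
                criterion1=res.c1, criterion2=res.c2, criterion3=res.c3))
    gains = [classify_reversals(g, record, config) for g in gains]
    if gains:
        gains[0].is_primary = True
    return gains


def identify_sudden_losses(record: PatientRecord,
                           config: GainCriteriaConfig | None = None,
                           ) -> list[SuddenLoss]:
    """Detect sudden losses: the inverse criteria of sudden gains."""
    config = config or GainCriteriaConfig()
    config.validate()
    s = np.asarray(record.symptom_series, dtype=float)
    lo, hi = config.candidate_pregain_sessions
    losses: list[SuddenLoss] = []
    for n in range(lo, min(hi, len(s) - 2) + 1):
        res = _evaluate(s, n, config, direction=-1)
        if res.all_met:
            losses.append(SuddenLoss(
                patient_id=record.patient_id,
                pregain_session=n, postgain_session=n + 1,
                magnitude=float(s[n + 1] - s[n]),
                criterion1=res.c1, criterion2=res.c2, criterion3=res.c3))
    return losses


def classify_reversals(gain: SuddenGain, record: PatientRecord,
                       config: GainCriteriaConfig | None = None,
                       ) -> SuddenGain:
    """Classify reversal, stable reversal, and regained-by-end status.

    A gain is reversed when any later observed score reaches the postgain
    score plus 50% of the magnitude; a stable reversal additionally meets
    sudden-loss criteria at some later interval (any later interval is
    considered, not only the candidate detection range). Regained-by-end
    holds when the last observed score is back below the 50% threshold.
    """
    config = config or GainCriteriaConfig()
    s = np.asarray(record.symptom_series, dtype=float)
    n = gain.pregain_session
    threshold = s[n + 1] + 0.5 * gain.magnitude
    later = s[n + 2:]
    later_obs = later[np.isfinite(later)]
    reversed_flag = bool(later_obs.size and (later_obs >= threshold).any())
    stable = False
    if reversed_flag:
        for m in range(n + 1, len(s) - 1):
            if _evaluate(s, m, config, direction=-1).all_met:
                stable = True
                break
    observed = np.flatnonzero(np.isfinite(s))
    regained = bool(s[observed[-1]] < threshold) if observed.size else False
    gain.reversed = reversed_flag
    gain.stable_reversal = stable
    gain.regained_by_end = regained
    return gain


def extract_values_around_gain(record: PatientRecord, session_n: int,
                               measure: str = "pds") -> np.ndarray:
    """Scores at sessions N-2 ... N+2 aligned to relative position.

    Positions falling before baseline or past the end of the series are
    missing (NaN), as are unobserved assessments.
    """
    series = np.asarray(record.series(measure), dtype=float)
    out = np.full(5, np.nan)
    for i, sess in enumerate(range(session_n - 2, session_n + 3)):
        if 0 <= sess < len(series):
            out[i] = series[sess]
    return out


def report_percentage(numerator: float, denominator: float) -> float:
    """Percentage rounded half-up to two decimals, as printed in reports."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    pct = decimal.Decimal(numerator) / decimal.Decimal(denominator) * 100
    return float(pct.quantize(decimal.Decimal("0.01"),
                              rounding=decimal.ROUND_HALF_UP))


def cohort_gain_summary(cohort: list[PatientRecord],
                        config: GainCriteriaConfig | None = None,
                        gains_by_patient: dict[str, list[SuddenGain]] | None = None,
                        ) -> dict:
    """Cohort-level counts and percentages of sudden-gain outcomes.

    Gainer/multiple-gain percentages use the analyzed-cohort denominator;
    reversal percentages the gainer denominator; regained-by-end the
    reversed denominator. Magnitude statistics are computed over all
    detected gains. Percentages are rounded half-up to two decimals.
    """
    if not cohort:
        raise ValueError("empty cohort")
    config = config or GainCriteriaConfig()
    if gains_by_patient is None:
        gains_by_patient = {rec.patient_id: identify_sudden_gains(rec, config)
                            for rec in cohort}
    per_patient = [g for g in gains_by_patient.values() if g]
    n = len(cohort)
    n_gainers = len(per_patient)
    all_gains = [g for gs in gains_by_patient.values() for g in gs]
    primary = [gs[0] for gs in per_patient]
    n_multiple = sum(len(gs) > 1 for gs in per_patient)
    n_reversed = sum(gs[0].reversed for gs in per_patient)
    n_stable = sum(gs[0].stable_reversal for gs in per_patient)
    n_regained = sum(gs[0].regained_by_end for gs in per_patient
                     if gs[0].reversed)
    magnitudes = np.array([g.magnitude for g in all_gains])
    sessions = [g.pregain_session for g in primary]
    summary = {
        "n_patients": n,
        "n_gainers": n_gainers,
        "pct_gainers": report_percentage(n_gainers, n),
        "total_gains": len(all_gains),
        "n_multiple_gainers": n_multiple,
        "pct_multiple_gainers": report_percentage(n_multiple, n),
        "n_reversed": n_reversed,
        "n_stable_reversals": n_stable,
        "pct_reversed": (report_percentage(n_reversed, n_gainers)
                         if n_gainers else 0.0),
        "pct_stable_reversals": (report_percentage(n_stable, n_gainers)
                                 if n_gainers else 0.0),
        "pct_regained_by_end": (report_percentage(n_regained, n_reversed)
                                if n_reversed else None),
        "mean_gain_magnitude": (float(magnitudes.mean())
                                if magnitudes.size else None),
        "sd_gain_magnitude": (float(magnitudes.std(ddof=1))
                              if magnitudes.size > 1 else None),
        "pregain_session_counts": {
            int(k): int(v) for k, v in
            zip(*np.unique(sessions, return_counts=True))} if sessions else {},
    }
    return summary


__all__ = [
    "GainCriteriaConfig", "CriteriaResult", "SuddenGain", "SuddenLoss",
    "compute_rci_cutoff", "evaluate_criteria", "identify_sudden_gains",
    "identify_sudden_losses", "classify_reversals",
    "extract_values_around_gain", "cohort_gain_summary", "report_percentage",
]
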