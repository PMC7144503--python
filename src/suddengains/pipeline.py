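"""End-to-end pipeline: simulate/read -> detect -> match -> model -> pool.

Mirrors the analysis plan of a two-cohort sudden-gains study: each sample
is a cohort of weekly symptom trajectories; gains are detected per
patient; gainers are matched 1:1 to non-gainers; end-of-treatment and
follow-up outcomes and around-gain process contrasts are estimated per
sample; the per-sample adjusted SMDs are pooled with a fixed-effects
model. All artifacts are CSV plus a JSON run report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortConfig, PatientRecord, generate_cohort
from .detect import (GainCriteriaConfig, cohort_gain_summary,
                     extract_values_around_gain, identify_sudden_gains)
from .matching import MatchedPair, MatchingConfig, balance_diagnostics, \
    match_gainers
from .meta import compute_adjusted_smd, interval_difference_stats, \
    pool_fixed_effects
from .models import fit_adjusted_outcome_model, fit_process_change_model
from .io import cohort_to_wide, read_cohort, write_cohort

log = logging.getLogger("suddengains")

OUTCOME_MEASURES = ("pds", "dep", "anx")
PROCESS_MEASURES = ("ptci", "mem")


@dataclass
class PipelineConfig:
    """Full-run configuration; sub-configs validate themselves."""

    samples: list = field(default_factory=list)  # CohortConfig or CSV path
    criteria: GainCriteriaConfig = field(default_factory=GainCriteriaConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    process_measures: tuple[str, ...] = PROCESS_MEASURES
    outcome_measures: tuple[str, ...] = OUTCOME_MEASURES
    seed: int = 0
    out_dir: str = "suddengains_run"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        kwargs = dict(data)
        samples = []
        for item in kwargs.pop("samples", []):
            samples.append(CohortConfig(**item) if isinstance(item, dict)
                           else item)
        if "criteria" in kwargs:
            kwargs["criteria"] = GainCriteriaConfig(**kwargs["criteria"])
        if "matching" in kwargs:
            m = dict(kwargs["matching"])
            if "covariate_names" in m:
                m["covariate_names"] = tuple(m["covariate_names"])
            kwargs["matching"] = MatchingConfig(**m)
        for key in ("process_measures", "outcome_measures"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(samples=samples, **kwargs)

    def default_samples(self) -> list[CohortConfig]:
        """Two synthetic samples with seeds derived from the run seed."""
        child = np.random.SeedSequence(self.seed).generate_state(2) % (2**31)
        return [CohortConfig(n_patients=248, seed=int(child[0])),
                CohortConfig(n_patients=234, seed=int(child[1]))]


def build_byperson(cohort: list[PatientRecord],
                   gains_by_patient: dict) -> pd.DataFrame:
    """One row per patient: covariates, baselines, gain status, outcomes.

    ``pds_end`` (and dep/anx) is the last observed weekly score;
    ``treatment_length`` the number of observed weekly sessions.
    """
    wide = cohort_to_wide(cohort)
    rows = []
    for rec in cohort:
        gains = gains_by_patient.get(rec.patient_id, [])
        primary = gains[0] if gains else None
        row = {
            "patient_id": rec.patient_id,
            "gainer": bool(gains),
            "n_gains": len(gains),
            "pregain_session": (primary.pregain_session if primary
                                else np.nan),
            "gain_magnitude": primary.magnitude if primary else np.nan,
            "reversed": primary.reversed if primary else False,
            "stable_reversal": primary.stable_reversal if primary else False,
            "treatment_length": int(
                np.isfinite(rec.symptom_series[1:]).sum()),
        }
        for measure in OUTCOME_MEASURES:
            s = rec.series(measure)
            obs = np.flatnonzero(np.isfinite(s))
            row[f"{measure}_end"] = s[obs[-1]] if obs.size else np.nan
        row["pds_fu"] = rec.followup_symptom
        row["dep_fu"] = rec.followup_depression
        row["anx_fu"] = rec.followup_anxiety
        rows.append(row)
    extra = pd.DataFrame(rows)
    keep = (["patient_id", "age", "gender", "months_since_trauma",
             "trauma_type", "comorbid_depression"]
            + [c for c in wide.columns if c.endswith("_s0")]
            + ["true_gain_session"])
    return wide[[c for c in keep if c in wide.columns]].merge(
        extra, on="patient_id")


def build_bygain(gains_by_patient: dict) -> pd.DataFrame:
    rows = []
    for gains in gains_by_patient.values():
        for g in gains:
            rows.append({
                "patient_id": g.patient_id,
                "pregain_session": g.pregain_session,
                "postgain_session": g.postgain_session,
                "magnitude": g.magnitude,
                "reversed": g.reversed,
                "stable_reversal": g.stable_reversal,
                "regained_by_end": g.regained_by_end,
                "is_primary": g.is_primary,
            })
    return pd.DataFrame(rows, columns=[
        "patient_id", "pregain_session", "postgain_session", "magnitude",
        "reversed", "stable_reversal", "regained_by_end", "is_primary"])


def build_around_gain_panel(cohort: list[PatientRecord],
                            pairs: list[MatchedPair],
                            measure: str) -> pd.DataFrame:
    """Long five-position panel for one measure over the matched data set."""
    by_id = {rec.patient_id: rec for rec in cohort}
    rows = []
    for pair in pairs:
        for pid, group in ((pair.gainer_id, 1), (pair.control_id, 0)):
            values = extract_values_around_gain(
                by_id[pid], pair.matched_session, measure)
            for pos, v in zip((-2, -1, 0, 1, 2), values):
                rows.append({"patient_id": pid, "group": group,
                             "position": pos, "value": v})
    return pd.DataFrame(rows)


def analyze_outcomes(byperson: pd.DataFrame,
                     measures=OUTCOME_MEASURES) -> pd.DataFrame:
    """Adjusted end/follow-up group differences per outcome measure."""
    rows = []
    for measure in measures:
        longs = []
        for tp, col in (("end", f"{measure}_end"), ("followup",
                                                    f"{measure}_fu")):
            if col not in byperson.columns:
                continue
            longs.append(pd.DataFrame({
                "patient_id": byperson["patient_id"],
                "timepoint": tp,
                "value": byperson[col],
                "group": byperson["gainer"].astype(int),
                "baseline": byperson[f"{measure}_s0"]}))
        estimates = fit_adjusted_outcome_model(pd.concat(longs), measure)
        for est in estimates:
            rows.append(dataclasses.asdict(est))
    return pd.DataFrame(rows)


def analyze_processes(cohort: list[PatientRecord],
                      pairs: list[MatchedPair], sample_id: str,
                      measures=PROCESS_MEASURES):
    """Per-interval contrasts and adjusted SMD records for one sample."""
    contrast_tables = []
    smd_rows = []
    for measure in measures:
        panel = build_around_gain_panel(cohort, pairs, measure)
        table = fit_process_change_model(panel, measure)
        table.insert(0, "sample_id", sample_id)
        contrast_tables.append(table)
        stats = interval_difference_stats(panel)
        for _, row in table.iterrows():
            sub = stats[stats["interval"] == row["interval"]]
            g = sub[sub["group"] == 1]
            m = sub[sub["group"] == 0]
            if (g.empty or m.empty or not np.isfinite(row["delta1"])
                    or g["n"].iat[0] < 2 or m["n"].iat[0] < 2):
                continue
            rec = compute_adjusted_smd(
                row["delta1"], row["delta2"],
                g["sd_diff"].iat[0], int(g["n"].iat[0]),
                m["sd_diff"].iat[0], int(m["n"].iat[0]),
                sample_id=sample_id, measure=measure,
                interval=row["interval"])
            smd_rows.append(dataclasses.asdict(rec))
    return pd.concat(contrast_tables, ignore_index=True), \
        pd.DataFrame(smd_rows)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a dict with the in-memory artifacts and the run report. With
    no gainers (or no matched pairs) in a sample the model stages are
    skipped with a notice and the corresponding tables stay empty.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    samples = config.samples or config.default_samples()
    notices: list[str] = []
    byperson_all, bygain_all, pairs_all, balance_all = [], [], [], []
    outcomes_all, contrasts_all, smd_all = [], [], []
    summaries = {}

    for k, sample in enumerate(samples, start=1):
        sid = f"s{k}"
        if isinstance(sample, CohortConfig):
            cohort = generate_cohort(sample)
        else:
            cohort = read_cohort(sample)
        log.info("%s: cohort of %d patients", sid, len(cohort))
        write_cohort(cohort, out / f"cohort_{sid}.csv")

        gains = {rec.patient_id: identify_sudden_gains(rec, config.criteria)
                 for rec in cohort}
        summaries[sid] = cohort_gain_summary(cohort, config.criteria, gains)
        byperson = build_byperson(cohort, gains)
        byperson.insert(0, "sample_id", sid)
        byperson_all.append(byperson)
        bygain = build_bygain(gains)
        bygain.insert(0, "sample_id", sid)
        bygain_all.append(bygain)
        log.info("%s: %d gainers, %d gains", sid,
                 summaries[sid]["n_gainers"], summaries[sid]["total_gains"])

        if summaries[sid]["n_gainers"] == 0:
            notices.append(f"{sid}: no sudden gains detected; matching and "
                           "matched analyses skipped")
            pairs = []
        else:
            pairs, unmatched = match_gainers(byperson, config.matching)
            if unmatched:
                notices.append(
                    f"{sid}: {len(unmatched)} gainers left unmatched "
                    f"(no in-caliper candidate): {unmatched}")
            log.info("%s: %d matched pairs", sid, len(pairs))
        summaries[sid]["n_matched_pairs"] = len(pairs)
        summaries[sid]["matched_set_size"] = 2 * len(pairs)
        if pairs:
            pdf = pd.DataFrame([dataclasses.asdict(p) for p in pairs])
            pdf.insert(0, "sample_id", sid)
            pairs_all.append(pdf)
            bal = balance_diagnostics(pairs, byperson,
                                      config.matching.covariate_names)
            bal.insert(0, "sample_id", sid)
            balance_all.append(bal)

        gainers = byperson["gainer"].astype(bool)
        if gainers.sum() >= 2 and (~gainers).sum() >= 2:
            ocs = analyze_outcomes(byperson, config.outcome_measures)
            ocs.insert(0, "sample_id", sid)
            outcomes_all.append(ocs)
        else:
            notices.append(f"{sid}: too few patients per group; outcome "
                           "models skipped")
        if len(pairs) >= 2:
            contrasts, smds = analyze_processes(
                cohort, pairs, sid, config.process_measures)
            contrasts_all.append(contrasts)
            smd_all.append(smds)
        elif pairs:
            notices.append(f"{sid}: fewer than 2 matched pairs; process "
                           "models skipped")

    def _concat(frames, columns=None):
        if frames:
            return pd.concat(frames, ignore_index=True)
        return pd.DataFrame(columns=columns or [])

    artifacts = {
        "byperson": _concat(byperson_all, ["sample_id", "patient_id"]),
        "bygain": _concat(bygain_all, ["sample_id", "patient_id"]),
        "pairs": _concat(pairs_all, ["sample_id", "gainer_id", "control_id"]),
        "balance": _concat(balance_all, ["sample_id", "covariate"]),
        "outcomes": _concat(outcomes_all, ["sample_id", "measure"]),
        "contrasts": _concat(contrasts_all, ["sample_id", "measure"]),
        "smd": _concat(smd_all, ["sample_id", "measure", "interval"]),
    }

    smd_df = artifacts["smd"]
    pooled_rows = []
    if not smd_df.empty:
        from .meta import SMDRecord
        for (measure, interval), sub in smd_df.groupby(
                ["measure", "interval"]):
            recs = [SMDRecord(**row) for row in
                    sub[[f.name for f in dataclasses.fields(SMDRecord)]]
                    .to_dict("records")]
            pe = pool_fixed_effects(recs)
            pooled_rows.append({
                "measure": measure, "interval": interval,
                "beta": pe.beta, "se": pe.se, "ci_low": pe.ci_low,
                "ci_high": pe.ci_high, "p": pe.p,
                "n_samples": len(recs),
                "weights": ";".join(f"{w:.4f}" for w in pe.weights)})
    else:
        notices.append("no SMD records; meta-analysis skipped")
    artifacts["pooled"] = pd.DataFrame(pooled_rows, columns=[
        "measure", "interval", "beta", "se", "ci_low", "ci_high", "p",
        "n_samples", "weights"])

    for name, frame in artifacts.items():
        frame.to_csv(out / f"{name}.csv", index=False)

    cfg_json = json.dumps(_config_to_jsonable(config), sort_keys=True)
    report = {
        "seed": config.seed,
        "version": __version__,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "n_samples": len(samples),
        "summaries": summaries,
        "notices": notices,
        "artifacts": sorted(f"{name}.csv" for name in artifacts),
    }
    (out / "report.json").write_text(json.dumps(report, indent=2))
    (out / "metadata.json").write_text(json.dumps(
        {"seed": config.seed, "config_hash": report["config_hash"],
         "config": json.loads(cfg_json)}, indent=2))
    return {"artifacts": artifacts, "report": report, "out_dir": str(out)}


def _config_to_jsonable(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, dict):
            return {str(k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        if isinstance(obj, Path):
            return str(obj)
        return obj

    return enc(config)


__all__ = ["PipelineConfig", "run_pipeline", "build_byperson",
           "build_bygain", "build_around_gain_panel", "analyze_outcomes",
           "analyze_processes", "OUTCOME_MEASURES", "PROCESS_MEASURES"]
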