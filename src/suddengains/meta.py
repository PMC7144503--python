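"""Adjusted standardized mean differences and fixed-effects pooling.

For one interval around the (matched) gain session, the adjusted SMD is
the model-estimated within-gainer change minus the within-matched change
(delta1 - delta2), divided by the pooled SD of the raw interval
difference scores; its n counts patients with an observed difference
score. Per-sample SMDs are combined with an inverse-variance fixed-
effects model (individuals assumed drawn from one population).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .models import INTERVALS, POSITIONS


@dataclass(frozen=True)
class SMDRecord:
    sample_id: str
    measure: str
    interval: str
    smd: float
    se: float
    n_gain: int
    n_matched: int
    sd_gain: float
    sd_matched: float


@dataclass(frozen=True)
class PooledEffect:
    beta: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    weights: tuple[float, ...]  # per-sample inverse-variance, sum to 1


def compute_adjusted_smd(delta1: float, delta2: float, sd_gain: float,
                         n_gain: int, sd_matched: float, n_matched: int,
                         sample_id: str = "", measure: str = "",
                         interval: str = "", hedges: bool = False,
                         ) -> SMDRecord:
    """Standardize delta1 - delta2 by the pooled difference-score SD.

    se follows the large-sample formula for a two-group standardized
    difference. ``hedges`` applies the small-sample correction factor
    J = 1 - 3 / (4 df - 1) to the SMD (off by default).
    """
    if n_gain < 2 or n_matched < 2:
        raise ValueError("each group needs n >= 2")
    if not all(np.isfinite([delta1, delta2, sd_gain, sd_matched])):
        raise ValueError("inputs must be finite")
    df = n_gain + n_matched - 2
    sp = np.sqrt(((n_gain - 1) * sd_gain ** 2
                  + (n_matched - 1) * sd_matched ** 2) / df)
    if sp == 0:
        raise ZeroDivisionError("pooled difference-score SD is zero")
    smd = (delta1 - delta2) / sp
    if hedges:
        smd *= 1.0 - 3.0 / (4.0 * df - 1.0)
    n = n_gain + n_matched
    se = np.sqrt(n / (n_gain * n_matched) + smd ** 2 / (2.0 * n))
    return SMDRecord(sample_id=sample_id, measure=measure,
                     interval=interval, smd=float(smd), se=float(se),
                     n_gain=n_gain, n_matched=n_matched,
                     sd_gain=float(sd_gain), sd_matched=float(sd_matched))


def pool_fixed_effects(records: list[SMDRecord]) -> PooledEffect:
    """Inverse-variance fixed-effects pooling of per-sample SMDs."""
    if not records:
        raise ValueError("no records to pool")
    smds = np.array([r.smd for r in records])
    w = np.array([1.0 / r.se ** 2 for r in records])
    beta = float(np.sum(w * smds) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(2 * sps.norm.sf(abs(beta) / se))
    return PooledEffect(beta=beta, se=se, ci_low=beta - 1.96 * se,
                        ci_high=beta + 1.96 * se, p=p,
                        weights=tuple(w / np.sum(w)))


def interval_difference_stats(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-interval, per-group raw difference-score statistics.

    ``panel`` is the around-gain long table (columns ``patient_id``,
    ``position``, ``group``, ``value``). For each adjacent-position
    interval and group, reports the n, mean and SD of the per-patient raw
    difference scores (patients with both endpoint scores observed).
    """
    wide = panel.pivot_table(index=["patient_id", "group"],
                             columns="position", values="value",
                             aggfunc="first")
    rows = []
    for label, (a, b) in zip(INTERVALS, zip(POSITIONS, POSITIONS[1:])):
        if a not in wide.columns or b not in wide.columns:
            continue
        diff = wide[b] - wide[a]
        for group, sub in diff.groupby(level="group"):
            obs = sub.dropna()
            rows.append({"interval": label, "group": int(group),
                         "n": int(len(obs)),
                         "mean_diff": float(obs.mean()) if len(obs) else np.nan,
                         "sd_diff": float(obs.std(ddof=1))
                         if len(obs) > 1 else np.nan})
    return pd.DataFrame(rows)


def forest_table(records: list[SMDRecord],
                 pooled: PooledEffect) -> pd.DataFrame:
    """Forest-plot data: one row per sample plus the pooled row.

    Weights are the normalized inverse-variance weights; point sizes in a
    forest plot are proportional to precision, i.e. to these weights.
    """
    rows = [{"label": r.sample_id, "effect": r.smd,
             "ci_low": r.smd - 1.96 * r.se, "ci_high": r.smd + 1.96 * r.se,
             "weight": w} for r, w in zip(records, pooled.weights)]
    rows.append({"label": "pooled", "effect": pooled.beta,
                 "ci_low": pooled.ci_low, "ci_high": pooled.ci_high,
                 "weight": 1.0})
    return pd.DataFrame(rows)


__all__ = [
    "SMDRecord", "PooledEffect", "compute_adjusted_smd",
    "pool_fixed_effects", "interval_difference_stats", "forest_table",
]
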