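"""Random-intercept longitudinal models and logistic predictor screens.

Three analyses share this module:

* adjusted end-of-treatment / follow-up group differences: a linear
  mixed-effects model with categorical time, group, their interaction and
  the baseline score as fixed effects plus a per-patient random intercept,
  estimated by maximum likelihood; Cohen's d standardizes the adjusted
  difference by the pooled baseline SD;
* around-gain process change: the same random-intercept structure on the
  five scores at sessions N-2 ... N+2, time categorical, yielding for each
  adjacent-session interval the within-gainer change (delta1), the
  within-matched change (delta2) and their between-group difference
  (delta3 = delta1 - delta2) as linear contrasts of the fixed effects;
* a univariate/multivariate logistic screen of baseline predictors of
  gain status.

Contrast p-values use the normal approximation to the contrast z.
Patients missing a timepoint contribute their remaining rows through the
likelihood (missing-at-random handling, no imputation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             PerfectSeparationError)

INTERVALS = ("Nm2_Nm1", "Nm1_N", "N_Np1", "Np1_Np2")
POSITIONS = (-2, -1, 0, 1, 2)  # sessions relative to the (matched) gain


@dataclass(frozen=True)
class OutcomeEstimate:
    """Adjusted group difference at one timepoint for one measure."""

    measure: str
    timepoint: str  # "end" or "followup"
    n_gain: int
    n_control: int
    adjusted_difference: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    cohens_d: float
    d_ci_low: float
    d_ci_high: float


def cohens_d(adjusted_difference: float, sd_g1: float, n1: int,
             sd_g2: float, n2: int) -> float:
    """|adjusted difference| over the pooled baseline SD.

    Reported as a magnitude with the convention that a negative adjusted
    difference (gainers lower symptoms) yields a positive d.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd_g1 < 0 or sd_g2 < 0:
        raise ValueError("standard deviations must be >= 0")
    sp = np.sqrt(((n1 - 1) * sd_g1 ** 2 + (n2 - 1) * sd_g2 ** 2)
                 / (n1 + n2 - 2))
    if sp == 0:
        raise ZeroDivisionError("pooled baseline SD is zero")
    return float(abs(adjusted_difference) / sp)


def _fit_lmm(y: pd.Series, X: pd.DataFrame, groups: pd.Series):
    """ML random-intercept fit; OLS fallback on degenerate data.

    With balanced complete data the fixed-effect estimates of the two
    coincide, so the fallback preserves point estimates when the mixed
    model cannot converge (e.g. zero residual variance).
    """
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            res = sm.MixedLM(y, X, groups=groups).fit(reml=False)
        if np.all(np.isfinite(res.params)) and np.all(
                np.isfinite(np.diag(res.cov_params())[:X.shape[1]])):
            return res
    except (np.linalg.LinAlgError, ValueError):
        pass
    return sm.OLS(y, X).fit()


def _contrast(res, X_cols, weights: dict[str, float]):
    """Estimate, SE and normal-approximation p for a fixed-effect contrast."""
    L = np.zeros(len(X_cols))
    for name, w in weights.items():
        L[X_cols.index(name)] += w
    params = np.asarray(res.params)[:len(X_cols)]
    cov = np.asarray(res.cov_params())[:len(X_cols), :len(X_cols)]
    est = float(L @ params)
    se = float(np.sqrt(max(L @ cov @ L, 0.0)))
    if se > 0:
        p = float(2 * sps.norm.sf(abs(est) / se))
    else:
        p = 0.0 if est != 0 else float("nan")
    return est, se, p


def fit_adjusted_outcome_model(outcomes: pd.DataFrame, measure: str = "",
                               ) -> list[OutcomeEstimate]:
    """Adjusted group differences at end of treatment and follow-up.

    ``outcomes`` is long, one row per patient x timepoint, with columns
    ``patient_id``, ``timepoint`` ("end"/"followup"), ``value``, boolean
    ``group`` (1 = gainer) and ``baseline`` (the same measure's baseline
    score, entered as a covariate). Rows with a missing value are dropped;
    remaining rows contribute through the likelihood.
    """
    df = outcomes.dropna(subset=["value", "baseline"]).copy()
    timepoints = [t for t in ("end", "followup")
                  if t in set(df["timepoint"])]
    if not timepoints:
        raise ValueError("no observed timepoints")
    for t in timepoints:
        counts = df[df["timepoint"] == t].groupby("group")["value"].count()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError(
                f"fewer than 2 patients in a group at timepoint '{t}'")
    g = df["group"].astype(float)
    X = pd.DataFrame({"Intercept": 1.0, "group": g}, index=df.index)
    if df["baseline"].nunique() > 1:  # constant baseline is no covariate
        X["baseline"] = df["baseline"].astype(float)
    for t in timepoints[1:]:
        ind = (df["timepoint"] == t).astype(float)
        X[f"time[{t}]"] = ind
        X[f"time[{t}]:group"] = ind * g
    res = _fit_lmm(df["value"].astype(float), X, df["patient_id"])
    cols = list(X.columns)
    out = []
    for t in timepoints:
        weights = {"group": 1.0}
        if t != timepoints[0]:
            weights[f"time[{t}]:group"] = 1.0
        est, se, p = _contrast(res, cols, weights)
        sub = df[df["timepoint"] == t]
        n1 = int((sub["group"] == 1).sum())
        n0 = int((sub["group"] == 0).sum())
        base1 = df.loc[df["group"] == 1, ["patient_id", "baseline"]] \
            .drop_duplicates("patient_id")["baseline"]
        base0 = df.loc[df["group"] == 0, ["patient_id", "baseline"]] \
            .drop_duplicates("patient_id")["baseline"]
        try:
            d = cohens_d(est, float(base1.std(ddof=1)), len(base1),
                         float(base0.std(ddof=1)), len(base0))
        except ZeroDivisionError:  # degenerate (constant) baseline
            d = float("nan")
        se_d = np.sqrt((n1 + n0) / (n1 * n0) + d ** 2 / (2 * (n1 + n0)))
        out.append(OutcomeEstimate(
            measure=measure, timepoint=t, n_gain=n1, n_control=n0,
            adjusted_difference=est, se=se,
            ci_low=est - 1.96 * se, ci_high=est + 1.96 * se, p=p,
            cohens_d=d, d_ci_low=d - 1.96 * se_d, d_ci_high=d + 1.96 * se_d))
    return out


def fit_process_change_model(panel: pd.DataFrame, measure: str = "",
                             ) -> pd.DataFrame:
    """Interval contrasts delta1/delta2/delta3 around the (matched) gain.

    ``panel`` is long with columns ``patient_id``, ``position`` (-2..2,
    sessions relative to the pregain/matched session), ``group`` (1 =
    gainer, 0 = matched control) and ``value``. Returns a ContrastTable:
    one row per adjacent-position interval with each contrast's estimate,
    SE and p-value. Intervals touching a position unobserved for a whole
    group are reported as absent (NaN).
    """
    df = panel.dropna(subset=["value"]).copy()
    cells = df.groupby(["group", "position"])["value"].count()
    usable = [p for p in POSITIONS
              if cells.get((0, p), 0) > 0 and cells.get((1, p), 0) > 0]
    df = df[df["position"].isin(usable)]
    if df.empty or df["group"].nunique() < 2:
        raise ValueError("panel has no usable positions for both groups")
    g = df["group"].astype(float)
    X = pd.DataFrame({"Intercept": 1.0, "group": g}, index=df.index)
    ref = usable[0]
    for p in usable[1:]:
        ind = (df["position"] == p).astype(float)
        X[f"pos[{p}]"] = ind
        X[f"pos[{p}]:group"] = ind * g
    res = _fit_lmm(df["value"].astype(float), X, df["patient_id"])
    cols = list(X.columns)

    def pos_term(p, interacted):
        if p == ref:
            return {}
        name = f"pos[{p}]:group" if interacted else f"pos[{p}]"
        return {name: 1.0}

    rows = []
    for label, (a, b) in zip(INTERVALS, zip(POSITIONS, POSITIONS[1:])):
        row = {"measure": measure, "interval": label,
               "from_position": a, "to_position": b}
        if a not in usable or b not in usable:
            for k in ("delta1", "se1", "p1", "delta2", "se2", "p2",
                      "delta3", "se3", "p3"):
                row[k] = np.nan
            rows.append(row)
            continue
        # delta2: change in the matched group (group = 0)
        w2: dict[str, float] = {}
        for name, v in pos_term(b, False).items():
            w2[name] = w2.get(name, 0.0) + v
        for name, v in pos_term(a, False).items():
            w2[name] = w2.get(name, 0.0) - v
        # delta3: group difference in the change (interaction terms)
        w3: dict[str, float] = {}
        for name, v in pos_term(b, True).items():
            w3[name] = w3.get(name, 0.0) + v
        for name, v in pos_term(a, True).items():
            w3[name] = w3.get(name, 0.0) - v
        # delta1 = delta2 + delta3: change in the sudden-gains group
        w1 = dict(w2)
        for name, v in w3.items():
            w1[name] = w1.get(name, 0.0) + v
        for key, w in (("1", w1), ("2", w2), ("3", w3)):
            est, se, p = _contrast(res, cols, w)
            row[f"delta{key}"], row[f"se{key}"], row[f"p{key}"] = est, se, p
        rows.append(row)
    return pd.DataFrame(rows)


def screen_baseline_predictors(byperson: pd.DataFrame,
                               predictor_names,
                               status_col: str = "gainer",
                               alpha: float = 0.05) -> pd.DataFrame:
    """Univariate and multivariate logistic screen of baseline predictors.

    One univariate fit per predictor; a multivariate fit containing the
    univariately significant predictors. Odds ratios are per unit for
    continuous predictors and versus the reference level for categorical
    ones. Zero-variance predictors are reported as absent with a reason.
    """
    from .matching import _design_matrix

    y = byperson[status_col].astype(float)
    rows = []
    significant = []
    for name in predictor_names:
        X = _design_matrix(byperson, [name])
        keep = X.notna().all(axis=1) & y.notna()
        if X[keep].nunique().min() < 2:
            for col in X.columns:
                rows.append({"model": "univariate", "predictor": col,
                             "odds_ratio": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan,
                             "note": "zero variance"})
            continue
        try:
            fit = sm.Logit(y[keep], sm.add_constant(X[keep])).fit(disp=0)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            for col in X.columns:
                rows.append({"model": "univariate", "predictor": col,
                             "odds_ratio": np.nan, "ci_low": np.nan,
                             "ci_high": np.nan, "p": np.nan,
                             "note": "separation"})
            continue
        any_sig = False
        for col in X.columns:
            ci = fit.conf_int().loc[col]
            p = float(fit.pvalues[col])
            rows.append({"model": "univariate", "predictor": col,
                         "odds_ratio": float(np.exp(fit.params[col])),
                         "ci_low": float(np.exp(ci[0])),
                         "ci_high": float(np.exp(ci[1])), "p": p,
                         "note": ""})
            any_sig |= p < alpha
        if any_sig:
            significant.append(name)
    if significant:
        X = _design_matrix(byperson, significant)
        keep = X.notna().all(axis=1) & y.notna()
        try:
            fit = sm.Logit(y[keep], sm.add_constant(X[keep])).fit(disp=0)
            for col in X.columns:
                ci = fit.conf_int().loc[col]
                rows.append({"model": "multivariate", "predictor": col,
                             "odds_ratio": float(np.exp(fit.params[col])),
                             "ci_low": float(np.exp(ci[0])),
                             "ci_high": float(np.exp(ci[1])),
                             "p": float(fit.pvalues[col]), "note": ""})
        except (PerfectSeparationError, np.linalg.LinAlgError):
            rows.append({"model": "multivariate", "predictor": "",
                         "odds_ratio": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "p": np.nan,
                         "note": "separation"})
    return pd.DataFrame(rows)


__all__ = [
    "OutcomeEstimate", "INTERVALS", "POSITIONS", "cohens_d",
    "fit_adjusted_outcome_model", "fit_process_change_model",
    "screen_baseline_predictors",
]
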