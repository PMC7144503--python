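"""Matched-control construction for sudden gainers.

Each patient with a sudden gain is paired with one similar non-gainer:
a logistic propensity model of gain status on ten baseline covariates
defines calipers on the linear propensity (log-odds), and within the
caliper the nearest non-gainer by Mahalanobis distance on the covariates
is selected greedily without replacement. Each matched control inherits
its gainer's pregain session as a "matched session", aligning the two
patients' timelines for the around-gain analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

DEFAULT_COVARIATES = (
    "age", "gender", "months_since_trauma", "trauma_type",
    "comorbid_depression", "pds_s0", "dep_s0", "anx_s0", "ptci_s0",
    "mem_s0",
)


@dataclass(frozen=True)
class MatchingConfig:
    """Parameters of the propensity-caliper Mahalanobis matching."""

    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES
    caliper_width: float = 0.25
    caliper_scale: str = "logit"  # "logit" or "probability"
    ratio: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.caliper_width <= 0:
            raise ValueError("caliper_width must be > 0")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")
        if self.caliper_scale not in ("logit", "probability"):
            raise ValueError("caliper_scale must be 'logit' or 'probability'")


@dataclass
class MatchedPair:
    gainer_id: str
    control_id: str
    matched_session: int
    mahalanobis_distance: float
    propensity_gainer: float
    propensity_control: float
    lp_gainer: float
    lp_control: float


def _design_matrix(df: pd.DataFrame, covariate_names) -> pd.DataFrame:
    """Numeric design with indicator contrasts for categorical covariates."""
    cols = {}
    for name in covariate_names:
        col = df[name]
        if col.dtype == bool:
            cols[name] = col.astype(float)
        elif col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.dropna().unique())
            for lev in levels[1:]:
                cols[f"{name}[{lev}]"] = (col == lev).astype(float)
        else:
            cols[name] = col.astype(float)
    return pd.DataFrame(cols, index=df.index)


def estimate_propensity(byperson: pd.DataFrame,
                        covariate_names=DEFAULT_COVARIATES,
                        status_col: str = "gainer",
                        ) -> tuple[pd.DataFrame, list]:
    """Logistic propensity of sudden-gain status given baseline covariates.

    Rows with any missing matching covariate are excluded and returned
    separately. Returns a frame indexed like the retained rows with the
    fitted probability (``ps``) and its log-odds (``lp``). Perfect
    separation falls back to a ridge-penalized fit with a warning.
    """
    X = _design_matrix(byperson, covariate_names)
    complete = X.notna().all(axis=1)
    dropped = list(byperson.index[~complete])
    X = X[complete]
    # constant covariates carry no information; keeping them makes the
    # design singular
    X = X.loc[:, X.nunique() > 1]
    y = byperson.loc[complete, status_col].astype(float)
    if y.nunique() < 2:
        raise ValueError("both gainers and non-gainers are required "
                         "to fit the propensity model")
    Xc = sm.add_constant(X, has_constant="add")
    try:
        fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
        lp = np.asarray(Xc @ fit.params, dtype=float)
        if not np.all(np.isfinite(lp)) or not fit.mle_retvals["converged"]:
            raise PerfectSeparationError("propensity fit did not converge")
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        warnings.warn(
            f"propensity fit failed ({type(exc).__name__}); "
            "falling back to a ridge-penalized logistic fit")
        from sklearn.linear_model import LogisticRegression
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.values, y.values)
        lp = clf.decision_function(X.values)
    ps = 1.0 / (1.0 + np.exp(-lp))
    out = pd.DataFrame({"ps": ps, "lp": lp}, index=X.index)
    return out, dropped


def match_gainers(byperson: pd.DataFrame,
                  config: MatchingConfig | None = None,
                  ) -> tuple[list[MatchedPair], list[str]]:
    """Greedy 1:1 (or 1:ratio) caliper matching on Mahalanobis distance.

    ``byperson`` needs one row per patient with a ``patient_id`` column,
    boolean ``gainer``, the gainer's ``pregain_session`` and the matching
    covariates. Gainers are processed in descending linear-propensity
    order (hardest to match first); candidates are the unused non-gainers
    within ``caliper_width`` times the SD of the linear propensity; exact
    distance ties are broken in seeded random order. Returns the pairs and
    the ids of gainers left unmatched.
    """
    config = config or MatchingConfig()
    config.validate()
    df = byperson.set_index("patient_id", drop=False) \
        if byperson.index.name != "patient_id" else byperson
    scores, dropped = estimate_propensity(df, config.covariate_names)
    df = df.loc[scores.index]
    if config.caliper_scale == "logit":
        cal_score = scores["lp"]
    else:
        cal_score = scores["ps"]
    caliper = config.caliper_width * float(cal_score.std(ddof=1))

    X = _design_matrix(df, config.covariate_names)
    # pooled covariance over the full analyzed cohort
    cov = np.cov(X.values, rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    try:
        vi = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance of matching covariates; "
                      "using pseudo-inverse")
        vi = np.linalg.pinv(cov)

    gainers = df.index[df["gainer"].astype(bool)]
    controls = df.index[~df["gainer"].astype(bool)]
    if len(controls) == 0:
        raise ValueError("no eligible controls available")
    rng = np.random.default_rng(config.seed)
    # seeded candidate order breaks exact distance ties deterministically
    control_order = list(rng.permutation(np.asarray(controls, dtype=object)))
    order = scores.loc[gainers, "lp"].sort_values(ascending=False).index

    used: set = set()
    pairs: list[MatchedPair] = []
    unmatched: list[str] = []
    for gid in order:
        xg = X.loc[gid].values
        matched_any = False
        for _ in range(config.ratio):
            best, best_d = None, np.inf
            for cid in control_order:
                if cid in used:
                    continue
                if abs(cal_score[gid] - cal_score[cid]) > caliper:
                    continue
                diff = xg - X.loc[cid].values
                d = float(np.sqrt(diff @ vi @ diff))
                if d < best_d - 1e-12:
                    best, best_d = cid, d
            if best is None:
                break
            used.add(best)
            matched_any = True
            pairs.append(MatchedPair(
                gainer_id=str(gid), control_id=str(best),
                matched_session=int(df.loc[gid, "pregain_session"]),
                mahalanobis_distance=best_d,
                propensity_gainer=float(scores.loc[gid, "ps"]),
                propensity_control=float(scores.loc[best, "ps"]),
                lp_gainer=float(scores.loc[gid, "lp"]),
                lp_control=float(scores.loc[best, "lp"])))
        if not matched_any:
            unmatched.append(str(gid))
    return pairs, unmatched


def balance_diagnostics(pairs: list[MatchedPair], byperson: pd.DataFrame,
                        covariate_names=DEFAULT_COVARIATES,
                        smd_flag: float = 0.1) -> pd.DataFrame:
    """Covariate balance between matched gainers and matched controls.

    Reports group means (proportions for indicator-expanded categorical
    levels), raw mean differences, and standardized mean differences
    (difference over the pooled SD of the two matched groups); rows with
    |SMD| above ``smd_flag`` are flagged.
    """
    if not pairs:
        raise ValueError("no matched pairs")
    df = byperson.set_index("patient_id", drop=False) \
        if byperson.index.name != "patient_id" else byperson
    gid = [p.gainer_id for p in pairs]
    cid = [p.control_id for p in pairs]
    X = _design_matrix(df, covariate_names)
    rows = []
    for col in X.columns:
        a = X.loc[gid, col].astype(float)
        b = X.loc[cid, col].astype(float)
        diff = a.mean() - b.mean()
        sp = np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0)
        smd = diff / sp if sp > 0 else 0.0
        rows.append({"covariate": col, "mean_gainers": a.mean(),
                     "mean_controls": b.mean(), "mean_difference": diff,
                     "smd": smd, "flagged": abs(smd) > smd_flag})
    return pd.DataFrame(rows)


__all__ = [
    "MatchingConfig", "MatchedPair", "DEFAULT_COVARIATES",
    "estimate_propensity", "match_gainers", "balance_diagnostics",
]
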