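"""Mixed-effects models, WBGT aggregation and acceptability summaries.

Two linear mixed-effects specifications are provided, both with a
participant random intercept and maximum-likelihood estimation:

* metric-by-sex: ``Y_ij = b0 + b1*Sex_ij + u_i + e_ij`` (optionally
  adjusted for WBGT), used to compare summary metrics between sexes;
* PSI-by-WBGT: ``PSI = b0 + b1*Sex + b2*WBGT + b3*WBGT*Sex + b4*MVPA
  + b5*PrevNightSleep + b6*BMI + b7*FatMass% + u_i + e_ij``, fitted on
  daytime (06:30-18:30) observations on the natural covariate scale.

Fitting is delegated to statsmodels' ``MixedLM``; confidence intervals use
the normal approximation. Likert items (1 = strongly agree .. 5 = strongly
disagree) are collapsed to high {1,2} / neutral {3} / low {4,5} shares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .core import SensorSeries


@dataclass
class LMEFit:
    """Fixed effects with normal-approximation CIs plus variance components."""

    params: pd.DataFrame          # term, estimate, se, ci_low, ci_high, p
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_groups: int
    converged: bool

    def estimate(self, term: str) -> float:
        return float(self.params.set_index("term").loc[term, "estimate"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.params.set_index("term").loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def covers(self, term: str, value: float) -> bool:
        lo, hi = self.ci(term)
        return lo <= value <= hi


def _fit_mixedlm(formula: str, df: pd.DataFrame, group_col: str) -> LMEFit:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # singular-boundary chatter on degenerate fits
        model = smf.mixedlm(formula, df, groups=df[group_col])
        try:
            res = model.fit(reml=False, method="bfgs")
            bad = (not res.converged) or bool(np.isnan(res.bse_fe).any())
        except np.linalg.LinAlgError:
            res, bad = None, True
        if bad:
            # bfgs occasionally parks the variance on the boundary or walks
            # through a singular region; powell is slower but robust there
            res = model.fit(reml=False, method="powell")
    fe = res.fe_params
    se = res.bse_fe
    z = 1.959963984540054
    rows = []
    for term in fe.index:
        est, s = float(fe[term]), float(se[term])
        p = 2.0 * (1.0 - _norm_cdf(abs(est / s))) if s > 0 else float("nan")
        rows.append({"term": term, "estimate": est, "se": s,
                     "ci_low": est - z * s, "ci_high": est + z * s, "p": p})
    ri_var = float(res.cov_re.iloc[0, 0]) if res.cov_re.size else 0.0
    return LMEFit(pd.DataFrame(rows),
                  random_intercept_sd=float(np.sqrt(max(ri_var, 0.0))),
                  residual_sd=float(np.sqrt(res.scale)),
                  n_obs=int(res.nobs), n_groups=int(res.model.n_groups),
                  converged=bool(res.converged))


def _norm_cdf(x: float) -> float:
    from math import erf, sqrt
    return 0.5 * (1.0 + erf(x / sqrt(2.0)))


def fit_metric_by_sex_lme(df: pd.DataFrame, response: str = "value",
                          adjust_wbgt: bool = False) -> LMEFit:
    """Sex-comparison model for a repeated metric.

    ``df`` must hold ``participant_id``, ``sex`` and the response column
    (plus ``wbgt`` when ``adjust_wbgt``). The sex term is coded
    male=1/female=0, so its estimate is the male-minus-female difference.
    """
    data = df.copy()
    data["male"] = (data["sex"] == "male").astype(int)
    data = data.rename(columns={response: "y"}).dropna(subset=["y"])
    for sex in ("female", "male"):
        sub = data[data["sex"] == sex]
        if sub["participant_id"].nunique() < 2:
            raise ValueError(f"need >= 2 participants of each sex (got too few {sex})")
    if data["y"].nunique() == 1:
        # degenerate constant response: zero effect, zero variances
        base = float(data["y"].iloc[0])
        params = pd.DataFrame([
            {"term": "Intercept", "estimate": base, "se": 0.0,
             "ci_low": base, "ci_high": base, "p": float("nan")},
            {"term": "male", "estimate": 0.0, "se": 0.0,
             "ci_low": 0.0, "ci_high": 0.0, "p": float("nan")},
        ])
        return LMEFit(params, 0.0, 0.0, len(data),
                      data["participant_id"].nunique(), True)
    formula = "y ~ male + wbgt" if adjust_wbgt else "y ~ male"
    return _fit_mixedlm(formula, data, "participant_id")


PSI_MODEL_COLUMNS = ["participant_id", "psi", "sex", "wbgt", "mvpa_hours",
                     "sleep_hours", "bmi", "fat_mass_pct"]


def fit_psi_wbgt_lme(df: pd.DataFrame, restrict_day: bool = True) -> LMEFit:
    """PSI ~ WBGT mixed model with sex interaction and covariates.

    Observations are restricted to the day window (06:30-18:30) when
    timestamps are present; fixed effects are fitted by ML on the natural
    scale so coefficients are directly comparable across studies.
    """
    missing = [c for c in PSI_MODEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"model table missing column(s) {missing}")
    data = df.copy()
    if restrict_day and "timestamp" in data.columns:
        tod = pd.to_datetime(data["timestamp"]).dt.time
        from .core import DAY_END, DAY_START
        data = data[(tod >= DAY_START) & (tod < DAY_END)]
    data["male"] = (data["sex"] == "male").astype(int)
    data = data.dropna(subset=["psi", "wbgt"])
    formula = ("psi ~ male + wbgt + wbgt:male + mvpa_hours + sleep_hours"
               " + bmi + fat_mass_pct")
    return _fit_mixedlm(formula, data, "participant_id")


# ---------------------------------------------------------------------------
# WBGT aggregation


def wbgt_location_daynight(indoor: dict[str, SensorSeries],
                           outdoor: SensorSeries) -> dict[str, pd.DataFrame]:
    """Daily/diurnal WBGT aggregates by location.

    Returns ``daily`` (date x location daily means, day+night pooled),
    ``daynight`` (location x day/night means), ``overall`` (one mean per
    location), and ``hourly_max`` (date x hour maxima of the outdoor
    series, the heat-map surface).
    """
    frames = []
    for hid, s in indoor.items():
        d = s.data.copy()
        d["location"] = "indoor"
        d["unit"] = hid
        frames.append(d)
    od = outdoor.data.copy()
    od["location"] = "outdoor"
    od["unit"] = "station"
    frames.append(od)
    allv = pd.concat(frames, ignore_index=True)
    allv["date"] = allv["timestamp"].dt.normalize()

    # per-unit daily means first, then across units, so households weigh equally
    unit_daily = (allv.groupby(["location", "unit", "date"])["value"]
                  .mean().reset_index())
    daily = (unit_daily.groupby(["location", "date"])["value"]
             .mean().reset_index().rename(columns={"value": "daily_mean"}))
    overall = (daily.groupby("location")["daily_mean"].mean()
               .reset_index().rename(columns={"daily_mean": "overall_daily_mean"}))

    from .core import _day_mask
    allv["is_day"] = _day_mask(allv["timestamp"])
    rows = []
    for loc, grp in allv.groupby("location"):
        rows.append({"location": loc,
                     "day_mean": grp.loc[grp["is_day"], "value"].mean(),
                     "night_mean": grp.loc[~grp["is_day"], "value"].mean()})
    daynight = pd.DataFrame(rows)

    od["hour"] = od["timestamp"].dt.hour
    od["date"] = od["timestamp"].dt.normalize()
    hourly_max = (od.groupby(["date", "hour"])["value"].max()
                  .reset_index().rename(columns={"value": "wbgt_max"}))
    return {"daily": daily, "daynight": daynight, "overall": overall,
            "hourly_max": hourly_max}


# ---------------------------------------------------------------------------
# acceptability


def summarize_likert(responses: pd.DataFrame,
                     stratify_by_sex: bool = False) -> pd.DataFrame:
    """Collapse 1-5 Likert responses into high/neutral/low percentages.

    {1,2} -> high (agreement), {3} -> neutral, {4,5} -> low. Items with no
    responses are omitted with a warning. Percentages are of the stratum's
    respondent count and rounded to integers.
    """
    r = responses["response"]
    if ((r < 1) | (r > 5)).any():
        raise ValueError("Likert responses must lie in 1..5")
    keys = ["device", "item"] + (["sex"] if stratify_by_sex else [])
    rows = []
    for key, grp in responses.groupby(keys):
        n = len(grp)
        if n == 0:
            warnings.warn(f"empty Likert item {key}; omitted", stacklevel=2)
            continue
        high = int(round(100.0 * (grp["response"] <= 2).sum() / n))
        neutral = int(round(100.0 * (grp["response"] == 3).sum() / n))
        low = int(round(100.0 * (grp["response"] >= 4).sum() / n))
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec.update({"pct_high": high, "pct_neutral": neutral, "pct_low": low, "n": n})
        rows.append(rec)
    return pd.DataFrame(rows)


def social_experience_table(responses: pd.DataFrame) -> pd.DataFrame:
    """Counts and integer percentages of yes-responses per device x question,
    for women, men and overall, formatted ``"count (pct%)"``."""
    rows = []
    for (device, question), grp in responses.groupby(["device", "question"]):
        rec = {"device": device, "question": question}
        for stratum, sub in (("women", grp[grp["sex"] == "female"]),
                             ("men", grp[grp["sex"] == "male"]),
                             ("overall", grp)):
            n = len(sub)
            yes = int(sub["response"].sum())
            pct = int(round(100.0 * yes / n)) if n else 0
            rec[stratum] = f"{yes} ({pct}%)"
            rec[f"{stratum}_count"] = yes
            rec[f"{stratum}_n"] = n
        rows.append(rec)
    return pd.DataFrame(rows)
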