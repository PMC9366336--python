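"""Simulated tri-ethnic cohort tables.

Generates per-participant records for three ethnic groups (EU: white European,
SA: South Asian, AC: African Caribbean) with covariate distributions matching
the published demographic table of the emulated study: 120 participants per
group, group-specific means/SDs for age, height, blood pressure, lipids,
prevalences for diabetes, smoking, medication, and Circle-of-Willis variant
frequencies. Imaging outcomes (basilar-artery length and diameter, regional
WMH volumes) are generated from a linear truth model on centred covariates —
WMH volumes log-normally, so that the downstream log-linear model is correctly
specified — and missingness is applied afterwards, missing-at-random
conditioned on observed age.

The effect map and residual SDs are the knobs recovery tests turn: e.g. a
diameter-on-age slope of 11.3 um/year in the SA group with the residual SD
calibrated so the per-group regression CI half-width is ~8.3 um/year.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

GROUPS = ("EU", "SA", "AC")

#: IQR -> SD conversion for a normal distribution.
_IQR_TO_SD = 2.0 * norm.ppf(0.75)  # ~1.349

# Group-level distribution parameters: continuous as (mean, sd),
# skewed imaging variables as (median, q1, q3), prevalences as fractions,
# CoW variant as counts for variants (1, 2, 3).
GROUP_DISTRIBUTIONS: dict[str, dict] = {
    "EU": dict(
        female=0.342, age=(73.6, 5.9), education=(12.3, 3.9),
        height=(169.5, 9.3), weight=(79.4, 13.6),
        ever_smoker=0.467, diabetes=0.133, stroke=1 / 120, chd=8 / 120,
        statin=0.433, antihypertensive=0.400,
        tchol=(4.86, 1.07), hdl=(1.58, 0.49), sbp=(143, 18), dbp=(81, 9.6),
        cow_counts=(85, 25, 10), tiv=(1382.63, 116.01),
        ba_diameter=(2.90, 2.72, 3.10), ba_length=(48.16, 43.94, 54.48),
        wmh_total=(3.16, 1.66, 7.31), wmh_frontal=(1.68, 0.82, 3.88),
        wmh_po=(0.75, 0.47, 2.04),
    ),
    "SA": dict(
        female=0.442, age=(72.9, 6.0), education=(12.6, 3.4),
        height=(162.3, 9.0), weight=(70.5, 11.2),
        ever_smoker=0.025, diabetes=0.292, stroke=1 / 120, chd=14 / 120,
        statin=0.658, antihypertensive=0.717,
        tchol=(4.46, 1.07), hdl=(1.51, 0.40), sbp=(152, 17), dbp=(84, 9.4),
        cow_counts=(81, 33, 6), tiv=(1241.65, 109.49),
        ba_diameter=(2.78, 2.60, 2.96), ba_length=(47.36, 43.00, 51.81),
        wmh_total=(2.50, 1.31, 7.18), wmh_frontal=(1.33, 0.67, 3.92),
        wmh_po=(0.55, 0.28, 1.76),
    ),
    "AC": dict(
        female=0.658, age=(70.5, 8.5), education=(11.7, 3.1),
        height=(163.8, 7.5), weight=(80.8, 14.9),
        ever_smoker=0.175, diabetes=0.242, stroke=3 / 120, chd=0.009,
        statin=0.336, antihypertensive=0.681,
        tchol=(4.89, 1.08), hdl=(1.80, 0.55), sbp=(149, 17.8), dbp=(85, 10.6),
        cow_counts=(80, 25, 15), tiv=(1236.87, 128.23),
        ba_diameter=(2.82, 2.58, 2.96), ba_length=(51.29, 44.80, 56.49),
        wmh_total=(2.80, 1.56, 6.73), wmh_frontal=(1.59, 0.68, 3.81),
        wmh_po=(0.89, 0.41, 2.06),
    ),
}

#: Columns of the generated table (the shipped data dictionary).
COHORT_COLUMNS = [
    "id", "ethnicity", "age_years", "female", "years_education", "height_cm",
    "weight_kg", "ever_smoker", "diabetes", "stroke", "chd", "statin",
    "antihypertensive", "total_cholesterol_mmol_l", "hdl_mmol_l", "sbp_mmhg",
    "dbp_mmhg", "cow_variant", "tiv_ml", "ba_length_mm", "ba_diameter_mm",
    "wmh_total_ml", "wmh_frontal_ml", "wmh_po_ml",
]

OUTCOME_COLUMNS = ("ba_length_mm", "ba_diameter_mm",
                   "wmh_total_ml", "wmh_frontal_ml", "wmh_po_ml")

#: Covariate columns an effect map may reference.
EFFECT_COVARIATES = (
    "age_years", "female", "years_education", "height_cm", "weight_kg",
    "ever_smoker", "diabetes", "stroke", "chd", "statin", "antihypertensive",
    "total_cholesterol_mmol_l", "hdl_mmol_l", "sbp_mmhg", "dbp_mmhg",
    "tiv_ml",
)

_LOG_OUTCOMES = {"wmh_total_ml": "wmh_total", "wmh_frontal_ml": "wmh_frontal",
                 "wmh_po_ml": "wmh_po"}
_LINEAR_OUTCOMES = {"ba_length_mm": "ba_length", "ba_diameter_mm": "ba_diameter"}


def _skewed_params(median, q1, q3):
    """(mu, sigma) of a log-normal matched to median and quartiles."""
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / _IQR_TO_SD
    return mu, sigma


def _normal_from_iqr(median, q1, q3):
    return median, (q3 - q1) / _IQR_TO_SD


@dataclass
class CohortSimSpec:
    """Specification for one simulated cohort draw.

    ``effects`` maps outcome column -> {covariate column: slope} applied to
    every group; ``group_effects`` maps group -> the same structure, added on
    top for that group only. Slopes for BA outcomes are in outcome units per
    covariate unit (mm per year, mm per cm, ...); slopes for WMH outcomes act
    on the natural-log scale (log-mL per covariate unit).

    ``missingness`` maps column -> marginal missing fraction; missingness is
    applied after outcome generation and is missing-at-random given age.
    """

    n_per_group: int = 120
    groups: tuple[str, ...] = GROUPS
    effects: dict[str, dict[str, float]] = field(default_factory=dict)
    group_effects: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    residual_sd: dict[str, float] = field(default_factory=dict)
    missingness: dict[str, float] = field(default_factory=lambda: {
        "total_cholesterol_mmol_l": 0.05, "hdl_mmol_l": 0.05,
        "years_education": 0.03, "sbp_mmhg": 0.02, "dbp_mmhg": 0.02,
    })
    mar_age_coef: float = 0.5  # log-odds of missingness per SD of age
    seed: int = 0

    def validate(self) -> None:
        for src in [self.effects] + list(self.group_effects.values()):
            for outcome, slopes in src.items():
                if outcome not in OUTCOME_COLUMNS:
                    raise ValueError(f"unknown outcome {outcome!r}; "
                                     f"choose from {OUTCOME_COLUMNS}")
                # WMH outcomes may additionally depend on the vessel markers
                # (the large-vessel -> small-vessel-disease link under study)
                allowed = set(EFFECT_COVARIATES)
                if outcome in _LOG_OUTCOMES:
                    allowed |= set(_LINEAR_OUTCOMES)
                for cov in slopes:
                    if cov not in allowed:
                        raise ValueError(
                            f"effect map references unknown covariate {cov!r} "
                            f"for outcome {outcome!r}; known covariates: "
                            f"{sorted(allowed)}")
        for col, rate in self.missingness.items():
            if col not in COHORT_COLUMNS:
                raise ValueError(f"missingness on unknown column {col!r}")
            if not 0 <= rate < 1:
                raise ValueError("missingness rates must be in [0, 1)")


def residual_sd_for_ci_halfwidth(halfwidth: float, covariate_sd: float,
                                 n: int = 120, df: int | None = None) -> float:
    """Residual SD giving a regression CI half-width of ``halfwidth``.

    Inverts halfwidth = t_{0.975,df} * sigma / (sd_x * sqrt(n)), the
    single-covariate approximation (correlated covariates inflate this
    slightly). Used to calibrate simulation noise to a printed CI.
    """
    from scipy.stats import t as t_dist
    df = n - 2 if df is None else df
    tcrit = t_dist.ppf(0.975, df)
    return halfwidth * covariate_sd * np.sqrt(n) / tcrit


def _slopes_for(spec: CohortSimSpec, group: str, outcome: str) -> dict[str, float]:
    s = dict(spec.effects.get(outcome, {}))
    for cov, b in spec.group_effects.get(group, {}).get(outcome, {}).items():
        s[cov] = s.get(cov, 0.0) + b
    return s


def simulate_cohort(spec: CohortSimSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort table; returns (table, truth).

    ``truth`` records, per group and outcome, the slopes actually applied and
    the residual SD used, plus the covariate means subtracted (effects act on
    centred covariates so group-level outcome locations stay at their
    published values).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    frames = []
    truth: dict = {"effects": {}, "residual_sd": {}, "covariate_means": {}}

    for gi, group in enumerate(spec.groups):
        p = GROUP_DISTRIBUTIONS[group]
        n = spec.n_per_group
        d = {}
        d["id"] = [f"{group}{i:04d}" for i in range(n)]
        d["ethnicity"] = group
        d["age_years"] = rng.normal(*p["age"], n)
        d["female"] = (rng.random(n) < p["female"]).astype(int)
        d["years_education"] = np.clip(rng.normal(*p["education"], n), 0, None)
        d["height_cm"] = rng.normal(*p["height"], n)
        d["weight_kg"] = rng.normal(*p["weight"], n)
        for col, key in [("ever_smoker", "ever_smoker"), ("diabetes", "diabetes"),
                         ("stroke", "stroke"), ("chd", "chd"),
                         ("statin", "statin"),
                         ("antihypertensive", "antihypertensive")]:
            d[col] = (rng.random(n) < p[key]).astype(int)
        d["total_cholesterol_mmol_l"] = rng.normal(*p["tchol"], n)
        d["hdl_mmol_l"] = np.clip(rng.normal(*p["hdl"], n), 0.3, None)
        d["sbp_mmhg"] = rng.normal(*p["sbp"], n)
        d["dbp_mmhg"] = rng.normal(*p["dbp"], n)
        cw = np.asarray(p["cow_counts"], float)
        d["cow_variant"] = rng.choice([1, 2, 3], size=n, p=cw / cw.sum())
        d["tiv_ml"] = rng.normal(*p["tiv"], n)

        df = pd.DataFrame(d)

        cov_means = {c: float(df[c].mean()) for c in EFFECT_COVARIATES}
        truth["covariate_means"][group] = cov_means
        truth["effects"][group] = {}
        truth["residual_sd"][group] = {}

        for outcome, key in _LINEAR_OUTCOMES.items():
            mean, sd = _normal_from_iqr(*p[key])
            slopes = _slopes_for(spec, group, outcome)
            res_sd = spec.residual_sd.get(outcome, sd)
            y = mean + rng.normal(0.0, res_sd, n)
            for cov, b in slopes.items():
                y = y + b * (df[cov].to_numpy() - cov_means[cov])
            df[outcome] = y
            truth["effects"][group][outcome] = slopes
            truth["residual_sd"][group][outcome] = res_sd

        for outcome, key in _LOG_OUTCOMES.items():
            mu, sigma = _skewed_params(*p[key])
            slopes = _slopes_for(spec, group, outcome)
            res_sd = spec.residual_sd.get(outcome, sigma)
            logy = mu + rng.normal(0.0, res_sd, n)
            for cov, b in slopes.items():
                centre = cov_means.get(cov, float(df[cov].mean()))
                logy = logy + b * (df[cov].to_numpy() - centre)
            df[outcome] = np.exp(logy)
            truth["effects"][group][outcome] = slopes
            truth["residual_sd"][group][outcome] = res_sd

        frames.append(df)

    table = pd.concat(frames, ignore_index=True)[COHORT_COLUMNS]

    # missing-at-random given age: logit(p_miss) = alpha + coef * z(age),
    # with alpha solved so the marginal rate matches the spec
    z_age = (table["age_years"] - table["age_years"].mean()) / table["age_years"].std()
    z = z_age.to_numpy()
    for col, rate in spec.missingness.items():
        if rate <= 0:
            continue
        beta = spec.mar_age_coef

        def marginal(alpha):
            return expit(alpha + beta * z).mean() - rate

        alpha = brentq(marginal, -30, 30)
        miss = rng.random(len(table)) < expit(alpha + beta * z)
        table.loc[miss, col] = np.nan

    return table, truth
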