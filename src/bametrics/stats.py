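"""Ethnic-stratified cohort statistics.

Implements the analysis design used to compare basilar-artery geometry and
WMH load across three ethnic groups:

* group comparisons — Pearson chi-square for categorical variables, one-way
  ANOVA for continuous confounders, ANCOVA (group F after a-priori covariates
  age, sex and a scale variable) for imaging-derived variables, with
  uncorrected pairwise contrasts gated on the omnibus test;
* the antihypertensive-treatment correction (+10/+5 mmHg to systolic /
  diastolic pressure for treated participants);
* multiple imputation by chained equations (predictive mean matching, fully
  seeded) with Rubin's rules pooling;
* per-group linear regressions of each outcome on the full covariate set
  (Framingham risk-score variables plus diastolic BP, medication, history,
  scale, Circle-of-Willis variant for vessel outcomes, and education), with a
  Cohen's D effect size per covariate derived from the pooled t statistic,
  d = 2t/sqrt(df); WMH outcomes are modelled on the natural-log scale and
  reported as percent change per unit, 100*(exp(beta)-1);
* covariate-adjusted partial Spearman correlations (rank, residualize the
  ranks on the covariate design, correlate the residuals), pooled across
  imputations via Fisher z, reported in percent as in the source tables.

No multiplicity correction is applied anywhere, by design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

# ---------------------------------------------------------------------------
# covariate sets
# ---------------------------------------------------------------------------

#: Variables of the Framingham risk score (as regression covariates).
FRAMINGHAM_COVARIATES = [
    "sbp_mmhg", "total_cholesterol_mmol_l", "hdl_mmol_l", "age_years",
    "female", "ever_smoker", "diabetes",
]

_COMMON_EXTRA = ["dbp_mmhg", "statin", "antihypertensive", "stroke", "chd",
                 "years_education"]

#: Full covariate set for basilar-artery outcomes (scale = height; CoW variant in).
BA_COVARIATES = FRAMINGHAM_COVARIATES + _COMMON_EXTRA + ["height_cm", "cow_variant"]

#: Full covariate set for log-WMH outcomes (scale = TIV; no CoW variant).
WMH_COVARIATES = FRAMINGHAM_COVARIATES + _COMMON_EXTRA + ["tiv_ml"]

BA_OUTCOMES = ("ba_length_mm", "ba_diameter_mm")
WMH_OUTCOMES = ("wmh_total_ml", "wmh_frontal_ml", "wmh_po_ml")

#: Partial-correlation Model 1 adjustment sets (per side of the correlation).
MODEL1_X_COVARIATES = ["age_years", "female", "height_cm", "cow_variant"]  # BA side
MODEL1_Y_COVARIATES = ["age_years", "female", "tiv_ml"]                    # WMH side

#: Extra confounders added on both sides for Model 2.
MODEL2_EXTRA = ["ever_smoker", "diabetes", "total_cholesterol_mmol_l",
                "hdl_mmol_l", "sbp_mmhg", "dbp_mmhg", "statin",
                "antihypertensive", "stroke", "chd", "years_education"]

_CATEGORICAL = {"cow_variant", "ethnicity"}
_BINARY = {"female", "ever_smoker", "diabetes", "stroke", "chd", "statin",
           "antihypertensive"}


# ---------------------------------------------------------------------------
# blood-pressure medication adjustment
# ---------------------------------------------------------------------------

def adjust_bp(sbp, dbp, on_antihypertensive):
    """Add 10/5 mmHg to systolic/diastolic BP for treated participants.

    Element-wise; missing values propagate unchanged. Accepts scalars or
    array-likes (pandas Series included).
    """
    scalar = np.ndim(sbp) == 0 and np.ndim(dbp) == 0 \
        and np.ndim(on_antihypertensive) == 0
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    flag = np.asarray(pd.Series(on_antihypertensive).fillna(0).to_numpy(),
                      dtype=float) > 0
    out_s = np.where(flag, sbp + 10.0, sbp)
    out_d = np.where(flag, dbp + 5.0, dbp)
    if scalar:
        return float(np.ravel(out_s)[0]), float(np.ravel(out_d)[0])
    return out_s, out_d


def apply_bp_adjustment(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of the cohort table with treated BP values corrected."""
    out = table.copy()
    s, d = adjust_bp(out["sbp_mmhg"], out["dbp_mmhg"], out["antihypertensive"])
    out["sbp_mmhg"], out["dbp_mmhg"] = s, d
    return out


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    kind: str
    statistic: float
    df: float | tuple
    p: float
    pairwise: dict[tuple[str, str], float] | None = None
    warnings: list[str] = field(default_factory=list)


def chi_square_from_counts(counts: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    counts = np.asarray(counts, float)
    stat, p, dof, expected = sps.chi2_contingency(counts, correction=False)
    return float(stat), int(dof), float(p)


def compare_groups(table: pd.DataFrame, variable: str, kind: str,
                   adjusters: list[str] | None = None,
                   group_col: str = "ethnicity",
                   alpha: float = 0.05) -> GroupComparison:
    """Omnibus comparison across groups, with pairwise contrasts when p < alpha.

    ``kind`` is one of ``categorical`` (Pearson chi-square on the R x G
    table), ``continuous`` (one-way ANOVA), or ``adjusted-imaging`` (ANCOVA:
    F for group after the a-priori adjusters). Pairwise contrasts use the
    two-group analogue of the omnibus test and are uncorrected.
    """
    warns: list[str] = []
    groups = list(pd.unique(table[group_col]))

    def _omnibus(sub: pd.DataFrame):
        if kind == "categorical":
            ct = pd.crosstab(sub[variable], sub[group_col])
            stat, p, dof, expected = sps.chi2_contingency(ct.to_numpy(),
                                                          correction=False)
            if np.any(expected < 5):
                warns.append(f"{variable}: expected count below 5 in the "
                             "contingency table")
            return float(stat), int(dof), float(p)
        if kind == "continuous":
            arrays = [sub.loc[sub[group_col] == g, variable].dropna()
                      for g in pd.unique(sub[group_col])]
            res = sps.f_oneway(*arrays)
            dof = (len(arrays) - 1, sum(len(a) for a in arrays) - len(arrays))
            return float(res.statistic), dof, float(res.pvalue)
        if kind == "adjusted-imaging":
            if not adjusters:
                raise ValueError("adjusted-imaging comparison needs adjusters")
            terms = " + ".join(adjusters + [f"C({group_col})"])
            fit = smf.ols(f"{variable} ~ {terms}", data=sub).fit()
            aov = sm.stats.anova_lm(fit, typ=2)
            row = aov.loc[f"C({group_col})"]
            return float(row["F"]), (float(row["df"]),
                                     float(aov.loc["Residual", "df"])), \
                float(row["PR(>F)"])
        raise ValueError(f"unknown comparison kind {kind!r}")

    stat, dof, p = _omnibus(table)
    pairwise = None
    if p < alpha and len(groups) > 2:
        pairwise = {}
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                pair = (groups[i], groups[j])
                sub = table[table[group_col].isin(pair)]
                pairwise[pair] = _omnibus(sub)[2]
    return GroupComparison(variable, kind, stat, dof, p, pairwise, warns)


# ---------------------------------------------------------------------------
# multiple imputation (chained equations, predictive mean matching)
# ---------------------------------------------------------------------------

@dataclass
class ImputationSet:
    """m completed copies of a cohort table plus provenance."""

    tables: list[pd.DataFrame]
    m: int
    seed: int
    imputed_columns: list[str]

    def __iter__(self):
        return iter(self.tables)


def _bayes_draw_linear(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw (beta, and beta_hat) for a normal linear model."""
    n, k = X.shape
    XtX = X.T @ X + 1e-8 * np.eye(k)
    beta_hat = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - k, 1)
    sigma2 = resid @ resid / sps.chi2.rvs(df, random_state=rng)
    cov = sigma2 * np.linalg.inv(XtX)
    beta = rng.multivariate_normal(beta_hat, cov, method="cholesky")
    return beta, beta_hat


def impute(table: pd.DataFrame, m: int = 200, seed: int = 0,
           max_missing_fraction: float = 0.4, n_iterations: int = 10,
           pmm_donors: int = 5,
           predictor_columns: list[str] | None = None) -> ImputationSet:
    """Multiple imputation by chained equations with predictive mean matching.

    Each of the ``m`` chains: missing cells are initialized by resampling
    observed values, then each incomplete variable in turn is regressed on all
    other variables, regression parameters are drawn from their approximate
    posterior, and each missing value receives the observed value of a donor
    among the ``pmm_donors`` closest predicted observations. PMM keeps imputed
    binary/categorical values in their observed support, so one sampler serves
    all variable types. Observed values are never altered; everything is
    driven by the single integer ``seed``.
    """
    from .cohort_sim import COHORT_COLUMNS

    default_predictors = [c for c in table.columns
                          if c in COHORT_COLUMNS and c != "id"]
    predictors = predictor_columns or default_predictors

    miss = table.isna()
    incomplete = [c for c in table.columns if miss[c].any()]
    for c in incomplete:
        frac = miss[c].mean()
        if frac == 1.0:
            raise ValueError(f"column {c!r} is entirely missing")
        if frac > max_missing_fraction:
            raise ValueError(f"column {c!r} is {frac:.0%} missing, above the "
                             f"{max_missing_fraction:.0%} cap")

    if not incomplete:
        return ImputationSet([table.copy() for _ in range(m)], m, seed, [])

    order = sorted(incomplete, key=lambda c: miss[c].mean())

    # one design matrix shared by all chained models: intercept + every
    # predictor (categoricals as dummies); per-variable blocks are refreshed
    # in place after each imputation step
    n_rows = len(table)
    blocks: dict[str, slice] = {}
    pieces = [np.ones((n_rows, 1))]
    pos = 1
    dummy_levels: dict[str, np.ndarray] = {}
    for c in predictors:
        if c in _CATEGORICAL:
            levels = np.sort(pd.unique(table[c].dropna()))[1:]  # drop first
            dummy_levels[c] = levels
            block = (table[c].to_numpy()[:, None] == levels[None, :]).astype(float)
        else:
            block = table[c].to_numpy(dtype=float)[:, None]
        blocks[c] = slice(pos, pos + block.shape[1])
        pieces.append(block)
        pos += block.shape[1]
    X_template = np.concatenate(pieces, axis=1)

    def refresh(X, c, values):
        if c in dummy_levels:
            X[:, blocks[c]] = (values[:, None] == dummy_levels[c][None, :])
        else:
            X[:, blocks[c]] = values[:, None]

    miss_np = {c: miss[c].to_numpy() for c in order}
    obs_vals = {c: table.loc[~miss[c], c].to_numpy(dtype=float) for c in order}
    # all incomplete columns handled as float; PMM donors keep the support of
    # binary/categorical variables intact
    col_values = {c: table[c].to_numpy(dtype=float, copy=True) for c in order}

    seeds = np.random.SeedSequence(seed).spawn(m)
    tables = []
    for chain in range(m):
        rng = np.random.default_rng(seeds[chain])
        X = X_template.copy()
        current = {c: col_values[c].copy() for c in order}
        for c in order:
            current[c][miss_np[c]] = rng.choice(obs_vals[c],
                                                size=int(miss_np[c].sum()))
            if c in blocks:
                refresh(X, c, current[c])
        for _ in range(n_iterations):
            for c in order:
                mcol = miss_np[c]
                keep = [j for v, sl in blocks.items() if v != c
                        for j in range(sl.start, sl.stop)]
                cols_idx = np.array([0] + keep)
                X_obs = X[~mcol][:, cols_idx]
                X_mis = X[mcol][:, cols_idx]
                y_obs = obs_vals[c]
                beta, beta_hat = _bayes_draw_linear(X_obs, y_obs, rng)
                pred_obs = X_obs @ beta_hat
                pred_mis = X_mis @ beta
                # predictive mean matching: donor among k nearest predictions
                dist = np.abs(pred_obs[None, :] - pred_mis[:, None])
                k = min(pmm_donors, len(y_obs))
                donors = np.argpartition(dist, k - 1, axis=1)[:, :k]
                pick = donors[np.arange(len(pred_mis)),
                              rng.integers(0, k, len(pred_mis))]
                current[c][mcol] = y_obs[pick]
                if c in blocks:
                    refresh(X, c, current[c])
        df = table.copy()
        for c in order:
            df[c] = current[c]
        tables.append(df)
    return ImputationSet(tables, m, seed, order)


# ---------------------------------------------------------------------------
# Rubin's rules
# ---------------------------------------------------------------------------

def pool_rubin(estimates: np.ndarray, variances: np.ndarray,
               df_complete: float) -> pd.DataFrame:
    """Pool per-imputation estimates and variances by Rubin's rules.

    Total variance T = W + (1 + 1/m) B; degrees of freedom by the
    Barnard-Rubin small-sample correction. With m = 1 the pooled result
    equals the single fit. Rows follow the parameter axis of the inputs.
    """
    q = np.atleast_2d(np.asarray(estimates, float))      # (m, k)
    u = np.atleast_2d(np.asarray(variances, float))
    m = q.shape[0]
    qbar = q.mean(axis=0)
    w = u.mean(axis=0)
    if m > 1:
        b = q.var(axis=0, ddof=1)
    else:
        b = np.zeros_like(qbar)
    t_var = w + (1.0 + 1.0 / m) * b
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(t_var > 0, (1.0 + 1.0 / m) * b / t_var, 0.0)
        lam = np.clip(r, 0.0, 1.0 - 1e-12)
        df_old = np.where(lam > 0, (m - 1) / lam ** 2, np.inf)
        df_obs = (df_complete + 1) / (df_complete + 3) * df_complete * (1 - lam)
        df_br = np.where(np.isinf(df_old), df_obs,
                         1.0 / (1.0 / df_old + 1.0 / df_obs))
        # no between-imputation variance (incl. m = 1): identical to one fit
        df = np.where(b <= 0, df_complete, df_br)
    se = np.sqrt(t_var)
    tstat = np.where(se > 0, qbar / se, np.inf * np.sign(qbar))
    p = 2 * sps.t.sf(np.abs(tstat), df)
    tcrit = sps.t.ppf(0.975, df)
    return pd.DataFrame({
        "estimate": qbar, "se": se, "t": tstat, "df": df, "p": p,
        "ci_low": qbar - tcrit * se, "ci_high": qbar + tcrit * se,
        "between_var": b, "within_var": w,
    })


# ---------------------------------------------------------------------------
# per-group regression models
# ---------------------------------------------------------------------------

@dataclass
class RegressionReport:
    group: str
    outcome: str
    n: int
    m: int
    log_scale: bool
    table: pd.DataFrame  # per covariate: estimate, CI, p, cohen_d (+ percent_*)


def percent_effect(beta):
    """Percent change per covariate unit for a natural-log-scale coefficient."""
    return 100.0 * np.expm1(np.asarray(beta, float))


def percent_to_beta(pct):
    """Inverse of :func:`percent_effect`."""
    return np.log1p(np.asarray(pct, float) / 100.0)


def _design_formula(outcome_term: str, covariates: list[str]) -> str:
    terms = [f"C({c})" if c in _CATEGORICAL else c for c in covariates]
    return f"{outcome_term} ~ " + " + ".join(terms)


def fit_group_models(imputations: ImputationSet, outcome: str,
                     covariates: list[str] | None = None,
                     group: str = "SA",
                     group_col: str = "ethnicity") -> RegressionReport:
    """OLS of one outcome on the covariate set within one group, Rubin-pooled.

    WMH outcomes are log-transformed before fitting and additionally reported
    as percent change per covariate unit. Cohen's D per covariate is derived
    from the pooled t statistic as d = 2t/sqrt(df_residual). Raises on a
    rank-deficient design, naming the collinear columns.
    """
    log_scale = outcome in WMH_OUTCOMES
    if covariates is None:
        covariates = WMH_COVARIATES if log_scale else BA_COVARIATES

    # a covariate (near-)constant within the group — zero or one stroke event,
    # say — carries no estimable information there; drop it rather than fit a
    # degenerate design
    first = imputations.tables[0]
    sub0 = first[first[group_col] == group]
    kept = []
    for c in covariates:
        counts = sub0[c].value_counts()
        degenerate = len(counts) < 2 or (c in _BINARY
                                         and counts.min() < 2)
        if degenerate:
            warnings.warn(f"covariate {c!r} is (near-)constant in group "
                          f"{group}; dropped from the model")
        else:
            kept.append(c)
    covariates = kept

    outcome_term = f"np.log({outcome})" if log_scale else outcome
    formula = _design_formula(outcome_term, covariates)

    params, variances = [], []
    n = df_resid = None
    names = None
    for tab in imputations:
        sub = tab[tab[group_col] == group]
        fit = smf.ols(formula, data=sub).fit()
        exog = fit.model.exog
        scaled = exog / np.maximum(np.linalg.norm(exog, axis=0, keepdims=True),
                                   1e-300)
        rank = np.linalg.matrix_rank(scaled, tol=1e-8)
        if rank < exog.shape[1]:
            corr = pd.DataFrame(fit.model.exog,
                                columns=fit.model.exog_names).corr().abs()
            np.fill_diagonal(corr.values, 0)
            bad = corr.stack().idxmax()
            raise ValueError(f"rank-deficient design for {outcome} in {group}; "
                             f"most collinear columns: {bad}")
        params.append(fit.params.to_numpy())
        variances.append(fit.bse.to_numpy() ** 2)
        names = list(fit.params.index)
        n = int(fit.nobs)
        df_resid = float(fit.df_resid)
    pooled = pool_rubin(np.asarray(params), np.asarray(variances), df_resid)
    pooled.index = names
    pooled["cohen_d"] = 2.0 * pooled["t"] / np.sqrt(df_resid)
    if log_scale:
        for col, src in [("percent_per_unit", "estimate"),
                         ("percent_ci_low", "ci_low"),
                         ("percent_ci_high", "ci_high")]:
            pooled[col] = percent_effect(pooled[src])
    return RegressionReport(group=group, outcome=outcome, n=n,
                            m=imputations.m, log_scale=log_scale, table=pooled)


# ---------------------------------------------------------------------------
# partial Spearman correlation
# ---------------------------------------------------------------------------

@dataclass
class PartialCorrelationResult:
    group: str
    x: str
    y: str
    model: int | None
    rho: float          # on [-1, 1]
    rho_pct: float      # as reported: percent
    p: float
    n: int
    m: int


def _rank_design(sub: pd.DataFrame, covariates: list[str]) -> np.ndarray:
    cols = [np.ones(len(sub))]
    for c in covariates:
        if c in _CATEGORICAL:
            dummies = pd.get_dummies(sub[c], prefix=c, drop_first=True)
            cols.extend(dummies.to_numpy(dtype=float).T)
        elif c in _BINARY:
            cols.append(sub[c].to_numpy(dtype=float))
        else:
            cols.append(sps.rankdata(sub[c].to_numpy(dtype=float)))
    return np.stack(cols, axis=1)


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    coef, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ coef


def partial_spearman(imputations: ImputationSet, x: str, y: str,
                     covariates: list[str] | None = None,
                     x_covariates: list[str] | None = None,
                     y_covariates: list[str] | None = None,
                     group: str = "SA", group_col: str = "ethnicity",
                     model: int | None = None) -> PartialCorrelationResult:
    """Covariate-adjusted partial Spearman correlation, pooled over imputations.

    Within each completed table: average-rank x, y and the continuous
    covariates, residualize the ranks of x on the x-side design and of y on
    the y-side design, and correlate the residuals. With no covariates this
    reduces exactly to the plain Spearman coefficient. Pooling is by mean
    Fisher z; the p-value uses the t approximation with
    df = n - 2 - #covariates.
    """
    x_cov = x_covariates if x_covariates is not None else (covariates or [])
    y_cov = y_covariates if y_covariates is not None else (covariates or [])

    zs = []
    n = None
    for tab in imputations:
        sub = tab[tab[group_col] == group]
        xv = sub[x].to_numpy(dtype=float)
        yv = sub[y].to_numpy(dtype=float)
        if np.allclose(xv, xv[0]) or np.allclose(yv, yv[0]):
            raise ValueError(f"constant variable in partial Spearman: "
                             f"{x if np.allclose(xv, xv[0]) else y}")
        rx = sps.rankdata(xv)
        ry = sps.rankdata(yv)
        ex = _residualize(rx, _rank_design(sub, x_cov)) if x_cov else rx - rx.mean()
        ey = _residualize(ry, _rank_design(sub, y_cov)) if y_cov else ry - ry.mean()
        rho_i = float(np.corrcoef(ex, ey)[0, 1])
        rho_i = np.clip(rho_i, -1 + 1e-12, 1 - 1e-12)
        zs.append(np.arctanh(rho_i))
        n = len(sub)
    rho = float(np.tanh(np.mean(zs)))
    k = max(len(x_cov), len(y_cov))
    df = n - 2 - k
    if df <= 0:
        raise ValueError("not enough observations for the partial correlation")
    tstat = rho * np.sqrt(df / max(1.0 - rho ** 2, 1e-12))
    p = float(2 * sps.t.sf(abs(tstat), df))
    return PartialCorrelationResult(group=group, x=x, y=y, model=model,
                                    rho=rho, rho_pct=100.0 * rho, p=p,
                                    n=n, m=imputations.m)


def model1_model2_suite(imputations: ImputationSet, group: str,
                        group_col: str = "ethnicity") -> pd.DataFrame:
    """The 2 markers x 3 WMH regions x 2 adjustment models grid for one group.

    Model 1 adjusts the vessel marker for age, sex, height and CoW variant and
    the WMH volume for age, sex and TIV; Model 2 adds the demographic and
    cardiovascular confounders on both sides. Returns a tidy 12-row table.
    """
    rows = []
    for x in BA_OUTCOMES:
        for y in WMH_OUTCOMES:
            for model in (1, 2):
                x_cov = list(MODEL1_X_COVARIATES)
                y_cov = list(MODEL1_Y_COVARIATES)
                if model == 2:
                    x_cov += MODEL2_EXTRA
                    y_cov += MODEL2_EXTRA
                res = partial_spearman(imputations, x=x, y=y,
                                       x_covariates=x_cov, y_covariates=y_cov,
                                       group=group, group_col=group_col,
                                       model=model)
                rows.append({"group": group, "model": model, "x": x, "y": y,
                             "rho_pct": res.rho_pct, "p": res.p, "n": res.n})
    return pd.DataFrame(rows)
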