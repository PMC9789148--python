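"""Odds-ratio models for the selected gait variables.

Three model families, all on the assembled analysis table:

* binary logistic regression of mild unilateral walking pain vs no pain --
  unadjusted (gait variables only, treated jointly as the exposure) and
  adjusted (adding age, sex, race/site, BMI, CES-D and the radiographic OA
  count, whether or not selection picked them);
* a generalized-logit multinomial model for the 3-category outcome
  (mild vs no pain, moderate/severe vs no pain), used when the
  proportional-odds assumption fails;
* collinearity diagnostics (pairwise correlations, tolerance, VIF,
  eigenvalues and condition indices) with the conventional flags
  |r| > 0.80, tolerance < 0.10, VIF > 10.

Continuous predictors are expected standardized, so every OR is per sd.
Confidence intervals are Wald intervals on the log-odds scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ConfigError, InsufficientDataError

__all__ = [
    "ADJUSTMENT_COVARIATES",
    "AssociationReport",
    "fit_binary_logistic",
    "collinearity_diagnostics",
    "fit_multinomial_sensitivity",
    "proportional_odds_check",
]

log = logging.getLogger(__name__)

#: confounders always present in adjusted models
ADJUSTMENT_COVARIATES = ("age", "sex", "race_site", "bmi", "cesd", "roa_count")

_CATEGORICAL = ("sex", "race_site")

_OUTCOME3_ORDER = ("no_pain", "mild_unilateral", "modsev_unilateral")


@dataclass
class AssociationReport:
    """Collected model blocks plus diagnostics for one analysis sample."""

    models: dict[str, pd.DataFrame] = field(default_factory=dict)
    collinearity: dict | None = None
    proportional_odds: dict | None = None

    def to_table(self) -> pd.DataFrame:
        return pd.concat(self.models.values(), ignore_index=True)


def _design(table: pd.DataFrame, variables: list[str]) -> pd.DataFrame:
    """Reference-cell coded design matrix (no constant)."""
    cols = []
    for var in variables:
        if var in _CATEGORICAL and not pd.api.types.is_numeric_dtype(table[var]):
            dummies = pd.get_dummies(table[var], prefix=var, drop_first=True)
            cols.append(dummies.astype(float))
        else:
            cols.append(table[var].astype(float))
    return pd.concat(cols, axis=1)


def _prepare(
    table: pd.DataFrame, outcome: str, variables: list[str]
) -> tuple[pd.DataFrame, pd.Series]:
    missing_cols = [v for v in variables + [outcome] if v not in table.columns]
    if missing_cols:
        raise ConfigError(f"columns absent from the analysis table: {missing_cols}")
    data = table.dropna(subset=variables + [outcome])
    return data, data[outcome]


def fit_binary_logistic(
    table: pd.DataFrame,
    predictors: list[str],
    covariates: list[str] | None = None,
    outcome: str = "outcome2",
    model_label: str | None = None,
) -> pd.DataFrame:
    """Maximum-likelihood logistic fit; one row per term with OR and 95% CI.

    ``predictors`` are the (standardized) gait variables; ``covariates``,
    when given, are added to form the adjusted model.  Rows with missing
    values in any model variable are dropped listwise.  Raises on
    non-convergence or separation, naming the model.
    """
    variables = list(predictors) + list(covariates or [])
    data, y_raw = _prepare(table, outcome, variables)
    if pd.api.types.is_numeric_dtype(y_raw):
        y = y_raw.astype(float)
    else:
        y = (y_raw == "mild_unilateral").astype(float)
    if y.nunique() < 2:
        raise InsufficientDataError("outcome has a single class")
    X = sm.add_constant(_design(data, variables))
    label = model_label or ("adjusted" if covariates else "unadjusted")
    try:
        res = sm.Logit(y.to_numpy(), X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
    except Exception as exc:  # PerfectSeparationError and kin
        raise ConfigError(f"logistic model '{label}' failed: {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise ConfigError(f"logistic model '{label}' did not converge")

    names = list(X.columns)
    ci = res.conf_int(alpha=0.05)
    rows = []
    for i, name in enumerate(names):
        if name == "const":
            continue
        rows.append({
            "variable": name,
            "coef": float(res.params[i]),
            "se": float(res.bse[i]),
            "odds_ratio": float(np.exp(res.params[i])),
            "ci_low": float(np.exp(ci[i, 0])),
            "ci_high": float(np.exp(ci[i, 1])),
            "model": label,
            "contrast": "mild_vs_no_pain",
            "n": int(len(data)),
        })
    return pd.DataFrame(rows)


def collinearity_diagnostics(
    table: pd.DataFrame, variables: list[str]
) -> dict:
    """Correlations, tolerance/VIF, eigenvalues and condition indices.

    Tolerance of a variable is ``1 - R^2`` of its regression on the other
    model variables (VIF is the reciprocal); eigenvalues and condition
    indices come from the correlation matrix of the model variables.
    Constant columns are flagged and excluded.  Flags follow the usual
    screening thresholds: any pairwise ``|r| > 0.80``, ``tolerance <
    0.10`` or ``VIF > 10``.
    """
    X = _design(table.dropna(subset=variables), list(variables))
    flags: list[str] = []
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    for c in constant:
        flags.append(f"constant column '{c}' excluded from diagnostics")
    X = X.drop(columns=constant)
    if X.shape[1] < 2:
        raise InsufficientDataError("need >= 2 non-constant model variables")

    corr = X.corr()
    for i, a in enumerate(corr.columns):
        for b in corr.columns[i + 1:]:
            if abs(corr.loc[a, b]) > 0.80:
                flags.append(f"|r|>0.80: {a} vs {b} (r={corr.loc[a, b]:.3f})")

    tol = {}
    for c in X.columns:
        others = sm.add_constant(X.drop(columns=[c]).to_numpy(dtype=float))
        r2 = sm.OLS(X[c].to_numpy(dtype=float), others).fit().rsquared
        tol[c] = float(max(1.0 - r2, 1e-12))
    tolerance = pd.Series(tol)
    vif = 1.0 / tolerance
    for c in X.columns:
        if tolerance[c] < 0.10:
            flags.append(f"tolerance<0.10: {c} (tolerance={tolerance[c]:.4f})")
        if vif[c] > 10.0:
            flags.append(f"VIF>10: {c} (VIF={vif[c]:.2f})")

    eigvals = np.sort(np.linalg.eigvalsh(corr.to_numpy()))[::-1]
    eigvals = np.clip(eigvals, 1e-12, None)
    condition_indices = np.sqrt(eigvals[0] / eigvals)
    return {
        "correlations": corr,
        "tolerance": tolerance,
        "vif": vif,
        "eigenvalues": eigvals,
        "condition_indices": condition_indices,
        "flags": flags,
        "drop_recommendations": _recommend_drops(X),
    }


def _recommend_drops(X: pd.DataFrame) -> list[str]:
    """Variables to drop, greedily, until no screening threshold fires.

    At each step the variable with the highest VIF among those violating a
    threshold (|r| > 0.80 with a kept variable, tolerance < 0.10, VIF > 10)
    is removed; order of entry breaks exact ties.
    """
    kept = list(X.columns)
    drops: list[str] = []
    while len(kept) >= 2:
        sub = X[kept]
        corr = sub.corr().abs()
        np.fill_diagonal(corr.to_numpy(), 0.0)
        vifs = {}
        for c in kept:
            others = sm.add_constant(sub.drop(columns=[c]).to_numpy(dtype=float))
            r2 = sm.OLS(sub[c].to_numpy(dtype=float), others).fit().rsquared
            vifs[c] = 1.0 / max(1.0 - r2, 1e-12)
        offenders = [c for c in kept
                     if vifs[c] > 10.0 or corr[c].max() > 0.80]
        if not offenders:
            break
        worst = max(offenders, key=lambda c: (vifs[c], kept.index(c)))
        drops.append(worst)
        kept.remove(worst)
    return drops


def fit_multinomial_sensitivity(
    table: pd.DataFrame,
    predictors: list[str],
    covariates: list[str] | None = None,
    outcome: str = "outcome3",
) -> pd.DataFrame:
    """Generalized-logit model of the 3-category pain outcome.

    "No pain" is the reference; the returned table carries ORs with Wald
    95% CIs for both contrasts (mild vs no pain, moderate/severe vs no
    pain), per sd for standardized predictors.
    """
    variables = list(predictors) + list(covariates or [])
    data, y_raw = _prepare(table, outcome, variables)
    levels = [lv for lv in _OUTCOME3_ORDER if lv in set(y_raw)]
    if len(levels) < 2:
        raise InsufficientDataError("outcome3 needs >= 2 observed categories")
    counts = y_raw.value_counts()
    empty = [lv for lv in levels if counts.get(lv, 0) == 0]
    if empty:
        raise InsufficientDataError(f"empty outcome categories: {empty}")
    y = pd.Categorical(y_raw, categories=levels, ordered=False).codes
    X = sm.add_constant(_design(data, variables))
    res = sm.MNLogit(y, X.to_numpy(dtype=float)).fit(disp=0, maxiter=200)
    if not res.mle_retvals.get("converged", True):
        raise ConfigError("multinomial model did not converge")

    contrast_names = {
        "mild_unilateral": "mild_vs_no_pain",
        "modsev_unilateral": "modsev_vs_no_pain",
    }
    names = list(X.columns)
    params = np.asarray(res.params)          # (k_exog, n_levels - 1)
    bses = np.asarray(res.bse)
    z = stats.norm.ppf(0.975)
    rows = []
    for j, level in enumerate(levels[1:]):
        for i, name in enumerate(names):
            if name == "const":
                continue
            b, se = params[i, j], bses[i, j]
            rows.append({
                "variable": name,
                "coef": float(b),
                "se": float(se),
                "odds_ratio": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "model": "multinomial_generalized_logit",
                "contrast": contrast_names.get(level, f"{level}_vs_no_pain"),
                "n": int(len(data)),
            })
    return pd.DataFrame(rows)


def proportional_odds_check(
    table: pd.DataFrame,
    predictors: list[str],
    covariates: list[str] | None = None,
    outcome: str = "outcome3",
    alpha: float = 0.05,
) -> dict:
    """Likelihood comparison of proportional-odds vs generalized-logit fits.

    Fits a cumulative-logit proportional-odds model and an unconstrained
    generalized-logit model to the ordinal 3-category outcome and compares
    twice the log-likelihood gap to a chi-square with as many degrees of
    freedom as the extra slope parameters.  Recommends the generalized
    logit when the proportional-odds assumption is rejected at ``alpha``.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    variables = list(predictors) + list(covariates or [])
    data, y_raw = _prepare(table, outcome, variables)
    levels = [lv for lv in _OUTCOME3_ORDER if lv in set(y_raw)]
    if len(levels) < 3:
        raise InsufficientDataError(
            "proportional-odds check needs all 3 outcome categories"
        )
    y = pd.Categorical(y_raw, categories=levels, ordered=True)
    X = _design(data, variables)
    po = OrderedModel(y.codes, X.to_numpy(dtype=float), distr="logit").fit(
        disp=0, method="bfgs", maxiter=500
    )
    mn = sm.MNLogit(
        y.codes, sm.add_constant(X).to_numpy(dtype=float)
    ).fit(disp=0, maxiter=200)
    p = X.shape[1]
    df = (len(levels) - 2) * p
    statistic = float(2.0 * (mn.llf - po.llf))
    p_value = float(stats.chi2.sf(max(statistic, 0.0), df))
    return {
        "statistic": statistic,
        "df": df,
        "p_value": p_value,
        "reject_proportional_odds": p_value < alpha,
        "recommendation": "generalized_logit" if p_value < alpha
        else "proportional_odds",
    }
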