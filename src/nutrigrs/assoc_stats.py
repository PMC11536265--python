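"""Association and interaction models for the risk-score analysis.

All models are ordinary least squares with an intercept and adjustment for
age, sex and BMI. Outcomes and dietary exposure terms follow a fixed
transformation rule: every biochemical, anthropometric and dietary
variable is natural-log transformed before modelling, with the exception
of total fat, carbohydrate and MUFA intakes expressed as %TEI, which stay
on their original scale. When the outcome is log transformed, effects are
additionally reported as fold changes per unit (exp(beta)).

The interaction screen fits, per outcome and dietary factor,

    outcome' ~ grs_group + diet + grs_group : diet + age + sex + bmi

and takes the interaction p-value from the product-term coefficient.
Significant screens are followed by stratified estimation of the
high-vs-low GRS effect within each diet group, and a significant total-fat
interaction is decomposed into fat subtypes (SFA, MUFA, PUFA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diet_exposures import dichotomize_exposure, HIGH
from .errors import CollinearityError, DomainError, ValidationError

logger = logging.getLogger(__name__)

#: variables exempt from the log rule (percent-of-energy scales kept linear)
LOG_EXEMPT = frozenset({"fat_pct", "carb_pct", "mufa_pct"})

#: outcome set of the primary analyses
DEFAULT_OUTCOMES = ("tag", "tag_hdl_ratio", "hdl", "ldl", "tc", "sbp", "dbp")

#: dietary factors of the primary interaction screen
PRIMARY_DIET_FACTORS = ("fat_pct", "carb_pct", "protein_pct")

#: fat subtypes examined when the total-fat interaction is significant
FAT_SUBTYPES = ("sfa_pct", "mufa_pct", "pufa_pct")

DEFAULT_COVARIATES = ("age", "sex_m", "bmi")


# ---------------------------------------------------------------------------
# Transformation rule and normality reporting
# ---------------------------------------------------------------------------

def transform_for_analysis(name: str, values) -> tuple[np.ndarray, bool]:
    """Apply the fixed log rule to a named analysis variable.

    Returns (possibly transformed values, flag indicating a log transform
    was applied). Non-positive values under the log rule are an error that
    names the offending samples.
    """
    arr = np.asarray(values, dtype=float)
    if name in LOG_EXEMPT:
        return arr, False
    if np.any(arr <= 0):
        if isinstance(values, pd.Series):
            bad = list(values.index[arr <= 0])
        else:
            bad = list(np.nonzero(arr <= 0)[0])
        raise DomainError(
            f"variable {name!r} has non-positive value(s) at {bad}; "
            "log transform undefined"
        )
    return np.log(arr), True


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro-Wilk normality test (reported descriptively; the transform
    rule is fixed and not gated on it)."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 3 or arr.size > 5000:
        raise DomainError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(arr) == 0:
        raise DomainError("Shapiro-Wilk undefined for a constant sample")
    res = stats.shapiro(arr)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# OLS engine
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """One fitted linear model.

    ``terms`` is indexed by term name with columns beta, se, ci_low,
    ci_high, p and (when the outcome was log transformed) exp_beta,
    exp_ci_low, exp_ci_high.
    """

    outcome: str
    terms: pd.DataFrame
    n_used: int
    residual_df: int
    r_squared: float
    transformed: bool
    stable: bool = True

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]

    @property
    def term_names(self) -> list[str]:
        return list(self.terms.index)


def fit_linear(y: pd.Series, design: pd.DataFrame, outcome: str = "y",
               transformed: bool = False) -> FitResult:
    """Ordinary least squares of ``y`` on ``design`` plus an intercept.

    Rows with any missing value are dropped (and counted via ``n_used``);
    a rank-deficient design raises :class:`CollinearityError` naming the
    dependent columns. Confidence intervals use the t distribution on the
    residual degrees of freedom.
    """
    import statsmodels.api as sm

    data = design.copy()
    data.insert(0, "__y__", y)
    data = data.dropna()
    n_used = len(data)
    if n_used <= design.shape[1] + 1:
        raise DomainError(
            f"{n_used} complete rows for {design.shape[1] + 1} parameters; "
            "model is not estimable"
        )
    X = sm.add_constant(data.drop(columns="__y__"), has_constant="add")
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify columns that do not increase rank when added left to right
        culprits = []
        cols: list[str] = []
        for col in X.columns:
            trial = X[cols + [col]].to_numpy()
            if np.linalg.matrix_rank(trial) == len(cols):
                culprits.append(col)
            else:
                cols.append(col)
        raise CollinearityError(f"design is rank deficient; collinear column(s): {culprits}")
    res = sm.OLS(data["__y__"].to_numpy(), X).fit()
    ci = res.conf_int(alpha=0.05)
    terms = pd.DataFrame({
        "beta": res.params,
        "se": res.bse,
        "ci_low": ci[0],
        "ci_high": ci[1],
        "p": res.pvalues,
    })
    terms = terms.rename(index={"const": "intercept"})
    if transformed:
        terms["exp_beta"] = np.exp(terms["beta"])
        terms["exp_ci_low"] = np.exp(terms["ci_low"])
        terms["exp_ci_high"] = np.exp(terms["ci_high"])
    return FitResult(
        outcome=outcome, terms=terms, n_used=n_used,
        residual_df=int(res.df_resid), r_squared=float(res.rsquared),
        transformed=transformed,
    )


def _covariate_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Adjustment covariates: age, sex indicator (women 0, men 1), BMI."""
    return pd.DataFrame({
        "age": cohort["age"].astype(float),
        "sex_m": (cohort["sex"] == "M").astype(float),
        "bmi": cohort["bmi"].astype(float),
    }, index=cohort.index)


def _transformed_outcome(cohort: pd.DataFrame, outcome: str) -> tuple[pd.Series, bool]:
    values, flag = transform_for_analysis(outcome, cohort[outcome].dropna())
    return pd.Series(values, index=cohort[outcome].dropna().index, name=outcome), flag


# ---------------------------------------------------------------------------
# Association models
# ---------------------------------------------------------------------------

@dataclass
class AssociationResult:
    outcome: str
    group_fit: FitResult      # binary low/high risk-score exposure
    scaled_fit: FitResult     # per-SD continuous score

    def summary_row(self, threshold: float | None = None) -> dict:
        g = self.group_fit.term("grs_high")
        s = self.scaled_fit.term("grs_scaled")
        row = {
            "outcome": self.outcome,
            "n": self.group_fit.n_used,
            "beta_high_vs_low": g["beta"], "ci_low": g["ci_low"],
            "ci_high": g["ci_high"], "p": g["p"],
            "beta_per_sd": s["beta"], "p_per_sd": s["p"],
        }
        if self.group_fit.transformed:
            row["fold_change_per_sd"] = s["exp_beta"]
            row["fold_ci_low"] = s["exp_ci_low"]
            row["fold_ci_high"] = s["exp_ci_high"]
        if threshold is not None:
            row["significant"] = g["p"] < threshold
        return row


def association_analysis(cohort: pd.DataFrame, grs_df: pd.DataFrame,
                         outcomes=DEFAULT_OUTCOMES) -> dict[str, AssociationResult]:
    """Per outcome, regress the (transformed) trait on the risk score,
    adjusted for age, sex and BMI.

    Two exposures are always fitted: the binary high/low group and the
    SD-scaled continuous score.
    """
    covars = _covariate_frame(cohort)
    grs_high = (grs_df["grs_group"] == HIGH).astype(float).rename("grs_high")
    results = {}
    for outcome in outcomes:
        y, flag = _transformed_outcome(cohort, outcome)
        base = covars.join(grs_high, how="inner")
        group_design = base[["grs_high", "age", "sex_m", "bmi"]]
        group_fit = fit_linear(y, group_design, outcome=outcome, transformed=flag)
        scaled_design = covars.join(grs_df["grs_scaled"], how="inner")
        scaled_design = scaled_design[["grs_scaled", "age", "sex_m", "bmi"]]
        scaled_fit = fit_linear(y, scaled_design, outcome=outcome, transformed=flag)
        results[outcome] = AssociationResult(outcome, group_fit, scaled_fit)
    return results


# ---------------------------------------------------------------------------
# Interaction models
# ---------------------------------------------------------------------------

@dataclass
class StratumResult:
    stratum: str
    n: int
    fit: FitResult | None
    stable: bool
    note: str = ""


@dataclass
class InteractionResult:
    outcome: str
    exposure: str
    p_interaction: float
    beta: float
    ci_low: float
    ci_high: float
    fit: FitResult
    diet_form: str
    strata: dict[str, StratumResult] = field(default_factory=dict)
    followup: dict[str, "InteractionResult"] = field(default_factory=dict)

    def summary_row(self, threshold: float | None = None) -> dict:
        row = {
            "outcome": self.outcome, "exposure": self.exposure,
            "n": self.fit.n_used, "beta_interaction": self.beta,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_interaction": self.p_interaction,
        }
        if threshold is not None:
            row["significant"] = self.p_interaction < threshold
        return row


def _diet_term(exposures: pd.DataFrame, exposure: str, diet_form: str) -> pd.Series:
    """The dietary model term: transformed continuous %TEI (default) or the
    0/1 above-median indicator."""
    raw = exposures[exposure]
    if diet_form == "continuous":
        values, _ = transform_for_analysis(exposure, raw)
        return pd.Series(values, index=raw.index, name="diet")
    if diet_form == "binary":
        labels, _ = dichotomize_exposure(raw)
        return (labels == HIGH).astype(float).rename("diet")
    raise ValidationError(f"unknown diet_form {diet_form!r}")


def interaction_analysis(cohort: pd.DataFrame, grs_df: pd.DataFrame,
                         exposures: pd.DataFrame, exposure: str,
                         outcomes=DEFAULT_OUTCOMES,
                         diet_form: str = "continuous"
                         ) -> dict[str, InteractionResult]:
    """Fit the product-term model for one dietary factor across outcomes."""
    covars = _covariate_frame(cohort)
    grs_high = (grs_df["grs_group"] == HIGH).astype(float).rename("grs_high")
    diet = _diet_term(exposures, exposure, diet_form)
    results = {}
    for outcome in outcomes:
        y, flag = _transformed_outcome(cohort, outcome)
        design = pd.concat([grs_high, diet, covars], axis=1, join="inner")
        design["grs_x_diet"] = design["grs_high"] * design["diet"]
        design = design[["grs_high", "diet", "grs_x_diet", "age", "sex_m", "bmi"]]
        fit = fit_linear(y, design, outcome=outcome, transformed=flag)
        term = fit.term("grs_x_diet")
        results[outcome] = InteractionResult(
            outcome=outcome, exposure=exposure,
            p_interaction=float(term["p"]), beta=float(term["beta"]),
            ci_low=float(term["ci_low"]), ci_high=float(term["ci_high"]),
            fit=fit, diet_form=diet_form,
        )
    return results


def stratified_effects(cohort: pd.DataFrame, grs_df: pd.DataFrame,
                       diet_labels: pd.Series, outcome: str,
                       min_stratum_n: int = 10) -> dict[str, StratumResult]:
    """High-vs-low GRS effect within each diet stratum (adjusted model).

    A stratum smaller than ``min_stratum_n`` or without enough residual
    degrees of freedom is flagged unstable rather than reported as a
    trustworthy estimate.
    """
    covars = _covariate_frame(cohort)
    grs_high = (grs_df["grs_group"] == HIGH).astype(float).rename("grs_high")
    out = {}
    for stratum in sorted(diet_labels.unique()):
        ids = diet_labels.index[diet_labels == stratum]
        ids = ids.intersection(grs_high.index).intersection(cohort.index)
        n = len(ids)
        sub_cohort = cohort.loc[ids]
        y, flag = _transformed_outcome(sub_cohort, outcome)
        design = covars.loc[ids, ["age", "sex_m", "bmi"]].copy()
        design.insert(0, "grs_high", grs_high.loc[ids])
        note = ""
        stable = n >= min_stratum_n
        fit = None
        try:
            fit = fit_linear(y, design, outcome=outcome, transformed=flag)
        except (DomainError, CollinearityError) as exc:
            stable = False
            note = str(exc)
            logger.warning("stratum %s (%s): %s", stratum, outcome, exc)
        if fit is not None and not stable:
            note = note or f"stratum n={n} below floor {min_stratum_n}"
            logger.warning("stratum %s (%s) flagged unstable: %s", stratum, outcome, note)
        out[stratum] = StratumResult(stratum=stratum, n=n, fit=fit,
                                     stable=stable, note=note)
    return out


def fat_subtype_followup(cohort: pd.DataFrame, grs_df: pd.DataFrame,
                         exposures: pd.DataFrame, outcome: str,
                         parent: InteractionResult, alpha: float = 0.05,
                         diet_form: str = "continuous", force: bool = False
                         ) -> dict[str, InteractionResult]:
    """Decompose a significant total-fat interaction into SFA/MUFA/PUFA.

    Skipped (empty result, logged) unless the parent interaction is
    significant at ``alpha`` or ``force`` is set.
    """
    if not force and not (parent.p_interaction < alpha):
        logger.info(
            "fat-subtype follow-up skipped for %s: parent p_interaction %.3g >= %.3g",
            outcome, parent.p_interaction, alpha,
        )
        return {}
    out = {}
    for subtype in FAT_SUBTYPES:
        res = interaction_analysis(cohort, grs_df, exposures, subtype,
                                   outcomes=(outcome,), diet_form=diet_form)
        out[subtype] = res[outcome]
    return out


# ---------------------------------------------------------------------------
# Multiple testing, descriptives, power
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BonferroniThreshold:
    alpha: float
    n_tests: int
    raw: float
    display: float   # rounded to 3 decimals for reporting


def bonferroni_threshold(alpha: float, n_tests: int) -> BonferroniThreshold:
    """Family-wise threshold alpha / m, with a 3-decimal display value."""
    if n_tests < 1:
        raise DomainError("number of tests must be at least 1")
    if not (0 < alpha < 1):
        raise DomainError("alpha must be in (0, 1)")
    raw = alpha / n_tests
    return BonferroniThreshold(alpha=alpha, n_tests=n_tests, raw=raw,
                               display=round(raw, 3))


DESCRIPTIVE_VARIABLES = (
    "age", "bmi", "wc", "sbp", "dbp", "tag", "tc", "hdl", "ldl",
    "tag_hdl_ratio", "tei", "fat_pct", "sfa_pct", "mufa_pct", "pufa_pct",
    "carb_pct", "protein_pct",
)


def descriptive_comparisons(data: pd.DataFrame, group: pd.Series,
                            variables=None, equal_var: bool = True
                            ) -> pd.DataFrame:
    """Mean (SD) per group and a two-sample t-test per continuous variable.

    ``group`` must take exactly two values; the Student equal-variance test
    is the default (``equal_var=False`` gives Welch). A variable with zero
    variance in both groups is flagged untestable.
    """
    levels = sorted(group.dropna().unique())
    if len(levels) != 2:
        raise ValidationError(f"grouping must have exactly two levels, got {levels}")
    if variables is None:
        variables = [v for v in DESCRIPTIVE_VARIABLES if v in data.columns]
    a_ids = group.index[group == levels[0]]
    b_ids = group.index[group == levels[1]]
    rows = []
    for var in variables:
        a = data.loc[data.index.intersection(a_ids), var].dropna()
        b = data.loc[data.index.intersection(b_ids), var].dropna()
        if len(a) < 2 or len(b) < 2:
            raise ValidationError(f"{var}: each group needs n >= 2")
        row = {
            "variable": var,
            f"mean_{levels[0]}": a.mean(), f"sd_{levels[0]}": a.std(ddof=1),
            f"n_{levels[0]}": len(a),
            f"mean_{levels[1]}": b.mean(), f"sd_{levels[1]}": b.std(ddof=1),
            f"n_{levels[1]}": len(b),
        }
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            row.update(t=np.nan, p=np.nan, testable=False)
        else:
            t, p = stats.ttest_ind(a, b, equal_var=equal_var)
            row.update(t=float(t), p=float(p), testable=True)
        rows.append(row)
    return pd.DataFrame(rows)


def chi_square_2x2(table) -> tuple[float, float]:
    """Plain (uncorrected) chi-square test of independence on a 2x2 table."""
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValidationError("expected a 2x2 contingency table")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), float(p)


def min_detectable_effect(n: int, maf: float, residual_sd: float,
                          power: float = 0.80, alpha: float = 0.05) -> float:
    """Smallest per-allele effect detectable for a single SNP.

    Assumes additive dosage coding under Hardy-Weinberg, so the dosage
    variance is 2 maf (1 - maf):

        beta_min = (z_{1-alpha/2} + z_{power}) * sd / sqrt(n * 2 maf (1-maf))

    Units follow ``residual_sd`` (mg/dl for the lipid traits).
    """
    if not (0 < maf < 1):
        raise DomainError("maf must be in (0, 1)")
    if not (0 < power < 1) or not (0 < alpha < 1):
        raise DomainError("power and alpha must be in (0, 1)")
    if n < 1 or residual_sd <= 0:
        raise DomainError("n must be >= 1 and residual_sd > 0")
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(z * residual_sd / np.sqrt(n * 2.0 * maf * (1.0 - maf)))
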