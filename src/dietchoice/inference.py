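"""Statistical analysis of dietary decision-making task outcomes.

Implements the study-level analysis chain: plausibility cleaning of
participants, demographic covariate screening by pairwise correlation
(p < 0.10), standardized linear regressions of task outcomes (taste/health
sensitivity, preference proportions) on eating-behavior scores, pooled
trial-level reaction-time regressions on difference scores, and moderation
of the RT–difference slopes by cognitive restraint or disinhibited eating
(median-split, stratified, and continuous forms; interactions flagged at
p < 0.10 by Wald t-test), plus weight-status descriptives (ANOVA /
chi-square).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

logger = logging.getLogger(__name__)

#: height plausibility floor: 2 feet in meters
MIN_HEIGHT_M = 0.6096
#: default BMI plausibility floor (kg/m^2)
MIN_BMI = 10.0


# ---------------------------------------------------------------------------
# model-result containers
# ---------------------------------------------------------------------------

@dataclass
class ModelResult:
    """Coefficient table for one fitted linear model."""

    label: str
    table: pd.DataFrame  # term, estimate, se, t, p, ci_low, ci_high
    n_obs: int
    covariates: tuple = ()
    standardized: bool = True

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def pvalue(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


@dataclass
class ModerationResult:
    """Stratified slopes and interaction test for one moderator."""

    moderator: str
    form: str  # "median-split" or "continuous"
    difference_kind: str
    strata: dict = field(default_factory=dict)  # label -> ModelResult
    interaction_estimate: float = float("nan")
    interaction_se: float = float("nan")
    interaction_p: float = float("nan")
    significant: bool = False

    def slope(self, stratum: str) -> float:
        return self.strata[stratum].coef("difference")


def _fit_ols(y, X: pd.DataFrame, label: str, covariates=(), standardized=True
             ) -> ModelResult:
    """OLS with intercept; returns the full coefficient table with 95% CIs."""
    Xc = sm.add_constant(X, has_constant="add")
    fit = sm.OLS(np.asarray(y, float), np.asarray(Xc, float)).fit()
    ci = fit.conf_int(alpha=0.05)
    table = pd.DataFrame(
        {
            "term": list(Xc.columns),
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p": fit.pvalues,
            "ci_low": ci[:, 0],
            "ci_high": ci[:, 1],
        }
    )
    return ModelResult(
        label=label,
        table=table.reset_index(drop=True),
        n_obs=int(fit.nobs),
        covariates=tuple(covariates),
        standardized=standardized,
    )


def _zscore(x: pd.Series) -> pd.Series:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"cannot standardize constant column {x.name!r}")
    return (x - x.mean()) / sd


def _design_columns(df: pd.DataFrame, names, standardize: bool = True
                    ) -> pd.DataFrame:
    """Build a design block: z-scored continuous columns and reference-level
    dummies (reference = most frequent level) for categoricals."""
    blocks = []
    for name in names:
        col = df[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(_zscore(col).rename(name) if standardize else col)
        else:
            ref = col.value_counts().idxmax()
            levels = [l for l in col.unique() if l != ref]
            for lev in sorted(map(str, levels)):
                blocks.append((col.astype(str) == lev).astype(float)
                              .rename(f"{name}[{lev}]"))
    return pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)


# ---------------------------------------------------------------------------
# participant cleaning
# ---------------------------------------------------------------------------

def assign_weight_status(bmi) -> pd.Series:
    """CDC cut points: healthy ≤ 24.9, overweight 25–29.9, obese ≥ 30."""
    bmi = pd.Series(bmi)
    return pd.Series(
        np.where(bmi < 25.0, "healthy", np.where(bmi < 30.0, "overweight", "obese")),
        index=bmi.index,
    )


def clean_participants(
    demographics: pd.DataFrame,
    trials: pd.DataFrame,
    ratings: pd.DataFrame | None = None,
    *,
    min_height_m: float = MIN_HEIGHT_M,
    min_bmi: float = MIN_BMI,
):
    """Plausibility screening of participants.

    Exclusion rules, applied in order and each reported:

    1. implausible height (< 2 feet = 0.6096 m by default);
    2. implausible BMI (below ``min_bmi``, default 10);
    3. invariant task responding — the same preference on every trial and
       constant taste and health ratings (requires ``ratings``).

    Returns
    -------
    (cleaned demographics with bmi and weight_status columns, exclusion
    report DataFrame with columns participant_id, rule, detail)
    """
    demo = demographics.copy()
    demo["bmi"] = demo["weight_kg"] / demo["height_m"] ** 2
    exclusions = []

    bad_height = demo["height_m"] < min_height_m
    for _, row in demo[bad_height].iterrows():
        exclusions.append(
            {"participant_id": row["participant_id"], "rule": "height",
             "detail": f"height {row['height_m']} m < {min_height_m} m"}
        )
    bad_bmi = ~bad_height & (demo["bmi"] < min_bmi)
    for _, row in demo[bad_bmi].iterrows():
        exclusions.append(
            {"participant_id": row["participant_id"], "rule": "bmi",
             "detail": f"BMI {row['bmi']:.2f} < {min_bmi}"}
        )

    excluded = set(demo.loc[bad_height | bad_bmi, "participant_id"])

    pref_var = trials.groupby("participant_id")["preference"].nunique()
    invariant = set(pref_var[pref_var <= 1].index)
    if ratings is not None and invariant:
        rat_n = ratings.groupby("participant_id")[["taste", "health"]].nunique()
        constant_raters = set(rat_n[(rat_n <= 1).all(axis=1)].index)
        invariant &= constant_raters
    for pid in sorted(invariant - excluded):
        exclusions.append(
            {"participant_id": pid, "rule": "invariant_responder",
             "detail": "identical response on every task question"}
        )
    excluded |= invariant

    kept = demo[~demo["participant_id"].isin(excluded)].copy()
    if kept.empty:
        raise ValueError("no participants remain after cleaning")
    kept["weight_status"] = assign_weight_status(kept["bmi"]).to_numpy()
    report = pd.DataFrame(exclusions, columns=["participant_id", "rule", "detail"])
    logger.info("cleaning removed %d of %d participants", len(report), len(demo))
    return kept, report


# ---------------------------------------------------------------------------
# covariate screening
# ---------------------------------------------------------------------------

def screen_covariates(
    demographics: pd.DataFrame,
    outcomes: pd.DataFrame,
    demographic_vars=("age", "sex", "bmi", "race", "income_usd"),
    alpha: float = 0.10,
) -> list[str]:
    """Select demographic covariates by pairwise Pearson correlation.

    A demographic variable enters the covariate list when its correlation
    with *any* outcome column has p < ``alpha``.  Categorical demographics
    are expanded to indicator columns (reference = most frequent level); a
    variable is selected if any of its indicators correlates.

    Parameters
    ----------
    demographics
        Participant-level table (one row per participant).
    outcomes
        Participant-level numeric outcome columns, aligned on
        participant_id (both tables are merged on it).
    """
    merged = demographics.merge(outcomes, on="participant_id")
    out_cols = [c for c in outcomes.columns if c != "participant_id"]
    selected = []
    for var in demographic_vars:
        if var not in merged.columns:
            continue
        col = merged[var]
        if pd.api.types.is_numeric_dtype(col):
            numeric = {var: col.astype(float)}
        else:
            ref = col.value_counts().idxmax()
            numeric = {
                f"{var}[{lev}]": (col.astype(str) == str(lev)).astype(float)
                for lev in col.unique() if lev != ref
            }
        hit = False
        for code_name, x in numeric.items():
            if x.std(ddof=1) == 0:
                logger.warning("constant variable %s skipped in screening", code_name)
                continue
            for oc in out_cols:
                y = merged[oc].astype(float)
                ok = x.notna() & y.notna()
                if ok.sum() < 3 or y[ok].std(ddof=1) == 0:
                    continue
                _, p = stats.pearsonr(x[ok], y[ok])
                if p < alpha:
                    hit = True
                    break
            if hit:
                break
        if hit:
            selected.append(var)
    return selected


# ---------------------------------------------------------------------------
# outcome models
# ---------------------------------------------------------------------------

OUTCOME_COLUMNS = ("taste_sensitivity", "health_sensitivity",
                   "prop_healthy", "prop_tasty")
PREDICTOR_COLUMNS = ("cr", "disinhibited")


def fit_outcome_models(
    participants: pd.DataFrame,
    covariates=(),
    outcomes=OUTCOME_COLUMNS,
    predictors=PREDICTOR_COLUMNS,
) -> dict[str, ModelResult]:
    """Standardized regressions of task outcomes on eating-behavior scores.

    For every outcome: one unadjusted simple regression per predictor, and
    one adjusted multiple regression with both eating-behavior scores plus
    the screened covariates.  All continuous variables are z-scored, so
    unadjusted slopes equal Pearson correlations.

    Returns
    -------
    dict keyed "<outcome>~<predictor>" (unadjusted) and
    "<outcome>~adjusted" (one joint model per outcome).
    """
    df = participants.dropna(subset=list(outcomes) + list(predictors)).copy()
    results: dict[str, ModelResult] = {}
    for out in outcomes:
        y = _zscore(df[out])
        for pred in predictors:
            X = _design_columns(df, [pred])
            results[f"{out}~{pred}"] = _fit_ols(
                y, X, label=f"{out} on {pred} (unadjusted)")
        X = _design_columns(df, list(predictors) + list(covariates))
        results[f"{out}~adjusted"] = _fit_ols(
            y, X, label=f"{out} adjusted", covariates=covariates)
    return results


# ---------------------------------------------------------------------------
# reaction-time models
# ---------------------------------------------------------------------------

def _merge_trial_table(
    derived: pd.DataFrame, scores: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
) -> pd.DataFrame:
    df = derived.merge(scores, on="participant_id")
    if demographics is not None:
        df = df.merge(demographics, on="participant_id")
    return df


def fit_rt_models(
    derived: pd.DataFrame,
    scores: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    covariates=(),
    cluster_robust: bool = False,
) -> dict[str, ModelResult]:
    """Pooled trial-level regressions of reaction time on task predictors.

    RT (ms) is regressed on, separately: the trial health difference score,
    the taste difference score (both per rating unit, so coefficients read
    in ms per unit), and the participant's standardized cognitive-restraint
    and disinhibited-eating scores; each with and without covariates.  A
    joint sensitivity model fits both difference scores simultaneously.
    Only preferred (non-neutral) trials carry difference scores and enter
    those models.  With ``cluster_robust=True`` standard errors are
    clustered by participant (off by default).
    """
    df = _merge_trial_table(derived, scores, demographics)
    pref = df.dropna(subset=["health_diff", "taste_diff"]).copy()

    results: dict[str, ModelResult] = {}

    def fit(tag, frame, cols, covs, std_cols=()):
        blocks = []
        for c in cols:
            blocks.append(_zscore(frame[c]).rename(c) if c in std_cols
                          else frame[c].astype(float))
        X = pd.concat(blocks, axis=1)
        if covs:
            X = pd.concat([X, _design_columns(frame, covs)], axis=1)
        res = _fit_ols(frame["rt_ms"], X, label=tag, covariates=covs,
                       standardized=bool(std_cols))
        if cluster_robust:
            Xc = sm.add_constant(X, has_constant="add")
            f = sm.OLS(frame["rt_ms"].to_numpy(float), np.asarray(Xc, float)).fit(
                cov_type="cluster",
                cov_kwds={"groups": frame["participant_id"].to_numpy()},
            )
            ci = f.conf_int(alpha=0.05)
            res.table = pd.DataFrame(
                {"term": list(Xc.columns), "estimate": f.params, "se": f.bse,
                 "t": f.tvalues, "p": f.pvalues, "ci_low": ci[:, 0],
                 "ci_high": ci[:, 1]}
            )
        results[tag] = res

    for col in ("health_diff", "taste_diff"):
        fit(f"rt~{col}", pref, [col], ())
        fit(f"rt~{col}+cov", pref, [col], tuple(covariates))
    for col in ("cr", "disinhibited"):
        fit(f"rt~{col}", pref, [col], (), std_cols=(col,))
        fit(f"rt~{col}+cov", pref, [col], tuple(covariates), std_cols=(col,))
    fit("rt~health_diff+taste_diff", pref, ["health_diff", "taste_diff"], ())
    fit("rt~health_diff+taste_diff+cov", pref, ["health_diff", "taste_diff"],
        tuple(covariates))
    return results


_DIFF_COLUMN = {
    "health": "health_diff",
    "taste": "taste_diff",
    "health_minus_taste": "ht_diff_collapsed",
}


def moderation_analysis(
    derived: pd.DataFrame,
    scores: pd.DataFrame,
    moderator: str = "cr",
    difference_kind: str = "health",
    demographics: pd.DataFrame | None = None,
    covariates=(),
    form: str = "median-split",
    alpha: float = 0.10,
) -> ModerationResult:
    """Does the RT–difference slope depend on an eating-behavior trait?

    ``form="median-split"``: participants at or below the sample median of
    the moderator form the low stratum; RT-on-difference slopes are fitted
    per stratum (with covariate adjustment), and the interaction is tested
    in a pooled model with a difference × group term by Wald t-test,
    flagged significant at p < ``alpha`` (default 0.10).

    ``form="continuous"``: the same pooled model with the z-scored
    moderator in place of the group indicator.
    """
    diff_col = _DIFF_COLUMN[difference_kind]
    df = _merge_trial_table(derived, scores, demographics)
    df = df.dropna(subset=[diff_col]).copy()
    df = df.rename(columns={diff_col: "difference"})

    result = ModerationResult(
        moderator=moderator, form=form, difference_kind=difference_kind)

    if form == "median-split":
        med = scores[moderator].median()
        df["group"] = (df[moderator] > med).astype(float)  # ties -> low
        for label, sub in (("low", df[df["group"] == 0]),
                           ("high", df[df["group"] == 1])):
            if sub.empty:
                raise ValueError(f"empty {label} stratum for {moderator}")
            X = sub[["difference"]].astype(float)
            if covariates:
                X = pd.concat([X, _design_columns(sub, covariates)], axis=1)
            result.strata[label] = _fit_ols(
                sub["rt_ms"], X, label=f"{moderator} {label} stratum",
                covariates=covariates)
        df["_mod"] = df["group"]
    elif form == "continuous":
        df["_mod"] = _zscore(df[moderator])
    else:
        raise ValueError(f"unknown moderator form {form!r}")

    X = pd.DataFrame(
        {"difference": df["difference"].astype(float), "moderator": df["_mod"]})
    X["difference:moderator"] = X["difference"] * X["moderator"]
    if covariates:
        X = pd.concat([X, _design_columns(df, covariates)], axis=1)
    pooled = _fit_ols(df["rt_ms"], X, label=f"rt~difference*{moderator} ({form})",
                      covariates=covariates)
    row = pooled.table.set_index("term").loc["difference:moderator"]
    result.interaction_estimate = float(row["estimate"])
    result.interaction_se = float(row["se"])
    result.interaction_p = float(row["p"])
    result.significant = result.interaction_p < alpha
    return result


# ---------------------------------------------------------------------------
# descriptives
# ---------------------------------------------------------------------------

def describe_by_weight_status(
    demographics: pd.DataFrame,
    tfeq_scores: pd.DataFrame,
    continuous=("age", "income_usd", "cr", "ue", "ee"),
    categorical=("sex", "race"),
):
    """Weight-status stratified descriptives with ANOVA / chi-square tests.

    Returns
    -------
    DataFrame with one row per variable: per-status mean (SD) or counts
    (percent), plus the one-way ANOVA F and p (continuous) or chi-square
    statistic and p (categorical).
    """
    df = demographics.merge(tfeq_scores, on="participant_id")
    statuses = [s for s in ("healthy", "overweight", "obese")
                if (df["weight_status"] == s).any()]
    for s in ("healthy", "overweight", "obese"):
        if s not in statuses:
            logger.warning("weight status %r has no participants; omitted", s)
    rows = []
    for var in continuous:
        if var not in df.columns:
            continue
        groups = [df.loc[df["weight_status"] == s, var].dropna() for s in statuses]
        F, p = stats.f_oneway(*groups)
        row = {"variable": var, "kind": "continuous", "stat": float(F),
               "p": float(p)}
        for s, g in zip(statuses, groups):
            row[s] = f"{g.mean():.2f} ({g.std(ddof=1):.2f})"
        rows.append(row)
    for var in categorical:
        if var not in df.columns:
            continue
        ct = pd.crosstab(df[var], df["weight_status"])[statuses]
        chi2, p, _, _ = stats.chi2_contingency(ct)
        row = {"variable": var, "kind": "categorical", "stat": float(chi2),
               "p": float(p)}
        for s in statuses:
            n = ct[s]
            row[s] = "; ".join(f"{lev}: {n[lev]} ({100 * n[lev] / n.sum():.1f}%)"
                               for lev in ct.index)
        rows.append(row)
    return pd.DataFrame(rows)


def span_effect(coefficient: float, span: float) -> int:
    """RT change (ms, nearest integer) implied by a slope over a full span.

    E.g. a −11.67 ms-per-unit taste-difference slope over the full 8-unit
    span (−4 to +4) implies a ≈ 93 ms speed difference between preferring a
    very tasty versus a very un-tasty food.
    """
    if not (np.isfinite(coefficient) and np.isfinite(span)):
        raise ValueError("coefficient and span must be finite")
    return int(round(abs(coefficient) * span))
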