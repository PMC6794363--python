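"""Dietary decision-making task scoring.

The task has two phases.  Phase one: the participant rates 50 foods for
taste and health on 1–5 Likert scales; the food closest to the participant's
median taste and median health rating becomes the *referent*.  Phase two:
each remaining food (the *target*) is shown against the referent and the
participant reports a preference on a −2..+2 scale (0 = neutral), with the
reaction time (RT) recorded in milliseconds.

This module derives, per trial, the preferred-minus-non-preferred health and
taste difference scores and their composite (health − taste, collapsed to
±5), and, per participant, ordinary-least-squares *health sensitivity* and
*taste sensitivity* coefficients (preference regressed on target-minus-
referent rating differences), preference proportions, and a ±2.2 SD
reaction-time trim.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: collapsed range of the health-minus-taste composite score
HT_COLLAPSE_LIMIT = 5


class TaskValidationError(ValueError):
    """Raised on schema or range violations in ratings/trials tables."""


def _ratings_frame(ratings: pd.DataFrame) -> pd.DataFrame:
    req = {"item_id", "taste", "health"}
    missing = req - set(ratings.columns)
    if missing:
        raise TaskValidationError(f"ratings table missing columns {sorted(missing)}")
    bad = ratings[
        ~ratings["taste"].between(1, 5) | ~ratings["health"].between(1, 5)
    ]
    if len(bad):
        raise TaskValidationError(
            f"ratings outside 1..5 for items {bad['item_id'].tolist()[:5]}"
        )
    return ratings


def select_referent(ratings: pd.DataFrame, metric: str = "euclidean"):
    """Select the referent food: the item closest to the participant's median
    taste and median health rating.

    Parameters
    ----------
    ratings
        One participant's ratings with columns item_id, taste, health.
    metric
        "euclidean" (default) or "chebyshev" distance in (taste, health)
        space. Ties are broken by the lowest item_id.

    Returns
    -------
    The item_id of the referent.
    """
    ratings = _ratings_frame(ratings)
    if len(ratings) < 3:
        raise TaskValidationError("need at least 3 rated items to pick a referent")
    med_t = ratings["taste"].median()
    med_h = ratings["health"].median()
    dt = ratings["taste"].to_numpy(float) - med_t
    dh = ratings["health"].to_numpy(float) - med_h
    if metric == "euclidean":
        dist = np.hypot(dt, dh)
    elif metric == "chebyshev":
        dist = np.maximum(np.abs(dt), np.abs(dh))
    else:
        raise ValueError(f"unknown metric {metric!r}")
    # lowest item_id wins ties
    order = np.lexsort((ratings["item_id"].to_numpy(), dist))
    return ratings["item_id"].iloc[order[0]]


def collapse_ht_diff(ht_diff_raw):
    """Collapse the health-minus-taste composite to the ±5 range.

    Raw values −8, −7, −6 are recoded to −5 and 6, 7, 8 to 5; values already
    within ±5 are unchanged (the map is idempotent and order-preserving).
    """
    return np.clip(ht_diff_raw, -HT_COLLAPSE_LIMIT, HT_COLLAPSE_LIMIT)


def derive_trial(preference: int, target_rating: tuple, referent_rating: tuple) -> dict:
    """Derive difference scores for a single trial.

    Parameters
    ----------
    preference
        The Likert preference for the target over the referent, −2..+2.
    target_rating, referent_rating
        (taste, health) rating pairs for the two foods.

    Returns
    -------
    dict with keys preferred_side ("target", "referent" or "none"),
    health_diff, taste_diff, ht_diff_raw, ht_diff_collapsed.  Difference
    scores are the preferred food's rating minus the non-preferred food's
    rating and are None on neutral trials.
    """
    if preference not in (-2, -1, 0, 1, 2):
        raise TaskValidationError(f"preference {preference} outside -2..2")
    t_taste, t_health = target_rating
    r_taste, r_health = referent_rating
    if preference == 0:
        return {
            "preferred_side": "none",
            "health_diff": None,
            "taste_diff": None,
            "ht_diff_raw": None,
            "ht_diff_collapsed": None,
        }
    if preference > 0:
        side, hd, td = "target", t_health - r_health, t_taste - r_taste
    else:
        side, hd, td = "referent", r_health - t_health, r_taste - t_taste
    raw = hd - td
    return {
        "preferred_side": side,
        "health_diff": hd,
        "taste_diff": td,
        "ht_diff_raw": raw,
        "ht_diff_collapsed": int(collapse_ht_diff(raw)),
    }


def derive_trials(trials: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    """Vectorized trial derivation for a full trials table.

    Parameters
    ----------
    trials
        Columns participant_id, target_item_id, referent_item_id,
        preference, rt_ms.
    ratings
        Columns participant_id, item_id, taste, health.

    Returns
    -------
    The trials table with preferred_side, health_diff, taste_diff,
    ht_diff_raw, ht_diff_collapsed, and target-minus-referent columns
    d_health, d_taste appended.  Difference scores are NaN on neutral
    (preference 0) trials; d_health/d_taste are defined on every trial.
    """
    if (trials["target_item_id"] == trials["referent_item_id"]).any():
        raise TaskValidationError("target and referent must differ on every trial")
    if not trials["preference"].isin([-2, -1, 0, 1, 2]).all():
        raise TaskValidationError("preference values must lie in -2..2")
    _ratings_frame(ratings)

    idx = ratings.set_index(["participant_id", "item_id"])[["taste", "health"]]
    t_key = pd.MultiIndex.from_frame(trials[["participant_id", "target_item_id"]])
    r_key = pd.MultiIndex.from_frame(trials[["participant_id", "referent_item_id"]])
    for key, label in ((t_key, "target"), (r_key, "referent")):
        missing = ~key.isin(idx.index)
        if missing.any():
            bad = trials.loc[missing, ["participant_id"]].iloc[0]
            raise TaskValidationError(
                f"unrated {label} item in trial for participant {bad['participant_id']}"
            )
    t = idx.reindex(t_key).to_numpy(float)
    r = idx.reindex(r_key).to_numpy(float)

    pref = trials["preference"].to_numpy(int)
    sign = np.sign(pref).astype(float)
    d_taste = t[:, 0] - r[:, 0]
    d_health = t[:, 1] - r[:, 1]

    out = trials.copy()
    out["d_taste"] = d_taste
    out["d_health"] = d_health
    out["preferred_side"] = np.where(
        pref > 0, "target", np.where(pref < 0, "referent", "none")
    )
    with np.errstate(invalid="ignore"):
        hd = np.where(sign == 0, np.nan, sign * d_health)
        td = np.where(sign == 0, np.nan, sign * d_taste)
    out["health_diff"] = hd
    out["taste_diff"] = td
    out["ht_diff_raw"] = hd - td
    out["ht_diff_collapsed"] = collapse_ht_diff(out["ht_diff_raw"])
    return out


def estimate_sensitivities(trials: pd.DataFrame, ratings: pd.DataFrame | None = None):
    """Per-participant taste and health sensitivity coefficients.

    Fits ordinary least squares of preference (−2..+2, neutral trials
    included) on an intercept plus the target-minus-referent health and
    taste rating differences, over all completed trials for one participant.

    Parameters
    ----------
    trials
        One participant's trials. If ``ratings`` is given, difference
        columns are derived first; otherwise the table must already carry
        d_health and d_taste.

    Returns
    -------
    (taste_sensitivity, health_sensitivity) slope pair, or (nan, nan) when
    the design matrix is rank-deficient.
    """
    if ratings is not None:
        trials = derive_trials(trials, ratings)
    X = trials[["d_health", "d_taste"]].to_numpy(float)
    y = trials["preference"].to_numpy(float)
    if len(y) < 3:
        raise TaskValidationError("need at least 3 trials to estimate sensitivities")
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        return float("nan"), float("nan")
    fit = sm.OLS(y, Xc).fit()
    b_health, b_taste = fit.params[1], fit.params[2]
    return float(b_taste), float(b_health)


def preference_proportions(derived: pd.DataFrame):
    """Proportion of healthy and of tasty options preferred.

    Numerators count preferred (non-neutral) trials whose health (taste)
    difference score exceeds zero; the denominator is all completed trials,
    neutral ones included.
    """
    n = len(derived)
    if n == 0:
        raise TaskValidationError("no completed trials")
    prop_healthy = float((derived["health_diff"] > 0).sum()) / n
    prop_tasty = float((derived["taste_diff"] > 0).sum()) / n
    return prop_healthy, prop_tasty


def score_task(trials: pd.DataFrame, ratings: pd.DataFrame) -> pd.DataFrame:
    """Score the task for every participant.

    Returns
    -------
    DataFrame with one row per participant: health_sensitivity,
    taste_sensitivity, prop_healthy, prop_tasty, n_trials_completed,
    n_trials_preferred.  Participants with rank-deficient designs carry NaN
    sensitivities and are counted in the log.
    """
    derived = derive_trials(trials, ratings)
    rows = []
    n_flagged = 0
    for pid, grp in derived.groupby("participant_id", sort=True):
        taste_s, health_s = estimate_sensitivities(grp)
        if np.isnan(health_s):
            n_flagged += 1
        prop_h, prop_t = preference_proportions(grp)
        rows.append(
            {
                "participant_id": pid,
                "health_sensitivity": health_s,
                "taste_sensitivity": taste_s,
                "prop_healthy": prop_h,
                "prop_tasty": prop_t,
                "n_trials_completed": len(grp),
                "n_trials_preferred": int((grp["preference"] != 0).sum()),
            }
        )
    if n_flagged:
        logger.warning(
            "%d participants had rank-deficient sensitivity designs", n_flagged
        )
    return pd.DataFrame(rows)


@dataclass
class RTTrimReport:
    """Counts of reaction-time trials removed by the ±k·SD rule."""

    n_input: int
    n_removed: int
    per_participant: dict

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def filter_rt_outliers(
    trials: pd.DataFrame,
    k: float = 2.2,
    unit: str = "participant",
) -> tuple[pd.DataFrame, RTTrimReport]:
    """Remove trials whose RT lies outside mean ± k·SD.

    The mean and (n−1) SD are computed once within the trimming unit
    (default: per participant; ``unit="pooled"`` uses the whole table) —
    a single pass, not iterated.  Zero-variance units remove nothing.

    Returns
    -------
    (retained trials, RTTrimReport)
    """
    if unit not in ("participant", "pooled"):
        raise ValueError(f"unknown trimming unit {unit!r}")

    def _mask(rt: pd.Series) -> pd.Series:
        if len(rt) < 3:
            raise TaskValidationError("need at least 3 trials per trimming unit")
        sd = rt.std(ddof=1)
        if sd == 0:
            return pd.Series(True, index=rt.index)
        m = rt.mean()
        return (rt >= m - k * sd) & (rt <= m + k * sd)

    if unit == "pooled":
        keep = _mask(trials["rt_ms"])
    else:
        keep = trials.groupby("participant_id")["rt_ms"].transform(
            lambda s: _mask(s)
        ).astype(bool)

    removed = trials[~keep]
    per_part = removed.groupby("participant_id").size().to_dict()
    report = RTTrimReport(
        n_input=len(trials), n_removed=int((~keep).sum()), per_participant=per_part
    )
    logger.info(
        "RT trimming removed %d of %d trials", report.n_removed, report.n_input
    )
    return trials[keep], report
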