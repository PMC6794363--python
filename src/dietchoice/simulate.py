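"""Synthetic cohort generator with known ground truth.

Emulates the data structure of an online dietary decision-making study:

* latent eating-behavior traits (cognitive restraint CR, uncontrolled
  eating UE, emotional eating EE) on a 0–100 scale, with UE–EE correlated
  (default r = 0.70);
* TFEQ-R18 item responses obtained by discretizing each trait onto the
  item scale with item-level noise, so scored subscales approximately
  recover the traits;
* food taste/health latents (negatively correlated by default — tasty
  foods tend to be rated less healthy) and noisy per-participant 1–5
  Likert ratings;
* preference trials against a referent food, generated from a linear
  utility u = w_health·Δhealth + w_taste·Δtaste + ε mapped to the −2..+2
  Likert scale by fixed symmetric thresholds, where the weights shift
  with the participant's traits (restraint raises the health weight,
  disinhibition raises the taste weight);
* reaction times with linear difference-score slopes whose steepness is
  itself trait-modulated, multiplicative lognormal noise, an optional
  outlier fraction, and a stimulus cap;
* demographics (age, sex, height/weight, race, income, education) with
  configurable trait and RT links so covariate screening has signal.

The generator's latent weights and RT slopes are returned as a ground-truth
table that the scoring pipeline never reads, enabling parameter-recovery
tests.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dietchoice.task import select_referent
from dietchoice.tfeq import TFEQItemMap

#: fixed symmetric utility-to-Likert thresholds (utility units)
PREFERENCE_THRESHOLDS = (-1.5, -0.5, 0.5, 1.5)

#: hard floor on simulated reaction times (ms)
RT_FLOOR_MS = 200.0


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic cohort.

    Trait scale parameters follow typical adult samples (CR ≈ 42 ± 22,
    UE ≈ 36 ± 19, EE ≈ 36 ± 28 on the 0–100 scale). Reaction-time defaults
    put the average around 1.3 s with a 4 s stimulus cap and difference-
    score slopes near −13 ms (health) and −11 ms (taste) per rating unit.
    """

    n_participants: int = 500
    n_foods: int = 50
    seed: int = 0

    # latent traits (0-100 scale)
    rho_ue_ee: float = 0.70
    cr_mean: float = 42.0
    cr_sd: float = 22.0
    ue_mean: float = 36.0
    ue_sd: float = 19.0
    ee_mean: float = 36.0
    ee_sd: float = 28.0
    #: SD of the noise added to each discretized TFEQ item response
    item_noise_sd: float = 0.3

    # foods and ratings
    food_health_taste_corr: float = -0.3
    food_mean: float = 3.0
    food_sd: float = 1.0
    rating_noise_sd: float = 0.6

    # preference weights: w = base ± gamma·z(trait) + noise
    w_health_base: float = 0.35
    w_taste_base: float = 0.65
    gamma_health_cr: float = 0.05
    gamma_health_dis: float = 0.025
    gamma_taste_cr: float = 0.035
    gamma_taste_dis: float = 0.025
    weight_noise_sd: float = 0.18
    preference_noise_sd: float = 0.4

    # reaction times
    rt_base_ms: float = 1300.0
    rt_slope_health_ms: float = 13.0
    rt_slope_taste_ms: float = 11.0
    #: trait modulation of the RT slopes, ms per SD of trait
    rt_trait_modulation: float = 8.0
    rt_between_sd_ms: float = 40.0
    rt_noise_sigma: float = 0.15
    outlier_rate: float = 0.02
    rt_cap_ms: float = 4000.0

    # demographics
    age_mean: float = 34.0
    age_sd: float = 8.0
    age_rt_ms_per_year: float = 5.0
    bmi_mean: float = 27.5
    bmi_sd: float = 6.0
    bmi_cr_corr: float = 0.15
    bmi_dis_corr: float = 0.15

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be positive")
        if self.n_foods < 3:
            raise ValueError("n_foods must be at least 3")
        for name in ("rho_ue_ee", "food_health_taste_corr", "bmi_cr_corr",
                     "bmi_dis_corr"):
            v = getattr(self, name)
            if not np.isfinite(v) or not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must be a correlation in [-1, 1]")
        if not 0.0 <= self.outlier_rate <= 1.0:
            raise ValueError("outlier_rate must be a probability in [0, 1]")
        for name in ("cr_sd", "ue_sd", "ee_sd", "item_noise_sd", "food_sd",
                     "rating_noise_sd", "weight_noise_sd", "preference_noise_sd",
                     "rt_between_sd_ms", "rt_noise_sigma", "age_sd", "bmi_sd"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name}={v} must be a nonnegative finite number")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and not np.isfinite(v):
                raise ValueError(f"{f.name} must be finite, got {v}")
        if not self.rt_cap_ms > self.rt_base_ms:
            raise ValueError("rt_cap_ms must exceed rt_base_ms")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


#: inflation applied to the latent UE-EE normal correlation so that the
#: *scored* subscales hit the configured rho despite the attenuation from
#: range clipping and item discretization (calibrated once at defaults)
_RHO_CALIBRATION = 1.12


def _draw_traits(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent (CR, UE, EE) on 0-100, UE-EE correlated, clipped to range."""
    rho_latent = float(np.clip(cfg.rho_ue_ee * _RHO_CALIBRATION, -0.999, 0.999))
    corr = np.array(
        [
            [1.0, 0.0, 0.0],
            [0.0, 1.0, rho_latent],
            [0.0, rho_latent, 1.0],
        ]
    )
    sds = np.array([cfg.cr_sd, cfg.ue_sd, cfg.ee_sd])
    means = np.array([cfg.cr_mean, cfg.ue_mean, cfg.ee_mean])
    cov = corr * np.outer(sds, sds)
    z = rng.multivariate_normal(means, cov, size=cfg.n_participants,
                                method="cholesky")
    return np.clip(z, 0.0, 100.0)


def _tfeq_items(
    traits: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator,
    item_map: TFEQItemMap,
) -> pd.DataFrame:
    """Discretize each trait onto its subscale's item scales with noise."""
    n = traits.shape[0]
    trait_for = {"cr": traits[:, 0], "ue": traits[:, 1], "ee": traits[:, 2]}
    cols: dict[str, np.ndarray] = {}
    for sub, items in item_map.assignment.items():
        t = trait_for[sub]
        for i in items:
            lo, hi = item_map.ranges[i]
            expected = lo + (hi - lo) * t / 100.0
            resp = np.rint(expected + rng.normal(0.0, cfg.item_noise_sd, size=n))
            if i in item_map.reverse:
                resp = lo + hi - resp
            cols[f"item_{i}"] = np.clip(resp, lo, hi).astype(int)
    df = pd.DataFrame(cols)
    df = df[[f"item_{i}" for i in range(1, item_map.n_items + 1)]]
    df.insert(0, "participant_id", np.arange(1, n + 1))
    return df


def _food_latents(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-food latent (taste, health) with the configured correlation."""
    r = cfg.food_health_taste_corr
    cov = cfg.food_sd**2 * np.array([[1.0, r], [r, 1.0]])
    return rng.multivariate_normal(
        [cfg.food_mean, cfg.food_mean], cov, size=cfg.n_foods, method="cholesky"
    )


def _ratings(
    latents: np.ndarray, cfg: SimulationConfig, rng: np.random.Generator
) -> np.ndarray:
    """Noisy 1-5 Likert ratings, shape (participants, foods, 2) = (taste, health)."""
    n, m = cfg.n_participants, cfg.n_foods
    noise = rng.normal(0.0, cfg.rating_noise_sd, size=(n, m, 2))
    return np.clip(np.rint(latents[None, :, :] + noise), 1, 5).astype(int)


def _ratings_table(vals: np.ndarray) -> pd.DataFrame:
    n, m, _ = vals.shape
    return pd.DataFrame(
        {
            "participant_id": np.repeat(np.arange(1, n + 1), m),
            "item_id": np.tile(np.arange(1, m + 1), n),
            "taste": vals[:, :, 0].ravel(),
            "health": vals[:, :, 1].ravel(),
        }
    )


def generate_cohort(
    config: SimulationConfig | None = None,
    item_map: TFEQItemMap | None = None,
):
    """Generate a complete synthetic study dataset.

    Returns
    -------
    (demographics, tfeq_items, ratings, trials, ground_truth)
        Five DataFrames. ``ground_truth`` holds the latent trait values,
        preference weights (w_health, w_taste) and RT slopes
        (b_health, b_taste) per participant; the scoring pipeline must
        never read it.

    Notes
    -----
    Deterministic: identical (config, seed) gives bit-identical tables.
    All ratings lie in 1..5, preferences in −2..+2 and reaction times in
    (0, rt_cap_ms].
    """
    cfg = config or SimulationConfig()
    imap = item_map or TFEQItemMap()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_participants

    traits = _draw_traits(cfg, rng)
    tfeq_items = _tfeq_items(traits, cfg, rng, imap)
    latents = _food_latents(cfg, rng)
    rating_vals = _ratings(latents, cfg, rng)
    ratings = _ratings_table(rating_vals)

    # standardized traits on the configured (not sample) scale
    z_cr = (traits[:, 0] - cfg.cr_mean) / cfg.cr_sd
    dis = (traits[:, 1] + traits[:, 2]) / 2.0
    dis_mean = (cfg.ue_mean + cfg.ee_mean) / 2.0
    dis_sd = 0.5 * np.sqrt(
        cfg.ue_sd**2 + cfg.ee_sd**2 + 2.0 * cfg.rho_ue_ee * cfg.ue_sd * cfg.ee_sd
    )
    z_dis = (dis - dis_mean) / dis_sd

    w_health = (
        cfg.w_health_base
        + cfg.gamma_health_cr * z_cr
        - cfg.gamma_health_dis * z_dis
        + rng.normal(0.0, cfg.weight_noise_sd, size=n)
    )
    w_taste = (
        cfg.w_taste_base
        - cfg.gamma_taste_cr * z_cr
        + cfg.gamma_taste_dis * z_dis
        + rng.normal(0.0, cfg.weight_noise_sd, size=n)
    )
    b_health = cfg.rt_slope_health_ms + cfg.rt_trait_modulation * (z_cr - z_dis)
    b_taste = cfg.rt_slope_taste_ms - cfg.rt_trait_modulation * (z_cr - z_dis)

    # demographics, with age->RT and trait->BMI links for screening to find
    age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n), 18, 50)
    sex = np.where(rng.random(n) < 0.5, "male", "female")
    resid = np.sqrt(max(0.0, 1.0 - cfg.bmi_cr_corr**2 - cfg.bmi_dis_corr**2))
    bmi = np.clip(
        cfg.bmi_mean
        + cfg.bmi_sd
        * (cfg.bmi_cr_corr * z_cr + cfg.bmi_dis_corr * z_dis
           + resid * rng.normal(size=n)),
        16.0,
        60.0,
    )
    height = np.clip(rng.normal(1.70, 0.10, size=n), 1.45, 2.05)
    weight = bmi * height**2
    race = rng.choice(
        ["White", "African American", "Other"], size=n, p=[0.83, 0.065, 0.105]
    )
    income = np.clip(np.exp(rng.normal(np.log(40000.0), 0.6, size=n)), 5000, 250000)
    education = rng.choice(
        ["high school", "some college", "bachelor", "graduate"],
        size=n,
        p=[0.2, 0.3, 0.35, 0.15],
    )
    demographics = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "age": np.round(age, 1),
            "sex": sex,
            "height_m": np.round(height, 3),
            "weight_kg": np.round(weight, 1),
            "race": race,
            "income_usd": np.round(income, 0),
            "education": education,
        }
    )

    rt_base = (
        cfg.rt_base_ms
        + cfg.age_rt_ms_per_year * (age - cfg.age_mean)
        + rng.normal(0.0, cfg.rt_between_sd_ms, size=n)
    )

    trial_rows = []
    thr = np.asarray(PREFERENCE_THRESHOLDS)
    item_ids = np.arange(1, cfg.n_foods + 1)
    for p in range(n):
        pid = p + 1
        pr = pd.DataFrame(
            {"item_id": item_ids, "taste": rating_vals[p, :, 0],
             "health": rating_vals[p, :, 1]}
        )
        referent = int(select_referent(pr))
        targets = item_ids[item_ids != referent].copy()
        rng.shuffle(targets)

        r_taste = float(rating_vals[p, referent - 1, 0])
        r_health = float(rating_vals[p, referent - 1, 1])
        t_taste = rating_vals[p, targets - 1, 0].astype(float)
        t_health = rating_vals[p, targets - 1, 1].astype(float)
        d_taste = t_taste - r_taste
        d_health = t_health - r_health

        u = (
            w_health[p] * d_health
            + w_taste[p] * d_taste
            + rng.normal(0.0, cfg.preference_noise_sd, size=len(targets))
        )
        pref = np.searchsorted(thr, u, side="right") - 2  # -2..+2

        sign = np.sign(pref)
        hd = sign * d_health  # preferred-minus-nonpreferred; 0 when neutral
        td = sign * d_taste
        rt = rt_base[p] - b_health[p] * hd - b_taste[p] * td
        if cfg.rt_noise_sigma > 0:
            rt = rt * np.exp(rng.normal(0.0, cfg.rt_noise_sigma, size=len(rt)))
        if cfg.outlier_rate > 0:
            mask = rng.random(len(rt)) < cfg.outlier_rate
            rt = np.where(mask, rt * rng.uniform(2.0, 3.0, size=len(rt)), rt)
        rt = np.clip(rt, RT_FLOOR_MS, cfg.rt_cap_ms)

        trial_rows.append(
            pd.DataFrame(
                {
                    "participant_id": pid,
                    "trial": np.arange(1, len(targets) + 1),
                    "target_item_id": targets,
                    "referent_item_id": referent,
                    "preference": pref.astype(int),
                    "rt_ms": np.round(rt, 3),
                }
            )
        )
    trials = pd.concat(trial_rows, ignore_index=True)

    ground_truth = pd.DataFrame(
        {
            "participant_id": np.arange(1, n + 1),
            "cr_true": traits[:, 0],
            "ue_true": traits[:, 1],
            "ee_true": traits[:, 2],
            "w_health": w_health,
            "w_taste": w_taste,
            "b_health": b_health,
            "b_taste": b_taste,
        }
    )
    return demographics, tfeq_items, ratings, trials, ground_truth
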