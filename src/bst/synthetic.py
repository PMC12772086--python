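"""Synthetic questionnaire and clinic-record cohorts with known ground truth.

Two linked tables are generated from one configuration:

* a **questionnaire cohort** — one row per dog/owner dyad with breed, sex,
  age, neuter status, an owner-reported 9-point body condition score (BCS)
  and 26 Likert items (13 dog eating-behaviour items, 13 owner-management
  items) produced by thresholding item-level latents; and
* an **EHR cohort** — clinic visits with breed, sex, whole-year age and a
  5-point BCS drawn from a 3-category (underweight / ideal / overweight-
  obese) multinomial on the log-odds scale.

Both tables share the same per-breed latent food-motivation means, and the
per-breed overweight propensity in the EHR arm is constructed to correlate
with breed latent food motivation at an exact configurable target, so the
end-to-end breed-level association is recoverable by downstream analysis.
Breed sample sizes are drawn log-uniformly between configurable bounds to
mimic the heavy breed imbalance of real clinic populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .scoring import LABELS_DESCENDING, default_items

SEXES = ("female", "male")
NEUTER = ("entire", "neutered")
BCS_CATEGORIES = ("underweight", "ideal", "overweight_obese")


@dataclass
class SimConfig:
    """Generative parameters for both synthetic cohorts.

    Latent food motivation (FM) for dog *i* of breed *b* is::

        fm_i = fm_b + beta_sex*male_i + beta_neuter*neutered_i
                    + beta_age*(age_i - age_mean) + N(0, fm_individual_sd)

    with breed means ``fm_b ~ N(breed_fm_mean, breed_fm_sd)``.  Owner BCS is
    a rounded, clamped linear function of latent FM, latent owner control
    and their product.  EHR body-condition categories come from a softmax
    against the 'ideal' reference with per-breed overweight propensities
    correlated with ``fm_b`` at exactly ``obesity_breed_corr``.
    """

    # cohort sizes and breed structure
    n_dogs: int = 14960
    n_breeds: int = 46
    breed_size_imbalance: float = 35.0  # max/min log-uniform breed-weight ratio

    # latent food motivation
    breed_fm_mean: float = 0.633     # grand mean of the 0-1 composite
    breed_fm_sd: float = 0.10        # between-breed sd
    fm_individual_sd: float = 0.20   # within-breed sd
    beta_sex: float = 0.02           # male effect
    beta_neuter: float = 0.06        # neutered effect
    beta_age: float = 0.004          # per year, centred at age_mean
    age_mean: float = 5.41
    age_sd: float = 3.32

    # owner-control latent and Likert measurement
    oc_mean: float = 0.5
    oc_sd: float = 0.15
    fm_oc_corr: float = 0.12         # latent FM / owner-control correlation
    item_noise_sd: float = 0.12
    # threshold geometry calibrated so the measured 0-1 composite reproduces
    # the questionnaire population's mean ~0.63 and sd ~0.25
    item_threshold_step: float = 0.25
    item_threshold_shift: float = -0.09

    # owner-reported 9-point BCS
    bcs_intercept: float = 5.0
    bcs_fm_slope: float = 0.8
    bcs_breed_slope: float = 0.5     # breed obesity propensity beyond measured FM
    bcs_control_slope: float = -1.5
    bcs_interaction_slope: float = -3.0
    bcs_beta_sex: float = 0.10       # direct male effect on owner BCS
    bcs_beta_neuter: float = 0.35    # direct neutering effect on owner BCS
    bcs_beta_age: float = 0.02       # per year of age, centred at age_mean
    bcs_noise_sd: float = 0.9
    bcs_missing_rate: float = 0.03

    # EHR arm
    ehr_n_dogs: int = 27600
    ehr_age_range: tuple = (1, 15)
    ehr_under_intercept: float = -2.4  # log-odds underweight vs ideal
    ehr_over_intercept: float = -0.3   # log-odds overweight/obese vs ideal
    ehr_beta_age_over: float = 0.05    # per year of age
    ehr_beta_sex_over: float = 0.10    # male effect
    ehr_beta_age_under: float = -0.03
    ehr_beta_sex_under: float = 0.0
    obesity_breed_corr: float = 0.7
    obesity_propensity_sd: float = 0.5

    seed: int = 0

    def validate(self) -> None:
        for f in ("n_dogs", "n_breeds", "ehr_n_dogs"):
            v = getattr(self, f)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ConfigurationError(f, "must be a non-negative integer")
        if self.n_breeds == 0 and (self.n_dogs > 0 or self.ehr_n_dogs > 0):
            raise ConfigurationError("n_breeds", "must be positive when dogs are requested")
        for f in ("breed_fm_sd", "fm_individual_sd", "item_noise_sd", "oc_sd",
                  "bcs_noise_sd", "obesity_propensity_sd", "age_sd"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f, "standard deviations must be >= 0")
        if not 0.0 <= self.breed_fm_mean <= 1.0:
            raise ConfigurationError("breed_fm_mean", "must lie in [0, 1]")
        if not -1.0 <= self.obesity_breed_corr <= 1.0:
            raise ConfigurationError("obesity_breed_corr", "must lie in [-1, 1]")
        if not -1.0 <= self.fm_oc_corr <= 1.0:
            raise ConfigurationError("fm_oc_corr", "must lie in [-1, 1]")
        if not 0.0 <= self.bcs_missing_rate <= 1.0:
            raise ConfigurationError("bcs_missing_rate", "must lie in [0, 1]")
        lo, hi = self.ehr_age_range
        if not (1 <= lo <= hi <= 15):
            raise ConfigurationError("ehr_age_range", "must satisfy 1 <= lo <= hi <= 15")
        if self.breed_size_imbalance < 1:
            raise ConfigurationError("breed_size_imbalance", "must be >= 1")


@dataclass
class SimTruth:
    """Ground truth written alongside each generated table.

    ``breed_latent_fm`` and ``breed_obesity_propensity`` cover exactly the
    generated breeds; ``coefficients`` holds every generative parameter so
    expected category probabilities can be recomputed for any row (see
    :meth:`ehr_category_probs`).  ``dog_latent_fm`` / ``dog_latent_oc`` are
    per-row diagnostics for the questionnaire arm.
    """

    breed_latent_fm: dict
    breed_obesity_propensity: dict
    coefficients: dict
    dog_latent_fm: np.ndarray | None = None
    dog_latent_oc: np.ndarray | None = None

    def ehr_category_probs(self, breed: str, age: float, sex: str):
        """Expected (underweight, ideal, overweight_obese) probabilities."""
        c = self.coefficients
        male = 1.0 if sex == "male" else 0.0
        age_c = age - c["ehr_age_mid"]
        eta_u = c["ehr_under_intercept"] + c["ehr_beta_age_under"] * age_c \
            + c["ehr_beta_sex_under"] * male
        eta_o = c["ehr_over_intercept"] + self.breed_obesity_propensity[breed] \
            + c["ehr_beta_age_over"] * age_c + c["ehr_beta_sex_over"] * male
        p_ideal = 1.0 / (1.0 + np.exp(eta_u) + np.exp(eta_o))
        return np.exp(eta_u) * p_ideal, p_ideal, np.exp(eta_o) * p_ideal

    def to_json_dict(self) -> dict:
        return {
            "breed_latent_fm": {k: float(v) for k, v in self.breed_latent_fm.items()},
            "breed_obesity_propensity": {
                k: float(v) for k, v in self.breed_obesity_propensity.items()
            },
            "coefficients": {k: (list(v) if isinstance(v, tuple) else v)
                             for k, v in self.coefficients.items()},
        }


def _streams(config: SimConfig):
    """Child RNG streams: (breeds, questionnaire, ehr) from one root seed."""
    children = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _breed_truth(config: SimConfig, rng: np.random.Generator):
    """Per-breed latent FM and overweight propensity at the exact target correlation."""
    names = [f"breed_{i + 1:02d}" for i in range(config.n_breeds)]
    z_fm = rng.standard_normal(config.n_breeds)
    z_res = rng.standard_normal(config.n_breeds)
    fm_b = config.breed_fm_mean + config.breed_fm_sd * z_fm
    rho = config.obesity_breed_corr
    if config.n_breeds >= 3 and np.std(z_fm) > 0:
        # Gram-Schmidt so the realised breed-level correlation equals rho exactly
        a = (z_fm - z_fm.mean()) / z_fm.std()
        r = z_res - z_res.mean()
        r -= (r @ a) / (a @ a) * a
        if np.std(r) > 0:
            r /= r.std()
        prop = config.obesity_propensity_sd * (rho * a + np.sqrt(1 - rho**2) * r)
    else:
        prop = config.obesity_propensity_sd * (
            rho * z_fm + np.sqrt(1 - rho**2) * z_res
        )
    return names, dict(zip(names, fm_b)), dict(zip(names, prop))


def _breed_assignment(rng, names, n, imbalance):
    """Multinomial breed sizes with log-uniform weights in [1, imbalance]."""
    if not names:
        return np.array([], dtype=int)
    w = np.exp(rng.uniform(0.0, np.log(imbalance), size=len(names)))
    return rng.choice(len(names), size=n, p=w / w.sum())


def _likert_labels(latent, centre, n_options, step, reversed_item):
    """Discretise an item latent into labels, monotone in the scored value."""
    cuts = centre + step * (np.arange(1, n_options) - n_options / 2.0)
    idx = np.searchsorted(cuts, latent, side="right")  # 0 = lowest score
    labels = LABELS_DESCENDING[n_options]
    if reversed_item:
        return [labels[i] for i in idx]
    return [labels[n_options - 1 - i] for i in idx]


def generate_questionnaire_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the dyad questionnaire table and its ground truth.

    Ages are drawn wider ([0.5, 21]) than the downstream inclusion window
    (>1, <19 years) so that age filters are exercised, and a small fraction
    of owner BCS values is missing.
    """
    config.validate()
    rng_breed, rng_q, _ = _streams(config)
    names, fm_map, prop_map = _breed_truth(config, rng_breed)
    n = config.n_dogs
    truth = SimTruth(fm_map, prop_map, _coefficients(config))
    if n == 0:
        return _empty_questionnaire_frame(), truth

    breed_idx = _breed_assignment(rng_q, names, n, config.breed_size_imbalance)
    breed = np.array(names)[breed_idx]
    male = rng_q.random(n) < 0.5
    neutered = rng_q.random(n) < 0.68

    shape = (config.age_mean / config.age_sd) ** 2
    scale = config.age_sd**2 / config.age_mean
    age = np.clip(rng_q.gamma(shape, scale, size=n), 0.5, 21.0)
    # force a small tail outside the analysis window so filters always bite
    u = rng_q.random(n)
    age = np.where(u < 0.02, rng_q.uniform(0.5, 1.0, size=n), age)
    age = np.where(u > 0.98, rng_q.uniform(19.0, 21.0, size=n), age)
    age = np.round(age, 1)

    fm_b = np.array([fm_map[b] for b in breed])
    fm = (
        fm_b
        + config.beta_sex * male
        + config.beta_neuter * neutered
        + config.beta_age * (age - config.age_mean)
        + config.fm_individual_sd * rng_q.standard_normal(n)
    )
    # owner-control latent, correlated with FM via empirical standardisation
    fm_sd = fm.std()
    z_fm = (fm - fm.mean()) / fm_sd if fm_sd > 0 else np.zeros(n)
    rho = config.fm_oc_corr
    oc = config.oc_mean + config.oc_sd * (
        rho * z_fm + np.sqrt(1 - rho**2) * rng_q.standard_normal(n)
    )

    records = {
        "dog_id": [f"dog_{i + 1:06d}" for i in range(n)],
        "breed": breed,
        "sex": np.where(male, "male", "female"),
        "age_years": age,
        "neuter": np.where(neutered, "neutered", "entire"),
    }

    fm_c = fm - config.breed_fm_mean
    oc_c = oc - config.oc_mean
    prop_b = np.array([prop_map[b] for b in breed])
    bcs_latent = (
        config.bcs_intercept
        + config.bcs_fm_slope * fm_c
        + config.bcs_breed_slope * prop_b
        + config.bcs_control_slope * oc_c
        + config.bcs_interaction_slope * fm_c * oc_c
        + config.bcs_beta_sex * male
        + config.bcs_beta_neuter * neutered
        + config.bcs_beta_age * (age - config.age_mean)
        + config.bcs_noise_sd * rng_q.standard_normal(n)
    )
    bcs = np.clip(np.round(bcs_latent), 1, 9)
    bcs = np.where(rng_q.random(n) < config.bcs_missing_rate, np.nan, bcs)
    records["bcs_owner_9pt"] = bcs

    items = default_items()
    # deterministic item intercepts spread the item difficulties slightly
    offsets = np.linspace(-0.05, 0.05, len(items))
    for it, off in zip(items, offsets):
        construct = fm if it.factor in ("responsiveness_satiety", "lack_fussiness",
                                        "interest_in_food") else oc
        centre = config.breed_fm_mean if construct is fm else config.oc_mean
        centre += config.item_threshold_shift
        latent = construct + off + config.item_noise_sd * rng_q.standard_normal(n)
        records[it.column] = _likert_labels(
            latent, centre, it.n_options, config.item_threshold_step, it.reversed
        )

    truth.dog_latent_fm = fm
    truth.dog_latent_oc = oc
    return pd.DataFrame(records), truth


def generate_ehr_cohort(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Generate the clinic-visit table (1-4 visits per dog) and ground truth.

    The 5-point BCS is drawn by first sampling a 3-category body-condition
    state from the softmax model and then splitting 'underweight' into
    scores 1/2 and 'overweight_obese' into scores 4/5.
    """
    config.validate()
    rng_breed, _, rng_e = _streams(config)
    names, fm_map, prop_map = _breed_truth(config, rng_breed)
    truth = SimTruth(fm_map, prop_map, _coefficients(config))
    n = config.ehr_n_dogs
    if n == 0:
        return _empty_ehr_frame(), truth

    breed_idx = _breed_assignment(rng_e, names, n, config.breed_size_imbalance)
    breed = np.array(names)[breed_idx]
    male = rng_e.random(n) < 0.5
    lo, hi = config.ehr_age_range
    shape = (config.age_mean / config.age_sd) ** 2
    scale = config.age_sd**2 / config.age_mean
    base_age = np.clip(np.round(rng_e.gamma(shape, scale, size=n)), lo, hi).astype(int)
    n_visits = rng_e.integers(1, 5, size=n)

    dog_ids = np.repeat([f"ehrdog_{i + 1:06d}" for i in range(n)], n_visits)
    v_breed = np.repeat(breed, n_visits)
    v_male = np.repeat(male, n_visits)
    visit_no = np.concatenate([np.arange(k) for k in n_visits])
    v_age = np.clip(np.repeat(base_age, n_visits) + visit_no, lo, hi)

    c = truth.coefficients
    prop = np.array([prop_map[b] for b in v_breed])
    age_c = v_age - c["ehr_age_mid"]
    eta_u = (config.ehr_under_intercept + config.ehr_beta_age_under * age_c
             + config.ehr_beta_sex_under * v_male)
    eta_o = (config.ehr_over_intercept + prop + config.ehr_beta_age_over * age_c
             + config.ehr_beta_sex_over * v_male)
    p_ideal = 1.0 / (1.0 + np.exp(eta_u) + np.exp(eta_o))
    p_under = np.exp(eta_u) * p_ideal

    u = rng_e.random(v_age.size)
    category = np.where(u < p_under, 0, np.where(u < p_under + p_ideal, 1, 2))
    # split merged categories onto the raw 5-point scale
    split = rng_e.random(v_age.size)
    bcs5 = np.select(
        [category == 0, category == 1, category == 2],
        [np.where(split < 0.3, 1, 2), 3, np.where(split < 0.7, 4, 5)],
    )

    frame = pd.DataFrame(
        {
            "visit_id": [f"visit_{i + 1:07d}" for i in range(v_age.size)],
            "dog_id": dog_ids,
            "breed": v_breed,
            "sex": np.where(v_male, "male", "female"),
            "age_years": v_age.astype(int),
            "bcs_5pt": bcs5.astype(int),
        }
    )
    return frame, truth


def _coefficients(config: SimConfig) -> dict:
    c = asdict(config)
    lo, hi = config.ehr_age_range
    c["ehr_age_mid"] = (lo + hi) / 2.0
    c["ehr_age_range"] = (int(lo), int(hi))
    return c


def _empty_questionnaire_frame() -> pd.DataFrame:
    cols = ["dog_id", "breed", "sex", "age_years", "neuter", "bcs_owner_9pt"]
    cols += [it.column for it in default_items()]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _empty_ehr_frame() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "visit_id": pd.Series(dtype=object),
            "dog_id": pd.Series(dtype=object),
            "breed": pd.Series(dtype=object),
            "sex": pd.Series(dtype=object),
            "age_years": pd.Series(dtype=int),
            "bcs_5pt": pd.Series(dtype=int),
        }
    )
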