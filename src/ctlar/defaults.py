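"""Default configuration tables for the national-mimic analysis.

Everything here is editable input, not algorithm: national utilization totals
for 2023, the exam distribution over (sex, age-group, category) cells, mean
examinations per patient, last-year-of-life fractions, the per-stratum organ
dose table, BEIR VII-style risk coefficients, and synthetic US-like life
tables and baseline cancer incidence.

Published summary statistics are used directly where available (national exam
and patient totals, pediatric share, sex/age exam mix, exams-per-patient
means, last-year-of-life anchors, and a set of printed per-stratum mean (SD)
organ doses that override the parametric dose generator). Where no published
value exists the defaults are this package's own synthetic choices and are
flagged as such in the docstrings.
"""

from __future__ import annotations

import math

from .registry import (
    BaselineIncidence,
    LifeTable,
    RegistryGenConfig,
    generate_baseline_incidence,
    generate_life_table,
)
from .risk import (
    DDREFConfig,
    LatencyConfig,
    LatencyGroup,
    LeukemiaCoef,
    RiskConfig,
    SiteRiskModel,
    SolidCoef,
)
from .vocab import (
    ADULT_AGE_GROUPS,
    AGE_GROUPS,
    CATEGORY_BY_NAME,
    CHILD_AGE_GROUPS,
    ORGANS,
    SEXES,
    SITES,
    StratumKey,
    categories_for_group,
    enumerate_strata,
    is_child_group,
)

# --- national utilization constants (2023) ---------------------------------
TOTAL_EXAMS_2023 = 93_000_000
TOTAL_PATIENTS_2023 = 61_510_000
PEDIATRIC_SHARE_ACR = 0.033   # baseline pediatric share of examinations
PEDIATRIC_SHARE_IMV = 0.090   # higher survey-based alternative (sensitivity)
MULTIPHASE_PROB = 0.285       # fraction of exams acquired in multiple phases
TOTAL_EXAMS_2007 = 68_700_000
ANNUAL_CANCER_DIAGNOSES = 1_950_000

# --- exams per patient (mean, by sex and age group) -------------------------
# From published per-patient means by sex and age block, carried onto the
# finer age grouping used for stratification.
DEFAULT_EXAMS_PER_PATIENT: dict[tuple[str, str], float] = {}
_EPP_FEMALE = {
    "0": 1.12, "1-4": 1.18, "5-9": 1.18, "10-14": 1.18, "15-17": 1.18,
    "18-29": 1.34, "30-39": 1.34, "40-49": 1.46, "50-59": 1.46,
    "60-69": 1.56, "70-79": 1.56, "80-89": 1.63, "90-99": 1.63,
}
_EPP_MALE = {
    "0": 1.14, "1-4": 1.18, "5-9": 1.18, "10-14": 1.23, "15-17": 1.23,
    "18-29": 1.41, "30-39": 1.41, "40-49": 1.52, "50-59": 1.52,
    "60-69": 1.61, "70-79": 1.61, "80-89": 1.66, "90-99": 1.66,
}
for g, v in _EPP_FEMALE.items():
    DEFAULT_EXAMS_PER_PATIENT[("female", g)] = v
for g, v in _EPP_MALE.items():
    DEFAULT_EXAMS_PER_PATIENT[("male", g)] = v

# --- exam share by sex and age group ----------------------------------------
# Published exam counts by sex and coarse age block, split onto the finer
# grouping (split fractions are synthetic but conserve the block totals, so
# the pediatric share of exams is 3.3% by construction).
_EXAMS_BY_BLOCK = {
    "female": {
        "<1": 97_000, "1-9": 439_300, "10-17": 870_000, "18-39": 7_972_500,
        "40-59": 13_147_100, "60-79": 18_767_100, "80-99": 7_256_200,
    },
    "male": {
        "<1": 119_800, "1-9": 580_100, "10-17": 962_800, "18-39": 7_282_700,
        "40-59": 11_780_600, "60-79": 18_278_300, "80-99": 5_446_600,
    },
}
_BLOCK_SPLIT = {
    "<1": {"0": 1.0},
    "1-9": {"1-4": 0.45, "5-9": 0.55},
    "10-17": {"10-14": 0.60, "15-17": 0.40},
    "18-39": {"18-29": 0.50, "30-39": 0.50},
    "40-59": {"40-49": 0.50, "50-59": 0.50},
    "60-79": {"60-69": 0.50, "70-79": 0.50},
    "80-99": {"80-89": 0.75, "90-99": 0.25},
}


def default_exam_shares() -> dict[tuple[str, str], float]:
    """Share of all national examinations in each (sex, age-group) cell."""
    total = sum(sum(b.values()) for b in _EXAMS_BY_BLOCK.values())
    shares: dict[tuple[str, str], float] = {}
    for sex, blocks in _EXAMS_BY_BLOCK.items():
        for block, count in blocks.items():
            for group, frac in _BLOCK_SPLIT[block].items():
                shares[(sex, group)] = count * frac / total
    return shares


def default_demographics() -> dict[tuple[str, str], float]:
    """Patient-level (sex, age-group) probabilities: exam shares divided by
    the cell's mean exams per patient, renormalized."""
    shares = default_exam_shares()
    raw = {
        cell: share / DEFAULT_EXAMS_PER_PATIENT[cell] for cell, share in shares.items()
    }
    s = sum(raw.values())
    return {cell: v / s for cell, v in raw.items()}


# --- last-year-of-life fractions --------------------------------------------
# Published anchors: overall 10.6% (9.4% female, 12.1% male); 1.4%/0.5%
# (girls/boys 1-4); 35.1%/44.4% (women/men 90-99). Intermediate ages follow a
# smooth increasing curve whose exam-weighted sex means sit near the anchors.
DEFAULT_EOL_PROB: dict[tuple[str, str], float] = {}
_EOL_FEMALE = {
    "0": 0.020, "1-4": 0.014, "5-9": 0.008, "10-14": 0.008, "15-17": 0.010,
    "18-29": 0.015, "30-39": 0.022, "40-49": 0.035, "50-59": 0.055,
    "60-69": 0.085, "70-79": 0.135, "80-89": 0.220, "90-99": 0.351,
}
_EOL_MALE = {
    "0": 0.025, "1-4": 0.005, "5-9": 0.009, "10-14": 0.009, "15-17": 0.012,
    "18-29": 0.020, "30-39": 0.030, "40-49": 0.045, "50-59": 0.070,
    "60-69": 0.105, "70-79": 0.165, "80-89": 0.270, "90-99": 0.444,
}
for g, v in _EOL_FEMALE.items():
    DEFAULT_EOL_PROB[("female", g)] = v
for g, v in _EOL_MALE.items():
    DEFAULT_EOL_PROB[("male", g)] = v

EOL_OVERALL_FRACTION = 0.106  # published overall last-year-of-life fraction


def default_eol_prob_2yr() -> dict[tuple[str, str], float]:
    """Synthetic last-2-years-of-life fractions: 1.6x the 1-year map capped at
    1.0 (the real 2-year tabulation is not public)."""
    return {cell: min(1.0, 1.6 * p) for cell, p in DEFAULT_EOL_PROB.items()}


# --- category mix ------------------------------------------------------------
# Body-region exam shares from the published national table (head-dominant in
# children, abdomen/pelvis-dominant in adults); within-region tier splits are
# synthetic. The same mix is used for every age group within adults and within
# children.
_ADULT_REGION_SHARE = {
    "abdomen_pelvis": 0.3284, "head": 0.2504, "chest": 0.2191, "spine": 0.0828,
    "head_neck_combined": 0.0314, "cardiac": 0.0116, "full_body": 0.0506,
    "extremity": 0.0257,
}
_CHILD_REGION_SHARE = {
    "abdomen_pelvis": 0.2248, "head": 0.5216, "chest": 0.0897, "spine": 0.0945,
    "cardiac": 0.0086, "full_body": 0.0187, "extremity": 0.0421,
}
_ADULT_TIER_SPLIT = {
    "abdomen_pelvis": {"abdomen_pelvis_routine": 0.55, "abdomen_pelvis_low": 0.25,
                       "abdomen_pelvis_high": 0.20},
    "head": {"head_routine": 0.65, "head_low": 0.10, "head_high": 0.10,
             "head_angiography": 0.15},
    "chest": {"chest_routine": 0.55, "chest_low": 0.30, "chest_high": 0.15},
    "spine": {"spine_routine": 0.80, "spine_high": 0.20},
    "head_neck_combined": {"head_neck_combined": 1.0},
    "cardiac": {"cardiac_calcium_scoring": 0.50, "cardiac_angiography": 0.50},
    "full_body": {"full_body_routine": 0.70, "full_body_high": 0.30},
    "extremity": {"extremity": 1.0},
}
_CHILD_TIER_SPLIT = {
    "abdomen_pelvis": {"abdomen_pelvis_routine": 0.60, "abdomen_pelvis_low_child": 0.25,
                       "abdomen_pelvis_high_child": 0.15},
    "head": {"head_routine": 0.70, "head_low_child": 0.20, "head_high_child": 0.10},
    "chest": {"chest_routine": 0.65, "chest_low_child": 0.35},
    "spine": {"spine_routine": 0.70, "spine_low_child": 0.30},
    "cardiac": {"cardiac_child": 1.0},
    "full_body": {"full_body_child": 1.0},
    "extremity": {"extremity": 1.0},
}


def _mix_for_class(child: bool) -> dict[str, float]:
    region_share = _CHILD_REGION_SHARE if child else _ADULT_REGION_SHARE
    tier_split = _CHILD_TIER_SPLIT if child else _ADULT_TIER_SPLIT
    mix: dict[str, float] = {}
    for region, share in region_share.items():
        for cat, frac in tier_split[region].items():
            mix[cat] = share * frac
    total = sum(mix.values())
    return {c: p / total for c, p in mix.items()}


def default_category_mix() -> dict[tuple[str, str], dict[str, float]]:
    child_mix = _mix_for_class(child=True)
    adult_mix = _mix_for_class(child=False)
    out: dict[tuple[str, str], dict[str, float]] = {}
    for sex in SEXES:
        for group in AGE_GROUPS:
            out[(sex, group)] = dict(child_mix if is_child_group(group) else adult_mix)
    return out


# --- organ dose table ---------------------------------------------------------
# Parametric mean-dose model: region base dose x tier multiplier x age factor
# x small sex factor, with region-specific relative organ exposure weights.
# A set of published per-stratum mean (SD) doses overrides the generated
# values exactly (ANCHOR_DOSES below).
_REGION_BASE_MGY = {
    "head": 42.0, "chest": 20.0, "abdomen_pelvis": 24.0, "spine": 13.0,
    "head_neck_combined": 30.0, "cardiac": 18.0, "full_body": 24.0,
    "extremity": 2.5,
}
_TIER_MULT = {"low": 0.45, "routine": 1.0, "high": 1.8, "not_tiered": 1.0}
_DISTANT_WEIGHT = 0.01
_ORGAN_WEIGHTS: dict[str, dict[str, float]] = {
    "head": {"brain": 1.0, "oral_cavity_pharynx": 0.25, "thyroid": 0.10,
             "remainder": 0.06},
    "chest": {"lung": 1.0, "breast": 0.85, "esophagus": 0.70, "thyroid": 0.35,
              "liver": 0.30, "stomach": 0.25, "red_bone_marrow": 0.25,
              "remainder": 0.30},
    "abdomen_pelvis": {"colon": 1.0, "liver": 0.95, "kidney": 0.95,
                       "stomach": 0.90, "bladder": 0.90, "rectum": 0.85,
                       "ovary": 0.85, "uterus": 0.85, "prostate": 0.85,
                       "pancreas": 0.80, "remainder": 0.45,
                       "red_bone_marrow": 0.30, "lung": 0.12,
                       "esophagus": 0.05},
    "spine": {"red_bone_marrow": 0.55, "lung": 0.35, "esophagus": 0.30,
              "kidney": 0.30, "remainder": 0.30, "colon": 0.25, "liver": 0.25,
              "stomach": 0.20, "thyroid": 0.15},
    "head_neck_combined": {"thyroid": 0.95, "oral_cavity_pharynx": 0.95,
                           "brain": 0.85, "esophagus": 0.35,
                           "red_bone_marrow": 0.20, "remainder": 0.15,
                           "lung": 0.05},
    "cardiac": {"lung": 0.85, "breast": 0.70, "esophagus": 0.55, "liver": 0.20,
                "remainder": 0.20, "stomach": 0.15, "red_bone_marrow": 0.15,
                "thyroid": 0.08},
    "full_body": {"lung": 0.90, "colon": 0.90, "liver": 0.90, "kidney": 0.90,
                  "stomach": 0.85, "bladder": 0.85, "breast": 0.80,
                  "pancreas": 0.80, "ovary": 0.80, "uterus": 0.80,
                  "prostate": 0.80, "rectum": 0.80, "esophagus": 0.60,
                  "remainder": 0.60, "thyroid": 0.40,
                  "red_bone_marrow": 0.35, "oral_cavity_pharynx": 0.25,
                  "brain": 0.15},
    "extremity": {"red_bone_marrow": 0.05, "remainder": 0.03},
}
# Head doses peak in infancy; trunk doses scale with body size.
_HEAD_AGE_FACTOR = {
    "0": 1.40, "1-4": 1.20, "5-9": 1.12, "10-14": 1.05, "15-17": 1.00,
    **{g: 1.0 for g in ADULT_AGE_GROUPS},
}
_BODY_AGE_FACTOR = {
    "0": 0.45, "1-4": 0.50, "5-9": 0.55, "10-14": 0.65, "15-17": 0.80,
    "18-29": 0.90, "30-39": 0.95, "40-49": 1.00, "50-59": 1.05,
    "60-69": 1.08, "70-79": 1.08, "80-89": 1.05, "90-99": 1.00,
}
# Red bone marrow from head CT: dominated by the skull's marrow fraction,
# which falls sharply with age.
_HEAD_RBM_WEIGHT = {
    "0": 0.44, "1-4": 0.37, "5-9": 0.30, "10-14": 0.22, "15-17": 0.15,
    **{g: 0.085 for g in ADULT_AGE_GROUPS},
}
_SEX_FACTOR = {"female": 0.98, "male": 1.02}
_SD_FRACTION = 0.58  # default coefficient of variation of within-stratum doses

# Published per-stratum mean (SD) organ doses in mGy; exact overrides.
ANCHOR_DOSES: dict[tuple[str, str, str, str], tuple[float, float]] = {
    ("male", "5-9", "head_routine", "brain"): (48.0, 27.3),
    ("female", "5-9", "head_routine", "brain"): (45.7, 24.1),
    ("male", "0", "head_routine", "brain"): (60.0, 36.5),
    ("male", "0", "head_routine", "red_bone_marrow"): (26.7, 16.7),
    ("male", "5-9", "head_routine", "red_bone_marrow"): (14.6, 10.0),
    ("male", "50-59", "head_routine", "red_bone_marrow"): (3.5, 2.7),
    ("male", "5-9", "full_body_child", "pancreas"): (21.5, 13.5),
    ("female", "5-9", "full_body_child", "pancreas"): (16.7, 8.9),
    ("female", "50-59", "abdomen_pelvis_routine", "colon"): (25.4, 15.2),
    ("female", "5-9", "abdomen_pelvis_routine", "colon"): (12.8, 8.7),
}


def mean_dose_mgy(sex: str, age_group: str, category: str, organ: str) -> float:
    cat = CATEGORY_BY_NAME[category]
    region = cat.body_region
    if region == "head" and organ == "red_bone_marrow":
        weight = _HEAD_RBM_WEIGHT[age_group]
    else:
        weight = _ORGAN_WEIGHTS[region].get(organ, _DISTANT_WEIGHT)
    age_factor = (
        _HEAD_AGE_FACTOR[age_group]
        if region in ("head", "head_neck_combined")
        else _BODY_AGE_FACTOR[age_group]
    )
    return (
        _REGION_BASE_MGY[region]
        * _TIER_MULT[cat.dose_tier]
        * weight
        * age_factor
        * _SEX_FACTOR[sex]
    )


def default_dose_params() -> dict[StratumKey, dict[str, tuple[float, float]]]:
    """(mean, SD) organ dose in mGy for every organ in all 418 strata."""
    table: dict[StratumKey, dict[str, tuple[float, float]]] = {}
    for key in enumerate_strata():
        organ_table: dict[str, tuple[float, float]] = {}
        for organ in ORGANS:
            anchor = ANCHOR_DOSES.get((key.sex, key.age_group, key.category, organ))
            if anchor is not None:
                organ_table[organ] = anchor
            else:
                m = mean_dose_mgy(key.sex, key.age_group, key.category, organ)
                organ_table[organ] = (m, _SD_FRACTION * m)
        table[key] = organ_table
    return table


def default_registry_config(n_patients: int = 100_000, seed: int = 0) -> RegistryGenConfig:
    """National-mimic generation config (pediatric exam share ~3.3%)."""
    return RegistryGenConfig(
        n_patients=n_patients,
        demographics=default_demographics(),
        category_mix=default_category_mix(),
        dose_params=default_dose_params(),
        exams_per_patient_mean=dict(DEFAULT_EXAMS_PER_PATIENT),
        eol_prob=dict(DEFAULT_EOL_PROB),
        multiphase_prob=MULTIPHASE_PROB,
        seed=seed,
    )


# --- risk model configuration -------------------------------------------------
# Solid-cancer coefficients: ERR per Gy and EAR per 10^4 person-year-Gy at
# exposure age >= 30 and attained age 60, with per-decade exposure-age
# modifier gamma and attained-age power eta. Values are this implementation's
# transcription of the BEIR VII preferred models for the 11 dedicated sites;
# the 7 additional sites carry implementer-chosen pooled defaults. All values
# are editable configuration.
_ERR_GAMMA, _ERR_ETA = -0.30, -1.4
_EAR_GAMMA, _EAR_ETA = -0.41, 2.8

# site: (err_f, err_m, ear_f, ear_m, transfer_weight)
_SOLID_TABLE: dict[str, tuple[float, float, float, float, float]] = {
    "stomach": (0.48, 0.21, 4.9, 4.9, 0.7),
    "colon": (0.43, 0.63, 1.6, 3.2, 0.7),
    "liver": (0.32, 0.32, 1.0, 2.2, 0.7),
    "lung": (1.40, 0.32, 3.4, 2.3, 0.3),
    "breast": (0.51, 0.0, 9.4, 0.0, 0.0),
    "uterus": (0.055, 0.0, 1.2, 0.0, 0.7),
    "ovary": (0.38, 0.0, 0.70, 0.0, 0.7),
    "prostate": (0.0, 0.12, 0.0, 0.11, 0.7),
    "bladder": (1.65, 0.50, 0.75, 1.2, 0.7),
    "thyroid": (1.05, 0.53, 0.0, 0.0, 1.0),
    "oral_cavity_pharynx": (0.53, 0.23, 0.50, 0.70, 0.7),
    "esophagus": (0.30, 0.40, 0.40, 0.70, 0.7),
    "rectum": (0.12, 0.12, 0.30, 0.34, 0.7),
    "pancreas": (0.36, 0.36, 0.50, 0.60, 0.7),
    "kidney": (0.34, 0.34, 0.40, 0.60, 0.7),
    "brain_cns": (0.60, 0.60, 0.25, 0.30, 0.7),
    "other": (0.45, 0.27, 4.8, 6.2, 0.7),
}
# Site-specific modifier overrides (gamma, eta) by model.
_ERR_MOD_OVERRIDE = {"thyroid": (-0.83, 0.0), "brain_cns": (-0.60, -1.4)}
_EAR_MOD_OVERRIDE = {"lung": (-0.41, 5.2), "breast": (-0.51, 2.0)}

DEFAULT_BETA_SIGMA = 0.25  # lognormal sigma of the coefficient multiplier


def default_risk_config() -> RiskConfig:
    sites: dict[str, SiteRiskModel] = {}
    for site, (err_f, err_m, ear_f, ear_m, w) in _SOLID_TABLE.items():
        eg, ee = _ERR_MOD_OVERRIDE.get(site, (_ERR_GAMMA, _ERR_ETA))
        ag, ae = _EAR_MOD_OVERRIDE.get(site, (_EAR_GAMMA, _EAR_ETA))
        sites[site] = SiteRiskModel(
            site=site,
            model_class="solid",
            err={"female": SolidCoef(err_f, eg, ee), "male": SolidCoef(err_m, eg, ee)},
            ear={"female": SolidCoef(ear_f, ag, ae), "male": SolidCoef(ear_m, ag, ae)},
            transfer_weight=w,
            beta_sigma=DEFAULT_BETA_SIGMA,
        )
    sites["leukemia"] = SiteRiskModel(
        site="leukemia",
        model_class="leukemia",
        err={
            "female": LeukemiaCoef(beta=1.2, theta=0.88, gamma=-0.40, delta=-0.48, phi=0.42),
            "male": LeukemiaCoef(beta=1.1, theta=0.88, gamma=-0.40, delta=-0.48, phi=0.42),
        },
        ear={
            "female": LeukemiaCoef(beta=0.93, theta=0.88, gamma=0.29, delta=0.0, phi=0.56),
            "male": LeukemiaCoef(beta=1.62, theta=0.88, gamma=0.29, delta=0.0, phi=0.56),
        },
        transfer_weight=0.7,
        beta_sigma=DEFAULT_BETA_SIGMA,
    )
    latency = LatencyConfig(
        groups={
            "solid": LatencyGroup(mu_min=5.0, mu_mode=7.5, mu_max=10.0,
                                  window_start=4.0, window_end=11.0),
            "thyroid": LatencyGroup(mu_min=3.0, mu_mode=5.0, mu_max=7.0,
                                    window_start=2.5, window_end=7.6),
            "leukemia": LatencyGroup(mu_min=2.0, mu_mode=2.25, mu_max=2.5,
                                     window_start=0.4, window_end=4.1),
        }
    )
    return RiskConfig(sites=sites, latency=latency, ddref=DDREFConfig())


# --- life tables and baseline incidence --------------------------------------


def default_life_tables() -> dict[str, LifeTable]:
    return {sex: generate_life_table(sex) for sex in SEXES}


# site: (rate_at_60 female, rate_at_60 male, age exponent, childhood peak)
# Synthetic US-like magnitudes (incident cases per person-year at age 60).
_BASELINE_TABLE: dict[str, tuple[float, float, float, float]] = {
    "stomach": (0.00025, 0.00045, 2.8, 0.0),
    "colon": (0.00110, 0.00130, 3.0, 0.0),
    "liver": (0.00015, 0.00040, 3.2, 0.0),
    "lung": (0.00180, 0.00220, 4.0, 0.0),
    "breast": (0.00330, 0.0, 1.8, 0.0),
    "uterus": (0.00090, 0.0, 2.2, 0.0),
    "ovary": (0.00035, 0.0, 2.0, 0.0),
    "prostate": (0.0, 0.00450, 5.0, 0.0),
    "bladder": (0.00035, 0.00120, 3.5, 0.0),
    "thyroid": (0.00030, 0.00012, 0.8, 0.0),
    "leukemia": (0.00045, 0.00060, 2.0, 6e-5),
    "oral_cavity_pharynx": (0.00025, 0.00050, 2.2, 0.0),
    "esophagus": (0.00008, 0.00035, 3.5, 0.0),
    "rectum": (0.00035, 0.00045, 2.8, 0.0),
    "pancreas": (0.00045, 0.00055, 3.3, 0.0),
    "kidney": (0.00040, 0.00070, 2.5, 0.0),
    "brain_cns": (0.00015, 0.00020, 1.0, 1.5e-5),
    "other": (0.00160, 0.00180, 2.5, 0.0),
}


def default_baseline_incidence() -> dict[tuple[str, str], BaselineIncidence]:
    out: dict[tuple[str, str], BaselineIncidence] = {}
    for site, (rf, rm, p, peak) in _BASELINE_TABLE.items():
        out[(site, "female")] = generate_baseline_incidence(site, "female", rf, p, peak)
        out[(site, "male")] = generate_baseline_incidence(site, "male", rm, p, peak)
    return out


__all__ = [
    "TOTAL_EXAMS_2023",
    "TOTAL_PATIENTS_2023",
    "PEDIATRIC_SHARE_ACR",
    "PEDIATRIC_SHARE_IMV",
    "MULTIPHASE_PROB",
    "TOTAL_EXAMS_2007",
    "ANNUAL_CANCER_DIAGNOSES",
    "EOL_OVERALL_FRACTION",
    "DEFAULT_EXAMS_PER_PATIENT",
    "DEFAULT_EOL_PROB",
    "ANCHOR_DOSES",
    "default_exam_shares",
    "default_demographics",
    "default_eol_prob_2yr",
    "default_category_mix",
    "default_dose_params",
    "default_registry_config",
    "default_risk_config",
    "default_life_tables",
    "default_baseline_incidence",
    "mean_dose_mgy",
]
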