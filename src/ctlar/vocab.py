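"""Controlled vocabularies for the CT risk-projection pipeline.

Defines the examination category scheme (26 categories combining body region
and dose tier: 18 applicable to adults, 13 to children, 5 shared), the age
grouping used for stratification (5 pediatric + 8 adult groups), the 18
modeled organs and the 18 modeled cancer sites with their organ mapping, and
the enumeration of the 418 (sex x age-group x category) strata at which organ
doses are averaged and risks applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

SEXES = ("female", "male")

BODY_REGIONS = (
    "abdomen_pelvis",
    "head",
    "chest",
    "spine",
    "head_neck_combined",
    "cardiac",
    "full_body",
    "extremity",
)

DOSE_TIERS = ("low", "routine", "high", "not_tiered")

EXCLUSION_REASONS = ("biopsy_procedure", "pet", "research", "none")


@dataclass(frozen=True)
class CTCategory:
    """One CT examination category: a body region at a dose tier, with an
    age-applicability flag (``adult``, ``child`` or ``both``)."""

    name: str
    body_region: str
    dose_tier: str
    applicability: str

    def __post_init__(self) -> None:
        if self.body_region not in BODY_REGIONS:
            raise ValueError(f"unknown body region {self.body_region!r}")
        if self.dose_tier not in DOSE_TIERS:
            raise ValueError(f"unknown dose tier {self.dose_tier!r}")
        if self.applicability not in ("adult", "child", "both"):
            raise ValueError(f"unknown applicability {self.applicability!r}")


def _cat(name: str, region: str, tier: str, appl: str) -> CTCategory:
    return CTCategory(name, region, tier, appl)


# Default 26-category vocabulary. The real scheme subdivides body regions by
# clinical indication (e.g. low-dose abdomen for kidney stones, high-dose for
# cancer); this default reproduces its shape: 5 categories shared between
# adults and children, 13 adult-only, 8 child-only.
DEFAULT_CATEGORIES: tuple[CTCategory, ...] = (
    # shared (5)
    _cat("abdomen_pelvis_routine", "abdomen_pelvis", "routine", "both"),
    _cat("head_routine", "head", "routine", "both"),
    _cat("chest_routine", "chest", "routine", "both"),
    _cat("spine_routine", "spine", "routine", "both"),
    _cat("extremity", "extremity", "not_tiered", "both"),
    # adult-only (13)
    _cat("abdomen_pelvis_low", "abdomen_pelvis", "low", "adult"),
    _cat("abdomen_pelvis_high", "abdomen_pelvis", "high", "adult"),
    _cat("head_low", "head", "low", "adult"),
    _cat("head_high", "head", "high", "adult"),
    _cat("head_angiography", "head", "high", "adult"),
    _cat("chest_low", "chest", "low", "adult"),
    _cat("chest_high", "chest", "high", "adult"),
    _cat("spine_high", "spine", "high", "adult"),
    _cat("head_neck_combined", "head_neck_combined", "routine", "adult"),
    _cat("cardiac_calcium_scoring", "cardiac", "low", "adult"),
    _cat("cardiac_angiography", "cardiac", "routine", "adult"),
    _cat("full_body_routine", "full_body", "routine", "adult"),
    _cat("full_body_high", "full_body", "high", "adult"),
    # child-only (8)
    _cat("abdomen_pelvis_low_child", "abdomen_pelvis", "low", "child"),
    _cat("abdomen_pelvis_high_child", "abdomen_pelvis", "high", "child"),
    _cat("head_low_child", "head", "low", "child"),
    _cat("head_high_child", "head", "high", "child"),
    _cat("chest_low_child", "chest", "low", "child"),
    _cat("spine_low_child", "spine", "low", "child"),
    _cat("cardiac_child", "cardiac", "routine", "child"),
    _cat("full_body_child", "full_body", "routine", "child"),
)

CATEGORY_BY_NAME: dict[str, CTCategory] = {c.name: c for c in DEFAULT_CATEGORIES}

ADULT_CATEGORIES = tuple(
    c.name for c in DEFAULT_CATEGORIES if c.applicability in ("adult", "both")
)
CHILD_CATEGORIES = tuple(
    c.name for c in DEFAULT_CATEGORIES if c.applicability in ("child", "both")
)

# Age grouping: 5 pediatric + 8 adult groups -> with 13 child and 18 adult
# categories and 2 sexes this yields 130 + 288 = 418 strata.
CHILD_AGE_GROUPS = ("0", "1-4", "5-9", "10-14", "15-17")
ADULT_AGE_GROUPS = (
    "18-29", "30-39", "40-49", "50-59", "60-69", "70-79", "80-89", "90-99",
)
AGE_GROUPS = CHILD_AGE_GROUPS + ADULT_AGE_GROUPS

_AGE_GROUP_BOUNDS: dict[str, tuple[int, int]] = {
    "0": (0, 0),
    "1-4": (1, 4),
    "5-9": (5, 9),
    "10-14": (10, 14),
    "15-17": (15, 17),
    "18-29": (18, 29),
    "30-39": (30, 39),
    "40-49": (40, 49),
    "50-59": (50, 59),
    "60-69": (60, 69),
    "70-79": (70, 79),
    "80-89": (80, 89),
    "90-99": (90, 99),
}


def age_group_of(age_years: int) -> str:
    """Age-group label for an integer age in [0, 99]."""
    if not 0 <= age_years <= 99:
        raise ValueError(f"age_years must be in [0, 99], got {age_years}")
    for label, (lo, hi) in _AGE_GROUP_BOUNDS.items():
        if lo <= age_years <= hi:
            return label
    raise AssertionError("unreachable")


def age_group_bounds(label: str) -> tuple[int, int]:
    try:
        return _AGE_GROUP_BOUNDS[label]
    except KeyError:
        raise ValueError(f"unknown age group {label!r}") from None


def age_group_midpoint(label: str) -> float:
    """Midpoint age used to evaluate risk for a stratum.

    Integer-age groups span [lo, hi+1) in exact age, so the midpoint of e.g.
    50-59 is 55.0 and of <1 is 0.5.
    """
    lo, hi = age_group_bounds(label)
    return (lo + hi + 1) / 2.0


def is_child_group(label: str) -> bool:
    return label in CHILD_AGE_GROUPS


# 18 organs with per-stratum dose distributions: one per modeled cancer site
# (leukemia <- red bone marrow; the remainder organ backs the pooled
# "other and ill-defined sites" category).
ORGANS = (
    "brain",
    "thyroid",
    "lung",
    "breast",
    "stomach",
    "colon",
    "liver",
    "pancreas",
    "kidney",
    "bladder",
    "ovary",
    "uterus",
    "prostate",
    "esophagus",
    "oral_cavity_pharynx",
    "rectum",
    "red_bone_marrow",
    "remainder",
)

# 18 modeled cancer sites: the 11 with dedicated BEIR VII models (stomach,
# colon, liver, lung, breast, uterus, ovary, prostate, bladder, thyroid,
# leukemia) plus 7 additional sites and a remainder category.
SITES = (
    "stomach",
    "colon",
    "liver",
    "lung",
    "breast",
    "uterus",
    "ovary",
    "prostate",
    "bladder",
    "thyroid",
    "leukemia",
    "oral_cavity_pharynx",
    "esophagus",
    "rectum",
    "pancreas",
    "kidney",
    "brain_cns",
    "other",
)

ORGAN_FOR_SITE: dict[str, str] = {
    "leukemia": "red_bone_marrow",
    "brain_cns": "brain",
    "other": "remainder",
    **{s: s for s in SITES if s not in ("leukemia", "brain_cns", "other")},
}

# Sites incident in only one sex. Breast is modeled in females only (male
# breast cancer risk is not separately parameterized), configurable upstream.
FEMALE_ONLY_SITES = ("breast", "ovary", "uterus")
MALE_ONLY_SITES = ("prostate",)


def site_applies_to_sex(site: str, sex: str) -> bool:
    if site in FEMALE_ONLY_SITES:
        return sex == "female"
    if site in MALE_ONLY_SITES:
        return sex == "male"
    return True


class StratumKey(NamedTuple):
    """A (sex, age-group, CT-category) cell."""

    sex: str
    age_group: str
    category: str


def categories_for_group(age_group: str) -> tuple[str, ...]:
    return CHILD_CATEGORIES if is_child_group(age_group) else ADULT_CATEGORIES


def enumerate_strata() -> list[StratumKey]:
    """All valid strata under the default vocabulary: 288 adult + 130 child."""
    keys: list[StratumKey] = []
    for sex in SEXES:
        for group in AGE_GROUPS:
            for cat in categories_for_group(group):
                keys.append(StratumKey(sex, group, cat))
    return keys


DOSE_COLUMNS = tuple(f"dose_{organ}_mGy" for organ in ORGANS)

# Fixed exam-table column order (documented external interface).
EXAM_COLUMNS = (
    "exam_id",
    "patient_id",
    "age_years",
    "sex",
    "age_group",
    "category",
    "multiphase",
    "last_year_of_life",
    "excluded_reason",
) + DOSE_COLUMNS
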