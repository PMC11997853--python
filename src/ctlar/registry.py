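"""Synthetic CT dose-registry generation.

Real exam-level registries (DICOM metadata plus reconstructed organ doses)
are not public, so this module generates exam-level records with the
statistical structure the downstream analysis assumes:

* each patient has a sex and an age (0-99) drawn from configurable
  demographics, and a count of examinations in the year with a configurable
  mean (1 + Poisson, so the median is 1);
* each examination draws a CT category from the patient's
  (sex, age-group)-conditional category mix, and per-organ absorbed doses
  (mGy) from a lognormal distribution moment-matched to the stratum's
  configured mean and SD;
* a multiphase flag (descriptive only; doses are per-examination totals over
  all phases) and a last-year-of-life flag per patient;
* a small fraction of exams carry exclusion reasons (biopsy/procedure, PET,
  research) that the stratification step removes.

Also provides synthetic sex-specific life tables (Gompertz-Makeham hazard)
and site/sex/age baseline cancer incidence curves, stand-ins for the US
population tables a production analysis would load.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .vocab import (
    AGE_GROUPS,
    DOSE_COLUMNS,
    EXAM_COLUMNS,
    EXCLUSION_REASONS,
    ORGANS,
    SEXES,
    SITES,
    FEMALE_ONLY_SITES,
    MALE_ONLY_SITES,
    StratumKey,
    age_group_bounds,
    categories_for_group,
    site_applies_to_sex,
)

Cell = tuple[str, str]  # (sex, age_group)


class ConfigurationError(ValueError):
    """Raised when a generation config is internally inconsistent."""


@dataclass
class RegistryGenConfig:
    """Configuration for synthetic registry generation.

    ``category_mix`` is conditional: probabilities over categories must sum
    to 1 within each (sex, age-group) cell. ``demographics`` gives the
    marginal probability that a patient falls in each cell.
    """

    n_patients: int
    demographics: dict[Cell, float]
    category_mix: dict[Cell, dict[str, float]]
    dose_params: dict[StratumKey, dict[str, tuple[float, float]]]
    exams_per_patient_mean: dict[Cell, float]
    eol_prob: dict[Cell, float]
    multiphase_prob: float = 0.285
    exclusion_probs: dict[str, float] = field(
        default_factory=lambda: {"biopsy_procedure": 0.012, "pet": 0.008, "research": 0.004}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        total = sum(self.demographics.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"demographics must sum to 1, got {total}")
        for cell, mix in self.category_mix.items():
            s = sum(mix.values())
            if not math.isclose(s, 1.0, abs_tol=1e-9):
                raise ConfigurationError(
                    f"category_mix for cell {cell} sums to {s}, expected 1"
                )
            if any(p < 0 or p > 1 for p in mix.values()):
                raise ConfigurationError(f"category_mix for cell {cell} outside [0,1]")
            valid = set(categories_for_group(cell[1]))
            bad = set(mix) - valid
            if bad:
                raise ConfigurationError(
                    f"categories {sorted(bad)} not applicable to age group {cell[1]}"
                )
        for cell, p in self.eol_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"eol_prob for cell {cell} outside [0,1]")
        for cell, m in self.exams_per_patient_mean.items():
            if m < 1.0:
                raise ConfigurationError(
                    f"exams_per_patient_mean for cell {cell} must be >= 1, got {m}"
                )
        if not 0.0 <= self.multiphase_prob <= 1.0:
            raise ConfigurationError("multiphase_prob outside [0,1]")
        p_excl = sum(self.exclusion_probs.values())
        if p_excl > 1.0 or any(v < 0 for v in self.exclusion_probs.values()):
            raise ConfigurationError("exclusion_probs invalid")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of the lognormal whose mean and SD match the arguments."""
    if mean <= 0:
        raise ConfigurationError(f"dose mean must be > 0, got {mean}")
    if sd < 0:
        raise ConfigurationError(f"dose SD must be >= 0, got {sd}")
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_organ_doses(
    mean: float, sd: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Sample ``n`` absorbed doses (mGy) from a lognormal moment-matched to
    (mean, sd). With sd=0 every sample equals the mean; samples are > 0."""
    mu, sigma = _lognormal_params(mean, sd)
    if sigma == 0.0:
        return np.full(n, mean, dtype=float)
    return rng.lognormal(mu, sigma, size=n)


def generate_registry(config: RegistryGenConfig) -> pd.DataFrame:
    """Generate the exam-level table (one row per examination).

    Deterministic given ``config.seed``. Columns follow
    :data:`ctlar.vocab.EXAM_COLUMNS`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cells = sorted(config.demographics)
    probs = np.array([config.demographics[c] for c in cells])
    cell_counts = rng.multinomial(config.n_patients, probs / probs.sum())

    frames: list[pd.DataFrame] = []
    patient_offset = 0
    exam_offset = 0
    for cell, n_pat in zip(cells, cell_counts):
        if n_pat == 0:
            continue
        sex, group = cell
        lo, hi = age_group_bounds(group)
        try:
            mean_exams = config.exams_per_patient_mean[cell]
        except KeyError:
            raise ConfigurationError(
                f"missing exams_per_patient_mean for cell {cell}"
            ) from None
        try:
            p_eol = config.eol_prob[cell]
        except KeyError:
            raise ConfigurationError(f"missing eol_prob for cell {cell}") from None
        mix = config.category_mix.get(cell)
        if not mix:
            raise ConfigurationError(f"missing category_mix for cell {cell}")

        ages = rng.integers(lo, hi + 1, size=n_pat)
        n_exams = 1 + rng.poisson(mean_exams - 1.0, size=n_pat)
        eol = rng.random(n_pat) < p_eol

        total = int(n_exams.sum())
        pat_idx = np.repeat(np.arange(n_pat), n_exams)

        cat_names = sorted(mix)
        cat_p = np.array([mix[c] for c in cat_names])
        cat_draw = rng.choice(len(cat_names), size=total, p=cat_p / cat_p.sum())

        u = rng.random(total)
        reason = np.full(total, "none", dtype=object)
        lo_p = 0.0
        for rname in ("biopsy_procedure", "pet", "research"):
            p = config.exclusion_probs.get(rname, 0.0)
            reason[(u >= lo_p) & (u < lo_p + p)] = rname
            lo_p += p

        doses = np.empty((total, len(ORGANS)), dtype=float)
        for ci, cname in enumerate(cat_names):
            sel = np.flatnonzero(cat_draw == ci)
            if sel.size == 0:
                continue
            key = StratumKey(sex, group, cname)
            try:
                organ_params = config.dose_params[key]
            except KeyError:
                raise ConfigurationError(
                    f"missing dose_params for stratum {key}"
                ) from None
            for oi, organ in enumerate(ORGANS):
                try:
                    m, s = organ_params[organ]
                except KeyError:
                    raise ConfigurationError(
                        f"missing dose_params for stratum {key}, organ {organ!r}"
                    ) from None
                doses[sel, oi] = sample_organ_doses(m, s, sel.size, rng)

        df = pd.DataFrame(
            {
                "exam_id": np.arange(exam_offset, exam_offset + total),
                "patient_id": patient_offset + pat_idx,
                "age_years": ages[pat_idx],
                "sex": sex,
                "age_group": group,
                "category": np.array(cat_names, dtype=object)[cat_draw],
                "multiphase": rng.random(total) < config.multiphase_prob,
                "last_year_of_life": eol[pat_idx],
                "excluded_reason": reason,
            }
        )
        for oi, col in enumerate(DOSE_COLUMNS):
            df[col] = doses[:, oi]
        frames.append(df)
        patient_offset += n_pat
        exam_offset += total

    out = pd.concat(frames, ignore_index=True)
    return out[list(EXAM_COLUMNS)]


def write_registry(df: pd.DataFrame, path: str) -> None:
    """Write the exam table: CSV (text default) or parquet (columnar binary)
    chosen by extension."""
    if str(path).endswith(".parquet"):
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_registry(path: str) -> pd.DataFrame:
    if str(path).endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        df = pd.read_csv(path)
    missing = set(EXAM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"exam table missing columns: {sorted(missing)}")
    return df[list(EXAM_COLUMNS)]


# ---------------------------------------------------------------------------
# Life tables and baseline incidence (synthetic stand-ins)


@dataclass(frozen=True)
class LifeTable:
    """Sex-specific survival from birth: S(a) for integer ages 0..100."""

    sex: str
    survival: np.ndarray  # shape (101,)

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if s.shape != (101,):
            raise ValueError("survival must have 101 entries (ages 0..100)")
        if not math.isclose(s[0], 1.0, abs_tol=1e-12):
            raise ValueError("S(0) must be 1")
        if np.any(np.diff(s) > 1e-15) or np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival must be non-increasing within [0,1]")

    def at(self, age: float) -> float:
        """S(age) with linear interpolation between integer ages."""
        return float(np.interp(age, np.arange(101), self.survival))


def generate_life_table(
    sex: str,
    makeham: float = 5e-4,
    gompertz_scale: float | None = None,
    gompertz_rate: float = 0.09,
) -> LifeTable:
    """Life table from a Gompertz-Makeham hazard h(a) = c + h0*exp(b*a).

    Defaults give S(100) of a few percent with female survival above male,
    qualitatively matching a modern national life table.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    if gompertz_scale is None:
        gompertz_scale = 2.4e-5 if sex == "female" else 3.6e-5
    c, h0, b = makeham, gompertz_scale, gompertz_rate
    if c < 0 or h0 < 0 or b < 0:
        raise ValueError("hazard parameters must be non-negative")
    ages = np.arange(101, dtype=float)
    if h0 == 0.0:
        cumhaz = c * ages
    elif b == 0.0:
        cumhaz = (c + h0) * ages
    else:
        cumhaz = c * ages + (h0 / b) * (np.exp(b * ages) - 1.0)
    return LifeTable(sex=sex, survival=np.exp(-cumhaz))


@dataclass(frozen=True)
class BaselineIncidence:
    """Site- and sex-specific baseline cancer incidence: lambda(a) in incident
    cases per person-year, integer ages 0..100."""

    site: str
    sex: str
    rate: np.ndarray  # shape (101,)

    def __post_init__(self) -> None:
        r = np.asarray(self.rate, dtype=float)
        if r.shape != (101,):
            raise ValueError("rate must have 101 entries (ages 0..100)")
        if np.any(r < 0):
            raise ValueError("rates must be non-negative")
        if not site_applies_to_sex(self.site, self.sex) and np.any(r > 0):
            raise ValueError(f"{self.site} rate must be zero for sex={self.sex}")

    def at(self, age: int) -> float:
        return float(self.rate[int(age)])


def generate_baseline_incidence(
    site: str,
    sex: str,
    rate_at_60: float,
    age_exponent: float = 2.5,
    childhood_peak: float = 0.0,
) -> BaselineIncidence:
    """Synthetic baseline incidence curve.

    Solid sites use a power law in age, lambda(a) = rate_at_60*((a+1)/61)**p;
    a childhood-peaked Gaussian bump (centered near age 4) can be added for
    leukemia. Sex-specific sites are zeroed in the non-applicable sex.
    """
    if site not in SITES:
        raise ValueError(f"unknown site {site!r}; valid sites: {', '.join(SITES)}")
    if rate_at_60 < 0 or childhood_peak < 0:
        raise ValueError("rates must be non-negative")
    ages = np.arange(101, dtype=float)
    rate = rate_at_60 * ((ages + 1.0) / 61.0) ** age_exponent
    if childhood_peak > 0:
        rate = rate + childhood_peak * np.exp(-(((ages - 4.0) / 3.0) ** 2))
    if not site_applies_to_sex(site, sex):
        rate = np.zeros_like(rate)
    return BaselineIncidence(site=site, sex=sex, rate=rate)


__all__ = [
    "RegistryGenConfig",
    "ConfigurationError",
    "generate_registry",
    "sample_organ_doses",
    "write_registry",
    "read_registry",
    "LifeTable",
    "BaselineIncidence",
    "generate_life_table",
    "generate_baseline_incidence",
]
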