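"""National cancer projections.

Combines per-stratum national examination counts (after end-of-life
exclusion) with per-exam lifetime attributable risks to produce projected
lifetime cancer counts with 90% uncertainty limits, marginalized by cancer
site, CT body region, age group, sex, and adult/child split. Uncertainty
limits for every marginal are the 5th/95th percentiles of that marginal's own
per-draw totals, so limits are coherent within a table but deliberately not
additive across rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .risk import PerExamRisk, uncertainty_limits
from .strata import NationalCounts
from .vocab import (
    BODY_REGIONS,
    CATEGORY_BY_NAME,
    SITES,
    StratumKey,
    is_child_group,
)


@dataclass
class ProjectionResult:
    """One projected-cancer cell: expected count and 90% uncertainty limits."""

    grouping: str
    key: str
    point: float
    lower90: float
    upper90: float
    n_draws: int


@dataclass
class ProjectionSet:
    """All projection marginals from one run.

    ``total`` is the national total; the ``by_*`` DataFrames carry one row per
    group with columns point/lower90/upper90. The raw per-stratum arrays are
    retained for downstream re-aggregation (sensitivity deltas, rate curves).
    """

    total: ProjectionResult
    by_site: pd.DataFrame
    by_region: pd.DataFrame
    by_age_group: pd.DataFrame
    by_sex: pd.DataFrame
    by_site_split: pd.DataFrame    # site x {all, adult, child}
    by_region_split: pd.DataFrame  # region x {all, adult, child}
    n_draws: int
    strata: list[StratumKey] = field(repr=False, default_factory=list)
    included_exams: np.ndarray = field(repr=False, default=None)  # (n_strata,)
    central: np.ndarray = field(repr=False, default=None)  # (n_strata, n_sites)
    draws: np.ndarray = field(repr=False, default=None)    # (n_strata, n_draws, n_sites)
    total_draws: np.ndarray = field(repr=False, default=None)  # (n_draws,)


def _limits(draw_totals: np.ndarray) -> tuple[float, float]:
    if draw_totals.size >= 20:
        return uncertainty_limits(draw_totals)
    # too few draws for meaningful percentiles; degenerate limits
    return float(draw_totals.min()), float(draw_totals.max())


def _marginal(
    labels: list[str],
    masks: list[np.ndarray],
    point_by_stratum: np.ndarray,
    draws_by_stratum: np.ndarray,
) -> pd.DataFrame:
    rows = []
    for label, m in zip(labels, masks):
        pt = float(point_by_stratum[m].sum())
        dr = draws_by_stratum[m].sum(axis=0)
        lo, hi = _limits(dr)
        rows.append({"key": label, "point": pt, "lower90": lo, "upper90": hi})
    return pd.DataFrame(rows).set_index("key")


def project_cancers(
    counts: NationalCounts, risks: dict[StratumKey, PerExamRisk]
) -> ProjectionSet:
    """Project lifetime cancers: included exams x per-exam risk, by stratum,
    then marginalized. Every counted stratum must have a risk entry."""
    keys = counts.keys()
    missing = [k for k in keys if k not in risks]
    if missing:
        raise ValueError(f"no per-exam risk for stratum {missing[0]} "
                         f"({len(missing)} missing in total)")
    n_strata = len(keys)
    any_risk = risks[keys[0]]
    n_draws = any_risk.draws.shape[0]
    n_sites = len(any_risk.sites)

    included = counts.table["included_exams"].to_numpy(dtype=float)
    central = np.empty((n_strata, n_sites))
    draws = np.empty((n_strata, n_draws, n_sites))
    for i, k in enumerate(keys):
        r = risks[k]
        central[i] = r.central * included[i]
        draws[i] = r.draws * included[i]

    point_total = central.sum(axis=1)          # per stratum, central
    draw_total = draws.sum(axis=2)             # (n_strata, n_draws)
    national_draws = draw_total.sum(axis=0)
    lo, hi = _limits(national_draws)
    total = ProjectionResult(
        "total", "all", float(point_total.sum()), lo, hi, n_draws
    )

    sexes = np.array([k.sex for k in keys])
    groups = np.array([k.age_group for k in keys])
    regions = np.array([CATEGORY_BY_NAME[k.category].body_region for k in keys])
    child = np.array([is_child_group(k.age_group) for k in keys])

    # by site: sum strata per site column
    site_rows = []
    for j, site in enumerate(any_risk.sites):
        pt = float(central[:, j].sum())
        dr = draws[:, :, j].sum(axis=0)
        slo, shi = _limits(dr)
        site_rows.append({"key": site, "point": pt, "lower90": slo, "upper90": shi})
    by_site = pd.DataFrame(site_rows).set_index("key")

    region_labels = [r for r in BODY_REGIONS if (regions == r).any()]
    by_region = _marginal(
        region_labels, [regions == r for r in region_labels], point_total, draw_total
    )
    age_labels = list(dict.fromkeys(groups))
    by_age = _marginal(
        age_labels, [groups == g for g in age_labels], point_total, draw_total
    )
    by_sex = _marginal(
        ["female", "male"], [sexes == s for s in ("female", "male")],
        point_total, draw_total,
    )

    region_split_rows = []
    for label in region_labels:
        m = regions == label
        entry: dict = {"key": label}
        for col, mask in (("all", m), ("adult", m & ~child), ("child", m & child)):
            pt = float(point_total[mask].sum())
            dr = draw_total[mask].sum(axis=0)
            slo, shi = _limits(dr)
            entry[f"{col}_point"] = pt
            entry[f"{col}_lower90"] = slo
            entry[f"{col}_upper90"] = shi
        region_split_rows.append(entry)
    by_region_split = pd.DataFrame(region_split_rows).set_index("key")

    site_split_rows = []
    for j, site in enumerate(any_risk.sites):
        entry = {"key": site}
        for col, mask in (
            ("all", np.ones(n_strata, bool)),
            ("adult", ~child),
            ("child", child),
        ):
            pt = float(central[mask, j].sum())
            dr = draws[mask][:, :, j].sum(axis=0)
            slo, shi = _limits(dr)
            entry[f"{col}_point"] = pt
            entry[f"{col}_lower90"] = slo
            entry[f"{col}_upper90"] = shi
        site_split_rows.append(entry)
    by_site_split = pd.DataFrame(site_split_rows).set_index("key")

    return ProjectionSet(
        total=total,
        by_site=by_site,
        by_region=by_region,
        by_age_group=by_age,
        by_sex=by_sex,
        by_site_split=by_site_split,
        by_region_split=by_region_split,
        n_draws=n_draws,
        strata=keys,
        included_exams=included,
        central=central,
        draws=draws,
        total_draws=national_draws,
    )


def risk_per_1000_exams(projected_cancers: float, total_exams: float) -> float:
    """Projected cancers per 1000 examinations.

    The denominator is the group's TOTAL examination count (before
    end-of-life exclusion) — a conservative rate convention.
    """
    if total_exams <= 0:
        raise ValueError("cannot compute a rate for a group with no examinations")
    return 1000.0 * projected_cancers / total_exams


def rate_curve_by_age(
    projections: ProjectionSet, counts: NationalCounts
) -> pd.DataFrame:
    """Figure-ready long table: cancers per 1000 total exams by sex and age
    group (denominator: total scaled exams in the cell)."""
    point = projections.central.sum(axis=1)
    df = pd.DataFrame(
        {
            "sex": [k.sex for k in projections.strata],
            "age_group": [k.age_group for k in projections.strata],
            "cancers": point,
            "scaled_exams": counts.table["scaled_exams"].to_numpy(dtype=float),
        }
    )
    agg = df.groupby(["sex", "age_group"], sort=False).sum().reset_index()
    agg["per_1000_exams"] = [
        risk_per_1000_exams(c, n) if n > 0 else 0.0
        for c, n in zip(agg["cancers"], agg["scaled_exams"])
    ]
    return agg


def patients_vs_exams_equivalence(
    counts: NationalCounts,
    risks: dict[StratumKey, PerExamRisk],
    exams_per_patient: dict[tuple[str, str], float],
    per_patient_risk=None,
    rel_tol: float = 1e-9,
) -> bool:
    """Check that projecting per patient equals projecting per examination.

    Because risk is linear in the number of examinations, patients(cell) x
    mean-exams(cell) x per-exam risk equals exams x per-exam risk. The
    ``per_patient_risk`` hook (default: mean_exams * per_exam_risk) exists so
    a deliberately nonlinear model can be shown to break the equivalence.
    """
    if per_patient_risk is None:
        per_patient_risk = lambda mean_exams, r: mean_exams * r  # noqa: E731
    by_exam = 0.0
    by_patient = 0.0
    for row in counts.table.itertuples(index=False):
        key = StratumKey(row.sex, row.age_group, row.category)
        r = risks[key].total_central
        mean_exams = exams_per_patient[(row.sex, row.age_group)]
        patients = row.included_exams / mean_exams
        by_exam += row.included_exams * r
        by_patient += patients * per_patient_risk(mean_exams, r)
    if by_exam == by_patient:
        return True
    denom = max(abs(by_exam), abs(by_patient), 1e-300)
    return abs(by_exam - by_patient) / denom <= rel_tol


__all__ = [
    "ProjectionResult",
    "ProjectionSet",
    "project_cancers",
    "risk_per_1000_exams",
    "rate_curve_by_age",
    "patients_vs_exams_equivalence",
]
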