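"""Stratification and national scaling of exam-level records.

Turns the exam table into (sex x age-group x CT-category) stratum summaries
(counts, proportions, per-organ dose mean/SD), estimates mean examinations
per patient by sex and age group, scales the retained stratum distribution to
a national examination total with a fixed pediatric share, and removes
examinations performed in the last year(s) of life, which cannot contribute
future radiation-induced cancers.

Rules applied when summarizing: exams flagged with an exclusion reason
(biopsy/procedure, PET, research) are dropped, and strata with fewer than 12
examinations are dropped (their dose estimates would be imprecise), with the
remaining proportions renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .vocab import (
    DOSE_COLUMNS,
    ORGANS,
    StratumKey,
    is_child_group,
)

MIN_EXAMS_PER_STRATUM = 12

Cell = tuple[str, str]


@dataclass
class StratumSummary:
    """One retained stratum: exam count, share of retained exams, and the
    per-organ dose mean/SD in mGy."""

    key: StratumKey
    n_exams: int
    proportion: float
    dose_mean: dict[str, float]
    dose_sd: dict[str, float]


def summarize_strata(
    records: pd.DataFrame, min_exams: int = MIN_EXAMS_PER_STRATUM
) -> list[StratumSummary]:
    """Summarize exam records into retained strata.

    Drops exams with a non-``none`` exclusion reason, then strata with fewer
    than ``min_exams`` exams; proportions are renormalized over the retained
    strata and per-organ dose means/SDs (sample SD) computed.
    """
    if len(records) == 0:
        raise ValueError("no exam records supplied")
    kept = records[records["excluded_reason"] == "none"]
    if len(kept) == 0:
        raise ValueError("all exam records carry exclusion reasons; nothing to summarize")

    grouped = kept.groupby(["sex", "age_group", "category"], sort=True)
    sizes = grouped.size()
    retained = sizes[sizes >= min_exams]
    if len(retained) == 0:
        raise ValueError(f"no stratum has at least {min_exams} examinations")
    total = int(retained.sum())

    means = grouped[list(DOSE_COLUMNS)].mean()
    sds = grouped[list(DOSE_COLUMNS)].std(ddof=1).fillna(0.0)

    out: list[StratumSummary] = []
    for idx, n in retained.items():
        key = StratumKey(*idx)
        out.append(
            StratumSummary(
                key=key,
                n_exams=int(n),
                proportion=float(n) / total,
                dose_mean={o: float(means.loc[idx, f"dose_{o}_mGy"]) for o in ORGANS},
                dose_sd={o: float(sds.loc[idx, f"dose_{o}_mGy"]) for o in ORGANS},
            )
        )
    return out


def estimate_exams_per_patient(records: pd.DataFrame) -> tuple[dict[Cell, float], float]:
    """Mean exams per distinct patient, by (sex, age-group) and overall."""
    per_cell = (
        records.groupby(["sex", "age_group"])
        .agg(n_exams=("exam_id", "size"), n_patients=("patient_id", "nunique"))
    )
    cell_means = {
        (sex, group): float(row.n_exams) / float(row.n_patients)
        for (sex, group), row in per_cell.iterrows()
    }
    overall = len(records) / records["patient_id"].nunique()
    return cell_means, float(overall)


def mean_exams_per_patient(total_exams: float, total_patients: float) -> float:
    """Overall mean examinations per patient from national totals."""
    if total_patients <= 0:
        raise ValueError("total_patients must be positive")
    return total_exams / total_patients


def largest_remainder_round(values: np.ndarray, target_total: int) -> np.ndarray:
    """Round non-negative reals to integers summing exactly to target_total."""
    values = np.asarray(values, dtype=float)
    if values.sum() == 0:
        if target_total != 0:
            raise ValueError("cannot allocate a positive total over zero weights")
        return np.zeros(len(values), dtype=np.int64)
    scaled = values * (target_total / values.sum())
    floors = np.floor(scaled).astype(np.int64)
    shortfall = int(target_total - floors.sum())
    if shortfall:
        order = np.argsort(-(scaled - floors), kind="stable")
        floors[order[:shortfall]] += 1
    return floors


@dataclass
class NationalCounts:
    """Per-stratum national examination counts.

    ``table`` has one row per stratum with columns: sex, age_group, category,
    scaled_exams, eol_excluded, included_exams. ``total_patients`` is derived
    as exams / mean-exams-per-patient where the per-cell means are known.
    """

    table: pd.DataFrame
    total_exams: int
    total_patients: float | None = None

    def copy(self) -> "NationalCounts":
        return NationalCounts(self.table.copy(), self.total_exams, self.total_patients)

    @property
    def total_included(self) -> float:
        return float(self.table["included_exams"].sum())

    def keys(self) -> list[StratumKey]:
        return [
            StratumKey(r.sex, r.age_group, r.category)
            for r in self.table.itertuples(index=False)
        ]


def scale_to_national(
    summaries: list[StratumSummary],
    total_exams: int,
    pediatric_share: float,
    exams_per_patient: dict[Cell, float] | None = None,
) -> NationalCounts:
    """Scale retained stratum proportions to the national examination total.

    The pediatric share of ``total_exams`` is allocated across pediatric
    strata proportionally to the (renormalized) pediatric registry mix, the
    remainder across adult strata; counts are rounded by largest remainder so
    each block total is exact.
    """
    if not 0.0 <= pediatric_share <= 1.0:
        raise ValueError("pediatric_share must be in [0, 1]")
    child = [s for s in summaries if is_child_group(s.key.age_group)]
    adult = [s for s in summaries if not is_child_group(s.key.age_group)]
    if pediatric_share > 0 and not child:
        raise ValueError("pediatric_share > 0 but no pediatric strata present")
    if pediatric_share < 1 and not adult:
        raise ValueError("adult share > 0 but no adult strata present")

    child_total = int(round(total_exams * pediatric_share))
    adult_total = total_exams - child_total

    rows: list[dict] = []
    for block, block_total in ((child, child_total), (adult, adult_total)):
        if not block:
            continue
        weights = np.array([s.proportion for s in block])
        counts = largest_remainder_round(weights, block_total)
        for s, n in zip(block, counts):
            rows.append(
                {
                    "sex": s.key.sex,
                    "age_group": s.key.age_group,
                    "category": s.key.category,
                    "scaled_exams": int(n),
                    "eol_excluded": 0,
                    "included_exams": float(n),
                }
            )
    table = pd.DataFrame(rows)

    total_patients: float | None = None
    if exams_per_patient is not None:
        per_cell = table.groupby(["sex", "age_group"])["scaled_exams"].sum()
        total_patients = 0.0
        for (sex, group), n in per_cell.items():
            try:
                m = exams_per_patient[(sex, group)]
            except KeyError:
                raise ValueError(
                    f"missing exams-per-patient mean for cell {(sex, group)}"
                ) from None
            total_patients += n / m
    return NationalCounts(table=table, total_exams=total_exams, total_patients=total_patients)


def apply_eol_exclusion(
    counts: NationalCounts, eol_prob: dict[Cell, float]
) -> NationalCounts:
    """Remove the last-year(s)-of-life fraction of each stratum's exams.

    Excluded counts are rounded by largest remainder so the national excluded
    total equals the rounded sum of the exact per-stratum exclusions.
    """
    table = counts.table.copy()
    exact = np.empty(len(table))
    for i, row in enumerate(table.itertuples(index=False)):
        cell = (row.sex, row.age_group)
        try:
            p = eol_prob[cell]
        except KeyError:
            raise ValueError(
                f"missing last-year-of-life fraction for cell {cell}"
            ) from None
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"eol fraction for cell {cell} outside [0, 1]")
        exact[i] = row.scaled_exams * p
    target = int(round(exact.sum()))
    excluded = (
        largest_remainder_round(exact, target)
        if target > 0
        else np.zeros(len(table), dtype=np.int64)
    )
    # largest-remainder shifts must not push any stratum negative
    excluded = np.minimum(excluded, table["scaled_exams"].to_numpy())
    table["eol_excluded"] = excluded
    table["included_exams"] = (table["scaled_exams"] - excluded).astype(float)
    return NationalCounts(
        table=table, total_exams=counts.total_exams, total_patients=counts.total_patients
    )


__all__ = [
    "MIN_EXAMS_PER_STRATUM",
    "StratumSummary",
    "NationalCounts",
    "summarize_strata",
    "estimate_exams_per_patient",
    "mean_exams_per_patient",
    "largest_remainder_round",
    "scale_to_national",
    "apply_eol_exclusion",
]
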