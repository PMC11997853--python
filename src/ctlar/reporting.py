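"""Report tables and run manifests.

Renders the examination-volume table (patients, exams, exams per patient,
body-region columns, by sex and age group) and the projected-cancers table
(18 cancer types + 8 body regions, each as "point (lower-upper)" with
adult/child columns), plus the run manifest that makes outputs traceable to a
config digest and seed. Rendered tables are pure functions of the stored
unrounded results; rounding happens only at display time (counts >= 1000 to
the nearest 100, below 1000 to the nearest 10).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone

import pandas as pd

from .projection import ProjectionSet
from .strata import NationalCounts
from .vocab import AGE_GROUPS, BODY_REGIONS, CATEGORY_BY_NAME, SEXES, SITES


def display_round(x: float) -> int:
    """Report rounding: counts below 1000 to the nearest 10, otherwise to the
    nearest 100. Stored values stay unrounded."""
    if abs(x) < 1000:
        return int(round(x / 10.0) * 10)
    return int(round(x / 100.0) * 100)


def format_point_ul(point: float, lower: float, upper: float) -> str:
    return f"{display_round(point)} ({display_round(lower)}-{display_round(upper)})"


def make_table_examinations(
    counts: NationalCounts, exams_per_patient: dict[tuple[str, str], float]
) -> pd.DataFrame:
    """Examination-volume table: All/Child/Adult rows plus sex x age-group
    rows; exam and patient totals, percent of exams, mean exams per patient,
    and per-body-region exam counts. Percents derive from unrounded counts."""
    t = counts.table.copy()
    if len(t) == 0:
        raise ValueError("no national counts to tabulate")
    t["body_region"] = [CATEGORY_BY_NAME[c].body_region for c in t["category"]]
    t["child"] = t["age_group"].isin(("0", "1-4", "5-9", "10-14", "15-17"))
    total_exams = float(t["scaled_exams"].sum())

    def block(mask, label: str, sex: str | None) -> dict:
        sub = t[mask]
        exams = float(sub["scaled_exams"].sum())
        patients = 0.0
        for (s, g), n in sub.groupby(["sex", "age_group"])["scaled_exams"].sum().items():
            patients += n / exams_per_patient[(s, g)]
        row = {
            "group": label,
            "sex": sex or "all",
            "patients": patients,
            "exams": exams,
            "pct_exams": 100.0 * exams / total_exams,
            "mean_exams_per_patient": exams / patients if patients else 0.0,
        }
        for region in BODY_REGIONS:
            row[region] = float(sub.loc[sub["body_region"] == region, "scaled_exams"].sum())
        return row

    rows = [
        block(t.index == t.index, "all", None),
        block(t["child"], "child", None),
        block(~t["child"], "adult", None),
    ]
    for sex in SEXES:
        rows.append(block(t["sex"] == sex, "all_ages", sex))
        for group in AGE_GROUPS:
            mask = (t["sex"] == sex) & (t["age_group"] == group)
            if mask.any():
                rows.append(block(mask, group, sex))
    return pd.DataFrame(rows)


def make_table_projected(projections: ProjectionSet) -> pd.DataFrame:
    """Projected-cancers table: one row per cancer type then per body region,
    with "point (lower-upper)" strings for all/adult/child examinations."""
    if len(projections.by_site_split) == 0 or len(projections.strata) == 0:
        raise ValueError("empty projection set: nothing to tabulate")
    rows = []
    for block_name, table, labels in (
        ("cancer_type", projections.by_site_split, list(SITES)),
        ("body_region", projections.by_region_split, list(projections.by_region_split.index)),
    ):
        for label in labels:
            if label not in table.index:
                continue
            r = table.loc[label]
            rows.append(
                {
                    "block": block_name,
                    "row": label,
                    "all": format_point_ul(r["all_point"], r["all_lower90"], r["all_upper90"]),
                    "adult": format_point_ul(
                        r["adult_point"], r["adult_lower90"], r["adult_upper90"]
                    ),
                    "child": format_point_ul(
                        r["child_point"], r["child_lower90"], r["child_upper90"]
                    ),
                }
            )
    total_row = {
        "block": "total",
        "row": "total",
        "all": format_point_ul(
            projections.total.point, projections.total.lower90, projections.total.upper90
        ),
    }
    adult = projections.by_site_split[["adult_point"]].sum().iloc[0]
    child = projections.by_site_split[["child_point"]].sum().iloc[0]
    total_row["adult"] = str(display_round(adult))
    total_row["child"] = str(display_round(child))
    return pd.DataFrame([total_row] + rows)


@dataclass
class RunManifest:
    """Provenance record written alongside every CLI run."""

    config_digest: str
    seed: int
    n_draws: int
    package_version: str
    created_utc: str
    outputs: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def config_digest(config: dict) -> str:
    """SHA-256 of the canonical (sorted-key) JSON serialization, so the digest
    is stable under key reordering."""
    blob = json.dumps(config, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(blob.encode()).hexdigest()


def make_manifest(
    config: dict, seed: int, n_draws: int, outputs: list[str]
) -> RunManifest:
    from . import __version__

    return RunManifest(
        config_digest=config_digest(config),
        seed=seed,
        n_draws=n_draws,
        package_version=__version__,
        created_utc=datetime.now(timezone.utc).isoformat(),
        outputs=sorted(outputs),
    )


__all__ = [
    "display_round",
    "format_point_ul",
    "make_table_examinations",
    "make_table_projected",
    "RunManifest",
    "config_digest",
    "make_manifest",
]
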