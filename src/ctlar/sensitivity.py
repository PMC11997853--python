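"""Sensitivity scenarios.

Eight named scenarios re-run the projection under one coherent modification
of the baseline assumptions each, with the same parameter draws as the
baseline so comparisons are paired:

1. ``male_lung_coefficients_for_females`` — swap the female lung ERR/EAR
   betas for the male values (some cohorts do not support a 3-fold higher
   female radiation-induced lung cancer risk);
2. ``volume_minus_10pct`` / 3. ``volume_plus_10pct`` — national exam total
   scaled by 0.9 / 1.1 (survey over-/under-estimation);
4. ``dose_minus_20pct`` / 5. ``dose_plus_20pct`` — all organ doses scaled by
   0.8 / 1.2 (registry doses may differ from national practice);
6. ``pediatric_share_imv`` — pediatric exam share 9.0% instead of 3.3%;
7. ``distribution_2018_2019`` — alternative exam-distribution profile (the
   baseline mix year may be atypical); the shipped profile is synthetic;
8. ``eol_2yr_exclusion`` — exclude exams in the last 2 years of life instead
   of 1 (the shipped 2-year map is synthetic: 1.6x the 1-year map, capped).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import pandas as pd

from . import defaults
from .pipeline import PipelineState, compute_risks, scaled_dose_summaries
from .projection import ProjectionSet, project_cancers
from .risk import RiskConfig, RiskEngine
from .strata import NationalCounts, apply_eol_exclusion, scale_to_national
from .vocab import CATEGORY_BY_NAME


@dataclass(frozen=True)
class ScenarioConfig:
    name: str
    dose_scale: float = 1.0
    volume_scale: float = 1.0
    pediatric_share_override: float | None = None
    lung_female_uses_male_coefs: bool = False
    eol_years: int = 1
    distribution_profile: str = "baseline"

    def __post_init__(self) -> None:
        if self.dose_scale <= 0 or self.volume_scale <= 0:
            raise ValueError("scale multipliers must be > 0")
        if self.pediatric_share_override is not None and not (
            0.0 <= self.pediatric_share_override <= 1.0
        ):
            raise ValueError("pediatric_share_override must be in [0, 1]")
        if self.eol_years not in (1, 2):
            raise ValueError("eol_years must be 1 or 2")


NULL_SCENARIO = ScenarioConfig(name="baseline")

SCENARIOS: dict[str, ScenarioConfig] = {
    "male_lung_coefficients_for_females": ScenarioConfig(
        name="male_lung_coefficients_for_females", lung_female_uses_male_coefs=True
    ),
    "volume_minus_10pct": ScenarioConfig(name="volume_minus_10pct", volume_scale=0.9),
    "volume_plus_10pct": ScenarioConfig(name="volume_plus_10pct", volume_scale=1.1),
    "dose_minus_20pct": ScenarioConfig(name="dose_minus_20pct", dose_scale=0.8),
    "dose_plus_20pct": ScenarioConfig(name="dose_plus_20pct", dose_scale=1.2),
    "pediatric_share_imv": ScenarioConfig(
        name="pediatric_share_imv",
        pediatric_share_override=defaults.PEDIATRIC_SHARE_IMV,
    ),
    "distribution_2018_2019": ScenarioConfig(
        name="distribution_2018_2019", distribution_profile="2018_2019"
    ),
    "eol_2yr_exclusion": ScenarioConfig(name="eol_2yr_exclusion", eol_years=2),
}


def _profile_weights(profile: str, category: str) -> float:
    """Stratum proportion tilt for a named distribution profile.

    The ``2018_2019`` profile is a synthetic stand-in (the real alternate-year
    mix is not public): routine-tier categories up-weighted, low-tier
    down-weighted, renormalized downstream.
    """
    if profile == "baseline":
        return 1.0
    if profile == "2018_2019":
        tier = CATEGORY_BY_NAME[category].dose_tier
        return {"routine": 1.08, "low": 0.85, "high": 1.0, "not_tiered": 1.0}[tier]
    raise ValueError(f"unknown distribution profile {profile!r}")


def _swap_lung_betas(config: RiskConfig) -> RiskConfig:
    lung = config.sites["lung"]
    new = dataclasses.replace(
        lung,
        err={**lung.err, "female": lung.err["male"]},
        ear={**lung.ear, "female": lung.ear["male"]},
    )
    return config.with_site("lung", new)


@dataclass
class ScenarioResult:
    scenario: ScenarioConfig
    projections: ProjectionSet
    baseline_total: float
    total: float
    delta_abs: float
    delta_pct: float


def run_scenario(base: PipelineState, scenario: ScenarioConfig | str) -> ScenarioResult:
    """Run one scenario against a completed baseline run.

    Reuses the baseline's stratum summaries, exams-per-patient estimates and
    parameter draws; applies exactly the scenario's modifications before
    projection.
    """
    if isinstance(scenario, str):
        if scenario == "baseline":
            scenario = NULL_SCENARIO
        elif scenario in SCENARIOS:
            scenario = SCENARIOS[scenario]
        else:
            raise ValueError(
                f"unknown scenario {scenario!r}; valid scenarios: "
                + ", ".join(sorted(SCENARIOS))
            )
    cfg = base.config

    # examination distribution and national scaling
    summaries = base.summaries
    if scenario.distribution_profile != "baseline":
        tilted = []
        for s in summaries:
            wgt = _profile_weights(scenario.distribution_profile, s.key.category)
            tilted.append(dataclasses.replace(s, proportion=s.proportion * wgt))
        summaries = tilted  # proportions renormalized within scale_to_national
    share = (
        scenario.pediatric_share_override
        if scenario.pediatric_share_override is not None
        else cfg.pediatric_share
    )
    if (
        scenario.distribution_profile != "baseline"
        or scenario.pediatric_share_override is not None
    ):
        counts = scale_to_national(
            summaries, cfg.total_exams, share, exams_per_patient=base.exams_per_patient
        )
        eol = cfg.eol_prob if scenario.eol_years == 1 else cfg.eol_prob_2yr
        counts = apply_eol_exclusion(counts, eol)
    elif scenario.eol_years == 2:
        counts = apply_eol_exclusion(
            NationalCounts(
                base.counts.table.assign(eol_excluded=0).assign(
                    included_exams=lambda t: t["scaled_exams"].astype(float)
                ),
                base.counts.total_exams,
                base.counts.total_patients,
            ),
            cfg.eol_prob_2yr,
        )
    else:
        counts = base.counts.copy()
    if scenario.volume_scale != 1.0:
        counts.table["included_exams"] = (
            counts.table["included_exams"] * scenario.volume_scale
        )

    # risks: same draws as baseline for a paired comparison
    risks = base.risks
    engine = base.engine
    if scenario.lung_female_uses_male_coefs:
        engine = RiskEngine(
            _swap_lung_betas(base.risk_config),
            base.engine.life_tables,
            base.engine.baselines,
            base.engine.draws,
        )
    if scenario.dose_scale != 1.0:
        risks = compute_risks(
            scaled_dose_summaries(base.summaries, scenario.dose_scale), engine
        )
    elif engine is not base.engine:
        risks = compute_risks(base.summaries, engine)

    projections = project_cancers(counts, risks)
    baseline_total = base.projections.total.point
    total = projections.total.point
    return ScenarioResult(
        scenario=scenario,
        projections=projections,
        baseline_total=baseline_total,
        total=total,
        delta_abs=total - baseline_total,
        delta_pct=percent_change(total, baseline_total),
    )


def percent_change(new: float, old: float) -> float:
    if old == 0:
        raise ValueError("percent change undefined for a zero baseline")
    return 100.0 * (new - old) / old


def scenario_suite(base: PipelineState) -> pd.DataFrame:
    """Run all eight scenarios; one row per scenario with total, absolute and
    percent change from the baseline."""
    rows = []
    for name in SCENARIOS:
        res = run_scenario(base, name)
        rows.append(
            {
                "scenario": name,
                "total_projected_cancers": res.total,
                "delta_abs": res.delta_abs,
                "delta_pct": res.delta_pct,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "SCENARIOS",
    "NULL_SCENARIO",
    "run_scenario",
    "scenario_suite",
    "percent_change",
]
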