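"""End-to-end pipeline: synthetic registry -> strata -> national counts ->
per-exam risks -> projections.

All randomness flows from one root seed, split per stage via
``numpy.random.SeedSequence.spawn`` (stage order: registry generation, then
uncertainty draws), so each stage is independently reproducible and two runs
with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import defaults
from .defaults import (
    default_baseline_incidence,
    default_life_tables,
    default_registry_config,
    default_risk_config,
)
from .projection import ProjectionSet, project_cancers
from .registry import generate_registry
from .risk import PerExamRisk, RiskConfig, RiskEngine, sample_uncertainty
from .strata import (
    NationalCounts,
    StratumSummary,
    apply_eol_exclusion,
    estimate_exams_per_patient,
    scale_to_national,
    summarize_strata,
)
from .vocab import StratumKey


@dataclass
class PipelineConfig:
    """Top-level run configuration (all fields have national-mimic defaults)."""

    seed: int = 0
    n_patients: int = 100_000
    n_draws: int = 500
    total_exams: int = defaults.TOTAL_EXAMS_2023
    pediatric_share: float = defaults.PEDIATRIC_SHARE_ACR
    eol_prob: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(defaults.DEFAULT_EOL_PROB)
    )
    eol_prob_2yr: dict[tuple[str, str], float] = field(
        default_factory=defaults.default_eol_prob_2yr
    )

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_patients": self.n_patients,
            "n_draws": self.n_draws,
            "total_exams": self.total_exams,
            "pediatric_share": self.pediatric_share,
            "eol_prob": {f"{s}|{g}": p for (s, g), p in sorted(self.eol_prob.items())},
            "eol_prob_2yr": {
                f"{s}|{g}": p for (s, g), p in sorted(self.eol_prob_2yr.items())
            },
        }


def stage_seeds(root_seed: int, n: int = 2) -> list[int]:
    """Per-stage seeds split from the root seed (kept below 2**31)."""
    children = np.random.SeedSequence(root_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2**31)) for c in children]


@dataclass
class PipelineState:
    """All intermediate products of one run."""

    config: PipelineConfig
    summaries: list[StratumSummary]
    exams_per_patient: dict[tuple[str, str], float]
    counts: NationalCounts
    risk_config: RiskConfig
    engine: RiskEngine
    risks: dict[StratumKey, PerExamRisk]
    projections: ProjectionSet


def compute_risks(
    summaries: list[StratumSummary], engine: RiskEngine
) -> dict[StratumKey, PerExamRisk]:
    return {s.key: engine.per_exam(s) for s in summaries}


def run_pipeline(
    config: PipelineConfig, risk_config: RiskConfig | None = None
) -> PipelineState:
    reg_seed, draw_seed = stage_seeds(config.seed)
    gen_config = default_registry_config(n_patients=config.n_patients, seed=reg_seed)
    records = generate_registry(gen_config)

    summaries = summarize_strata(records)
    epp_cells, _ = estimate_exams_per_patient(records)
    # fall back to configured means for cells too sparse to estimate
    epp = dict(defaults.DEFAULT_EXAMS_PER_PATIENT)
    epp.update(epp_cells)

    counts = scale_to_national(
        summaries, config.total_exams, config.pediatric_share, exams_per_patient=epp
    )
    counts = apply_eol_exclusion(counts, config.eol_prob)

    if risk_config is None:
        risk_config = default_risk_config()
    draws = sample_uncertainty(risk_config, config.n_draws, draw_seed)
    engine = RiskEngine(
        risk_config, default_life_tables(), default_baseline_incidence(), draws
    )
    risks = compute_risks(summaries, engine)
    projections = project_cancers(counts, risks)
    return PipelineState(
        config=config,
        summaries=summaries,
        exams_per_patient=epp,
        counts=counts,
        risk_config=risk_config,
        engine=engine,
        risks=risks,
        projections=projections,
    )


def scaled_dose_summaries(
    summaries: list[StratumSummary], dose_scale: float
) -> list[StratumSummary]:
    return [
        dataclasses.replace(
            s,
            dose_mean={o: v * dose_scale for o, v in s.dose_mean.items()},
            dose_sd={o: v * dose_scale for o, v in s.dose_sd.items()},
        )
        for s in summaries
    ]


__all__ = [
    "PipelineConfig",
    "PipelineState",
    "run_pipeline",
    "compute_risks",
    "stage_seeds",
    "scaled_dose_summaries",
]
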