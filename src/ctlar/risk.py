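"""Lifetime attributable risk (LAR) engine.

Implements the BEIR VII-style projection of excess lifetime cancer risk from
an organ absorbed dose:

* solid cancers: excess relative risk ERR = beta * D * exp(gamma * e_star) *
  (a/60)**eta and excess absolute risk EAR of the same form (different
  coefficients), with e_star = (min(e, 30) - 30) / 10 the capped exposure-age
  modifier; risk transfer is a weighted mix w*ERR + (1-w)*EAR, divided by the
  dose and dose-rate effectiveness factor (DDREF);
* leukemia: linear-quadratic in dose with log time-since-exposure modifiers,
  beta * D * (1 + theta*D) * exp(gamma*e_star + delta*ln(t/25) +
  phi*e_star*ln(t/25)); no DDREF;
* LAR(D, e) = sum over integer attained ages a with e < a <= 100 of
  latency_weight(a - e) * M(D, e, a) * S(a)/S(e), where M multiplies baseline
  rates (ERR path) or is an absolute rate per 10^4 person-years (EAR path),
  and S(a)/S(e) treats death as a competing risk;
* minimum-latency phase-in: a logistic ramp in time since exposure with an
  uncertain midpoint mu drawn from group-specific triangular distributions
  (solid T(5, 7.5, 10); thyroid T(3, 5, 7); leukemia T(2, 2.25, 2.5)) and a
  steepness fixed so the ramp traverses 5% -> 95% across the group's stated
  phase-in window at the modal midpoint;
* uncertainty: Latin hypercube sampling of risk-coefficient multipliers (one
  lognormal multiplier per site and sex), the DDREF (lognormal, median 1.5,
  90% interval (1.1, 2.3)), and the three latency midpoints. One set of draws
  is shared across all strata in a run, so projected uncertainty reflects
  systematic (parameter) uncertainty rather than sampling noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats
from scipy.special import expit
from scipy.stats import qmc

from .registry import BaselineIncidence, LifeTable
from .vocab import SITES, StratumKey, age_group_midpoint, site_applies_to_sex

_LOG19 = math.log(19.0)  # logistic quantile spread between 5% and 95%
_Z90 = stats.norm.ppf(0.95)


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class SolidCoef:
    """Solid-cancer coefficient set: beta at the reference ages, per-decade
    exposure-age modifier gamma, attained-age power eta."""

    beta: float
    gamma: float
    eta: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")


@dataclass(frozen=True)
class LeukemiaCoef:
    """Leukemia linear-quadratic coefficient set with log-time modifiers."""

    beta: float
    theta: float
    gamma: float
    delta: float
    phi: float

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")


@dataclass(frozen=True)
class SiteRiskModel:
    site: str
    model_class: str  # "solid" | "leukemia"
    err: dict[str, SolidCoef | LeukemiaCoef]
    ear: dict[str, SolidCoef | LeukemiaCoef]
    transfer_weight: float  # w: weight on the ERR (multiplicative) transfer
    beta_sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.model_class not in ("solid", "leukemia"):
            raise ValueError(f"unknown model_class {self.model_class!r}")
        if not 0.0 <= self.transfer_weight <= 1.0:
            raise ValueError("transfer_weight must be in [0, 1]")
        if self.beta_sigma < 0:
            raise ValueError("beta_sigma must be >= 0")


@dataclass(frozen=True)
class LatencyGroup:
    """Triangular distribution of the phase-in midpoint mu plus the window
    over which the ramp rises from ~5% to ~95% at the modal mu."""

    mu_min: float
    mu_mode: float
    mu_max: float
    window_start: float
    window_end: float

    def __post_init__(self) -> None:
        if not self.mu_min <= self.mu_mode <= self.mu_max:
            raise ValueError("require mu_min <= mu_mode <= mu_max")
        if not self.window_start < self.window_end:
            raise ValueError("require window_start < window_end")

    @property
    def steepness(self) -> float:
        return (self.window_end - self.window_start) / (2.0 * _LOG19)


@dataclass(frozen=True)
class LatencyConfig:
    groups: dict[str, LatencyGroup]

    @staticmethod
    def group_for_site(site: str) -> str:
        if site == "leukemia":
            return "leukemia"
        if site == "thyroid":
            return "thyroid"
        return "solid"


def _ddref_sigma(median: float, interval90: tuple[float, float]) -> float:
    """Lognormal sigma by least squares against the target 90% interval.

    The printed interval is not exactly log-symmetric about the median, so
    sigma minimizes the summed squared log-scale error of both endpoints.
    """
    lo, hi = interval90
    return (math.log(median / lo) + math.log(hi / median)) / (2.0 * _Z90)


@dataclass(frozen=True)
class DDREFConfig:
    """Dose and dose-rate effectiveness factor: divisor on solid-cancer risk,
    lognormal with median 1.5 and approximate 90% interval (1.1, 2.3)."""

    median: float = 1.5
    interval90: tuple[float, float] = (1.1, 2.3)

    def __post_init__(self) -> None:
        lo, hi = self.interval90
        if not lo < hi:
            raise ValueError("interval90 must be increasing")
        if not lo <= self.median <= hi:
            raise ValueError("median must lie within interval90")

    @property
    def sigma(self) -> float:
        return _ddref_sigma(self.median, self.interval90)


@dataclass(frozen=True)
class RiskConfig:
    sites: dict[str, SiteRiskModel]
    latency: LatencyConfig
    ddref: DDREFConfig

    def with_site(self, site: str, model: SiteRiskModel) -> "RiskConfig":
        new = dict(self.sites)
        new[site] = model
        return replace(self, sites=new)


# ---------------------------------------------------------------------------
# Elementary model functions


def _e_star(e: float) -> float:
    return (min(e, 30.0) - 30.0) / 10.0


def err_solid(D: float, e: float, a, coef: SolidCoef):
    """Excess relative risk for a solid site; linear in dose D (Gy)."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    a_arr = np.asarray(a, dtype=float)
    if np.any(a_arr < e):
        raise ValueError("attained age must be >= exposure age")
    if np.any(a_arr > 100):
        raise ValueError("attained age must be <= 100")
    out = coef.beta * D * math.exp(coef.gamma * _e_star(e)) * (a_arr / 60.0) ** coef.eta
    return out if isinstance(a, np.ndarray) else float(out)


def ear_solid(D: float, e: float, a, coef: SolidCoef):
    """Excess absolute risk (cases per 10^4 person-years); same functional
    form as :func:`err_solid` with its own coefficients."""
    return err_solid(D, e, a, coef)


def excess_leukemia(D: float, e: float, t, coef: LeukemiaCoef):
    """Leukemia excess risk (relative or absolute per coefficient set) at time
    t > 0 since exposure; linear-quadratic in dose."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr <= 0):
        raise ValueError("time since exposure must be > 0")
    es = _e_star(e)
    log_t = np.log(t_arr / 25.0)
    out = (
        coef.beta
        * D
        * (1.0 + coef.theta * D)
        * np.exp(coef.gamma * es + (coef.delta + coef.phi * es) * log_t)
    )
    return out if isinstance(t, np.ndarray) else float(out)


def latency_weight(t, group: LatencyGroup, mu):
    """Phase-in weight in [0, 1]: logistic ramp in time since exposure with
    midpoint ``mu`` (weight(mu) = 0.5 exactly). ``t`` and ``mu`` broadcast."""
    return expit((np.asarray(t, dtype=float) - np.asarray(mu, dtype=float))
                 / group.steepness)


# ---------------------------------------------------------------------------
# Uncertainty draws


@dataclass(frozen=True)
class UncertaintyDraws:
    """Shared Latin-hypercube parameter draws for one run.

    ``beta_mult`` holds one lognormal coefficient multiplier per (site, sex);
    ``mu`` the latency midpoint per site group; ``ddref`` the sampled DDREF.
    """

    n_draws: int
    ddref: np.ndarray                       # (n_draws,)
    mu: dict[str, np.ndarray]               # group -> (n_draws,)
    beta_mult: dict[tuple[str, str], np.ndarray]  # (site, sex) -> (n_draws,)


def sample_uncertainty(config: RiskConfig, n_draws: int, seed: int) -> UncertaintyDraws:
    """Latin hypercube draws of all uncertain parameters.

    Each parameter's ``n_draws`` samples occupy distinct equal-probability
    bins of its marginal distribution; deterministic given ``seed``.
    """
    if n_draws < 2:
        raise ValueError("n_draws must be >= 2")
    site_sex = sorted(
        (site, sex) for site in config.sites for sex in ("female", "male")
    )
    groups = sorted(config.latency.groups)
    ndim = len(site_sex) + 1 + len(groups)
    u = qmc.LatinHypercube(d=ndim, seed=seed).random(n_draws)

    beta_mult: dict[tuple[str, str], np.ndarray] = {}
    col = 0
    for site, sex in site_sex:
        sigma = config.sites[site].beta_sigma
        if sigma == 0:
            beta_mult[(site, sex)] = np.ones(n_draws)
        else:
            beta_mult[(site, sex)] = stats.lognorm.ppf(u[:, col], s=sigma, scale=1.0)
        col += 1
    ddref = stats.lognorm.ppf(u[:, col], s=config.ddref.sigma, scale=config.ddref.median)
    col += 1
    mu: dict[str, np.ndarray] = {}
    for g in groups:
        lg = config.latency.groups[g]
        span = lg.mu_max - lg.mu_min
        if span == 0:
            mu[g] = np.full(n_draws, lg.mu_mode)
        else:
            c = (lg.mu_mode - lg.mu_min) / span
            mu[g] = stats.triang.ppf(u[:, col], c, loc=lg.mu_min, scale=span)
        col += 1
    return UncertaintyDraws(n_draws=n_draws, ddref=ddref, mu=mu, beta_mult=beta_mult)


def central_draw(config: RiskConfig) -> UncertaintyDraws:
    """Degenerate single 'draw' at the central parameter values (multipliers
    1, DDREF at its median, latency midpoints at their modes)."""
    return UncertaintyDraws(
        n_draws=1,
        ddref=np.array([config.ddref.median]),
        mu={g: np.array([lg.mu_mode]) for g, lg in config.latency.groups.items()},
        beta_mult={
            (site, sex): np.ones(1)
            for site in config.sites
            for sex in ("female", "male")
        },
    )


def uncertainty_limits(per_draw_totals: np.ndarray) -> tuple[float, float]:
    """Empirical 90% uncertainty limits: the 5th and 95th percentiles of the
    per-draw totals."""
    x = np.asarray(per_draw_totals, dtype=float)
    if x.size < 20:
        raise ValueError("need at least 20 draws for 90% uncertainty limits")
    lo, hi = np.percentile(x, [5.0, 95.0])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# LAR computation


def _lar_kernels(
    e: float,
    sex: str,
    site: str,
    life_table: LifeTable,
    baseline: BaselineIncidence,
    config: RiskConfig,
    ddref: np.ndarray,
    mu: np.ndarray,
    beta_mult: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-Gy LAR kernels (ERR path, EAR path) for vectors of draw parameters.

    Each kernel is the latency-weighted, survival-weighted age sum at unit
    dose with the leukemia curvature factored out; solid kernels are already
    divided by the DDREF. LAR is reassembled from the kernels by
    :func:`_combine_kernels`.
    """
    if not 0.0 <= e <= 100.0:
        raise ValueError("exposure age must be in [0, 100]")
    n = len(ddref)
    if not site_applies_to_sex(site, sex):
        return np.zeros(n), np.zeros(n)
    model = config.sites[site]
    group = config.latency.groups[LatencyConfig.group_for_site(site)]

    ages = np.arange(math.floor(e) + 1, 101, dtype=float)
    if ages.size == 0:
        return np.zeros(n), np.zeros(n)
    t = ages - e
    surv = life_table.survival[ages.astype(int)] / life_table.at(e)
    lam = baseline.rate[ages.astype(int)]
    w_lat = expit((t[None, :] - mu[:, None]) / group.steepness)  # (n, n_ages)

    w = model.transfer_weight
    es = _e_star(e)
    if model.model_class == "solid":
        ce: SolidCoef = model.err[sex]  # type: ignore[assignment]
        ca: SolidCoef = model.ear[sex]  # type: ignore[assignment]
        err_shape = math.exp(ce.gamma * es) * (ages / 60.0) ** ce.eta
        ear_shape = math.exp(ca.gamma * es) * (ages / 60.0) ** ca.eta
        k_err = (w_lat * (w * ce.beta * err_shape * lam * surv)[None, :]).sum(axis=1)
        k_ear = (w_lat * ((1.0 - w) * ca.beta * ear_shape / 1e4 * surv)[None, :]).sum(axis=1)
        return beta_mult * k_err / ddref, beta_mult * k_ear / ddref
    # leukemia: linear-quadratic dose response, no DDREF
    le: LeukemiaCoef = model.err[sex]  # type: ignore[assignment]
    la: LeukemiaCoef = model.ear[sex]  # type: ignore[assignment]
    log_t = np.log(t / 25.0)
    err_shape = math.exp(le.gamma * es) * np.exp((le.delta + le.phi * es) * log_t)
    ear_shape = math.exp(la.gamma * es) * np.exp((la.delta + la.phi * es) * log_t)
    k_err = (w_lat * (w * le.beta * err_shape * lam * surv)[None, :]).sum(axis=1)
    k_ear = (w_lat * ((1.0 - w) * la.beta * ear_shape / 1e4 * surv)[None, :]).sum(axis=1)
    return beta_mult * k_err, beta_mult * k_ear


def _combine_kernels(
    D: float, sex: str, site: str, config: RiskConfig,
    k_err: np.ndarray, k_ear: np.ndarray,
) -> np.ndarray:
    """LAR(D) from per-Gy kernels: linear for solid sites, linear-quadratic
    (per-path curvature theta) for leukemia."""
    if D < 0:
        raise ValueError("dose must be >= 0")
    model = config.sites[site]
    if model.model_class == "solid":
        return D * (k_err + k_ear)
    le: LeukemiaCoef = model.err[sex]  # type: ignore[assignment]
    la: LeukemiaCoef = model.ear[sex]  # type: ignore[assignment]
    return D * ((1.0 + le.theta * D) * k_err + (1.0 + la.theta * D) * k_ear)


def _lar_vector(
    D: float,
    e: float,
    sex: str,
    site: str,
    life_table: LifeTable,
    baseline: BaselineIncidence,
    config: RiskConfig,
    ddref: np.ndarray,
    mu: np.ndarray,
    beta_mult: np.ndarray,
) -> np.ndarray:
    """LAR per exposed person for vectors of draw parameters (all same len)."""
    k_err, k_ear = _lar_kernels(
        e, sex, site, life_table, baseline, config, ddref, mu, beta_mult
    )
    return _combine_kernels(D, sex, site, config, k_err, k_ear)


def lar_site(
    D: float,
    e: float,
    sex: str,
    site: str,
    life_table: LifeTable,
    baseline: BaselineIncidence,
    config: RiskConfig,
    draw: UncertaintyDraws | None = None,
):
    """Lifetime attributable risk (excess lifetime cases per exposed person)
    for one site from organ dose ``D`` in Gy at exposure age ``e``.

    With ``draw=None`` evaluates at the central parameter values and returns a
    float; with an :class:`UncertaintyDraws` returns one value per draw.
    A site not incident in ``sex`` (e.g. prostate for females) returns 0.
    """
    if site not in config.sites:
        raise ValueError(f"no risk model configured for site {site!r}")
    scalar = draw is None
    if draw is None:
        draw = central_draw(config)
    group_name = LatencyConfig.group_for_site(site)
    out = _lar_vector(
        D, e, sex, site, life_table, baseline, config,
        ddref=draw.ddref,
        mu=draw.mu[group_name],
        beta_mult=draw.beta_mult[(site, sex)],
    )
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Bulk evaluation over strata


@dataclass
class PerExamRisk:
    """Expected excess lifetime cancers per examination for one stratum:
    central values and per-draw vectors, by site."""

    key: StratumKey
    sites: tuple[str, ...]
    central: np.ndarray        # (n_sites,)
    draws: np.ndarray          # (n_draws, n_sites)

    @property
    def total_central(self) -> float:
        return float(self.central.sum())

    @property
    def total_draws(self) -> np.ndarray:
        return self.draws.sum(axis=1)

    @property
    def by_site(self) -> dict[str, float]:
        return dict(zip(self.sites, map(float, self.central)))


class RiskEngine:
    """Evaluates per-exam LAR across strata with shared parameter draws.

    The expensive age sums depend only on (site, sex, exposure age, draws),
    so they are cached per age-group midpoint and reused across strata and
    dose scalings.
    """

    def __init__(
        self,
        config: RiskConfig,
        life_tables: dict[str, LifeTable],
        baselines: dict[tuple[str, str], BaselineIncidence],
        draws: UncertaintyDraws,
        organ_for_site: dict[str, str] | None = None,
    ) -> None:
        from .vocab import ORGAN_FOR_SITE

        self.config = config
        self.life_tables = life_tables
        self.baselines = baselines
        self.draws = draws
        self.central = central_draw(config)
        self.organ_for_site = dict(organ_for_site or ORGAN_FOR_SITE)
        # per-Gy kernel cache: (site, sex, age_group, which) -> (k_err, k_ear)
        self._cache: dict[tuple[str, str, str, str], tuple[np.ndarray, np.ndarray]] = {}

    def _kernels(
        self, site: str, sex: str, age_group: str, which: str
    ) -> tuple[np.ndarray, np.ndarray]:
        key = (site, sex, age_group, which)
        if key not in self._cache:
            dr = self.draws if which == "draws" else self.central
            group_name = LatencyConfig.group_for_site(site)
            e = age_group_midpoint(age_group)
            self._cache[key] = _lar_kernels(
                e, sex, site,
                self.life_tables[sex], self.baselines[(site, sex)], self.config,
                ddref=dr.ddref, mu=dr.mu[group_name],
                beta_mult=dr.beta_mult[(site, sex)],
            )
        return self._cache[key]

    def lar(self, D_gy: float, e_group: str, sex: str, site: str, which: str = "central"):
        """Per-exam LAR for one site at the stratum's midpoint exposure age."""
        k_err, k_ear = self._kernels(site, sex, e_group, which)
        out = _combine_kernels(D_gy, sex, site, self.config, k_err, k_ear)
        return float(out[0]) if which == "central" else out

    def per_exam(self, stratum) -> PerExamRisk:
        """Per-exam risk for a stratum summary (needs ``key`` and
        ``dose_mean`` in mGy); doses are converted to Gy."""
        key: StratumKey = stratum.key
        central = np.zeros(len(SITES))
        draws = np.zeros((self.draws.n_draws, len(SITES)))
        for i, site in enumerate(SITES):
            organ = self.organ_for_site[site]
            try:
                dose_mgy = stratum.dose_mean[organ]
            except KeyError:
                raise ValueError(
                    f"stratum {key} lacks a dose mean for organ {organ!r}"
                ) from None
            d_gy = dose_mgy / 1000.0
            central[i] = self.lar(d_gy, key.age_group, key.sex, site, "central")
            draws[:, i] = self.lar(d_gy, key.age_group, key.sex, site, "draws")
        return PerExamRisk(key=key, sites=SITES, central=central, draws=draws)


def lar_per_exam(stratum, engine: RiskEngine) -> PerExamRisk:
    """Per-exam lifetime attributable risk for one stratum (thin wrapper over
    :meth:`RiskEngine.per_exam`)."""
    return engine.per_exam(stratum)


__all__ = [
    "SolidCoef",
    "LeukemiaCoef",
    "SiteRiskModel",
    "LatencyGroup",
    "LatencyConfig",
    "DDREFConfig",
    "RiskConfig",
    "err_solid",
    "ear_solid",
    "excess_leukemia",
    "latency_weight",
    "lar_site",
    "lar_per_exam",
    "RiskEngine",
    "PerExamRisk",
    "UncertaintyDraws",
    "sample_uncertainty",
    "central_draw",
    "uncertainty_limits",
]
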