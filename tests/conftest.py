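import numpy as np
import pytest

from ctlar.defaults import default_registry_config, default_risk_config
from ctlar.registry import BaselineIncidence, LifeTable
from ctlar.risk import (
    DDREFConfig,
    LatencyConfig,
    LatencyGroup,
    RiskConfig,
    SiteRiskModel,
    SolidCoef,
)


@pytest.fixture(scope="session")
def risk_config():
    return default_risk_config()


@pytest.fixture(scope="session")
def flat_life_table():
    """No mortality: S(a) = 1 everywhere (competing risk switched off)."""
    return LifeTable(sex="female", survival=np.ones(101))


def constant_baseline(site: str, sex: str, rate: float) -> BaselineIncidence:
    return BaselineIncidence(site=site, sex=sex, rate=np.full(101, rate))


@pytest.fixture(scope="session")
def small_registry_config():
    return default_registry_config(n_patients=3000, seed=7)


def unit_solid_config(
    w: float = 1.0,
    beta_err: float = 1.0,
    beta_ear: float = 0.0,
    gamma: float = 0.0,
    eta: float = 0.0,
    latency_off: bool = True,
    ddref_median: float = 1.0,
) -> RiskConfig:
    """Single-site solid config with unit coefficients, optional disabled
    latency ramp (midpoint far in the past so the weight is exactly 1.0 in
    float arithmetic) and DDREF 1."""
    mu = -1e7 if latency_off else 7.5
    groups = {
        g: LatencyGroup(mu_min=mu, mu_mode=mu, mu_max=mu,
                        window_start=4.0, window_end=11.0)
        for g in ("solid", "thyroid", "leukemia")
    }
    lo, hi = 0.9 * ddref_median, 1.1 * ddref_median
    return RiskConfig(
        sites={
            "colon": SiteRiskModel(
                site="colon",
                model_class="solid",
                err={"female": SolidCoef(beta_err, gamma, eta),
                     "male": SolidCoef(beta_err, gamma, eta)},
                ear={"female": SolidCoef(beta_ear, gamma, eta),
                     "male": SolidCoef(beta_ear, gamma, eta)},
                transfer_weight=w,
                beta_sigma=0.0,
            )
        },
        latency=LatencyConfig(groups=groups),
        ddref=DDREFConfig(median=ddref_median, interval90=(lo, hi)),
    )
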