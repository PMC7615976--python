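"""Shared fixtures: exact fixtures with hand-computed expectations and
helpers to build harmonized instrument sets from simulations."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from targetmr.instruments import HarmonizedInstrument, InstrumentSet
from targetmr.simulate import SimulationConfig, simulate_two_sample
from targetmr.instruments import harmonize

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_set(beta_x, se_x, beta_y, se_y, **kwargs) -> InstrumentSet:
    """Build a harmonized set directly from effect arrays."""
    instruments = tuple(
        HarmonizedInstrument(
            variant_id=f"v{k + 1}",
            beta_x=float(bx),
            se_x=float(sx),
            beta_y=float(by),
            se_y=float(sy),
            wald_ratio=float(by) / float(bx),
            ratio_se=float(sy) / abs(float(bx)),
            flipped=False,
            palindromic=False,
        )
        for k, (bx, sx, by, sy) in enumerate(zip(beta_x, se_x, beta_y, se_y))
    )
    return InstrumentSet(
        exposure_name=kwargs.get("exposure_name", "X"),
        outcome_name=kwargs.get("outcome_name", "Y"),
        target=kwargs.get("target"),
        instruments=instruments,
    )


def simulated_set(seed: int = 0, **config_kwargs) -> InstrumentSet:
    """Simulate one exposure-outcome pair and harmonize every variant."""
    config = SimulationConfig(seed=seed, **config_kwargs)
    exposure, outcome, _ = simulate_two_sample(config)
    return harmonize(exposure, outcome, [r.variant_id for r in exposure])


@pytest.fixture
def collinear_set() -> InstrumentSet:
    """Three instruments lying exactly on the line beta_y = 0.5 * beta_x.

    With se_y = 0.01 throughout, the IVW weights are 1e4 each, the
    denominator sum(w * bx^2) = 1400, so the fixed-effect SE is
    sqrt(1/1400) and the estimate is exactly 0.5 with zero residuals
    (Q = 0, Egger intercept = 0).
    """
    return make_set(
        beta_x=[0.1, 0.2, 0.3],
        se_x=[0.01, 0.01, 0.01],
        beta_y=[0.05, 0.10, 0.15],
        se_y=[0.01, 0.01, 0.01],
    )
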