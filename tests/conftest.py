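"""Shared fixtures: simulated runs at the study's standard conditions and a
noise-free configuration factory for closed-form checks."""

from __future__ import annotations

import pytest

from cecflux.pipeline import analyze_simulated
from cecflux.synthetic import SampleSpec, SimConfig, simulate_run, standard_study


def make_noise_free_config(**overrides) -> SimConfig:
    """All stochastic terms off; deterministic plate with unit effects."""
    base = dict(
        seeding_cv=0.0,
        stain_cv=0.0,
        meas_cv=0.0,
        plate_gain_sd=0.0,
        plate_effect_sd=0.0,
        t0_ref_cv=0.0,
        well_outlier_rate=0.0,
        read_outlier_rate=0.0,
        lysis_residual=0.0,
        passive_frac=0.0,
        background_level=0.0,
        rng_seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def noise_free_config():
    return make_noise_free_config


@pytest.fixture(scope="session")
def small_run():
    """Three plates, eight study samples each, default (noisy) conditions."""
    cfg = SimConfig(rng_seed=1)
    return simulate_run(cfg, standard_study(3, 8, seed=1))


@pytest.fixture(scope="session")
def small_analysis(small_run):
    return analyze_simulated(small_run)


@pytest.fixture(scope="session")
def single_sample_specs():
    return [SampleSpec("S1")]
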