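import numpy as np
import pytest

import tractvar as tv


@pytest.fixture(scope="session")
def registry():
    return tv.load_pathway_registry()


@pytest.fixture(scope="session")
def registry_by_name(registry):
    return {r.name: r for r in registry}


def null_config(**overrides) -> tv.SyntheticConfig:
    """A generator configuration with every planted effect switched off."""
    flat = {
        name: tv.TrajectoryParams(tp.base, 0.0, tp.rise_tau, tp.peak_age, 0.0, tp.noise_sd)
        for name, tp in tv.SyntheticConfig().trajectories.items()
    }
    defaults = dict(
        asymmetry_offsets={},
        left_variance_multipliers={},
        variance_profile=(1.0,) * 8,
        trajectories=flat,
        behavior_couplings=(),
        behavior_age_coef=0.0,
        behavior_sex_coef=0.0,
        tbv_subject_sd=0.0,
    )
    defaults.update(overrides)
    return tv.SyntheticConfig(**defaults)


@pytest.fixture
def small_cohort():
    cfg = tv.SyntheticConfig(n_per_epoch=4, seed=11)
    return tv.make_cohort(cfg), cfg


@pytest.fixture(scope="session")
def medium_tables(registry):
    """A mid-size cohort with the default (planted-effect) configuration."""
    cfg = tv.SyntheticConfig(n_per_epoch=25, seed=5)
    subjects = tv.make_cohort(cfg)
    table, truth = tv.make_feature_table(subjects, registry, cfg)
    return subjects, table, truth, cfg
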