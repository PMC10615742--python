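import pytest

from actilipid.simulate import (
    ActivitySimConfig,
    EpisodeSpec,
    LipidEffect,
    LipidomicsSimConfig,
    simulate_activity,
    simulate_lipidomics,
)


@pytest.fixture(scope="session")
def nocturnal_series():
    """183-day null animal (no injected episodes), default settings."""
    series, _ = simulate_activity(ActivitySimConfig(n_days=183, seed=11))
    return series


@pytest.fixture(scope="session")
def episodic_series():
    """Animal with one 12-h hyperactivity bout and one 21-day hypoactivity
    episode with morning-light redistribution, plus the injected truth."""
    cfg = ActivitySimConfig(
        n_days=183,
        seed=12,
        episodes=[
            EpisodeSpec("HAB", onset_day=30, onset_hour=13.0, duration_hours=12.0,
                        amplitude=5.0),
            EpisodeSpec("DEPRESSION_LIKE", onset_day=90, duration_days=21,
                        amplitude=0.5, light_redistribution=0.3),
        ],
    )
    series, truth = simulate_activity(cfg)
    return series, truth, cfg


@pytest.fixture(scope="session")
def effect_lipid_table():
    """464-lipid table with a large (d=2) genotype effect on the PS class."""
    cfg = LipidomicsSimConfig(seed=21, effects=[LipidEffect("PS", 2.0)])
    return simulate_lipidomics(cfg)


@pytest.fixture(scope="session")
def null_lipid_table():
    cfg = LipidomicsSimConfig(seed=22)
    table, _ = simulate_lipidomics(cfg)
    return table
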