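import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """One small simulated study (reads included) shared across tests.

    20 loci, 12 cases / 12 controls, one strongly planted locus; small
    enough to regenerate in seconds yet exercises every pipeline stage.
    """
    from camlkit.simulate import (
        PlantedEffect,
        SimulationConfig,
        end_to_end_fixture,
    )

    config = SimulationConfig(
        seed=424241,
        n_loci=20,
        n_cases=12,
        n_controls=12,
        planted_effect_loci=(PlantedEffect(4, 0.05, 0.7),),
        mean_depth=30.0,
        depth_dispersion=0.0,
        noise_epsilon=0.0,
    )
    out = tmp_path_factory.mktemp("bundle")
    return end_to_end_fixture(out, config)
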