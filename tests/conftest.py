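import pytest

from netmoa.synthetic_data import GeneratorConfig, generate_world
from netmoa.training import AnnealSchedule, sample_ensemble


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world shared by training/analysis tests."""
    return generate_world(
        GeneratorConfig(
            n_nodes=60,
            m=2,
            k_processes=3,
            effectors_per_process=4,
            n_drugs=4,
            targets_per_drug=2,
            seed=7,
        )
    )


@pytest.fixture(scope="session")
def quick_schedule():
    """A shortened annealing schedule for unit tests."""
    return AnnealSchedule(steps_per_temperature=40, cycles=1)


@pytest.fixture(scope="session")
def small_ensemble(small_world, quick_schedule):
    return sample_ensemble(
        small_world.interactome,
        small_world.training_set,
        schedule=quick_schedule,
        n_solutions=5,
        base_seed=11,
    )
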