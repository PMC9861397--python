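import pytest

from bilayernet import PipelineConfig, SimulationConfig, run_pipeline
from bilayernet.simulate import simulate_dataset

DATASET_SEED = 1


@pytest.fixture(scope="session")
def dataset():
    """The bundled synthetic dataset at its default study conditions."""
    return simulate_dataset(SimulationConfig(seed=DATASET_SEED))


@pytest.fixture(scope="session")
def pipeline_results(tmp_path_factory):
    """One full pipeline run on the bundled dataset, shared across tests."""
    outdir = tmp_path_factory.mktemp("pipeline_run")
    config = PipelineConfig(simulate=SimulationConfig(seed=DATASET_SEED), seed=DATASET_SEED)
    return run_pipeline(config, outdir)


@pytest.fixture()
def small_config():
    """A fast, small but structurally complete simulation config."""
    return SimulationConfig(
        n_sites=400,
        n_genes=300,
        n_tumor=60,
        n_normal=20,
        seed=7,
    )
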