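import pandas as pd
import pytest

from splicefans.pipeline import RunConfig, run_pipeline
from splicefans.sim import SimulationConfig, simulate_dataset


def run_simulated_pipeline(config: SimulationConfig, directory, **run_kwargs):
    """Generate a dataset and run the full pipeline on its files."""
    paths = simulate_dataset(config, directory / "sim")
    result = run_pipeline(
        RunConfig(
            manifest=paths["manifest"],
            annotation=paths["annotation"],
            genome=paths["genome"],
            out_dir=directory / "out",
            **run_kwargs,
        )
    )
    truth_sites = pd.read_csv(paths["truth_sites"], sep="\t")
    return paths, result, truth_sites


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """A 30-gene simulated experiment run through the whole pipeline."""
    config = SimulationConfig(n_genes=30, seed=11)
    directory = tmp_path_factory.mktemp("small_run")
    paths, result, truth = run_simulated_pipeline(config, directory)
    return config, paths, result, truth
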