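import pathlib

import pandas as pd
import pytest

from venomics.synthetic_data import SimulationConfig, simulate_all

TABLE_PATH = (
    pathlib.Path(__file__).resolve().parents[1]
    / "src"
    / "venomics"
    / "data"
    / "candidate_fpkm_table.tsv"
)


@pytest.fixture(scope="session")
def candidate_table() -> pd.DataFrame:
    """The packaged 70-row FPKM fixture."""
    return pd.read_csv(TABLE_PATH, sep="\t")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_transcripts=120,
        n_venom=10,
        fold_change_venom=8.0,
        psm_depth=3.0,
        venn_design=(2, 3, 1, 4),
        seed=7,
    )


@pytest.fixture(scope="session")
def simulated(tmp_path_factory, small_config):
    """One simulated input directory shared across tests."""
    outdir = tmp_path_factory.mktemp("sim") / "inputs"
    truth = simulate_all(small_config, outdir)
    return outdir, truth, small_config
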