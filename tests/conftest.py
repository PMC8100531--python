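import numpy as np
import pytest

from cryopirna.pipeline import PipelineConfig, run_all
from cryopirna.simdata import SimulationConfig


def small_sim_config(**overrides) -> SimulationConfig:
    """Scaled-down study conditions used throughout the suite."""
    base = dict(
        n_chromosomes=1,
        chrom_length=30_000,
        n_clusters=3,
        pirnas_per_cluster=20,
        n_ncrna_loci=8,
        nb_mean_range=(10.0, 60.0),
        n_homolog_pairs=4,
        n_transcripts=30,
        transcript_length=300,
        n_target_sites=10,
    )
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture
def small_config() -> SimulationConfig:
    return small_sim_config()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full scaled-down pipeline run shared by CLI/report tests."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(seed=7, sim=small_sim_config(seed=7))
    run_all(outdir, cfg)
    return outdir, cfg
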