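import warnings

import numpy as np
import pytest

from radmap import pipeline, synthetic_data as sd

warnings.filterwarnings("ignore", message=".*correlation coefficient is not defined.*")


def _run(tmp_root, sim_cfg: sd.SimConfig):
    truth, scaffold_index, ad, gt = sd.simulate_dataset(sim_cfg)
    paths = sd.write_dataset(str(tmp_root / "sim"), sim_cfg, truth, scaffold_index, ad, gt)
    run_cfg = pipeline.RunConfig(
        vcf=paths["vcf"],
        depth_table=paths["depth"],
        scaffold_index=paths["scaffolds"],
        out_dir=str(tmp_root / "out"),
        seed=sim_cfg.seed,
    )
    result = pipeline.run_pipeline(run_cfg)
    return truth, scaffold_index, paths, run_cfg, result


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """Full pipeline on the generator's default study conditions
    (24 chromosomes, 90 offspring, dropout e = 0.05)."""
    root = tmp_path_factory.mktemp("default_run")
    return _run(root, sd.SimConfig(seed=11))


@pytest.fixture(scope="session")
def zero_dropout_run(tmp_path_factory):
    """Full pipeline on a no-dropout, no-error cross."""
    root = tmp_path_factory.mktemp("zero_dropout_run")
    return _run(root, sd.SimConfig(seed=12, dropout_e=0.0))


@pytest.fixture(scope="session")
def small_sim():
    """A small in-memory cross for unit-scale checks."""
    cfg = sd.SimConfig(
        n_chromosomes=3, n_scaffolds_per_chromosome=5, n_offspring=40, seed=5
    )
    truth, scaffold_index, ad, gt = sd.simulate_dataset(cfg)
    return cfg, truth, scaffold_index, ad, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
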