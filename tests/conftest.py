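import numpy as np
import pytest

from nuptools.simulate import SimConfig, simulate

#: scaled-down study conditions used by tests that regenerate many seeds
SMALL_SIM = dict(
    n_chromosomes=2,
    chromosome_length=200_000,
    n_structural_genes=40,
    n_te=80,
    n_other_repeat=20,
    n_nuclear_trna=20,
    n_rrna_eukaryotic=8,
    n_spliceosomal=5,
    n_other_rna=5,
    n_episode_I=60,
    n_episode_II=240,
    fragment_length_range=(100, 600),
)


@pytest.fixture(scope="session")
def sim_bundle(tmp_path_factory):
    """One default-condition synthetic bundle, generated once per session."""
    outdir = tmp_path_factory.mktemp("sim")
    cfg = SimConfig(seed=11)
    paths = simulate(cfg, outdir)
    return cfg, paths


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
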