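import warnings

import numpy as np
import pytest

from txqc.simulate import SimConfig, simulate_transcriptome, simulate_reads


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_genes=30)


@pytest.fixture(scope="session")
def small_sim(small_config):
    return simulate_transcriptome(small_config)


@pytest.fixture(scope="session")
def clean_config():
    """Error-free, contamination-free read regime for exactness checks."""
    return SimConfig(
        seed=12,
        n_genes=25,
        base_error_rate=0.0,
        rrna_fraction=0.0,
        adapter_fraction=0.0,
        lowq_tail_fraction=0.0,
        mean_isoforms_per_gene=1.0,
    )


@pytest.fixture(scope="session")
def clean_sim(clean_config):
    return simulate_transcriptome(clean_config)


@pytest.fixture(scope="session")
def clean_reads(clean_config, clean_sim):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_reads(
            clean_sim.transcripts, clean_sim.truth, clean_config, 600, rrna=clean_sim.rrna
        )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
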