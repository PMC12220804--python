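import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plvscan import element_caller
from plvscan.synthetic_data import SimConfig, simulate

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def random_dna(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


@pytest.fixture(scope="session")
def small_sim():
    """A small but complete simulated assembly shared across test modules."""
    config = SimConfig(
        seed=7, n_contigs=2, contig_len_bp=300_000, n_elements=8, n_nested=2
    )
    contigs, truth, marker_df = simulate(config)
    return config, contigs, truth, marker_df


@pytest.fixture(scope="session")
def small_sim_markers(small_sim, tmp_path_factory):
    _, _, _, marker_df = small_sim
    path = tmp_path_factory.mktemp("markers") / "marker_hits.tsv"
    marker_df.to_csv(path, sep="\t", index=False)
    return element_caller.load_marker_hits(path)
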