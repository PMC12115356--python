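import pandas as pd
import pytest
from hypothesis import settings

from nulliseq import CountMatrix, GeneAnnotation, SimulationConfig, simulate_experiment

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_ann() -> GeneAnnotation:
    """Three genes on two chromosomes."""
    return GeneAnnotation.from_records(
        [("g1", "A01", 1000), ("g2", "C01", 500), ("g3", "C01", 800)]
    )


@pytest.fixture
def tiny_counts() -> CountMatrix:
    frame = pd.DataFrame(
        {
            "Ctr_1": [10, 20, 0],
            "Ctr_2": [12, 18, 0],
            "Ctr_3": [11, 22, 1],
            "NC_1": [9, 2, 0],
            "NC_2": [13, 1, 0],
            "NC_3": [10, 3, 0],
        },
        index=pd.Index(["g1", "g2", "g3"], name="gene_id"),
    )
    return CountMatrix(frame)


@pytest.fixture(scope="session")
def small_sim():
    """One default-mode simulated experiment, small genome, shared per session."""
    cfg = SimulationConfig(genes_per_chromosome=60, seed=42)
    ann, hmap, counts, truth = simulate_experiment(cfg)
    return cfg, ann, hmap, counts, truth


@pytest.fixture(scope="session")
def fitted(small_sim):
    """A fitted pipeline on the session simulation (with homoeolog map)."""
    from nulliseq import NullisomyExperiment

    _, ann, hmap, counts, _ = small_sim
    return NullisomyExperiment(counts, ann, homolog_map=hmap).fit()
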