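import numpy as np
import pandas as pd
import pytest

from transmarker import PipelineConfig, simulate_dataset
from transmarker.classification import ClassifierConfig
from transmarker.network_construction import StateGraph
from transmarker.pipeline import run_from_dataset


def make_graph(edges, nodes=None, state_index=0):
    """Directed StateGraph from an edge list (nodes inferred if omitted)."""
    if nodes is None:
        nodes = sorted({g for e in edges for g in e})
    return StateGraph(state_index=state_index, nodes=tuple(nodes),
                      edges=frozenset(edges))


@pytest.fixture(scope="session")
def dataset30():
    return simulate_dataset(30, seed=5)


@pytest.fixture(scope="session")
def pipeline30(dataset30):
    """One full pipeline run (with a small classifier budget), shared."""
    cfg = PipelineConfig(states=list(dataset30.state_names), seed=5,
                         classifier=ClassifierConfig(n_runs=2))
    return run_from_dataset(dataset30, cfg)


@pytest.fixture
def counts_frames(dataset30):
    return [pd.DataFrame(m, index=list(dataset30.genes))
            for m in dataset30.counts]


@pytest.fixture
def rng():
    return np.random.default_rng(0)
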