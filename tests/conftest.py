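import numpy as np
import pandas as pd
import pytest

from bridgenet.scales import NODE_COMMUNITIES, NODE_IDS, NodeScoreTable, default_codebook
from bridgenet.synthetic import (
    SimulationConfig,
    default_symptom_thresholds,
    make_ground_truth,
    paper_like_config,
    simulate_responses,
)

#: bridge edges several times stronger than the study-like defaults; used
#: for stability checks that need a well-determined BEI ordering
STRONG_CROSS_EDGES = (
    ("NEU", "A3", 0.3),
    ("NEU", "A6", 0.25),
    ("NEU", "A1", 0.2),
    ("AGR", "D9", -0.3),
    ("AGR", "D2", -0.2),
    ("EXT", "D4", -0.25),
    ("CON", "A2", -0.2),
    ("OPE", "D6", -0.25),
)


def strong_truth(seed):
    """21-node ground truth with strong, well-separated bridge structure."""
    idx = {nid: k for k, nid in enumerate(NODE_IDS)}
    cross = [(idx[a], idx[b], w) for a, b, w in STRONG_CROSS_EDGES]
    return make_ground_truth(
        p=21,
        communities=[NODE_COMMUNITIES[nid] for nid in NODE_IDS],
        cross_edges=cross,
        intra_density=0.25,
        seed=seed,
        node_ids=NODE_IDS,
    )


def strong_scores(n, seed, mode="likert"):
    truth = strong_truth(seed)
    cfg = SimulationConfig(
        n=n,
        seed=seed + 1,
        thresholds={nid: default_symptom_thresholds() for nid in NODE_IDS[5:]},
    )
    return simulate_responses(truth, cfg, mode=mode), truth


@pytest.fixture(scope="session")
def codebook():
    return default_codebook()


@pytest.fixture
def complete_items(codebook):
    """Small fully answered item-response frame (n=8) in codebook order."""
    rng = np.random.default_rng(42)
    data = {}
    for it in codebook.items:
        data[it.item_id] = rng.integers(it.min_value, it.max_value + 1, size=8)
    return pd.DataFrame(data)


@pytest.fixture(scope="session")
def paper_truth():
    truth, cfg = paper_like_config(n=507, seed=11)
    return truth, cfg


@pytest.fixture(scope="session")
def likert_scores(paper_truth):
    truth, cfg = paper_truth
    return simulate_responses(truth, cfg)


def scores_from_array(X, node_ids=None):
    """Wrap a raw array as a NodeScoreTable with arbitrary node ids."""
    X = np.asarray(X, dtype=float)
    if node_ids is None:
        node_ids = [f"N{k}" for k in range(X.shape[1])]
    community = {
        nid: NODE_COMMUNITIES.get(nid, "personality" if k % 2 == 0 else "anxiety_depression")
        for k, nid in enumerate(node_ids)
    }
    return NodeScoreTable(
        values=pd.DataFrame(X, columns=list(node_ids)), community=community
    )
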