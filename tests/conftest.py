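import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netcontrast.expression import CountMatrix
from netcontrast.pathnet import MergedNetwork, annotate_topology, set_de_status
from netcontrast.syndata import SimulationConfig, SyntheticDataset, simulate_dataset


def make_counts(data: dict, conditions: dict) -> CountMatrix:
    """CountMatrix from {gene: [counts per sample]} and {sample: condition}."""
    samples = list(conditions)
    df = pd.DataFrame.from_dict(data, orient="index", columns=samples)
    df.index.name = "gene_id"
    return CountMatrix(df, dict(conditions))


def make_network(edges, de=(), hub_threshold=20, singletons=()) -> MergedNetwork:
    graph = nx.Graph()
    graph.add_edges_from(edges)
    net = MergedNetwork(graph=graph, singletons=set(singletons))
    set_de_status(net, set(de))
    annotate_topology(net, hub_threshold=hub_threshold)
    return net


def hits_frame(rows) -> pd.DataFrame:
    """Hit table from (query, subject, score, alen[, qlen[, slen]]) tuples."""
    out = []
    for row in rows:
        q, s, score, alen = row[:4]
        qlen = row[4] if len(row) > 4 else alen
        slen = row[5] if len(row) > 5 else alen
        out.append(
            {
                "query_id": q,
                "subject_id": s,
                "bit_score": float(score),
                "alignment_length": int(alen),
                "query_length": int(qlen),
                "subject_length": int(slen),
            }
        )
    return pd.DataFrame(out)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(n_genes=600, n_pathways=20, rng_seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_config) -> SyntheticDataset:
    return simulate_dataset(small_config)
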