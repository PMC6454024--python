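"""Calibration and recovery studies on synthetic data.

These are the package's standard self-checks: they quantify, under known
ground truth, the error rates of the neighborhood permutation test and
the accuracy of the reciprocal-best-hit mapping. Each function is a pure
computation (seeded, no I/O) so the analysis drivers, the test suite and
the reproduction script can share it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from netcontrast.homology import best_reciprocal_hits, filter_hits
from netcontrast.neighborhood import neighborhood_de_test, shuffle_null
from netcontrast.pathnet import annotate_topology, merge_network, set_de_status
from netcontrast.syndata import SimulationConfig, simulate_dataset


@dataclass
class NullMomentCheck:
    null_mean: float
    null_var: float
    expected_mean: float
    expected_var: float
    n_perm: int


def null_moment_check(
    n_total: int = 200,
    n_de: int = 40,
    n_neighborhood: int = 30,
    n_perm: int = 10000,
    rng_seed: int = 0,
) -> NullMomentCheck:
    """Compare shuffle-null moments with the hypergeometric closed form.

    Each shuffle draws the DE label set uniformly without replacement, so
    the exact null count is Hypergeometric(N, K, n) with mean nK/N and
    variance nK(N-K)(N-n) / (N^2 (N-1)).
    """
    nodes = [f"n{i}" for i in range(n_total)]
    neighborhood = set(nodes[:n_neighborhood])
    mean, sd, _ = shuffle_null(nodes, n_de, neighborhood, n_perm=n_perm, rng=rng_seed)
    expected_mean = n_neighborhood * n_de / n_total
    expected_var = (
        n_neighborhood
        * n_de
        * (n_total - n_de)
        * (n_total - n_neighborhood)
        / (n_total**2 * (n_total - 1))
    )
    return NullMomentCheck(
        null_mean=mean,
        null_var=sd**2,
        expected_mean=expected_mean,
        expected_var=expected_var,
        n_perm=n_perm,
    )


def _network_from_dataset(dataset, labels=None):
    net = merge_network(dataset.pathways)
    if labels is not None:
        set_de_status(net, labels)
    annotate_topology(net)
    return net


def type_one_error_study(
    n_networks: int = 40,
    n_draws_per_network: int = 10,
    n_perm: int = 1000,
    de_rate: float = 0.05,
    alpha: float = 0.05,
    n_genes: int = 800,
    n_pathways: int = 25,
    rng_seed: int = 0,
) -> dict:
    """Rejection rate of the neighborhood test under a uniform label null.

    On each unplanted synthetic network, DE labels are assigned uniformly
    at random (a fresh draw per replicate) and the two-sided normal p of
    the permutation z is compared with alpha. Under the null the rate
    should sit near alpha.
    """
    rng = np.random.default_rng(rng_seed)
    rejections = 0
    total = 0
    for net_index in range(n_networks):
        config = SimulationConfig(
            n_genes=n_genes,
            n_pathways=n_pathways,
            rng_seed=int(rng.integers(2**31)),
        )
        dataset = simulate_dataset(config)
        net = _network_from_dataset(dataset)
        nodes = sorted(net.graph.nodes)
        n_de = int(round(de_rate * len(nodes)))
        for _ in range(n_draws_per_network):
            de = set(rng.choice(nodes, size=n_de, replace=False))
            set_de_status(net, {n: ("up" if n in de else "none") for n in nodes})
            result = neighborhood_de_test(
                net,
                config.seed_genes,
                n_perm=n_perm,
                rng_seed=int(rng.integers(2**31)),
            )
            total += 1
            if result.p_normal is not None and result.p_normal < alpha:
                rejections += 1
    return {"rejection_rate": rejections / total, "n_replicates": total, "alpha": alpha}


def planted_recovery_study(
    n_datasets: int = 20,
    n_random_pairs: int = 50,
    n_perm: int = 500,
    n_genes: int = 800,
    n_pathways: int = 25,
    rng_seed: int = 0,
) -> dict:
    """How often the true seeds' z beats the median z of random seed pairs.

    Datasets are generated with the default planting (enriched radius-2
    neighborhood around the designated seed hubs); for each dataset the
    test is run on the true seeds and on random non-seed pairs, and a
    dataset counts as recovered when the true z exceeds the random median.
    """
    rng = np.random.default_rng(rng_seed)
    wins = 0
    z_true_values = []
    for _ in range(n_datasets):
        config = SimulationConfig(
            n_genes=n_genes,
            n_pathways=n_pathways,
            rng_seed=int(rng.integers(2**31)),
        )
        dataset = simulate_dataset(config)
        net = _network_from_dataset(dataset, dataset.truth.de_labels["species_a"])
        z_true = neighborhood_de_test(
            net,
            dataset.truth.seed_genes,
            n_perm=n_perm,
            rng_seed=int(rng.integers(2**31)),
        ).z
        z_true_values.append(z_true)
        candidates = sorted(set(net.graph.nodes) - set(dataset.truth.seed_genes))
        z_random = []
        for _ in range(n_random_pairs):
            pair = [str(g) for g in rng.choice(candidates, size=2, replace=False)]
            res = neighborhood_de_test(
                net, pair, n_perm=n_perm, rng_seed=int(rng.integers(2**31))
            )
            z_random.append(res.z if res.z is not None else 0.0)
        if z_true is not None and z_true > float(np.median(z_random)):
            wins += 1
    return {
        "recovery_fraction": wins / n_datasets,
        "n_datasets": n_datasets,
        "mean_z_true": float(np.mean([z for z in z_true_values if z is not None])),
    }


def brbh_benchmark(
    n_genes: int = 300,
    decoy_hit_fraction: float = 0.3,
    rng_seed: int = 21,
) -> dict:
    """Precision/recall of the reciprocal-best-hit map against planted pairs."""
    config = SimulationConfig(
        n_genes=n_genes,
        n_pathways=0,
        seed_genes=(),
        decoy_hit_fraction=decoy_hit_fraction,
        rng_seed=rng_seed,
    )
    dataset = simulate_dataset(config)
    pairs = best_reciprocal_hits(
        filter_hits(dataset.hits_ab), filter_hits(dataset.hits_ba)
    )
    found = set(zip(pairs["gene_a"], pairs["gene_b"]))
    truth = set(dataset.truth.true_homolog_pairs)
    precision = len(found & truth) / len(found) if found else 0.0
    recall = len(found & truth) / len(truth)
    bijective = bool(pairs["gene_a"].is_unique and pairs["gene_b"].is_unique)
    return {"precision": precision, "recall": recall, "bijective": bijective}
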