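"""Permutation z-score test for DE enrichment around seed nodes.

The statistic is the number of DE genes at graph distance 1..radius from
a set of seed nodes (seeds excluded). Its null distribution is estimated
by shuffling the DE labels over the network's connected nodes — each
permutation assigns the same number of DE labels to a uniform random node
subset — and counting labels landing in the neighborhood. The observed
count is converted to z = (obs - null mean) / null sd and a two-sided
normal p; an add-one empirical p is reported alongside. Because each
shuffle is a uniform draw without replacement, the exact null is
hypergeometric, which the permutation moments approach as the number of
permutations grows.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy import stats

from netcontrast.pathnet import MergedNetwork


def extract_neighborhood(
    net: MergedNetwork, seeds, radius: int = 2
) -> set[str]:
    """Nodes at distance 1..radius from any seed, seeds themselves excluded."""
    seeds = list(seeds)
    for seed in seeds:
        if seed not in net.graph:
            raise KeyError(f"seed {seed!r} not present in network")
    neighborhood: set[str] = set()
    for seed in seeds:
        reached = nx.single_source_shortest_path_length(net.graph, seed, cutoff=radius)
        neighborhood.update(reached)
    return neighborhood - set(seeds)


def shuffle_null(
    all_nodes,
    n_de: int,
    neighborhood,
    n_perm: int = 1000,
    rng: np.random.Generator | int | None = None,
    return_samples: bool = True,
):
    """Label-shuffling null for the neighborhood DE count.

    Each of ``n_perm`` permutations marks a uniform random subset of
    ``n_de`` nodes as DE and counts how many fall in ``neighborhood``.
    Returns (mean, sd with n-1 denominator, samples or None).
    """
    if n_perm < 2:
        raise ValueError("n_perm must be at least 2")
    nodes = list(all_nodes)
    n_total = len(nodes)
    if n_de > n_total:
        raise ValueError(f"n_de={n_de} exceeds the {n_total}-node universe")
    neighborhood = set(neighborhood)
    if not neighborhood <= set(nodes):
        raise ValueError("neighborhood must be a subset of the node universe")
    rng = np.random.default_rng(rng)
    indicator = np.fromiter((n in neighborhood for n in nodes), dtype=bool, count=n_total)
    samples = np.empty(n_perm, dtype=np.int64)
    # chunked vectorized shuffles: argpartition of uniform keys picks a
    # uniform random n_de-subset per row
    chunk = max(1, int(5e6) // max(n_total, 1))
    done = 0
    while done < n_perm:
        size = min(chunk, n_perm - done)
        keys = rng.random((size, n_total))
        picked = np.argpartition(keys, n_de - 1, axis=1)[:, :n_de] if n_de > 0 else None
        if picked is None:
            samples[done : done + size] = 0
        else:
            samples[done : done + size] = indicator[picked].sum(axis=1)
        done += size
    mean = float(samples.mean())
    sd = float(samples.std(ddof=1))
    return mean, sd, (samples if return_samples else None)


@dataclass
class ZScoreResult:
    z: float | None
    p_normal: float | None
    degenerate: bool


def permutation_zscore(observed: float, null_mean: float, null_sd: float) -> ZScoreResult:
    """z = (observed - null mean)/null sd with a two-sided normal p.

    A zero null sd yields an explicit degenerate flag rather than a NaN.
    """
    if null_sd < 0:
        raise ValueError("null_sd must be non-negative")
    if null_sd == 0:
        return ZScoreResult(z=None, p_normal=None, degenerate=True)
    z = (observed - null_mean) / null_sd
    p = 2.0 * stats.norm.sf(abs(z))
    return ZScoreResult(z=float(z), p_normal=float(min(p, 1.0)), degenerate=False)


@dataclass
class NeighborhoodTestResult:
    """Outcome of the label-shuffling neighborhood enrichment test."""

    seeds: list[str]
    radius: int
    neighborhood_size: int
    observed_de: int
    null_mean: float
    null_sd: float
    z: float | None
    p_normal: float | None
    p_empirical: float
    n_perm: int
    rng_seed: int
    restricted_to_hubs: bool
    degenerate: bool = False

    def check_invariants(self) -> None:
        assert 0 <= self.observed_de <= self.neighborhood_size
        assert 0.0 <= self.p_empirical <= 1.0
        if self.p_normal is not None:
            assert 0.0 <= self.p_normal <= 1.0
        if not self.degenerate and self.null_sd > 0:
            assert np.isclose(
                self.z, (self.observed_de - self.null_mean) / self.null_sd
            )

    def to_dict(self) -> dict:
        return {
            "seeds": ",".join(self.seeds),
            "radius": self.radius,
            "neighborhood_size": self.neighborhood_size,
            "observed_de": self.observed_de,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "z": self.z,
            "p_normal": self.p_normal,
            "p_empirical": self.p_empirical,
            "n_perm": self.n_perm,
            "rng_seed": self.rng_seed,
            "restricted_to_hubs": self.restricted_to_hubs,
            "degenerate": self.degenerate,
        }


def neighborhood_de_test(
    net: MergedNetwork,
    seeds,
    radius: int = 2,
    n_perm: int = 1000,
    rng_seed: int = 0,
    restrict_to_hubs: bool = False,
) -> NeighborhoodTestResult:
    """Compose extract -> observe -> shuffle -> z-score.

    Labels are shuffled over the connected component's nodes (the same
    universe on which degrees are computed); seeds keep their labels in the
    universe but are excluded from the neighborhood count. With
    ``restrict_to_hubs`` both the observed statistic and the shuffles are
    restricted to hub nodes. The empirical p is the add-one upper tail
    (1 + #{null >= observed}) / (n_perm + 1), doubled and capped at 1.
    """
    seeds = list(seeds)
    neighborhood = extract_neighborhood(net, seeds, radius=radius)
    universe = sorted(net.graph.nodes)
    if restrict_to_hubs:
        hubs = net.hubs()
        universe = sorted(hubs)
        neighborhood = neighborhood & hubs
    is_de = {
        n: net.graph.nodes[n].get("de_status", "none") != "none" for n in universe
    }
    n_de = sum(is_de.values())
    observed = sum(1 for n in neighborhood if is_de[n])
    null_mean, null_sd, samples = shuffle_null(
        universe, n_de, neighborhood, n_perm=n_perm, rng=rng_seed
    )
    zres = permutation_zscore(observed, null_mean, null_sd)
    p_emp = min(1.0, 2.0 * (1 + int((samples >= observed).sum())) / (n_perm + 1))
    result = NeighborhoodTestResult(
        seeds=seeds,
        radius=radius,
        neighborhood_size=len(neighborhood),
        observed_de=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=zres.z,
        p_normal=zres.p_normal,
        p_empirical=p_emp,
        n_perm=n_perm,
        rng_seed=rng_seed,
        restricted_to_hubs=restrict_to_hubs,
        degenerate=zres.degenerate,
    )
    result.check_invariants()
    return result
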