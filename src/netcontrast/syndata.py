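"""Synthetic two-species datasets with known ground truth.

The generator emulates the study design the pipeline targets: two species
treated with a hormone for 24 h and profiled by unreplicated RNA-seq.

* Counts are negative-binomial with gene-level log-normal baseline means;
  a planted fraction of genes responds with treated mean =
  2^(+/- lfc magnitude) x control mean.
* A pathway collection is a set of gene modules with Erdős–Rényi edges
  inside each module; designated seed genes are wired into enough modules
  to reach a target merged degree, and the DE labels in the seeds'
  radius-2 neighborhood are re-drawn at a chosen enrichment probability,
  planting the enriched subnetwork the neighborhood test should detect.
* Cross-species similarity hit tables contain mutual high-scoring hits
  for every true homolog pair plus lower-scoring decoys, some below the
  bit-score floor, so the reciprocal-best-hit filter is exercised.

All randomness flows from a single integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

import math
import os
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from netcontrast import io as ncio
from netcontrast.expression import CountMatrix
from netcontrast.pathnet import MergedNetwork, PathwayCollection, merge_network
from netcontrast.neighborhood import extract_neighborhood


class ConfigurationError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic two-species experiment.

    Defaults mirror the target design: one library per condition and
    species, ~5% of genes responding with |log2FC| >= 1.5, moderate
    negative-binomial overdispersion (shape k = 20, i.e. phi = 0.05, a
    typical value for genetically near-identical laboratory animals), and
    two seed genes wired as hubs whose radius-2 neighborhood is strongly
    (80%) enriched in DE labels.
    """

    n_genes: int = 2000
    n_samples_per_condition: int = 1
    nb_mean_log_mu: float = 5.0
    nb_mean_log_sigma: float = 1.0
    nb_dispersion: float = 20.0
    de_fraction: float = 0.05
    de_lfc_magnitude: float = 1.5
    n_pathways: int = 40
    pathway_size_range: tuple[int, int] = (10, 60)
    edge_density: float = 0.08
    seed_genes: tuple[str, ...] = ("gA0000", "gA0001")
    seed_target_degree: int = 25
    neighborhood_enrich_prob: float = 0.8
    decoy_hit_fraction: float = 0.2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_samples_per_condition <= 0:
            raise ConfigurationError("n_samples_per_condition must be positive")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be positive")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must be in [0, 1]")
        if self.de_lfc_magnitude <= 0:
            raise ConfigurationError("de_lfc_magnitude must be positive")
        if self.n_pathways < 0:
            raise ConfigurationError("n_pathways must be non-negative")
        lo, hi = self.pathway_size_range
        if lo < 2 or hi < lo:
            raise ConfigurationError("pathway_size_range must be an increasing pair >= 2")
        if not 0.0 < self.edge_density <= 1.0:
            raise ConfigurationError("edge_density must be in (0, 1]")
        if self.seed_target_degree <= 20:
            raise ConfigurationError("seed_target_degree must exceed the hub threshold of 20")
        if not 0.0 <= self.neighborhood_enrich_prob <= 1.0:
            raise ConfigurationError("neighborhood_enrich_prob must be in [0, 1]")
        if not 0.0 <= self.decoy_hit_fraction <= 1.0:
            raise ConfigurationError("decoy_hit_fraction must be in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["pathway_size_range"] = list(self.pathway_size_range)
        d["seed_genes"] = list(self.seed_genes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "pathway_size_range" in d:
            d["pathway_size_range"] = tuple(d["pathway_size_range"])
        if "seed_genes" in d:
            d["seed_genes"] = tuple(d["seed_genes"])
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    de_labels: dict[str, dict[str, str]]  # species -> gene -> up/down/none
    true_homolog_pairs: list[tuple[str, str]]
    seed_genes: list[str] = field(default_factory=list)
    planted_neighborhood: set[str] = field(default_factory=set)

    def de_genes(self, species: str) -> set[str]:
        return {g for g, s in self.de_labels[species].items() if s != "none"}

    def check_invariants(self) -> None:
        assert not (self.planted_neighborhood & set(self.seed_genes))
        a_side = [a for a, _ in self.true_homolog_pairs]
        b_side = [b for _, b in self.true_homolog_pairs]
        assert len(set(a_side)) == len(a_side) and len(set(b_side)) == len(b_side)

    def to_dict(self) -> dict:
        return {
            "de_labels": {sp: dict(sorted(lbl.items())) for sp, lbl in self.de_labels.items()},
            "true_homolog_pairs": [list(p) for p in self.true_homolog_pairs],
            "seed_genes": list(self.seed_genes),
            "planted_neighborhood": sorted(self.planted_neighborhood),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        return cls(
            de_labels={sp: dict(lbl) for sp, lbl in d["de_labels"].items()},
            true_homolog_pairs=[tuple(p) for p in d["true_homolog_pairs"]],
            seed_genes=list(d["seed_genes"]),
            planted_neighborhood=set(d["planted_neighborhood"]),
        )


SPECIES = ("species_a", "species_b")
_PREFIX = {"species_a": "gA", "species_b": "gB"}


def gene_ids(species: str, n_genes: int) -> list[str]:
    width = max(4, len(str(n_genes - 1)))
    return [f"{_PREFIX[species]}{i:0{width}d}" for i in range(n_genes)]


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, k: float, size) -> np.ndarray:
    """NB draws parametrized by mean and shape k (var = mu + mu^2/k)."""
    p = k / (k + mean)
    return rng.negative_binomial(k, p[:, None] * np.ones(size)[None, :]).astype(np.int64)


def simulate_expression(
    config: SimulationConfig,
) -> tuple[dict[str, CountMatrix], SyntheticTruth]:
    """Draw per-species count matrices with a planted DE gene set.

    Exactly floor(de_fraction * n_genes) genes are DE per species (drawn
    independently per species); planted genes have treated mean =
    2^(+/- de_lfc_magnitude) x control mean. Returns one CountMatrix per
    species holding both conditions, plus the truth record.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_de = int(math.floor(config.de_fraction * config.n_genes))
    n_rep = config.n_samples_per_condition

    matrices: dict[str, CountMatrix] = {}
    de_labels: dict[str, dict[str, str]] = {}
    for species in SPECIES:
        genes = gene_ids(species, config.n_genes)
        mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, config.n_genes)
        de_idx = rng.choice(config.n_genes, size=n_de, replace=False) if n_de else np.array([], int)
        direction = rng.choice([1.0, -1.0], size=n_de)
        labels = {g: "none" for g in genes}
        fold = np.ones(config.n_genes)
        for idx, sign in zip(de_idx, direction):
            fold[idx] = 2.0 ** (sign * config.de_lfc_magnitude)
            labels[genes[idx]] = "up" if sign > 0 else "down"
        ctrl = _nb_counts(rng, mu, config.nb_dispersion, n_rep)
        trt = _nb_counts(rng, mu * fold, config.nb_dispersion, n_rep)
        sample_ids = [f"ctrl_{i + 1}" for i in range(n_rep)] + [
            f"trt_{i + 1}" for i in range(n_rep)
        ]
        counts = pd.DataFrame(
            np.hstack([ctrl, trt]), index=pd.Index(genes, name="gene_id"), columns=sample_ids
        )
        conditions = {s: ("control" if s.startswith("ctrl") else "treated") for s in sample_ids}
        matrices[species] = CountMatrix(counts, conditions)
        de_labels[species] = labels

    genes_a = gene_ids("species_a", config.n_genes)
    genes_b = gene_ids("species_b", config.n_genes)
    truth = SyntheticTruth(
        de_labels=de_labels,
        true_homolog_pairs=list(zip(genes_a, genes_b)),
        seed_genes=list(config.seed_genes),
    )
    truth.check_invariants()
    return matrices, truth


def simulate_pathway_collection(
    config: SimulationConfig,
    gene_universe: list[str],
    truth: SyntheticTruth,
    species: str = "species_a",
) -> PathwayCollection:
    """Random pathway modules with planted hub seeds and an enriched neighborhood.

    Each pathway draws its members from the universe and wires them with
    Erdős–Rényi edges at ``edge_density``. Every seed gene is inserted into
    pathways and connected to random members until its merged degree
    reaches ``seed_target_degree``. Finally the DE labels of the seeds'
    radius-2 neighborhood are re-drawn: DE with probability
    ``neighborhood_enrich_prob`` (direction random), otherwise "none"; the
    seeds themselves are set to "up" and the truth record is updated.
    """
    config.validate()
    for seed in config.seed_genes:
        if seed not in gene_universe:
            raise ConfigurationError(f"seed gene {seed!r} not in gene universe")
    lo, hi = config.pathway_size_range
    if config.seed_genes and config.n_pathways * (hi - 1) < config.seed_target_degree:
        raise ConfigurationError(
            "seed_target_degree unattainable with the given pathway count/sizes"
        )
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 1)))
    members: dict[str, set[str]] = {}
    edges: dict[str, set[tuple[str, str]]] = {}
    universe = list(gene_universe)
    for p in range(config.n_pathways):
        name = f"pw{p:03d}"
        size = int(rng.integers(lo, hi + 1))
        mem = {str(g) for g in rng.choice(universe, size=min(size, len(universe)), replace=False)}
        pairs = []
        mem_sorted = sorted(mem)
        for i in range(len(mem_sorted)):
            for j in range(i + 1, len(mem_sorted)):
                pairs.append((mem_sorted[i], mem_sorted[j]))
        keep = rng.random(len(pairs)) < config.edge_density
        members[name] = mem
        edges[name] = {pairs[i] for i in np.flatnonzero(keep)}

    collection = PathwayCollection(members=members, edges=edges)
    if config.n_pathways == 0 or not config.seed_genes:
        return collection

    # wire each seed into pathways until its merged degree reaches target;
    # merged degree = number of distinct partners over the edge union
    pathway_names = sorted(members)
    for seed in config.seed_genes:
        partners = {
            (b if a == seed else a)
            for edge_set in edges.values()
            for a, b in edge_set
            if seed in (a, b)
        }
        guard = 0
        while len(partners) < config.seed_target_degree:
            guard += 1
            if guard > 100000:
                raise ConfigurationError(
                    f"could not reach seed_target_degree for {seed!r}"
                )
            name = pathway_names[int(rng.integers(len(pathway_names)))]
            members[name].add(seed)
            candidates = sorted(members[name] - {seed} - partners)
            if not candidates:
                continue
            partner = candidates[int(rng.integers(len(candidates)))]
            edges[name].add(tuple(sorted((seed, partner))))
            partners.add(partner)
    collection = PathwayCollection(members=members, edges=edges)

    # plant DE enrichment in the seeds' radius-2 neighborhood
    net = merge_network(collection)
    neighborhood = extract_neighborhood(net, list(config.seed_genes), radius=2)
    labels = truth.de_labels[species]
    for node in sorted(neighborhood):
        if rng.random() < config.neighborhood_enrich_prob:
            labels[node] = "up" if rng.random() < 0.5 else "down"
        else:
            labels[node] = "none"
    for seed in config.seed_genes:
        labels[seed] = "up"
    truth.planted_neighborhood = set(neighborhood)
    truth.seed_genes = list(config.seed_genes)
    truth.check_invariants()
    return collection


def simulate_hit_table(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mutual high-scoring hits for true pairs plus lower-scoring decoys.

    True pairs receive reciprocal hits with bit-scores in [150, 400).
    floor(decoy_hit_fraction x n_pairs) decoy hits link non-homologous
    genes at scores strictly below both partners' true scores, spanning the
    bit-score floor of 100 (the first decoy is pinned at 99 so the filter
    boundary is always exercised).
    """
    config.validate()
    pairs = truth.true_homolog_pairs
    if not pairs and config.decoy_hit_fraction < 1:
        raise ConfigurationError("true_homolog_pairs must be non-empty")
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 2)))
    n = len(pairs)
    true_scores = rng.uniform(150.0, 400.0, size=n)
    qlen = rng.integers(400, 3000, size=n)
    slen = rng.integers(400, 3000, size=n)
    alen = (0.6 * np.minimum(qlen, slen)).astype(int)

    def rows(queries, subjects, scores, qlens, slens, alens):
        return pd.DataFrame(
            {
                "query_id": queries,
                "subject_id": subjects,
                "bit_score": np.round(scores, 1),
                "alignment_length": alens,
                "query_length": qlens,
                "subject_length": slens,
            }
        )

    a_ids = [a for a, _ in pairs]
    b_ids = [b for _, b in pairs]
    ab = rows(a_ids, b_ids, true_scores, qlen, slen, alen)
    ba = rows(b_ids, a_ids, true_scores + rng.uniform(-10, 10, size=n), slen, qlen, alen)

    n_decoys = int(math.floor(config.decoy_hit_fraction * n)) if n >= 2 else 0
    decoy_ab, decoy_ba = [], []
    for d in range(n_decoys):
        i = int(rng.integers(n))
        j = int(rng.integers(n))
        if j == i:
            j = (i + 1) % n
        ceiling = min(true_scores[i], true_scores[j]) - 1.0
        score = 99.0 if d == 0 else float(np.round(rng.uniform(60.0, ceiling), 1))
        target = decoy_ab if rng.random() < 0.5 else decoy_ba
        if target is decoy_ab:
            target.append((a_ids[i], b_ids[j], score, int(alen[i] * 0.5), int(qlen[i]), int(slen[j])))
        else:
            target.append((b_ids[i], a_ids[j], score, int(alen[i] * 0.5), int(slen[i]), int(qlen[j])))
    cols = ["query_id", "subject_id", "bit_score", "alignment_length", "query_length", "subject_length"]
    if decoy_ab:
        ab = pd.concat([ab, pd.DataFrame(decoy_ab, columns=cols)], ignore_index=True)
    if decoy_ba:
        ba = pd.concat([ba, pd.DataFrame(decoy_ba, columns=cols)], ignore_index=True)
    return ab.reset_index(drop=True), ba.reset_index(drop=True)


@dataclass
class SyntheticDataset:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimulationConfig
    counts: dict[str, CountMatrix]
    pathways: PathwayCollection
    hits_ab: pd.DataFrame
    hits_ba: pd.DataFrame
    truth: SyntheticTruth

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticDataset):
            return NotImplemented
        return (
            self.config == other.config
            and all(self.counts[sp] == other.counts[sp] for sp in SPECIES)
            and self.pathways == other.pathways
            and _hits_equal(self.hits_ab, other.hits_ab)
            and _hits_equal(self.hits_ba, other.hits_ba)
            and self.truth.to_dict() == other.truth.to_dict()
        )


def _hits_equal(x: pd.DataFrame, y: pd.DataFrame) -> bool:
    cols = ["query_id", "subject_id", "bit_score", "alignment_length", "query_length", "subject_length"]
    xs = x[cols].sort_values(cols).reset_index(drop=True)
    ys = y[cols].sort_values(cols).reset_index(drop=True)
    return xs.equals(ys)


def _resync_counts(
    cm: CountMatrix,
    old_labels: dict[str, str],
    new_labels: dict[str, str],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> CountMatrix:
    """Re-draw counts of genes whose DE label changed during planting.

    Keeps the count matrix consistent with the (updated) truth labels:
    changed genes get a fresh baseline mean and negative-binomial draws
    under their new label, so planted neighborhoods are enriched in the
    expression data as well as in the truth record.
    """
    changed = sorted(g for g in new_labels if new_labels[g] != old_labels.get(g, "none"))
    if not changed:
        return cm
    counts = cm.counts.copy()
    n_rep = config.n_samples_per_condition
    ctrl_cols = [s for s in counts.columns if cm.conditions[s] == "control"]
    trt_cols = [s for s in counts.columns if cm.conditions[s] == "treated"]
    mu = rng.lognormal(config.nb_mean_log_mu, config.nb_mean_log_sigma, len(changed))
    fold = np.ones(len(changed))
    for i, gene in enumerate(changed):
        label = new_labels[gene]
        if label == "up":
            fold[i] = 2.0**config.de_lfc_magnitude
        elif label == "down":
            fold[i] = 2.0**-config.de_lfc_magnitude
    counts.loc[changed, ctrl_cols] = _nb_counts(rng, mu, config.nb_dispersion, n_rep)
    counts.loc[changed, trt_cols] = _nb_counts(rng, mu * fold, config.nb_dispersion, n_rep)
    return CountMatrix(counts, dict(cm.conditions))


def simulate_dataset(config: SimulationConfig | None = None) -> SyntheticDataset:
    """Run all generators in their fixed order and bundle the result.

    After pathway construction plants the enriched neighborhood (which
    rewrites some truth labels), the species-A counts of re-labeled genes
    are re-drawn so truth and expression agree.
    """
    config = config or SimulationConfig()
    counts, truth = simulate_expression(config)
    universe = list(counts["species_a"].gene_ids)
    old_labels = dict(truth.de_labels["species_a"])
    pathways = simulate_pathway_collection(config, universe, truth)
    resync_rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 3)))
    counts["species_a"] = _resync_counts(
        counts["species_a"], old_labels, truth.de_labels["species_a"], config, resync_rng
    )
    hits_ab, hits_ba = simulate_hit_table(truth, config)
    return SyntheticDataset(
        config=config,
        counts=counts,
        pathways=pathways,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        truth=truth,
    )


def write_dataset(dataset: SyntheticDataset, directory: str | os.PathLike) -> None:
    """Write the dataset in the pipeline's input formats (all plain text)."""
    os.makedirs(directory, exist_ok=True)
    d = str(directory)
    try:
        for species in SPECIES:
            cm = dataset.counts[species]
            ncio.write_counts_tsv(cm.counts, os.path.join(d, f"counts_{species}.tsv"))
            ncio.write_condition_map(
                cm.conditions, os.path.join(d, f"conditions_{species}.tsv")
            )
        dataset.pathways.write(
            os.path.join(d, "pathways.gmt"), os.path.join(d, "pathways.sif")
        )
        ncio.write_hits(dataset.hits_ab, os.path.join(d, "hits_ab.tsv"))
        ncio.write_hits(dataset.hits_ba, os.path.join(d, "hits_ba.tsv"))
        ncio.write_key_value(dataset.truth.to_dict(), os.path.join(d, "truth.yaml"))
        ncio.write_key_value(dataset.config.to_dict(), os.path.join(d, "config.yaml"))
    except OSError as exc:
        raise OSError(f"failed writing dataset under {d}: {exc}") from exc


def read_dataset(directory: str | os.PathLike) -> SyntheticDataset:
    d = str(directory)
    counts = {}
    for species in SPECIES:
        df = ncio.read_counts_tsv(os.path.join(d, f"counts_{species}.tsv"))
        conditions = ncio.read_condition_map(os.path.join(d, f"conditions_{species}.tsv"))
        counts[species] = CountMatrix(df, conditions)
    pathways = PathwayCollection.read(
        os.path.join(d, "pathways.gmt"), os.path.join(d, "pathways.sif")
    )
    hits_ab = ncio.read_hits(os.path.join(d, "hits_ab.tsv"))
    hits_ba = ncio.read_hits(os.path.join(d, "hits_ba.tsv"))
    truth = SyntheticTruth.from_dict(ncio.read_key_value(os.path.join(d, "truth.yaml")))
    config = SimulationConfig.from_dict(ncio.read_key_value(os.path.join(d, "config.yaml")))
    return SyntheticDataset(
        config=config,
        counts=counts,
        pathways=pathways,
        hits_ab=hits_ab,
        hits_ba=hits_ba,
        truth=truth,
    )
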