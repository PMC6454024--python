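"""Pipeline orchestration and report generation.

Runs the full analysis from a config file — per-species DE calling,
reciprocal-best-hit homology, merged pathway networks, the neighborhood
permutation test — and writes the report bundle: partitioned hub
report, network overlap summary, a fold-change heatmap matrix, an
optional annotation-term profile contrast, and a manifest. The bundle is
a pure function of (inputs, config, rng seed): no timestamps are written,
so two runs produce byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from netcontrast import __version__
from netcontrast import io as ncio
from netcontrast.expression import CountMatrix, call_de, de_genes, expression_table
from netcontrast.homology import best_reciprocal_hits, compare_de_sets, filter_hits
from netcontrast.neighborhood import neighborhood_de_test
from netcontrast.pathnet import (
    MergedNetwork,
    PathwayCollection,
    annotate_topology,
    merge_network,
    network_overlap,
    select_pathways,
    set_de_status,
)

logger = logging.getLogger("netcontrast")


@dataclass
class PipelineConfig:
    """Paths and thresholds driving a full pipeline run."""

    counts_a: str = ""
    conditions_a: str = ""
    counts_b: str = ""
    conditions_b: str = ""
    pathways_gmt: str = ""
    pathways_sif: str = ""
    hits_ab: str = ""
    hits_ba: str = ""
    annotations: str | None = None
    exclude_genes: list[str] = field(default_factory=list)
    min_total: int = 50
    lfc_threshold: float = 1.0
    min_bitscore: float = 100.0
    hub_threshold: int = 20
    radius: int = 2
    n_perm: int = 1000
    seeds: list[str] = field(default_factory=list)
    rng_seed: int = 0
    output_dir: str = "results"

    REQUIRED = (
        "counts_a",
        "conditions_a",
        "counts_b",
        "conditions_b",
        "pathways_gmt",
        "pathways_sif",
        "hits_ab",
        "hits_ba",
    )

    def validate(self) -> None:
        for name in self.REQUIRED:
            path = getattr(self, name)
            if not path:
                raise ValueError(f"pipeline config missing required path field {name!r}")
            if not os.path.exists(path):
                raise FileNotFoundError(f"config field {name!r}: no such file {path!r}")
        for name in ("min_total", "lfc_threshold", "min_bitscore", "hub_threshold", "radius", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name!r} must be positive")

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        data = ncio.read_key_value(path) or {}
        return cls(**data)

    def config_hash(self) -> str:
        # identifies the analysis, not its destination
        payload = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        canon = json.dumps(payload, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]

    @classmethod
    def for_dataset_dir(cls, directory: str, **overrides) -> "PipelineConfig":
        d = str(directory)
        fields = dict(
            counts_a=os.path.join(d, "counts_species_a.tsv"),
            conditions_a=os.path.join(d, "conditions_species_a.tsv"),
            counts_b=os.path.join(d, "counts_species_b.tsv"),
            conditions_b=os.path.join(d, "conditions_species_b.tsv"),
            pathways_gmt=os.path.join(d, "pathways.gmt"),
            pathways_sif=os.path.join(d, "pathways.sif"),
            hits_ab=os.path.join(d, "hits_ab.tsv"),
            hits_ba=os.path.join(d, "hits_ba.tsv"),
        )
        fields.update(overrides)
        return cls(**fields)


# ---------------------------------------------------------------------------
# hub report


def partition_de_hubs(hub_table: pd.DataFrame, lfc_threshold: float = 1.0) -> pd.DataFrame:
    """Partition hub genes by which species calls them DE.

    ``hub_table`` is indexed by gene with columns log2fc_a and log2fc_b
    (hub status is presumed). Adds de_a / de_b (up/down/none by the
    inclusive threshold rule), a ``partition`` column with values
    a_specific / both / b_specific / neither, and for shared hubs a
    ``direction`` column (concordant / opposite).
    """
    de_a = call_de(hub_table["log2fc_a"], threshold=lfc_threshold)
    de_b = call_de(hub_table["log2fc_b"], threshold=lfc_threshold)
    partition = []
    direction = []
    for sa, sb in zip(de_a, de_b):
        if sa != "none" and sb != "none":
            partition.append("both")
            direction.append("concordant" if sa == sb else "opposite")
        elif sa != "none":
            partition.append("a_specific")
            direction.append("")
        elif sb != "none":
            partition.append("b_specific")
            direction.append("")
        else:
            partition.append("neither")
            direction.append("")
    out = hub_table.copy()
    out["de_a"] = de_a.to_numpy()
    out["de_b"] = de_b.to_numpy()
    out["partition"] = partition
    out["direction"] = direction
    return out


def hub_report(
    net_a: MergedNetwork,
    net_b: MergedNetwork,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    homolog_map: pd.DataFrame,
    lfc_threshold: float = 1.0,
) -> pd.DataFrame:
    """Hub summary: hubs DE in at least one species, in the published table's layout.

    Genes are reported in species-A namespace (B-only hubs are translated
    through the homolog map). Rows are partitioned a_specific / both /
    b_specific and sorted by degree descending within each partition.
    Degree and neighborhood connectivity come from the species-A network
    when the gene is present there, otherwise from B.
    """
    a_to_b = dict(zip(homolog_map["gene_a"], homolog_map["gene_b"]))
    b_to_a = {b: a for a, b in a_to_b.items()}
    hubs_a = net_a.hubs()
    hubs_b = net_b.hubs()
    candidates = set(hubs_a) | {b_to_a[h] for h in hubs_b if h in b_to_a}
    rows = []
    for gene_a in sorted(candidates):
        gene_b = a_to_b.get(gene_a)
        lfc_a = float(table_a.loc[gene_a, "log2fc"]) if gene_a in table_a.index else np.nan
        lfc_b = (
            float(table_b.loc[gene_b, "log2fc"])
            if gene_b is not None and gene_b in table_b.index
            else np.nan
        )
        if gene_a in net_a.graph:
            deg = net_a.graph.nodes[gene_a].get("degree", net_a.graph.degree(gene_a))
            conn = net_a.graph.nodes[gene_a].get("neighborhood_connectivity", np.nan)
        elif gene_b is not None and gene_b in net_b.graph:
            deg = net_b.graph.nodes[gene_b].get("degree", net_b.graph.degree(gene_b))
            conn = net_b.graph.nodes[gene_b].get("neighborhood_connectivity", np.nan)
        else:
            deg, conn = 0, np.nan
        rows.append(
            {
                "gene": gene_a,
                "log2fc_a": lfc_a,
                "log2fc_b": lfc_b,
                "degree": deg,
                "neighborhood_connectivity": conn,
            }
        )
    columns = ["log2fc_a", "log2fc_b", "degree", "neighborhood_connectivity"]
    if not rows:
        empty = pd.DataFrame(
            columns=columns + ["de_a", "de_b", "partition", "direction"]
        ).rename_axis("gene")
        return empty
    table = pd.DataFrame(rows).set_index("gene")
    table = table.fillna({"log2fc_a": 0.0, "log2fc_b": 0.0})
    table = partition_de_hubs(table, lfc_threshold=lfc_threshold)
    table = table[table["partition"] != "neither"]
    order = {"a_specific": 0, "both": 1, "b_specific": 2}
    table = table.assign(_ord=table["partition"].map(order)).sort_values(
        ["_ord", "degree"], ascending=[True, False], kind="mergesort"
    )
    return table.drop(columns="_ord")


# ---------------------------------------------------------------------------
# term profiles


@dataclass
class TermProfile:
    """Per-term counts of annotated genes in a gene list."""

    counts: dict[str, int]
    list_size: int
    n_unannotated: int = 0


def build_term_profile(annotations: pd.DataFrame, gene_list) -> TermProfile:
    """Tally annotation terms over a gene list.

    ``annotations`` has columns gene_id and term; a gene may carry several
    terms. Genes with no annotation are ignored (their number is logged
    and recorded).
    """
    genes = set(gene_list)
    sub = annotations[annotations["gene_id"].isin(genes)]
    counts = sub.groupby("term")["gene_id"].nunique().to_dict()
    annotated = set(sub["gene_id"])
    n_unannotated = len(genes - annotated)
    if n_unannotated:
        logger.info("term profile: %d genes had no annotation", n_unannotated)
    return TermProfile(counts=counts, list_size=len(genes), n_unannotated=n_unannotated)


@dataclass
class ProfileComparison:
    per_term: pd.DataFrame
    global_chi2_p: float


def compare_profiles(profile_a: TermProfile, profile_b: TermProfile) -> ProfileComparison:
    """Contrast two term profiles term by term and globally.

    Per term: a 2x2 table (genes in list carrying the term vs not, list A
    vs list B) is tested with Fisher's exact test; p-values are BH-adjusted
    across terms. The log-ratio column is log2 of the term's relative
    frequency in A over B (0.5 continuity), positive = A-leaning. The
    global statistic is a chi-square homogeneity test over the two term
    count vectors, pooling terms with expected count < 1.
    """
    terms = sorted(set(profile_a.counts) | set(profile_b.counts))
    if not terms or (sum(profile_a.counts.values()) == 0 and sum(profile_b.counts.values()) == 0):
        raise ValueError("cannot compare all-zero term profiles")
    n_a, n_b = profile_a.list_size, profile_b.list_size
    rows = []
    for term in terms:
        c_a = profile_a.counts.get(term, 0)
        c_b = profile_b.counts.get(term, 0)
        table = np.array([[c_a, max(n_a - c_a, 0)], [c_b, max(n_b - c_b, 0)]])
        odds, p = stats.fisher_exact(table)
        log_ratio = float(
            np.log2(((c_a + 0.5) / (n_a + 1.0)) / ((c_b + 0.5) / (n_b + 1.0)))
        )
        rows.append(
            {"term": term, "count_a": c_a, "count_b": c_b, "odds_ratio": odds,
             "p": p, "log_ratio": log_ratio}
        )
    per_term = pd.DataFrame(rows).set_index("term")
    per_term["q"] = multipletests(per_term["p"], method="fdr_bh")[1]

    # global homogeneity over the count vectors, pooling small expectations
    counts = per_term[["count_a", "count_b"]].to_numpy(dtype=float)
    totals = counts.sum(axis=0)
    if (totals == 0).any():
        global_p = 1.0 if np.allclose(counts[:, 0], counts[:, 1]) else 0.0
    else:
        grand = counts.sum()
        expected = np.outer(counts.sum(axis=1), totals) / grand
        keep = expected.min(axis=1) >= 1.0
        pooled = counts[keep]
        small = counts[~keep].sum(axis=0)
        if (~keep).any() and small.sum() > 0:
            pooled = np.vstack([pooled, small])
        if pooled.shape[0] < 2 or np.allclose(pooled[:, 0] / totals[0], pooled[:, 1] / totals[1]):
            global_p = 1.0
        else:
            _, global_p, _, _ = stats.chi2_contingency(pooled)
    return ProfileComparison(per_term=per_term, global_chi2_p=float(global_p))


# ---------------------------------------------------------------------------
# heatmap matrix


def heatmap_matrix(
    comparison_pairs: pd.DataFrame, table_a: pd.DataFrame, table_b: pd.DataFrame
) -> pd.DataFrame:
    """lfc matrix for shared DE genes, rows clustered by sign pattern."""
    rows = []
    for a, b in zip(comparison_pairs["gene_a"], comparison_pairs["gene_b"]):
        rows.append(
            {
                "gene": a,
                "log2fc_a": float(table_a.loc[a, "log2fc"]),
                "log2fc_b": float(table_b.loc[b, "log2fc"]),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["log2fc_a", "log2fc_b"]).rename_axis("gene")
    df = pd.DataFrame(rows).set_index("gene")
    sign_pattern = (df["log2fc_a"] >= 0).astype(int) * 2 + (df["log2fc_b"] >= 0).astype(int)
    return df.assign(_p=sign_pattern).sort_values(["_p", "log2fc_a"]).drop(columns="_p")


# ---------------------------------------------------------------------------
# full pipeline


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute expression -> homology -> networks -> neighborhood -> reports.

    Writes every artifact under ``config.output_dir`` together with a
    manifest (package version, seed, config hash, input sizes). Returns the
    in-memory bundle. Deterministic for a fixed rng_seed.
    """
    config.validate()
    out = config.output_dir
    os.makedirs(out, exist_ok=True)
    bundle: dict = {}

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    # expression, per species
    tables = {}
    for label, counts_path, cond_path in (
        ("a", config.counts_a, config.conditions_a),
        ("b", config.counts_b, config.conditions_b),
    ):
        counts = stage(f"read_counts_{label}", ncio.read_counts_tsv, counts_path)
        conditions = stage(f"read_conditions_{label}", ncio.read_condition_map, cond_path)
        cm = CountMatrix(counts, conditions)
        logger.info("species %s: %d genes x %d samples", label, *cm.counts.shape)
        tables[label] = stage(
            f"expression_{label}",
            expression_table,
            cm,
            min_total=config.min_total,
            lfc_threshold=config.lfc_threshold,
        )
        tables[label].to_csv(os.path.join(out, f"expression_{label}.tsv"), sep="\t")
        logger.info(
            "species %s: %d genes pass the count filter, %d DE",
            label,
            len(tables[label]),
            len(de_genes(tables[label])),
        )

    # homology
    hits_ab = stage("read_hits_ab", ncio.read_hits, config.hits_ab)
    hits_ba = stage("read_hits_ba", ncio.read_hits, config.hits_ba)
    hits_ab = filter_hits(hits_ab, min_bitscore=config.min_bitscore)
    hits_ba = filter_hits(hits_ba, min_bitscore=config.min_bitscore)
    homolog_map = stage("brbh", best_reciprocal_hits, hits_ab, hits_ba)
    homolog_map.to_csv(os.path.join(out, "homolog_map.tsv"), sep="\t", index=False)
    logger.info("homology: %d reciprocal best-hit pairs", len(homolog_map))
    mapped_a = homolog_map[
        homolog_map["gene_a"].isin(tables["a"].index)
        & homolog_map["gene_b"].isin(tables["b"].index)
    ]
    comparison = stage("compare_de", compare_de_sets, mapped_a, tables["a"], tables["b"])
    ncio.write_key_value(comparison.counts(), os.path.join(out, "de_comparison.yaml"))

    # pathway networks, per species (pathways live in species-A namespace)
    collection = stage(
        "read_pathways", PathwayCollection.read, config.pathways_gmt, config.pathways_sif
    )
    b_to_a = dict(zip(homolog_map["gene_b"], homolog_map["gene_a"]))
    de_sets = {
        "a": de_genes(tables["a"]),
        "b": {b_to_a[g] for g in de_genes(tables["b"]) if g in b_to_a},
    }
    status_maps = {
        "a": tables["a"]["de_status"].to_dict(),
        "b": {
            b_to_a[g]: s
            for g, s in tables["b"]["de_status"].items()
            if g in b_to_a
        },
    }
    nets = {}
    selections = {}
    for label in ("a", "b"):
        selected = stage(f"select_pathways_{label}", select_pathways, collection, de_sets[label])
        selections[label] = selected
        net = merge_network(selected)
        set_de_status(net, status_maps[label])
        annotate_topology(net, hub_threshold=config.hub_threshold)
        if config.exclude_genes:
            from netcontrast.pathnet import exclude_gene_module

            net = stage(f"exclude_module_{label}", exclude_gene_module, net, config.exclude_genes)
            set_de_status(net, status_maps[label])
        nets[label] = net
        ncio.write_sif(
            net.graph.edges(),
            os.path.join(out, f"network_{label}.sif"),
            singletons=net.singletons,
        )
        net.node_table().to_csv(os.path.join(out, f"nodes_{label}.tsv"), sep="\t")
        ncio.write_key_value(net.summary(), os.path.join(out, f"topology_{label}.yaml"))
        logger.info("network %s: %s", label, net.summary())

    overlap = network_overlap(
        nets["a"], nets["b"], homolog_map=None,
        pathways_a=selections["a"], pathways_b=selections["b"],
    )
    ncio.write_key_value(
        {
            "shared_nodes": overlap.shared_nodes,
            "pct_a": overlap.pct_a,
            "pct_b": overlap.pct_b,
            "shared_pathways": overlap.shared_pathways,
        },
        os.path.join(out, "overlap.yaml"),
    )

    # neighborhood test (species-A network)
    neigh = None
    if config.seeds:
        present = [s for s in config.seeds if s in nets["a"].graph]
        missing = sorted(set(config.seeds) - set(present))
        if missing:
            raise PipelineError(f"stage 'neighborhood' failed: seeds absent from network: {missing}")
        neigh = stage(
            "neighborhood",
            neighborhood_de_test,
            nets["a"],
            config.seeds,
            radius=config.radius,
            n_perm=config.n_perm,
            rng_seed=config.rng_seed,
        )
        ncio.write_key_value(neigh.to_dict(), os.path.join(out, "neighborhood.yaml"))
        logger.info(
            "neighborhood test: z=%s p_normal=%s", neigh.z, neigh.p_normal
        )

    # reports
    hubs = hub_report(
        nets["a"], nets["b"], tables["a"], tables["b"], homolog_map,
        lfc_threshold=config.lfc_threshold,
    )
    hubs.to_csv(os.path.join(out, "hub_report.tsv"), sep="\t")
    shared_pairs = pd.DataFrame(
        sorted(comparison.shared_de), columns=["gene_a", "gene_b"]
    )
    heatmap_matrix(shared_pairs, tables["a"], tables["b"]).to_csv(
        os.path.join(out, "heatmap_lfc.tsv"), sep="\t"
    )

    profiles = None
    if config.annotations:
        annotations = pd.read_csv(config.annotations, sep="\t", dtype=str)
        prof_a = build_term_profile(annotations, de_sets["a"])
        prof_b = build_term_profile(annotations, de_genes(tables["b"]))
        profiles = compare_profiles(prof_a, prof_b)
        profiles.per_term.to_csv(os.path.join(out, "term_contrast.tsv"), sep="\t")
        ncio.write_key_value(
            {"global_chi2_p": profiles.global_chi2_p},
            os.path.join(out, "term_contrast_global.yaml"),
        )

    manifest = {
        "netcontrast_version": __version__,
        "rng_seed": config.rng_seed,
        "config_hash": config.config_hash(),
        "n_genes_a": int(len(tables["a"])),
        "n_genes_b": int(len(tables["b"])),
        "n_homolog_pairs": int(len(homolog_map)),
        "n_pathways_selected_a": len(selections["a"].members),
        "n_pathways_selected_b": len(selections["b"].members),
    }
    with open(os.path.join(out, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    bundle.update(
        tables=tables,
        homolog_map=homolog_map,
        comparison=comparison,
        networks=nets,
        overlap=overlap,
        neighborhood=neigh,
        hub_report=hubs,
        profiles=profiles,
        manifest=manifest,
    )
    return bundle
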