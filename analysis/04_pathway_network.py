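"""Merge DE-containing pathways into per-species networks and profile topology.

Writes network SIF/attribute files, degree ECDF tables and the
cross-species node overlap under results/network/.
"""

import argparse
import os

import pandas as pd

from netcontrast import io as ncio
from netcontrast.pathnet import (
    annotate_topology,
    degree_ecdf,
    merge_network,
    network_overlap,
    select_pathways,
    set_de_status,
)
from netcontrast.syndata import read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--expression", default="results/expression")
    parser.add_argument("--out", default="results/network")
    args = parser.parse_args()

    dataset = read_dataset(args.data)
    os.makedirs(args.out, exist_ok=True)
    homolog_a = dict(dataset.truth.true_homolog_pairs)
    b_to_a = {b: a for a, b in homolog_a.items()}

    nets, selections = {}, {}
    for species in ("species_a", "species_b"):
        table = pd.read_csv(
            os.path.join(args.expression, f"expression_{species}.tsv"),
            sep="\t",
            index_col=0,
        )
        status = table["de_status"].to_dict()
        if species == "species_b":  # pathways are in species-A namespace
            status = {b_to_a[g]: s for g, s in status.items() if g in b_to_a}
        de = {g for g, s in status.items() if s != "none"}
        selected = select_pathways(dataset.pathways, de)
        net = merge_network(selected)
        set_de_status(net, status)
        annotate_topology(net)
        nets[species], selections[species] = net, selected
        ncio.write_sif(
            net.graph.edges(),
            os.path.join(args.out, f"network_{species}.sif"),
            singletons=net.singletons,
        )
        net.node_table().to_csv(os.path.join(args.out, f"nodes_{species}.tsv"), sep="\t")
        summary = net.summary()
        print(f"{species}: {summary['n_nodes']} nodes, {summary['n_edges']} edges, "
              f"{summary['n_singletons']} singletons, {summary['n_hubs']} hubs "
              f"({len(selected.members)} pathways selected)")
        for group in ("DE", "non-DE"):
            try:
                curve = degree_ecdf(net, group)
            except ValueError:
                continue
            pd.DataFrame({"degree": curve.values, "cum_fraction": curve.fractions}).to_csv(
                os.path.join(args.out, f"ecdf_{species}_{group}.tsv"), sep="\t", index=False
            )

    overlap = network_overlap(
        nets["species_a"], nets["species_b"],
        pathways_a=selections["species_a"], pathways_b=selections["species_b"],
    )
    ncio.write_key_value(
        {
            "shared_nodes": overlap.shared_nodes,
            "pct_a": overlap.pct_a,
            "pct_b": overlap.pct_b,
            "shared_pathways": overlap.shared_pathways,
        },
        os.path.join(args.out, "overlap.yaml"),
    )
    print(
        f"overlap: {overlap.shared_nodes} shared nodes "
        f"({overlap.pct_a}% of A, {overlap.pct_b}% of B); "
        f"{overlap.shared_pathways} shared pathways"
    )


if __name__ == "__main__":
    main()
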