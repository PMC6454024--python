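"""Map genes across species by reciprocal best hits and compare DE calls.

Reads the hit tables and expression tables, writes the homolog map and
the cross-species DE comparison under results/homology/.
"""

import argparse
import os

import pandas as pd

from netcontrast import io as ncio
from netcontrast.homology import best_reciprocal_hits, compare_de_sets, filter_hits
from netcontrast.syndata import read_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", default="results/data")
    parser.add_argument("--expression", default="results/expression")
    parser.add_argument("--out", default="results/homology")
    args = parser.parse_args()

    dataset = read_dataset(args.data)
    os.makedirs(args.out, exist_ok=True)

    ab = filter_hits(dataset.hits_ab)
    ba = filter_hits(dataset.hits_ba)
    print(
        f"bit-score filter kept {len(ab)}/{len(dataset.hits_ab)} forward and "
        f"{len(ba)}/{len(dataset.hits_ba)} reverse hits"
    )
    pairs = best_reciprocal_hits(ab, ba)
    pairs.to_csv(os.path.join(args.out, "homolog_map.tsv"), sep="\t", index=False)
    truth = set(dataset.truth.true_homolog_pairs)
    found = set(zip(pairs["gene_a"], pairs["gene_b"]))
    print(
        f"reciprocal best hits: {len(pairs)} one-to-one pairs "
        f"({len(found & truth)} of {len(truth)} true pairs, "
        f"{len(found - truth)} spurious)"
    )

    table_a = pd.read_csv(
        os.path.join(args.expression, "expression_species_a.tsv"), sep="\t", index_col=0
    )
    table_b = pd.read_csv(
        os.path.join(args.expression, "expression_species_b.tsv"), sep="\t", index_col=0
    )
    covered = pairs[
        pairs["gene_a"].isin(table_a.index) & pairs["gene_b"].isin(table_b.index)
    ]
    cmp = compare_de_sets(covered, table_a, table_b)
    ncio.write_key_value(cmp.counts(), os.path.join(args.out, "de_comparison.yaml"))
    counts = cmp.counts()
    print(
        f"shared DE pairs: {counts['shared_de']} "
        f"({counts['concordant_up']} up/up, {counts['concordant_down']} down/down, "
        f"{counts['opposite']} opposite); species-specific DE: "
        f"{counts['a_specific']} (A), {counts['b_specific']} (B)"
    )


if __name__ == "__main__":
    main()
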