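"""Generate the synthetic two-species dataset used by the downstream steps.

Writes count matrices, pathway files, similarity hit tables and the
planted truth record under results/data/.
"""

import argparse

from netcontrast.syndata import SimulationConfig, simulate_dataset, write_dataset


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--out", default="results/data")
    args = parser.parse_args()

    config = SimulationConfig(rng_seed=args.seed)
    dataset = simulate_dataset(config)
    write_dataset(dataset, args.out)

    truth = dataset.truth
    print(f"dataset written to {args.out}")
    print(f"genes per species: {config.n_genes}, pathways: {config.n_pathways}")
    print(
        f"planted DE genes: {len(truth.de_genes('species_a'))} (A), "
        f"{len(truth.de_genes('species_b'))} (B)"
    )
    print(f"seed hubs: {', '.join(truth.seed_genes)}; "
          f"planted neighborhood: {len(truth.planted_neighborhood)} nodes")


if __name__ == "__main__":
    main()
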