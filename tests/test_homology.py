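"""Reciprocal-best-hit mapping and cross-species DE classification."""

import itertools

import numpy as np
import pandas as pd
import pytest

from netcontrast.homology import (
    best_reciprocal_hits,
    collapse_duplicates,
    compare_de_sets,
    filter_hits,
)
from netcontrast.syndata import SimulationConfig, simulate_dataset

from conftest import hits_frame


def brute_force_brbh(hits_ab, hits_ba):
    """Independent oracle: enumerate queries, pick max-score subject, check both ways."""
    def best(hits, query):
        sub = hits[hits["query_id"] == query]
        if sub.empty:
            return None
        top = sub["bit_score"].max()
        tied = sub[sub["bit_score"] == top]
        tied = tied.sort_values(["subject_length", "subject_id"], ascending=[False, True])
        return tied.iloc[0]["subject_id"]

    pairs = set()
    for a in hits_ab["query_id"].unique():
        b = best(hits_ab, a)
        if b is not None and best(hits_ba, b) == a:
            pairs.add((a, b))
    return pairs


class TestFilterHits:
    def test_strict_bitscore_boundary(self):
        hits = hits_frame([("a", "b", 99.0, 100), ("a", "c", 100.0, 100)])
        kept = filter_hits(hits)
        assert list(kept["subject_id"]) == ["c"]

    def test_matches_brute_force_on_fixture(self):
        scores = [40.0, 99.9, 100.0, 150.0, 250.0, 12.0]
        hits = hits_frame([("a", f"b{i}", s, 100) for i, s in enumerate(scores)])
        kept = filter_hits(hits, min_bitscore=100)
        assert set(kept["bit_score"]) == {s for s in scores if s >= 100}


class TestBestReciprocalHits:
    def test_single_mutual_pair(self):
        ab = hits_frame([("a1", "b1", 200, 100)])
        ba = hits_frame([("b1", "a1", 190, 100)])
        pairs = best_reciprocal_hits(ab, ba)
        assert list(zip(pairs["gene_a"], pairs["gene_b"])) == [("a1", "b1")]

    def test_non_reciprocal_query_unmapped(self):
        # a1's best is b1 but b1's best is a2: a1 stays unmapped
        ab = hits_frame([("a1", "b1", 300, 100), ("a2", "b1", 250, 100)])
        ba = hits_frame([("b1", "a2", 400, 100), ("b1", "a1", 100, 100)])
        pairs = best_reciprocal_hits(ab, ba)
        got = set(zip(pairs["gene_a"], pairs["gene_b"]))
        assert got == brute_force_brbh(ab, ba) == {("a2", "b1")}

    def test_score_tie_longest_query_wins(self):
        # a1 (len 1200) and a2 (len 800) tie for b1; the longer sequence is kept
        ab = hits_frame([("a1", "b1", 200, 100, 1200), ("a2", "b1", 200, 100, 800)])
        ba = hits_frame(
            [("b1", "a1", 200, 100, 500, 1200), ("b1", "a2", 200, 100, 500, 800)]
        )
        pairs = best_reciprocal_hits(ab, ba)
        assert list(zip(pairs["gene_a"], pairs["gene_b"])) == [("a1", "b1")]

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            rows_ab, rows_ba = [], []
            for a, b in itertools.product(range(4), range(4)):
                if rng.random() < 0.5:
                    rows_ab.append((f"a{a}", f"b{b}", float(rng.integers(100, 400)), 100))
                if rng.random() < 0.5:
                    rows_ba.append((f"b{b}", f"a{a}", float(rng.integers(100, 400)), 100))
            if not rows_ab or not rows_ba:
                continue
            ab, ba = hits_frame(rows_ab), hits_frame(rows_ba)
            pairs = best_reciprocal_hits(ab, ba)
            assert set(zip(pairs["gene_a"], pairs["gene_b"])) == brute_force_brbh(ab, ba)

    def test_symmetry_and_bijectivity(self):
        rng = np.random.default_rng(11)
        rows_ab = [
            (f"a{i}", f"b{j}", float(rng.integers(100, 400)), 100)
            for i, j in itertools.product(range(5), range(5))
            if rng.random() < 0.6
        ]
        rows_ba = [
            (f"b{j}", f"a{i}", float(rng.integers(100, 400)), 100)
            for i, j in itertools.product(range(5), range(5))
            if rng.random() < 0.6
        ]
        ab, ba = hits_frame(rows_ab), hits_frame(rows_ba)
        fwd = best_reciprocal_hits(ab, ba)
        rev = best_reciprocal_hits(ba, ab)
        assert set(zip(fwd["gene_a"], fwd["gene_b"])) == set(
            zip(rev["gene_b"], rev["gene_a"])
        )
        assert fwd["gene_a"].is_unique and fwd["gene_b"].is_unique


class TestCollapseDuplicates:
    def test_higher_score_kept(self):
        rows = hits_frame([("q1", "s", 250, 100), ("q2", "s", 200, 100)])
        kept = collapse_duplicates(rows)
        assert list(kept["query_id"]) == ["q1"]

    def test_equal_scores_longer_query_kept(self):
        rows = hits_frame([("q1", "s", 200, 100, 1200), ("q2", "s", 200, 100, 800)])
        kept = collapse_duplicates(rows)
        assert list(kept["query_id"]) == ["q1"]

    def test_random_tables_match_brute_force(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            rows = hits_frame(
                [
                    (
                        f"q{rng.integers(6)}",
                        f"s{rng.integers(3)}",
                        float(rng.integers(100, 300)),
                        100,
                        int(rng.integers(200, 2000)),
                    )
                    for _ in range(10)
                ]
            )
            kept = collapse_duplicates(rows)
            for subject, group in rows.groupby("subject_id"):
                ranked = group.sort_values(
                    ["bit_score", "query_length", "query_id"],
                    ascending=[False, False, True],
                )
                winner = ranked.iloc[0]["query_id"]
                assert kept.loc[kept["subject_id"] == subject, "query_id"].iloc[0] == winner


def _table(status: dict, lfc: dict | None = None) -> pd.DataFrame:
    lfc = lfc or {}
    return pd.DataFrame(
        {
            "log2fc": [lfc.get(g, 0.0) for g in status],
            "de_status": list(status.values()),
        },
        index=pd.Index(status.keys(), name="gene_id"),
    )


class TestCompareDESets:
    def test_opposite_regulation_pair(self):
        # a hub-like pair up in one species, down in the other
        pairs = pd.DataFrame({"gene_a": ["fos_a"], "gene_b": ["fos_b"]})
        table_a = _table({"fos_a": "up"}, {"fos_a": 1.39})
        table_b = _table({"fos_b": "down"}, {"fos_b": -2.26})
        cmp = compare_de_sets(pairs, table_a, table_b)
        assert cmp.opposite == {("fos_a", "fos_b")}
        assert cmp.n_concordant == 0

    def test_concordant_counts_add_up(self):
        n_up, n_down = 14, 18
        genes_a = [f"a{i}" for i in range(n_up + n_down)]
        genes_b = [f"b{i}" for i in range(n_up + n_down)]
        pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
        status = ["up"] * n_up + ["down"] * n_down
        cmp = compare_de_sets(
            pairs, _table(dict(zip(genes_a, status))), _table(dict(zip(genes_b, status)))
        )
        assert len(cmp.concordant_up) == 14
        assert len(cmp.concordant_down) == 18
        assert cmp.n_concordant == 32 == cmp.n_shared

    def test_empty_map_all_zero(self):
        pairs = pd.DataFrame(columns=["gene_a", "gene_b"])
        cmp = compare_de_sets(pairs, _table({"a": "up"}), _table({"b": "down"}))
        assert cmp.n_shared == 0
        assert cmp.a_specific == {"a"} and cmp.b_specific == {"b"}

    def test_missing_mapped_gene_raises(self):
        pairs = pd.DataFrame({"gene_a": ["a1"], "gene_b": ["b1"]})
        with pytest.raises(KeyError, match="b1"):
            compare_de_sets(pairs, _table({"a1": "up"}), _table({"other": "up"}))

    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(9)
        genes_a = [f"a{i}" for i in range(30)]
        genes_b = [f"b{i}" for i in range(30)]
        status_a = {g: rng.choice(["up", "down", "none"]) for g in genes_a}
        status_b = {g: rng.choice(["up", "down", "none"]) for g in genes_b}
        pairs = pd.DataFrame({"gene_a": genes_a, "gene_b": genes_b})
        cmp = compare_de_sets(pairs, _table(status_a), _table(status_b))
        expected_shared = {
            (a, b)
            for a, b in zip(genes_a, genes_b)
            if status_a[a] != "none" and status_b[b] != "none"
        }
        assert cmp.shared_de == expected_shared
        assert cmp.shared_de == cmp.concordant_up | cmp.concordant_down | cmp.opposite


class TestAgainstPlantedTruth:
    def test_precision_and_recall_with_decoys(self):
        config = SimulationConfig(n_genes=300, n_pathways=0, seed_genes=(),
                                  decoy_hit_fraction=0.3, rng_seed=21)
        ds = simulate_dataset(config)
        ab = filter_hits(ds.hits_ab)
        ba = filter_hits(ds.hits_ba)
        pairs = best_reciprocal_hits(ab, ba)
        found = set(zip(pairs["gene_a"], pairs["gene_b"]))
        truth = set(ds.truth.true_homolog_pairs)
        assert found <= truth  # precision 1.0
        assert len(found & truth) / len(truth) >= 0.95
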