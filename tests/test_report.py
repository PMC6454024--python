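"""Hub reports, term-profile contrasts and full-pipeline orchestration."""

import filecmp
import os

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.special import comb

from netcontrast.report import (
    PipelineConfig,
    PipelineError,
    TermProfile,
    build_term_profile,
    compare_profiles,
    heatmap_matrix,
    hub_report,
    partition_de_hubs,
    run_pipeline,
)
from netcontrast.syndata import write_dataset

from conftest import make_network

# Published hub table for the axolotl / X. tropicalis contrast (gene,
# lfc species A, lfc species B, degree, neighborhood connectivity).
PUBLISHED_HUB_ROWS = [
    ("AQR", -1.67, 0.9, 92, 85.59),
    ("EGFR", -1.77, 0.26, 92, 24.63),
    ("ERBB2", -1.71, 0.3, 41, 32.24),
    ("PTK2B", -1.33, -0.25, 27, 43.96),
    ("MAP2K1", -1.02, -0.18, 24, 31.58),
    ("ACTG1", 1.42, -1.96, 30, 12.6),
    ("FOS", 1.39, -2.26, 25, 27.08),
    ("LSM2", 0.1, 1.25, 101, 79.47),
    ("FAU", 0.19, -1.59, 72, 67.29),
    ("PSME3", 0.08, 1.58, 35, 34.23),
    ("POLR2H", 0.21, 1.16, 26, 14.08),
    ("IRS2", -0.57, 1.13, 25, 34.04),
    ("MCM5", -0.32, -1.44, 24, 22.67),
]


def published_hub_table() -> pd.DataFrame:
    df = pd.DataFrame(
        PUBLISHED_HUB_ROWS,
        columns=["gene", "log2fc_a", "log2fc_b", "degree", "neighborhood_connectivity"],
    )
    return df.set_index("gene")


class TestHubPartition:
    def test_published_rows_partition_5_2_6(self):
        """DE rule on the 13 published hub rows: 5 A-specific (all down),
        2 shared with opposite signs, 6 B-specific."""
        table = partition_de_hubs(published_hub_table())
        counts = table["partition"].value_counts()
        assert counts["a_specific"] == 5
        assert counts["both"] == 2
        assert counts["b_specific"] == 6
        a_rows = table[table["partition"] == "a_specific"]
        assert (a_rows["de_a"] == "down").all()
        both = table[table["partition"] == "both"]
        assert (both["direction"] == "opposite").all()
        assert set(both.index) == {"ACTG1", "FOS"}

    def test_no_hubs_gives_header_only(self):
        net = make_network([("a", "b")])
        table = pd.DataFrame(
            {"log2fc": [0.1, 0.2], "de_status": ["none", "none"]},
            index=pd.Index(["a", "b"], name="gene_id"),
        )
        hmap = pd.DataFrame({"gene_a": ["a"], "gene_b": ["a"]})
        report = hub_report(net, net, table, table, hmap)
        assert report.empty
        assert "partition" in report.columns

    def test_shared_opposite_hub_lands_in_both_partition(self):
        edges_a = [("actg1_a", f"x{i}") for i in range(30)]
        edges_b = [("actg1_b", f"y{i}") for i in range(30)]
        net_a = make_network(edges_a)
        net_b = make_network(edges_b)
        table_a = pd.DataFrame(
            {"log2fc": [1.42], "de_status": ["up"]},
            index=pd.Index(["actg1_a"], name="gene_id"),
        )
        table_b = pd.DataFrame(
            {"log2fc": [-1.96], "de_status": ["down"]},
            index=pd.Index(["actg1_b"], name="gene_id"),
        )
        hmap = pd.DataFrame({"gene_a": ["actg1_a"], "gene_b": ["actg1_b"]})
        report = hub_report(net_a, net_b, table_a, table_b, hmap)
        assert report.loc["actg1_a", "partition"] == "both"
        assert report.loc["actg1_a", "direction"] == "opposite"
        assert report.loc["actg1_a", "degree"] == 30


class TestTermProfiles:
    def _annotations(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g1", "g2", "g3", "g3"],
                "term": ["t1", "t2", "t3", "t1", "t2", "t4"],
            }
        )

    def test_empty_list_all_zero(self):
        profile = build_term_profile(self._annotations(), [])
        assert profile.counts == {} and profile.list_size == 0

    def test_single_gene_three_terms(self):
        profile = build_term_profile(self._annotations(), ["g1"])
        assert profile.counts == {"t1": 1, "t2": 1, "t3": 1}

    def test_tally_matches_brute_force(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(20)]
        terms = [f"t{i}" for i in range(6)]
        rows = [
            {"gene_id": g, "term": t}
            for g in genes
            for t in terms
            if rng.random() < 0.3
        ]
        annotations = pd.DataFrame(rows)
        chosen = genes[::2]
        profile = build_term_profile(annotations, chosen)
        for term in terms:
            expected = sum(
                1
                for g in chosen
                if any(r["gene_id"] == g and r["term"] == term for r in rows)
            )
            assert profile.counts.get(term, 0) == expected

    def test_identical_profiles_null_contrast(self):
        p = TermProfile(counts={"t1": 5, "t2": 3}, list_size=10)
        cmp = compare_profiles(p, p)
        assert np.allclose(cmp.per_term["odds_ratio"], 1.0)
        assert cmp.global_chi2_p == 1.0

    def test_single_term_exact_test_matches_enumeration(self):
        """Fisher p for [[10,0],[0,10]] equals the hypergeometric enumeration."""
        p_a = TermProfile(counts={"t": 10}, list_size=10)
        p_b = TermProfile(counts={"t": 0}, list_size=10)
        cmp = compare_profiles(p_a, p_b)
        # enumerate: P(table as or more extreme) with margins (10,10)x(10,10)
        total = comb(20, 10)
        p_exact = 2 * comb(10, 10) * comb(10, 0) / total
        assert cmp.per_term.loc["t", "p"] == pytest.approx(p_exact)

    def test_term_only_in_a_has_positive_log_ratio(self):
        p_a = TermProfile(counts={"t": 4}, list_size=10)
        p_b = TermProfile(counts={}, list_size=10)
        cmp = compare_profiles(p_a, p_b)
        assert cmp.per_term.loc["t", "log_ratio"] > 0

    def test_bh_q_monotone_and_bounded(self):
        rng = np.random.default_rng(5)
        p_a = TermProfile(
            counts={f"t{i}": int(rng.integers(0, 8)) for i in range(12)}, list_size=30
        )
        p_b = TermProfile(
            counts={f"t{i}": int(rng.integers(0, 8)) for i in range(12)}, list_size=25
        )
        cmp = compare_profiles(p_a, p_b)
        df = cmp.per_term.sort_values("p")
        assert (df["q"].diff().dropna() >= -1e-12).all()
        assert df["q"].between(0, 1).all()

    def test_global_p_invariant_to_term_order(self):
        counts = {f"t{i}": c for i, c in enumerate([9, 2, 7, 4, 5])}
        shuffled = dict(reversed(list(counts.items())))
        p_a = TermProfile(counts=counts, list_size=20)
        p_b = TermProfile(counts={k: v + 2 for k, v in counts.items()}, list_size=25)
        p_b_shuffled = TermProfile(
            counts={k: v + 2 for k, v in shuffled.items()}, list_size=25
        )
        assert compare_profiles(p_a, p_b).global_chi2_p == pytest.approx(
            compare_profiles(p_a, p_b_shuffled).global_chi2_p
        )

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError):
            compare_profiles(TermProfile({}, 0), TermProfile({}, 0))


class TestPipeline:
    def test_missing_path_aborts_naming_field(self, tmp_path):
        config = PipelineConfig(counts_a=str(tmp_path / "missing.tsv"))
        with pytest.raises((FileNotFoundError, ValueError), match="counts_a|conditions_a"):
            config.validate()

    def test_end_to_end_determinism_and_planted_recovery(
        self, small_config, small_dataset, tmp_path
    ):
        """Two runs on the same inputs produce byte-identical bundles, and the
        planted seed hubs surface in the hub report with a positive z."""
        data_dir = tmp_path / "data"
        write_dataset(small_dataset, data_dir)
        bundles = []
        for run_label in ("out1", "out2"):
            config = PipelineConfig.for_dataset_dir(
                str(data_dir),
                seeds=list(small_config.seed_genes),
                output_dir=str(tmp_path / run_label),
                rng_seed=11,
            )
            bundles.append(run_pipeline(config))
        files = sorted(os.listdir(tmp_path / "out1"))
        match, mismatch, errors = filecmp.cmpfiles(
            tmp_path / "out1", tmp_path / "out2", files, shallow=False
        )
        assert not mismatch and not errors

        bundle = bundles[0]
        assert bundle["neighborhood"].z > 0
        assert bundle["neighborhood"].p_normal < 0.05
        report_genes = set(bundle["hub_report"].index)
        assert set(small_config.seed_genes) <= report_genes

    def test_heatmap_contains_all_shared_pairs(self):
        pairs = pd.DataFrame({"gene_a": ["a1", "a2"], "gene_b": ["b1", "b2"]})
        table_a = pd.DataFrame(
            {"log2fc": [1.5, -2.0]}, index=pd.Index(["a1", "a2"], name="gene_id")
        )
        table_b = pd.DataFrame(
            {"log2fc": [-1.2, -1.8]}, index=pd.Index(["b1", "b2"], name="gene_id")
        )
        matrix = heatmap_matrix(pairs, table_a, table_b)
        assert set(matrix.index) == {"a1", "a2"}
        assert matrix.loc["a1", "log2fc_b"] == pytest.approx(-1.2)
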