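"""Reciprocal-best-hit homology mapping and cross-species DE comparison.

Cross-species gene pairing uses the reciprocal (reverse) best hit rule on
similarity search tables: a pair (a, b) is accepted when b is a's single
highest-scoring subject in the A->B search and a is b's highest-scoring
subject in B->A. Hits below a bit-score floor are discarded first
(strictly: score < 100 removed). Ties are resolved deterministically by
higher score, then longer sequence, then lexicographic id — realizing the
"keep only the longest with the best score" rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

REQUIRED_HIT_COLUMNS = ("query_id", "subject_id", "bit_score", "alignment_length")


def _validate_hits(hits: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_HIT_COLUMNS:
        if col not in hits.columns:
            raise ValueError(f"hit table missing column {col!r}")
    if (hits["bit_score"] < 0).any():
        raise ValueError("negative bit-scores")
    return hits


def filter_hits(hits: pd.DataFrame, min_bitscore: float = 100.0) -> pd.DataFrame:
    """Remove rows with bit_score strictly below ``min_bitscore``.

    A hit scoring exactly the floor is retained ("lower than" is strict).
    """
    _validate_hits(hits)
    return hits.loc[hits["bit_score"] >= min_bitscore].reset_index(drop=True)


def _collapse_hsps(hits: pd.DataFrame) -> pd.DataFrame:
    """Reduce multiple rows per (query, subject) to the max-score row."""
    order = hits.sort_values(
        ["bit_score", "alignment_length"], ascending=[False, False], kind="mergesort"
    )
    return order.drop_duplicates(["query_id", "subject_id"], keep="first")

def _best_per_query(hits: pd.DataFrame) -> pd.Series:
    """Map each query to its single best subject.

    Ranking: highest bit-score, then longest subject (falling back to the
    alignment length when no subject_length column is present), then
    lexicographically smallest subject id.
    """
    tie_len = hits["subject_length"] if "subject_length" in hits else hits["alignment_length"]
    ranked = hits.assign(_tie_len=tie_len).sort_values(
        ["query_id", "bit_score", "_tie_len", "subject_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    best = ranked.drop_duplicates("query_id", keep="first")
    return pd.Series(best["subject_id"].to_numpy(), index=best["query_id"].to_numpy())


def best_reciprocal_hits(hits_ab: pd.DataFrame, hits_ba: pd.DataFrame) -> pd.DataFrame:
    """One-to-one homolog map from mutual best hits.

    Both tables should already be bit-score filtered. Returns a DataFrame
    with columns gene_a, gene_b, score_ab, score_ba; the map is a bijection
    on its support (asserted).
    """
    ab = _collapse_hsps(_validate_hits(hits_ab))
    ba = _collapse_hsps(_validate_hits(hits_ba))
    if ab.empty or ba.empty:
        return pd.DataFrame(columns=["gene_a", "gene_b", "score_ab", "score_ba"])
    best_ab = _best_per_query(ab)
    best_ba = _best_per_query(ba)
    pairs = []
    score_ab = ab.set_index(["query_id", "subject_id"])["bit_score"]
    score_ba = ba.set_index(["query_id", "subject_id"])["bit_score"]
    for a, b in best_ab.items():
        if best_ba.get(b) == a:
            pairs.append((a, b, float(score_ab[(a, b)]), float(score_ba[(b, a)])))
    result = pd.DataFrame(pairs, columns=["gene_a", "gene_b", "score_ab", "score_ba"])
    result = result.sort_values("gene_a", kind="mergesort").reset_index(drop=True)
    assert result["gene_a"].is_unique and result["gene_b"].is_unique, (
        "reciprocal best hits must be one-to-one"
    )
    return result


def collapse_duplicates(assignments: pd.DataFrame) -> pd.DataFrame:
    """Keep one query per subject: max score, then max query length, then lex id.

    ``assignments`` needs columns query_id, subject_id, bit_score and
    query_length (fallback: alignment_length).
    """
    length = (
        assignments["query_length"]
        if "query_length" in assignments
        else assignments["alignment_length"]
    )
    ranked = assignments.assign(_len=length).sort_values(
        ["subject_id", "bit_score", "_len", "query_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    kept = ranked.drop_duplicates("subject_id", keep="first").drop(columns="_len")
    return kept.reset_index(drop=True)


@dataclass
class DEComparison:
    """Direction-aware comparison of two species' DE calls over homolog pairs."""

    shared_de: set[tuple[str, str]] = field(default_factory=set)
    concordant_up: set[tuple[str, str]] = field(default_factory=set)
    concordant_down: set[tuple[str, str]] = field(default_factory=set)
    opposite: set[tuple[str, str]] = field(default_factory=set)
    a_specific: set[str] = field(default_factory=set)
    b_specific: set[str] = field(default_factory=set)

    @property
    def n_shared(self) -> int:
        return len(self.shared_de)

    @property
    def n_concordant(self) -> int:
        return len(self.concordant_up) + len(self.concordant_down)

    def counts(self) -> dict[str, int]:
        return {
            "shared_de": len(self.shared_de),
            "concordant_up": len(self.concordant_up),
            "concordant_down": len(self.concordant_down),
            "concordant_total": self.n_concordant,
            "opposite": len(self.opposite),
            "a_specific": len(self.a_specific),
            "b_specific": len(self.b_specific),
        }


def compare_de_sets(
    homolog_map: pd.DataFrame,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
) -> DEComparison:
    """Classify homolog pairs DE in both species by sign agreement.

    ``table_a``/``table_b`` are expression tables (indexed by gene id with a
    de_status column) covering every mapped gene; a mapped gene absent from
    its table raises a KeyError naming it. Species-specific counts are DE
    genes whose partner is not DE (or which are unmapped).
    """
    result = DEComparison()
    status_a = table_a["de_status"]
    status_b = table_b["de_status"]
    mapped_a: dict[str, str] = {}
    for a, b in zip(homolog_map["gene_a"], homolog_map["gene_b"]):
        if a not in status_a.index:
            raise KeyError(f"mapped gene {a!r} missing from species A expression table")
        if b not in status_b.index:
            raise KeyError(f"mapped gene {b!r} missing from species B expression table")
        mapped_a[a] = b
        sa, sb = status_a[a], status_b[b]
        if sa != "none" and sb != "none":
            result.shared_de.add((a, b))
            if sa == sb == "up":
                result.concordant_up.add((a, b))
            elif sa == sb == "down":
                result.concordant_down.add((a, b))
            else:
                result.opposite.add((a, b))
    shared_a = {a for a, _ in result.shared_de}
    shared_b = {b for _, b in result.shared_de}
    result.a_specific = set(status_a.index[status_a != "none"]) - shared_a
    result.b_specific = set(status_b.index[status_b != "none"]) - shared_b
    return result
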