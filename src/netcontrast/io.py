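"""Readers and writers for the plain-text formats the pipeline consumes.

Formats:

* count matrices — TSV, genes in rows, samples in columns, header row;
  a sidecar two-column TSV maps sample ids to condition labels.
* pathway membership — GMT (pathway name, description, member genes,
  tab-separated).
* pathway / network edges — SIF, three whitespace-separated columns with
  the relation token ``pp``; a line holding a single node denotes a
  singleton.
* similarity hits — 12-column BLAST tabular (outfmt 6). Only query,
  subject, alignment length, bit-score and the coordinate columns are
  interpreted; query/subject lengths are recovered from the qstart..qend
  and sstart..send spans.
* key-value metadata (configs, truth records) — YAML.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import pandas as pd
import yaml

HIT_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "evalue",
    "bit_score",
]


class FormatError(ValueError):
    """A file does not conform to the expected plain-text format."""


def _check_identifier(name: str) -> str:
    if "\t" in name or "\n" in name or "\r" in name:
        raise FormatError(f"identifier {name!r} contains tab/newline characters")
    return name


# ---------------------------------------------------------------------------
# counts


def write_counts_tsv(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    for gene in counts.index:
        _check_identifier(str(gene))
    for sample in counts.columns:
        _check_identifier(str(sample))
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    return df


def write_condition_map(conditions: Mapping[str, str], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tcondition\n")
        for sample, cond in conditions.items():
            fh.write(f"{_check_identifier(str(sample))}\t{cond}\n")


def read_condition_map(path: str | os.PathLike) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample_id"], df["condition"]))


# ---------------------------------------------------------------------------
# pathways


def write_gmt(
    memberships: Mapping[str, Iterable[str]],
    path: str | os.PathLike,
    descriptions: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        for name, members in memberships.items():
            _check_identifier(name)
            desc = (descriptions or {}).get(name, "na")
            fields = [name, desc] + sorted(_check_identifier(str(m)) for m in members)
            fh.write("\t".join(fields) + "\n")


def read_gmt(path: str | os.PathLike) -> dict[str, set[str]]:
    memberships: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(f"malformed GMT line: {line!r}")
            memberships[fields[0]] = set(fields[2:])
    return memberships


def write_sif(
    edges: Iterable[tuple[str, str]],
    path: str | os.PathLike,
    singletons: Iterable[str] = (),
    relation: str = "pp",
) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted((str(u), str(v)))) for u, v in edges):
            fh.write(f"{_check_identifier(a)} {relation} {_check_identifier(b)}\n")
        for node in sorted(str(n) for n in singletons):
            fh.write(f"{_check_identifier(node)}\n")


def read_sif(path: str | os.PathLike) -> tuple[set[tuple[str, str]], set[str]]:
    """Return (undirected edge set with sorted endpoints, singleton set)."""
    edges: set[tuple[str, str]] = set()
    singletons: set[str] = set()
    with open(path) as fh:
        for line in fh:
            fields = line.split()
            if not fields:
                continue
            if len(fields) == 1:
                singletons.add(fields[0])
            elif len(fields) == 3:
                a, _, b = fields
                if a != b:  # self-loops dropped at load
                    edges.add(tuple(sorted((a, b))))  # type: ignore[arg-type]
            else:
                raise FormatError(f"malformed SIF line: {line!r}")
    return edges, singletons


# ---------------------------------------------------------------------------
# similarity hits


def write_hits(hits: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a hit table as 12-column BLAST tabular output.

    Expects columns query_id, subject_id, bit_score, alignment_length and
    optionally query_length / subject_length (encoded as 1-based spans).
    """
    out = pd.DataFrame(
        {
            "query_id": hits["query_id"].astype(str),
            "subject_id": hits["subject_id"].astype(str),
            "pct_identity": hits.get("pct_identity", 90.0),
            "alignment_length": hits["alignment_length"].astype(int),
            "mismatches": 0,
            "gap_opens": 0,
            "q_start": 1,
            "q_end": hits.get("query_length", hits["alignment_length"]).astype(int),
            "s_start": 1,
            "s_end": hits.get("subject_length", hits["alignment_length"]).astype(int),
            "evalue": hits.get("evalue", 1e-30),
            "bit_score": hits["bit_score"].astype(float),
        }
    )
    for col in ("query_id", "subject_id"):
        out[col].map(_check_identifier)
    out.to_csv(path, sep="\t", header=False, index=False)


def read_hits(path: str | os.PathLike) -> pd.DataFrame:
    """Read BLAST outfmt-6; extra columns beyond the 12 standard are ignored."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#")
    if raw.shape[1] < 12:
        raise FormatError(f"expected >=12 tab-separated columns in {path}")
    raw = raw.iloc[:, :12]
    raw.columns = HIT_COLUMNS
    return pd.DataFrame(
        {
            "query_id": raw["query_id"].astype(str),
            "subject_id": raw["subject_id"].astype(str),
            "bit_score": raw["bit_score"].astype(float),
            "alignment_length": raw["alignment_length"].astype(int),
            "query_length": (raw["q_end"] - raw["q_start"] + 1).astype(int),
            "subject_length": (raw["s_end"] - raw["s_start"] + 1).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# key-value metadata


def write_key_value(data: dict, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def read_key_value(path: str | os.PathLike) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
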