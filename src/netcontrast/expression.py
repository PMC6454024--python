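"""Threshold-based differential-expression calling for unreplicated RNA-seq.

With a single library per condition there is no within-group variance to
estimate, so DE calling reduces to: discard genes with low total raw
counts, equalize sequencing depth with median-of-ratios size factors,
compute a pseudocount-stabilized log2 fold change of treated over
control, and call a gene up (down) when the fold change is >= +1
(<= -1) on the log2 scale, boundaries inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CONTROL = "control"
TREATED = "treated"
DE_STATES = ("up", "down", "none")


@dataclass
class CountMatrix:
    """Raw integer counts, genes x samples, with per-sample condition labels.

    ``counts`` is indexed by gene id with one column per sample;
    ``conditions`` maps every sample id to ``"control"`` or ``"treated"``.
    """

    counts: pd.DataFrame
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.counts.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = [s for s in self.counts.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples without condition label: {missing}")
        bad = {s: c for s, c in self.conditions.items() if c not in (CONTROL, TREATED)}
        if bad:
            raise ValueError(f"unknown condition labels: {bad}")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.counts.columns if self.conditions[s] == condition]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return self.counts.equals(other.counts) and self.conditions == {
            k: other.conditions.get(k) for k in self.conditions
        }


def filter_low_counts(cm: CountMatrix, min_total: int = 50) -> CountMatrix:
    """Drop genes whose summed raw count over all samples is < ``min_total``.

    The comparison is strict: a gene totalling exactly ``min_total`` is
    retained. Gene order is preserved. An empty result triggers a warning,
    not an error.
    """
    totals = cm.counts.sum(axis=1)
    kept = cm.counts.loc[totals >= min_total]
    if kept.empty:
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return CountMatrix(kept, dict(cm.conditions))


def estimate_size_factors(cm: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors (the DESeq estimator).

    For each sample, the factor is the median over reference genes of
    count / geometric-mean-across-samples, where reference genes are those
    with strictly positive counts in every sample.
    """
    counts = cm.counts.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "size factors undefined: no gene has positive counts in every sample"
        )
    ref = counts[positive]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    ratios = np.exp(np.log(ref) - log_geo_mean)
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=cm.counts.columns, name="size_factor")


def _normalized(cm: CountMatrix, factors: pd.Series) -> pd.DataFrame:
    return cm.counts.div(factors, axis=1)


def log2_fold_change(
    cm: CountMatrix, factors: pd.Series, pseudocount: float = 1.0
) -> pd.Series:
    """Per-gene log2((mean normalized treated + pc) / (mean normalized control + pc))."""
    norm = _normalized(cm, factors)
    mean_t = norm[cm.samples_for(TREATED)].mean(axis=1)
    mean_c = norm[cm.samples_for(CONTROL)].mean(axis=1)
    lfc = np.log2((mean_t + pseudocount) / (mean_c + pseudocount))
    lfc.name = "log2fc"
    return lfc


def call_de(lfc: pd.Series, threshold: float = 1.0) -> pd.Series:
    """Call up/down/none by an inclusive |log2FC| >= threshold rule."""
    values = lfc.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        bad = lfc.index[~np.isfinite(values)].tolist()
        raise ValueError(f"non-finite log2 fold changes for genes: {bad}")
    status = np.where(values >= threshold, "up", np.where(values <= -threshold, "down", "none"))
    return pd.Series(status, index=lfc.index, name="de_status")


def expression_table(
    cm: CountMatrix,
    min_total: int = 50,
    lfc_threshold: float = 1.0,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Run the fixed pipeline filter -> size factors -> lfc -> DE call.

    Returns a per-gene table with columns total_count, norm_mean_control,
    norm_mean_treated, log2fc, de_status. Re-running on already filtered
    input is idempotent.
    """
    filtered = filter_low_counts(cm, min_total=min_total)
    factors = estimate_size_factors(filtered)
    norm = _normalized(filtered, factors)
    lfc = log2_fold_change(filtered, factors, pseudocount=pseudocount)
    status = call_de(lfc, threshold=lfc_threshold)
    return pd.DataFrame(
        {
            "total_count": filtered.counts.sum(axis=1).astype(int),
            "norm_mean_control": norm[filtered.samples_for(CONTROL)].mean(axis=1),
            "norm_mean_treated": norm[filtered.samples_for(TREATED)].mean(axis=1),
            "log2fc": lfc,
            "de_status": status,
        }
    ).rename_axis("gene_id")


def de_genes(table: pd.DataFrame) -> set[str]:
    """Gene ids called up or down in an expression table."""
    return set(table.index[table["de_status"] != "none"])


def qc_pca(cm: CountMatrix, factors: pd.Series | None = None):
    """PCA on log2(normalized counts + 1), genes centered across samples.

    Returns (variance fractions summing to 1, sample coordinate DataFrame).
    Samples are the observations; components span the sample space.
    """
    if cm.counts.shape[1] < 2:
        raise ValueError("PCA requires at least 2 samples")
    if factors is None:
        factors = estimate_size_factors(cm)
    log_norm = np.log2(_normalized(cm, factors).to_numpy() + 1.0)
    centered = log_norm - log_norm.mean(axis=1, keepdims=True)
    # samples as rows for the decomposition
    x = centered.T
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    total = float((s**2).sum())
    if total == 0.0:
        raise ValueError("zero total variance: all samples identical")
    fractions = s**2 / total
    coords = pd.DataFrame(
        u * s,
        index=cm.counts.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    return fractions, coords
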