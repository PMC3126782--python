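"""Unique/weighted read counting and RPKM normalization.

A read hitting exactly one gene contributes 1 to that gene's unique and
weighted counts. A read hitting k > 1 distinct genes contributes 1/k to each
gene's weighted count under the default equal-split scheme, or a share
proportional to each candidate's unique count under the rescue scheme
(uniform fallback when every candidate has zero unique hits). Weighted
counts therefore conserve the mapped read total exactly.

RPKM = 1e9 * C / (L * N) for weighted count C, longest-transcript length L
(bp) and per-sample mapped weighted total N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from chemoseq.mapping import HitSet

WEIGHTING_SCHEMES = ("equal", "rescue")


def weight_counts(
    hitsets: Iterable[HitSet],
    gene_ids: Sequence[str],
    scheme: str = "equal",
) -> pd.DataFrame:
    """Counts for one library: DataFrame indexed by gene with columns
    ``unique_hits`` and ``weighted_hits``."""
    if scheme not in WEIGHTING_SCHEMES:
        raise ValueError(f"unknown weighting scheme {scheme!r}")
    unique = {g: 0 for g in gene_ids}
    weighted = {g: 0.0 for g in gene_ids}
    ambiguous: list[frozenset[str]] = []
    for hs in hitsets:
        genes = hs.distinct_genes
        if not genes:
            continue
        missing = genes - unique.keys()
        if missing:
            raise KeyError(f"hit on unannotated gene(s): {sorted(missing)}")
        if len(genes) == 1:
            (g,) = genes
            unique[g] += 1
            weighted[g] += 1.0
        else:
            ambiguous.append(genes)

    if scheme == "equal":
        for genes in ambiguous:
            share = 1.0 / len(genes)
            for g in genes:
                weighted[g] += share
    else:  # rescue: apportion by unique evidence
        for genes in ambiguous:
            total = sum(unique[g] for g in genes)
            if total == 0:
                share = 1.0 / len(genes)
                for g in genes:
                    weighted[g] += share
            else:
                for g in genes:
                    weighted[g] += unique[g] / total

    out = pd.DataFrame(
        {
            "unique_hits": pd.Series(unique, dtype=np.int64),
            "weighted_hits": pd.Series(weighted, dtype=float),
        }
    ).loc[list(gene_ids)]
    return out.rename_axis("gene_id")


@dataclass
class CountTable:
    """Per gene x sample unique and weighted counts.

    ``unique`` and ``weighted`` are gene x sample DataFrames with identical
    axes; ``totals[s]`` is the mapped weighted total N for sample s.
    """

    unique: pd.DataFrame
    weighted: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.unique.index.equals(self.weighted.index):
            raise ValueError("unique/weighted gene index mismatch")
        if list(self.unique.columns) != list(self.weighted.columns):
            raise ValueError("unique/weighted sample columns mismatch")

    @property
    def samples(self) -> list[str]:
        return list(self.weighted.columns)

    @property
    def genes(self) -> pd.Index:
        return self.weighted.index

    @property
    def totals(self) -> pd.Series:
        return self.weighted.sum(axis=0)

    @classmethod
    def from_columns(cls, columns: dict[str, pd.DataFrame]) -> "CountTable":
        """Assemble from per-sample ``weight_counts`` outputs."""
        unique = pd.DataFrame({s: df["unique_hits"] for s, df in columns.items()})
        weighted = pd.DataFrame({s: df["weighted_hits"] for s, df in columns.items()})
        return cls(unique=unique, weighted=weighted)


def compute_rpkm(c: float, length_bp: float, n_mapped: float) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if length_bp <= 0:
        raise ValueError("transcript length must be positive")
    if n_mapped <= 0:
        raise ValueError("mapped total must be positive (empty library?)")
    return 1e9 * c / (length_bp * n_mapped)


@dataclass
class ExpressionTable:
    """Gene x sample RPKM values plus the lengths and totals behind them."""

    rpkm: pd.DataFrame
    lengths: pd.Series
    totals: pd.Series

    @property
    def samples(self) -> list[str]:
        return list(self.rpkm.columns)

    @property
    def genes(self) -> pd.Index:
        return self.rpkm.index


def rpkm_table(counts: CountTable, lengths: pd.Series) -> ExpressionTable:
    """RPKM for every gene and sample from weighted counts.

    ``lengths`` must cover every gene in the count table (longest annotated
    transcript, bp). Samples with zero mapped reads are rejected.
    """
    missing = counts.genes.difference(lengths.index)
    if len(missing):
        raise KeyError(f"lengths missing for genes: {list(missing)[:5]}")
    lengths = lengths.loc[counts.genes].astype(float)
    if (lengths <= 0).any():
        raise ValueError("non-positive transcript length in annotation")
    totals = counts.totals
    zero = totals[totals <= 0]
    if len(zero):
        raise ValueError(f"samples with zero mapped reads: {list(zero.index)}")
    rpkm = 1e9 * counts.weighted.div(lengths, axis=0).div(totals, axis=1)
    return ExpressionTable(rpkm=rpkm, lengths=lengths, totals=totals)


def summarize_expression(
    expr: ExpressionTable, counts: CountTable, sample: str
) -> dict:
    """Per-sample expression summary: detected gene count and RPKM stats.

    Detection rule: weighted_hits > 0. Standard deviation is the sample sd
    (n - 1), flagged in the output metadata.
    """
    if sample not in expr.samples:
        raise KeyError(f"sample {sample!r} not present")
    detected = counts.weighted[sample] > 0
    vals = expr.rpkm.loc[detected, sample]
    n = int(detected.sum())
    if n == 0:
        return {
            "sample": sample,
            "gene_count": 0,
            "median_rpkm": math.nan,
            "mean_rpkm": math.nan,
            "sd_rpkm": math.nan,
            "sd_kind": "sample (n-1)",
            "detection_rule": "weighted_hits > 0",
        }
    return {
        "sample": sample,
        "gene_count": n,
        "median_rpkm": float(vals.median()),
        "mean_rpkm": float(vals.mean()),
        "sd_rpkm": float(vals.std(ddof=1)) if n > 1 else math.nan,
        "sd_kind": "sample (n-1)",
        "detection_rule": "weighted_hits > 0",
    }
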