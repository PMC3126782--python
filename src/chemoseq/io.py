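"""File formats: FASTA/FASTQ, annotation TSV, count/expression tables, YAML.

All TSV writers emit '#'-prefixed header comments naming units and
conventions so outputs are self-describing; readers skip those lines.
Round-trips are lossless at 12 significant digits.

The count-table dialect mirrors the six-sample supplementary layout used by
the source study (gene ID, transcript length, RPKM per sample, unique hits
per sample, total weighted hits per sample) and tolerates extra columns, so
an externally produced table in that dialect can be fed straight into the
enhancement and comparative stages.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from chemoseq.quantify import CountTable, ExpressionTable, rpkm_table
from chemoseq.simulate import SAMPLES, SimRead, Transcriptome

FLOAT_FMT = "%.12g"


# ---------------------------------------------------------------- sequences

def write_fasta(transcriptome: Transcriptome, path: str | Path) -> None:
    """One record per isoform, header ``GENEID|isoformN``."""
    with open(path, "w") as fh:
        for _gene, iso_id, seq in transcriptome.isoforms():
            fh.write(f">{iso_id}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def read_transcriptome_fasta(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse ``GENEID|isoformN`` FASTA into (gene, isoform, seq) triples."""
    triples: list[tuple[str, str, str]] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        gene, _, iso = header.partition("|")
        iso_id = f"{gene}|{iso}" if iso else header
        triples.append((gene, iso_id, "".join(chunks)))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line.upper())
    flush()
    if not triples:
        raise ValueError(f"empty FASTA: {path}")
    return triples


def write_fastq(reads: Iterable[SimRead | tuple[str, str]], path: str | Path) -> None:
    """Phred+33 FASTQ with constant 'I' qualities (qualities are unused)."""
    with open(path, "w") as fh:
        for read in reads:
            read_id, seq = read[0], read[1]
            fh.write(f"@{read_id}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path: str | Path) -> Iterable[tuple[str, str]]:
    """Yield (read_id, sequence) from a Phred+33 FASTQ file."""
    with open(path) as fh:
        for title, seq, _qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq.upper()


# --------------------------------------------------------------------- TSVs

def _write_tsv(df: pd.DataFrame, path: str | Path, comments: Sequence[str]) -> None:
    with open(path, "w") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FMT)


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


ANNOTATION_COLUMNS = ("length", "family", "pfam")


def write_annotation(annotation: pd.DataFrame, path: str | Path) -> None:
    _write_tsv(
        annotation,
        path,
        [
            "gene annotation: length = longest annotated transcript (bp);",
            "family = chemosensory family tag (may be empty); pfam = PfamA best hit",
        ],
    )


def read_annotation(path: str | Path) -> pd.DataFrame:
    """Annotation TSV -> DataFrame indexed by gene_id.

    Requires ``gene_id`` and ``length`` columns; ``family`` and ``pfam``
    default to empty strings. Duplicate gene IDs are rejected by name.
    """
    df = _read_tsv(path, dtype={"gene_id": str})
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise ValueError(f"annotation missing required column: {col!r}")
    dupes = df["gene_id"][df["gene_id"].duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene ID(s) in annotation: {sorted(set(dupes))}")
    df = df.set_index("gene_id")
    if (df["length"] <= 0).any():
        raise ValueError("annotation lengths must be positive")
    for col in ("family", "pfam"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("")
    return df[list(ANNOTATION_COLUMNS)]


def write_truth(truth_df: pd.DataFrame, path: str | Path, what: str) -> None:
    _write_tsv(truth_df, path, [f"simulation ground truth: {what}"])


def write_hits(hitsets, path: str | Path) -> None:
    """Per-read hit TSV: read_id, comma-joined gene list, min mismatches."""
    rows = [
        {
            "read_id": hs.read_id,
            "genes": ",".join(sorted(hs.distinct_genes)),
            "min_mismatches": hs.min_mismatches if hs.mapped else "",
        }
        for hs in hitsets
    ]
    _write_tsv(
        pd.DataFrame(rows).set_index("read_id"),
        path,
        ["per-read gene hits; empty genes = unmapped; offsets 0-based internally"],
    )


def write_mapping_summary(summaries: dict[str, dict], path: str | Path) -> None:
    df = pd.DataFrame(summaries).T.rename_axis("sample")
    _write_tsv(df, path, ["per-library mapping summary: reads, mapped reads, fraction"])


# ---------------------------------------------------- count/expression table

def write_counts_table(
    counts: CountTable,
    expr: ExpressionTable,
    annotation: pd.DataFrame,
    path: str | Path,
) -> None:
    """Six-sample supplementary-style table: gene ID, transcript length,
    RPKM per sample, unique hits per sample, total (weighted) hits."""
    df = pd.DataFrame(index=counts.genes)
    df["transcript_length"] = annotation.loc[counts.genes, "length"]
    for col in ("family", "pfam"):
        df[col] = annotation.loc[counts.genes, col]
    for s in counts.samples:
        df[f"RPKM_{s}"] = expr.rpkm[s]
    for s in counts.samples:
        df[f"unique_{s}"] = counts.unique[s]
    for s in counts.samples:
        df[f"total_{s}"] = counts.weighted[s]
    _write_tsv(
        df.rename_axis("gene_id"),
        path,
        [
            "per-gene expression table; transcript_length in bp (longest isoform);",
            "RPKM = 1e9 * total / (length * N); unique = uniquely mapped reads;",
            "total = weighted reads (unique + fractional multi-map shares)",
        ],
    )


def read_counts_table(
    path: str | Path,
    samples: Sequence[str] = SAMPLES,
    totals: dict[str, float] | None = None,
) -> tuple[CountTable, ExpressionTable]:
    """Read a six-sample count/expression table back into pipeline objects.

    Per-sample N defaults to the column sum of total (weighted) hits;
    ``totals`` overrides it (e.g. when externally published mapped totals
    should be used instead). Extra columns are tolerated; required columns
    are matched by header name. Non-numeric cells are rejected with their
    row and column.
    """
    df = _read_tsv(path, dtype={"gene_id": str})
    if df.empty:
        raise ValueError(f"empty counts table: {path}")
    if "gene_id" not in df.columns:
        raise ValueError("counts table missing required column: 'gene_id'")
    df = df.set_index("gene_id")
    required = ["transcript_length"] + [f"total_{s}" for s in samples] + [
        f"unique_{s}" for s in samples
    ]
    for col in required:
        if col not in df.columns:
            raise ValueError(f"counts table missing required column: {col!r}")
    numeric = required + [f"RPKM_{s}" for s in samples if f"RPKM_{s}" in df.columns]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad):
            raise ValueError(f"non-numeric cell at row {bad[0]!r}, column {col!r}")
        df[col] = converted
    unique = df[[f"unique_{s}" for s in samples]].copy()
    unique.columns = list(samples)
    weighted = df[[f"total_{s}" for s in samples]].copy()
    weighted.columns = list(samples)
    counts = CountTable(unique=unique.round().astype(int), weighted=weighted)
    lengths = df["transcript_length"].astype(float)
    expr = rpkm_table(counts, lengths)
    if totals is not None:
        n = pd.Series(totals).reindex(list(samples))
        if n.isna().any():
            raise ValueError("totals override must cover every sample")
        rpkm = 1e9 * counts.weighted.div(lengths, axis=0).div(n, axis=1)
        expr = ExpressionTable(rpkm=rpkm, lengths=lengths, totals=n)
    return counts, expr


# ------------------------------------------------------------------- config

def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"config must be a mapping: {path}")
    return data
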