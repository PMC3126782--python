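"""Synthetic transcriptome, expression profiles and read libraries.

Generates a toy gene-level transcriptome (optionally with near-identical
paralog pairs that force ambiguous mapping), six tissue/sex-structured
abundance profiles with designated enhanced gene sets at controlled fold
changes, and single-end FASTQ read libraries with full ground truth.

All randomness flows from a single master seed; each stage draws from an
independent deterministic substream so outputs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

#: Canonical sample labels: female/male bodies, antennae, palps.
SAMPLES = ("FB", "FA", "FP", "MB", "MA", "MP")

#: Matched whole-body sample for each tissue sample.
BODY_OF = {"FA": "FB", "FP": "FB", "MA": "MB", "MP": "MB", "FB": "FB", "MB": "MB"}

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# substream tags for the master seed
_STAGE_TRANSCRIPTOME = 1
_STAGE_EXPRESSION = 2
_STAGE_READS = 3


class SimRead(NamedTuple):
    """One simulated read plus its (truth-only) origin."""

    read_id: str
    seq: str
    gene: str
    pos: int
    strand: str


@dataclass
class SimulationConfig:
    """Parameters for the synthetic study design.

    ``enhanced_design`` maps a sample label to ``{gene_index: fold}``;
    the fold (> 1) multiplies that gene's baseline abundance in that
    sample relative to its matched body sample.
    """

    n_genes: int = 500
    n_paralog_families: int = 0
    paralog_divergence: float = 0.05
    isoforms_per_gene: int = 1
    transcript_length_range: tuple[int, int] = (300, 2000)
    base_expression: tuple[float, float] = (0.0, 1.0)  # log-normal (mu, sigma)
    samples: tuple[str, ...] = SAMPLES
    enhanced_design: dict[str, dict[int, float]] = field(default_factory=dict)
    family_design: dict[str, list[int]] = field(default_factory=dict)
    pfam_design: dict[str, list[int]] = field(default_factory=dict)
    library_size: int = 200_000
    read_length: int = 43
    error_rate: float = 0.0
    antisense_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.n_paralog_families < 0:
            raise ValueError("n_paralog_families must be >= 0")
        if 2 * self.n_paralog_families > self.n_genes:
            raise ValueError("paralog families need 2 genes each")
        if not 0.0 <= self.paralog_divergence <= 0.5:
            raise ValueError("paralog_divergence must be in [0, 0.5]")
        if self.isoforms_per_gene < 1:
            raise ValueError("isoforms_per_gene must be >= 1")
        lo, hi = self.transcript_length_range
        if lo > hi or lo <= 0:
            raise ValueError("invalid transcript_length_range")
        if lo < self.read_length:
            raise ValueError(
                "transcript_length_range minimum "
                f"({lo}) is below read_length ({self.read_length})"
            )
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.read_length <= 0:
            raise ValueError("read_length must be positive")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")
        if not 0.0 <= self.antisense_fraction <= 1.0:
            raise ValueError("antisense_fraction must be in [0, 1]")
        unknown = set(self.samples) - set(SAMPLES)
        if unknown:
            raise ValueError(f"unknown sample labels: {sorted(unknown)}")
        for sample, design in self.enhanced_design.items():
            if sample not in self.samples:
                raise ValueError(f"enhanced_design references unknown sample {sample}")
            for idx, fold in design.items():
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"enhanced_design gene index {idx} out of range")
                if fold <= 1:
                    raise ValueError(f"fold multipliers must be > 1, got {fold}")
        for label, members in {**self.family_design, **self.pfam_design}.items():
            for idx in members:
                if not 0 <= idx < self.n_genes:
                    raise ValueError(f"design for {label!r}: gene index {idx} out of range")

    def gene_id(self, index: int) -> str:
        return f"SIM{index:05d}"


@dataclass
class Transcriptome:
    """Gene-condensed transcript sequences: gene -> [(isoform_id, seq), ...]."""

    genes: dict[str, list[tuple[str, str]]]

    def longest(self, gene: str) -> str:
        return max((seq for _, seq in self.genes[gene]), key=len)

    def isoforms(self):
        """Yield (gene_id, isoform_id, sequence); isoform IDs are globally
        unique ("GENE|isoformN")."""
        for gene, isos in self.genes.items():
            for iso_id, seq in isos:
                yield gene, f"{gene}|{iso_id}", seq


@dataclass
class GroundTruth:
    """True relative abundances and designed enhancement labels.

    ``abundance``: genes x samples, each column sums to 1.
    ``enhanced_labels``: genes x comparisons (e.g. "FA_vs_FB"), values in
    {"tissue", "body", "none"}, assigned from pre-normalization ratios.
    ``designed_folds``: genes x comparisons, designed fold (1.0 = none).
    """

    abundance: pd.DataFrame
    enhanced_labels: pd.DataFrame
    designed_folds: pd.DataFrame


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(rng: np.random.Generator, codes: np.ndarray, rate: float) -> np.ndarray:
    out = codes.copy()
    if rate > 0:
        mask = rng.random(codes.size) < rate
        # shift by 1..3 guarantees a different base
        out[mask] = (out[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def build_transcriptome(config: SimulationConfig) -> tuple[Transcriptome, pd.DataFrame]:
    """Generate gene sequences and the per-gene annotation table.

    Paralog family ``f`` occupies gene indices ``2f`` and ``2f + 1``; the
    second copy is the first mutated at ``paralog_divergence`` per base, so
    zero divergence yields identical sequences (and guaranteed ambiguous
    mapping). Isoform 1 is the full-length transcript; further isoforms are
    random-length prefixes. The annotation length is the longest isoform.

    Returns ``(Transcriptome, annotation)`` where annotation has columns
    ``gene_id``, ``length``, ``family``, ``pfam``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_TRANSCRIPTOME])
    lo, hi = config.transcript_length_range
    lengths = rng.integers(lo, hi + 1, size=config.n_genes)
    # paralog partners share a length
    for fam in range(config.n_paralog_families):
        lengths[2 * fam + 1] = lengths[2 * fam]

    codes: list[np.ndarray] = []
    for i in range(config.n_genes):
        fam = i // 2 if i < 2 * config.n_paralog_families else None
        if fam is not None and i % 2 == 1:
            codes.append(_mutate(rng, codes[i - 1], config.paralog_divergence))
        else:
            codes.append(_random_seq(rng, int(lengths[i])))

    genes: dict[str, list[tuple[str, str]]] = {}
    ann_rows = []
    family_of = {
        config.gene_id(idx): label
        for label, members in config.family_design.items()
        for idx in members
    }
    pfam_of = {
        config.gene_id(idx): acc
        for acc, members in config.pfam_design.items()
        for idx in members
    }
    for i in range(config.n_genes):
        gid = config.gene_id(i)
        full = _decode(codes[i])
        isoforms = [("isoform1", full)]
        for k in range(2, config.isoforms_per_gene + 1):
            iso_len = int(rng.integers(config.read_length, len(full) + 1))
            isoforms.append((f"isoform{k}", full[:iso_len]))
        genes[gid] = isoforms
        ann_rows.append(
            {
                "gene_id": gid,
                "length": max(len(seq) for _, seq in isoforms),
                "family": family_of.get(gid, ""),
                "pfam": pfam_of.get(gid, ""),
            }
        )
    annotation = pd.DataFrame(ann_rows).set_index("gene_id")
    return Transcriptome(genes), annotation


def simulate_expression(config: SimulationConfig) -> GroundTruth:
    """Draw baseline abundances and apply the designed enhancements.

    Baselines are log-normal(mu, sigma), shared across samples; each
    designed (sample, gene, fold) multiplies that gene's abundance in that
    sample only. Labels are recorded from the pre-normalization tissue:body
    ratio, then every column is renormalized to sum to 1.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, _STAGE_EXPRESSION])
    mu, sigma = config.base_expression
    baseline = rng.lognormal(mu, sigma, size=config.n_genes)
    gene_ids = pd.Index(
        [config.gene_id(i) for i in range(config.n_genes)], name="gene_id"
    )

    raw = pd.DataFrame(
        {s: baseline.copy() for s in config.samples}, index=gene_ids
    )
    for sample, design in config.enhanced_design.items():
        for idx, fold in design.items():
            raw.loc[config.gene_id(idx), sample] *= fold

    comparisons = [
        f"{s}_vs_{BODY_OF[s]}" for s in config.samples if s != BODY_OF[s]
    ]
    labels = pd.DataFrame("none", index=gene_ids, columns=comparisons)
    folds = pd.DataFrame(1.0, index=gene_ids, columns=comparisons)
    for s in config.samples:
        body = BODY_OF[s]
        if s == body:
            continue
        comp = f"{s}_vs_{body}"
        ratio = raw[s] / raw[body]
        labels.loc[ratio > 1, comp] = "tissue"
        labels.loc[ratio < 1, comp] = "body"
        folds[comp] = np.maximum(ratio, 1.0 / ratio)
        folds.loc[labels[comp] == "none", comp] = 1.0

    abundance = raw / raw.sum(axis=0)
    return GroundTruth(abundance=abundance, enhanced_labels=labels, designed_folds=folds)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def simulate_reads(
    truth: GroundTruth,
    transcriptome: Transcriptome,
    config: SimulationConfig,
    sample: str,
) -> list[SimRead]:
    """Sample ``library_size`` error-prone reads for one library.

    Reads are drawn multinomially over (gene, start position) cells with
    weight abundance x (longest-isoform length - read_length + 1) — done as
    a gene-level multinomial followed by uniform starts, which induces the
    same distribution. Substitution errors are independent per base at
    ``error_rate``; an optional fraction of reads is emitted antisense.
    """
    config.validate()
    if sample not in config.samples:
        raise ValueError(f"sample {sample!r} not in config.samples")
    if not transcriptome.genes:
        raise ValueError("empty transcriptome")
    sample_index = config.samples.index(sample)
    rng = np.random.default_rng([config.seed, _STAGE_READS, sample_index])

    gene_ids = list(truth.abundance.index)
    rl = config.read_length
    templates = {}
    eff_len = np.empty(len(gene_ids), dtype=np.int64)
    for j, g in enumerate(gene_ids):
        seq = transcriptome.longest(g)
        if len(seq) < rl:
            raise ValueError(f"transcript {g} shorter than read_length")
        codes = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
        lut = np.zeros(256, dtype=np.uint8)
        lut[ord("A")], lut[ord("C")], lut[ord("G")], lut[ord("T")] = 0, 1, 2, 3
        templates[g] = lut[codes]
        eff_len[j] = len(seq) - rl + 1

    weights = truth.abundance[sample].to_numpy() * eff_len
    weights = weights / weights.sum()
    counts = rng.multinomial(config.library_size, weights)

    reads: list[SimRead] = []
    serial = 0
    for j, g in enumerate(gene_ids):
        n = int(counts[j])
        if n == 0:
            continue
        tmpl = templates[g]
        starts = rng.integers(0, eff_len[j], size=n)
        mat = tmpl[starts[:, None] + np.arange(rl)[None, :]]
        if config.error_rate > 0:
            mask = rng.random(mat.shape) < config.error_rate
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=int(mask.sum()))) % 4
        if config.antisense_fraction > 0:
            anti = rng.random(n) < config.antisense_fraction
        else:
            anti = np.zeros(n, dtype=bool)
        for r in range(n):
            codes = mat[r]
            strand = "+"
            if anti[r]:
                codes = _revcomp_codes(codes)
                strand = "-"
            reads.append(
                SimRead(
                    read_id=f"{sample}.{serial:07d}",
                    seq=_decode(codes),
                    gene=g,
                    pos=int(starts[r]),
                    strand=strand,
                )
            )
            serial += 1
    return reads
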