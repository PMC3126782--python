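"""Read trimming and mismatch-tolerant transcriptome mapping.

The mapper is a k-mer seed index with full Hamming verification. For a
trimmed read of length L and mismatch budget m, exact lookup of m + 1
disjoint seeds guarantees (pigeonhole) that every placement with <= m
mismatches is found, provided (m + 1) * seed_length <= L. Both strands are
searched; placements on several isoforms of one gene collapse to a single
gene membership downstream.

Coordinates are 0-based, half-open. Qualities are carried through trimming
but otherwise ignored.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCHES = 3

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class TrimSpec:
    """Uniform end trimming: 4 nt from the 5' end and 12 nt from the 3' end
    by default (adapter carry-over and 3' degeneration)."""

    five_prime: int = 4
    three_prime: int = 12

    def __post_init__(self) -> None:
        if self.five_prime < 0 or self.three_prime < 0:
            raise ValueError("trim lengths must be >= 0")

    def trimmed_length(self, read_length: int) -> int:
        return read_length - self.five_prime - self.three_prime


def trim_read(
    seq: str, qual: str | None = None, spec: TrimSpec = TrimSpec()
) -> tuple[str, str | None]:
    """Trim one read; raises ValueError when nothing would remain."""
    if spec.trimmed_length(len(seq)) <= 0:
        raise ValueError(f"read too short to trim: length {len(seq)}")
    end = len(seq) - spec.three_prime
    trimmed = seq[spec.five_prime : end]
    tq = qual[spec.five_prime : end] if qual is not None else None
    return trimmed, tq


def trim_library(
    reads: Iterable[tuple[str, str]], spec: TrimSpec = TrimSpec()
) -> tuple[list[tuple[str, str]], int]:
    """Trim (read_id, seq) pairs; returns surviving reads and the count of
    too-short reads excluded."""
    kept: list[tuple[str, str]] = []
    too_short = 0
    for read_id, seq in reads:
        try:
            trimmed, _ = trim_read(seq, None, spec)
        except ValueError:
            too_short += 1
            continue
        kept.append((read_id, trimmed))
    if too_short:
        logger.info("trim: excluded %d too-short reads", too_short)
    return kept, too_short


@dataclass(frozen=True)
class HitSet:
    """Mapping outcome for one read.

    ``gene_hits`` holds (gene_id, isoform_id, start, strand, mismatches)
    tuples for every placement within the mismatch budget.
    """

    read_id: str
    gene_hits: frozenset[tuple[str, str, int, str, int]]

    @property
    def distinct_genes(self) -> frozenset[str]:
        return frozenset(h[0] for h in self.gene_hits)

    @property
    def mapped(self) -> bool:
        return bool(self.gene_hits)

    @property
    def min_mismatches(self) -> int | None:
        return min((h[4] for h in self.gene_hits), default=None)


@dataclass
class MappingSummary:
    """Per-library tallies mirroring a reads / mapped (%) report."""

    n_reads: int = 0
    n_mapped: int = 0
    n_skipped: int = 0

    @property
    def fraction_mapped(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class TranscriptomeIndex:
    """Exact-match seed index over the forward strand of every isoform.

    Reads are queried as-is and reverse-complemented, so a placement is
    reported iff its Hamming distance is within budget on either strand.
    Isoform sequences are concatenated into one byte array so candidate
    windows can be gathered and verified with vectorized operations.
    """

    def __init__(
        self,
        isoforms: Sequence[tuple[str, str, str]],
        seed_length: int = 6,
    ) -> None:
        if not isoforms:
            raise ValueError("empty transcriptome")
        if seed_length < 1:
            raise ValueError("seed_length must be >= 1")
        seen: set[str] = set()
        self.seed_length = seed_length
        self.genes: list[str] = []
        self.iso_ids: list[str] = []
        self.seqs: list[str] = []
        offsets = [0]
        for gene, iso_id, seq in isoforms:
            if iso_id in seen:
                raise ValueError(f"duplicate isoform ID: {iso_id}")
            seen.add(iso_id)
            self.genes.append(gene)
            self.iso_ids.append(iso_id)
            self.seqs.append(seq)
            offsets.append(offsets[-1] + len(seq))
        self._concat = np.frombuffer(
            "".join(self.seqs).encode("ascii"), dtype=np.uint8
        )
        self._iso_start = np.asarray(offsets[:-1], dtype=np.int64)
        self._iso_end = np.asarray(offsets[1:], dtype=np.int64)

        # 2-bit base codes for word-packed Hamming counting; positions with
        # non-ACGT transcript bases disable the packed fast path
        lut = np.full(256, 255, dtype=np.uint8)
        for code, base in enumerate(b"ACGT"):
            lut[base] = code
        self._codes2 = lut[self._concat]
        self._packable = not bool((self._codes2 == 255).any())
        self._packed_cache: dict[int, np.ndarray] = {}

        k = seed_length
        seed_lists: dict[str, list] = defaultdict(lambda: ([], []))
        for idx, seq in enumerate(self.seqs):
            base = offsets[idx]
            for off in range(len(seq) - k + 1):
                gpos, isos = seed_lists[seq[off : off + k]]
                gpos.append(base + off)
                isos.append(idx)
        self._seeds: dict[str, tuple[np.ndarray, np.ndarray]] = {
            kmer: (
                np.asarray(gpos, dtype=np.int64),
                np.asarray(isos, dtype=np.int32),
            )
            for kmer, (gpos, isos) in seed_lists.items()
        }

    @property
    def n_isoforms(self) -> int:
        return len(self.seqs)

    def _packed_windows(self, length: int) -> np.ndarray:
        """uint64 2-bit packings of every window of ``length`` bases."""
        if length in self._packed_cache:
            return self._packed_cache[length]
        n = self._codes2.size - length + 1
        packed = np.zeros(n, dtype=np.uint64)
        for j in range(length):
            packed = (packed << np.uint64(2)) | self._codes2[j : j + n].astype(
                np.uint64
            )
        self._packed_cache[length] = packed
        return packed

    def n_seed_positions(self) -> int:
        """Total number of indexed seed positions (one per k-mer start)."""
        return sum(len(gpos) for gpos, _ in self._seeds.values())

    def seed_positions(self, kmer: str) -> list[tuple[int, int]]:
        """(isoform index, offset) pairs whose seed matches ``kmer`` exactly."""
        if kmer not in self._seeds:
            return []
        gpos, isos = self._seeds[kmer]
        return [
            (int(i), int(g - self._iso_start[i])) for g, i in zip(gpos, isos)
        ]

    def _strand_hits(
        self, arr: np.ndarray, s: str, max_mismatches: int
    ) -> list[tuple[int, int, int]]:
        """(iso_idx, start, mismatches) placements for one read orientation."""
        k = self.seed_length
        L = len(s)
        cand_g: list[np.ndarray] = []
        cand_iso: list[np.ndarray] = []
        for i in range(max_mismatches + 1):
            p = i * k
            if p + k > L:
                break
            entry = self._seeds.get(s[p : p + k])
            if entry is None:
                continue
            gpos, isos = entry
            cand_g.append(gpos - p)
            cand_iso.append(isos)
        if not cand_g:
            return []
        g = np.concatenate(cand_g)
        iso = np.concatenate(cand_iso)
        ok = (g >= self._iso_start[iso]) & (g + L <= self._iso_end[iso])
        g, iso = g[ok], iso[ok]
        if g.size == 0:
            return []
        # a global start uniquely identifies the placement
        g, first = np.unique(g, return_index=True)
        iso = iso[first]
        windows = self._concat[g[:, None] + np.arange(L)]
        mm = (windows != arr).sum(axis=1)
        keep = mm <= max_mismatches
        return [
            (int(i), int(gg - self._iso_start[i]), int(m))
            for gg, i, m in zip(g[keep], iso[keep], mm[keep])
        ]

    def map_read(
        self,
        seq: str,
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        best_stratum: bool = False,
    ) -> frozenset[tuple[str, str, int, str, int]]:
        """All placements of ``seq`` with <= max_mismatches on either strand.

        Bases that are not an exact match (including N against anything)
        count as mismatches.
        """
        hits: set[tuple[str, str, int, str, int]] = set()
        for strand, s in (("+", seq), ("-", _revcomp(seq))):
            arr = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
            for iso_idx, start, mm in self._strand_hits(arr, s, max_mismatches):
                hits.add(
                    (self.genes[iso_idx], self.iso_ids[iso_idx], start, strand, mm)
                )
        if best_stratum and hits:
            best = min(h[4] for h in hits)
            hits = {h for h in hits if h[4] == best}
        return frozenset(hits)

    def _verify(
        self, codes: np.ndarray, g: np.ndarray, q: np.ndarray, L: int
    ) -> np.ndarray:
        """Mismatch counts for candidate placements.

        Uses XOR + popcount on 2-bit packed words when the read length fits
        in 64 bits and neither reads nor transcripts contain non-ACGT bases;
        otherwise falls back to a byte-wise window comparison.
        """
        lut = np.full(256, 255, dtype=np.uint8)
        for code, base in enumerate(b"ACGT"):
            lut[base] = code
        read_codes2 = lut[codes]
        if self._packable and L <= 32 and not (read_codes2 == 255).any():
            rp = np.zeros(len(codes), dtype=np.uint64)
            for j in range(L):
                rp = (rp << np.uint64(2)) | read_codes2[:, j].astype(np.uint64)
            x = self._packed_windows(L)[g] ^ rp[q]
            diff_pairs = (x | (x >> np.uint64(1))) & np.uint64(
                0x5555555555555555
            )
            return np.bitwise_count(diff_pairs).astype(np.int64)
        windows = self._concat[g[:, None] + np.arange(L)]
        return (windows != codes[q]).sum(axis=1)

    def map_batch(
        self,
        seqs: Sequence[str],
        max_mismatches: int = DEFAULT_MAX_MISMATCHES,
        best_stratum: bool = False,
    ) -> list[frozenset[tuple[str, str, int, str, int]]]:
        """Vectorized :meth:`map_read` over many reads.

        Candidate placements from every read (both strands) are pooled and
        verified with one gather/compare per read-length group; results are
        identical to per-read mapping.
        """
        results: list[set] = [set() for _ in seqs]
        k = self.seed_length
        by_len: dict[int, list[tuple[int, str, str]]] = defaultdict(list)
        for qi, seq in enumerate(seqs):
            by_len[len(seq)].append((qi, "+", seq))
            by_len[len(seq)].append((qi, "-", _revcomp(seq)))
        total_len = int(self._iso_end[-1])
        for L, qs in by_len.items():
            codes = np.frombuffer(
                "".join(s for _, _, s in qs).encode("ascii"), dtype=np.uint8
            ).reshape(len(qs), L)
            g_parts, iso_parts, q_parts = [], [], []
            for row, (_qi, _strand, s) in enumerate(qs):
                for i in range(max_mismatches + 1):
                    p = i * k
                    if p + k > L:
                        break
                    entry = self._seeds.get(s[p : p + k])
                    if entry is None:
                        continue
                    gpos, isos = entry
                    g_parts.append(gpos - p)
                    iso_parts.append(isos)
                    q_parts.append(np.full(gpos.size, row, dtype=np.int64))
            if not g_parts:
                continue
            g = np.concatenate(g_parts)
            iso = np.concatenate(iso_parts)
            q = np.concatenate(q_parts)
            ok = (g >= self._iso_start[iso]) & (g + L <= self._iso_end[iso])
            g, iso, q = g[ok], iso[ok], q[ok]
            if g.size == 0:
                continue
            # (query row, global start) uniquely identifies a placement
            _, first = np.unique(q * (total_len + 1) + g, return_index=True)
            g, iso, q = g[first], iso[first], q[first]
            mm = self._verify(codes, g, q, L)
            keep = mm <= max_mismatches
            for gg, ii, qq, m in zip(g[keep], iso[keep], q[keep], mm[keep]):
                qi, strand, _ = qs[qq]
                results[qi].add(
                    (
                        self.genes[ii],
                        self.iso_ids[ii],
                        int(gg - self._iso_start[ii]),
                        strand,
                        int(m),
                    )
                )
        if best_stratum:
            for i, hits in enumerate(results):
                if hits:
                    best = min(h[4] for h in hits)
                    results[i] = {h for h in hits if h[4] == best}
        return [frozenset(r) for r in results]


def build_index(
    isoforms: Iterable[tuple[str, str, str]], seed_length: int = 6
) -> TranscriptomeIndex:
    """Build a :class:`TranscriptomeIndex` from (gene, isoform, seq) triples."""
    return TranscriptomeIndex(list(isoforms), seed_length=seed_length)


def map_library(
    reads: Iterable[tuple[str, str]],
    index: TranscriptomeIndex,
    max_mismatches: int = DEFAULT_MAX_MISMATCHES,
    best_stratum: bool = False,
) -> tuple[list[HitSet], MappingSummary]:
    """Map trimmed (read_id, seq) pairs; returns hit sets and a summary.

    Records with empty sequences are skipped and tallied, not fatal.
    Reads are processed in batches through the vectorized index path.
    """
    hitsets: list[HitSet] = []
    summary = MappingSummary()
    batch_ids: list[str] = []
    batch_seqs: list[str] = []

    def flush() -> None:
        for read_id, hits in zip(
            batch_ids, index.map_batch(batch_seqs, max_mismatches, best_stratum)
        ):
            if hits:
                summary.n_mapped += 1
            hitsets.append(HitSet(read_id=read_id, gene_hits=hits))
        batch_ids.clear()
        batch_seqs.clear()

    for read_id, seq in reads:
        if not seq:
            summary.n_skipped += 1
            continue
        summary.n_reads += 1
        batch_ids.append(read_id)
        batch_seqs.append(seq)
        if len(batch_seqs) >= 2000:
            flush()
    flush()
    logger.info(
        "map: %d reads, %d mapped (%.2f%%), %d skipped",
        summary.n_reads,
        summary.n_mapped,
        100.0 * summary.fraction_mapped,
        summary.n_skipped,
    )
    return hitsets, summary
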