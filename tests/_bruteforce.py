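"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's seed-index code path: placements are
found by scanning every offset of every isoform on both strands.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def naive_hits(
    read: str,
    isoforms: list[tuple[str, str, str]],
    max_mismatches: int,
) -> frozenset[tuple[str, str, int, str, int]]:
    """All placements of one read by sliding-window Hamming scan."""
    hits = set()
    for strand, s in (("+", read), ("-", revcomp(read))):
        L = len(s)
        for gene, iso_id, seq in isoforms:
            for start in range(len(seq) - L + 1):
                mm = sum(1 for a, b in zip(s, seq[start : start + L]) if a != b)
                if mm <= max_mismatches:
                    hits.add((gene, iso_id, start, strand, mm))
    return frozenset(hits)


def batch_hits(
    reads: list[str],
    isoforms: list[tuple[str, str, str]],
    max_mismatches: int,
    chunk: int = 1000,
) -> list[frozenset[tuple[str, str, int, str, int]]]:
    """Vectorized all-offsets Hamming scan for many same-length reads.

    One-hot encodes reads and every transcript window, then counts matches
    with a single matrix product per chunk and strand. Exhaustive over all
    offsets — no seeding involved.
    """
    L = len(reads[0])
    assert all(len(r) == L for r in reads)
    lut = np.full(256, 4, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        lut[b] = i

    windows = []
    window_meta = []
    for gene, iso_id, seq in isoforms:
        codes = lut[np.frombuffer(seq.encode(), dtype=np.uint8)]
        for start in range(len(seq) - L + 1):
            windows.append(codes[start : start + L])
            window_meta.append((gene, iso_id, start))
    wmat = np.stack(windows)  # (n_windows, L)
    w_onehot = np.zeros((wmat.shape[0], L * 4), dtype=np.float32)
    for b in range(4):
        w_onehot[:, b * L : (b + 1) * L] = wmat == b

    results: list[set] = [set() for _ in reads]
    for strand in ("+", "-"):
        seqs = reads if strand == "+" else [revcomp(r) for r in reads]
        codes = np.stack(
            [lut[np.frombuffer(s.encode(), dtype=np.uint8)] for s in seqs]
        )
        r_onehot = np.zeros((len(reads), L * 4), dtype=np.float32)
        for b in range(4):
            r_onehot[:, b * L : (b + 1) * L] = codes == b
        for lo in range(0, len(reads), chunk):
            hi = min(lo + chunk, len(reads))
            matches = r_onehot[lo:hi] @ w_onehot.T  # (chunk, n_windows)
            mm = L - matches
            rows, cols = np.nonzero(mm <= max_mismatches)
            for r, c in zip(rows, cols):
                gene, iso_id, start = window_meta[c]
                results[lo + r].add((gene, iso_id, start, strand, int(mm[r, c])))
    return [frozenset(s) for s in results]


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by exhaustive enumeration in exact rationals."""
    n1, n2 = a + b, c + d
    kk = a + c
    if n1 + n2 == 0 or kk == 0 or kk == n1 + n2:
        return Fraction(1)
    denom = comb(n1 + n2, kk)
    obs = Fraction(comb(n1, a) * comb(n2, c), denom)
    p = Fraction(0)
    for k in range(max(0, kk - n2), min(kk, n1) + 1):
        pk = Fraction(comb(n1, k) * comb(n2, kk - k), denom)
        if pk <= obs:
            p += pk
    return min(p, Fraction(1))
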