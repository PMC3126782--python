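"""Tissue-enhancement calling: two-sided Fisher's exact test on weighted
counts with Bonferroni family-wise control and a fold-ratio filter.

A gene is called enhanced toward a sample when its RPKM ratio is at least
``fold_threshold`` in that direction AND its two-sided Fisher p-value on the
2x2 table (gene reads vs remaining mapped reads in each sample) is below
``alpha / n_tests``. Zero RPKMs are replaced by a small pseudo-value before
ratios so log-ratios stay finite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import hypergeom

from chemoseq.quantify import CountTable, ExpressionTable

#: below this grand total the p-value is computed in exact integer arithmetic
_EXACT_TOTAL_LIMIT = 2000

#: relative slack when comparing floating-point table probabilities
_PMF_RELATIVE_SLACK = 1e-7

#: p-values are floored here, never reported as exactly zero
P_FLOOR = 1e-300


@dataclass(frozen=True)
class SignificancePolicy:
    """Family-wise significance and fold policy for one comparison set."""

    alpha: float = 0.05
    n_tests: int = 1
    fold_threshold: float = 2.0
    pseudo_rpkm: float = 0.10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if self.pseudo_rpkm <= 0:
            raise ValueError("pseudo_rpkm must be > 0")

    @property
    def threshold(self) -> float:
        return bonferroni_threshold(self.alpha, self.n_tests)


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test threshold alpha / n_tests controlling family-wise error."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n_tests < 1:
        raise ValueError("n_tests must be a positive integer")
    return alpha / n_tests


def _fisher_exact_int(a: int, b: int, c: int, d: int) -> float:
    # Exact integer path: probabilities share the denominator comb(M, K),
    # so only numerators comb(N1, k) * comb(N2, K - k) are compared.
    n1, n2 = a + b, c + d
    kk = a + c
    kmin, kmax = max(0, kk - n2), min(kk, n1)
    obs = math.comb(n1, a) * math.comb(n2, c)
    num = 0
    for k in range(kmin, kmax + 1):
        w = math.comb(n1, k) * math.comb(n2, kk - k)
        if w <= obs:
            num += w
    return num / math.comb(n1 + n2, kk)


def _fisher_log_space(a: int, b: int, c: int, d: int) -> float:
    n1, n2 = a + b, c + d
    m, kk = n1 + n2, a + c
    kmin, kmax = max(0, kk - n2), min(kk, n1)
    support = np.arange(kmin, kmax + 1)
    logp = hypergeom.logpmf(support, m, kk, n1)
    log_obs = hypergeom.logpmf(a, m, kk, n1)
    sel = logp <= log_obs + math.log1p(_PMF_RELATIVE_SLACK)
    return float(np.exp(logsumexp(logp[sel])))


def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher's exact p for the 2x2 table [[a, b], [c, d]].

    Probability-mass definition: the p-value sums the hypergeometric
    probabilities of every table with the same margins that is at most as
    probable as the observed one. Small tables are evaluated in exact
    integer arithmetic; large tables in log space with a 1e-7 relative
    slack on probability comparisons. Result is clipped to [1e-300, 1].
    """
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    m = a + b + c + d
    kk = a + c
    if m == 0 or kk == 0 or kk == m:
        return 1.0
    if m <= _EXACT_TOTAL_LIMIT:
        p = _fisher_exact_int(a, b, c, d)
    else:
        p = _fisher_log_space(a, b, c, d)
    return min(1.0, max(P_FLOOR, p))


def ratio_with_pseudo(
    rpkm_1: float, rpkm_2: float, pseudo_rpkm: float = 0.10
) -> tuple[float, float]:
    """(ratio, log2 ratio) after replacing zero RPKMs with the pseudo-value."""
    if rpkm_1 < 0 or rpkm_2 < 0:
        raise ValueError("RPKM values must be >= 0")
    r1 = rpkm_1 if rpkm_1 > 0 else pseudo_rpkm
    r2 = rpkm_2 if rpkm_2 > 0 else pseudo_rpkm
    ratio = r1 / r2
    return ratio, math.log2(ratio)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def run_comparison(
    counts: CountTable,
    expr: ExpressionTable,
    sample_1: str,
    sample_2: str,
    policy: SignificancePolicy,
) -> tuple[pd.DataFrame, dict]:
    """Enhancement calls for every gene between two samples.

    For each gene the 2x2 table is (rounded weighted gene reads, remaining
    mapped reads) in each sample; weighted counts are rounded half-up since
    the exact test needs integers. Returns a records DataFrame indexed by
    gene (columns rpkm_1, rpkm_2, ratio, log2_ratio, p_value, call) and a
    summary dict with per-direction totals.
    """
    if sample_1 == sample_2:
        raise ValueError("sample_1 and sample_2 must differ")
    for s in (sample_1, sample_2):
        if s not in counts.samples or s not in expr.samples:
            raise KeyError(f"sample {s!r} not present")

    n1 = _round_half_up(float(counts.totals[sample_1]))
    n2 = _round_half_up(float(counts.totals[sample_2]))
    threshold = policy.threshold

    genes = list(counts.genes)
    w1 = counts.weighted[sample_1]
    w2 = counts.weighted[sample_2]
    e1 = expr.rpkm[sample_1]
    e2 = expr.rpkm[sample_2]

    rows = []
    for g in genes:
        a = min(_round_half_up(float(w1[g])), n1)
        c = min(_round_half_up(float(w2[g])), n2)
        p = fisher_two_sided(a, n1 - a, c, n2 - c)
        ratio, log2_ratio = ratio_with_pseudo(
            float(e1[g]), float(e2[g]), policy.pseudo_rpkm
        )
        if p < threshold and ratio >= policy.fold_threshold:
            call = sample_1
        elif p < threshold and 1.0 / ratio >= policy.fold_threshold:
            call = sample_2
        else:
            call = "none"
        rows.append((g, float(e1[g]), float(e2[g]), ratio, log2_ratio, p, call))

    records = pd.DataFrame(
        rows,
        columns=["gene_id", "rpkm_1", "rpkm_2", "ratio", "log2_ratio", "p_value", "call"],
    ).set_index("gene_id")
    summary = {
        "sample_1": sample_1,
        "sample_2": sample_2,
        "n_genes": len(genes),
        "threshold": threshold,
        "fold_threshold": policy.fold_threshold,
        f"enhanced_{sample_1}": int((records["call"] == sample_1).sum()),
        f"enhanced_{sample_2}": int((records["call"] == sample_2).sum()),
        "enhanced_total": int((records["call"] != "none").sum()),
    }
    return records, summary


#: -log10(p) display cap applied by volcano_table
VOLCANO_LOG10_CAP = 300.0


def volcano_table(
    records: pd.DataFrame, families: pd.Series | None = None
) -> pd.DataFrame:
    """Plot-ready volcano table from comparison records.

    Columns: log2_ratio, neg_log10_p (capped at VOLCANO_LOG10_CAP, cap
    recorded in ``df.attrs``), significance class: "significant",
    "not_significant", or "chemosensory_significant" for called genes with
    a non-empty family tag in ``families``.
    """
    if records.empty:
        out = pd.DataFrame(columns=["log2_ratio", "neg_log10_p", "klass"])
        out.attrs["neg_log10_cap"] = VOLCANO_LOG10_CAP
        return out
    neg = -np.log10(records["p_value"].clip(lower=P_FLOOR))
    neg = neg.clip(upper=VOLCANO_LOG10_CAP)
    called = records["call"] != "none"
    klass = np.where(called, "significant", "not_significant")
    if families is not None:
        fam = families.reindex(records.index).fillna("")
        klass = np.where(called & (fam != ""), "chemosensory_significant", klass)
    out = pd.DataFrame(
        {
            "log2_ratio": records["log2_ratio"],
            "neg_log10_p": neg,
            "klass": klass,
        },
        index=records.index,
    )
    out.attrs["neg_log10_cap"] = VOLCANO_LOG10_CAP
    return out
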