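"""Cross-tissue and cross-sex synthesis of enhancement results.

Venn overlaps between enhanced gene sets, Pfam/family tallies, family
expression-profile matrices in a fixed report sample order, cross-sex
normalization factors (sensilla-count or reference-gene based), and
recovery scoring of enhancement calls against simulated ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from chemoseq.quantify import ExpressionTable
from chemoseq.simulate import GroundTruth

#: report order used for family profile matrices
PROFILE_SAMPLE_ORDER = ("FP", "FB", "FA", "MA", "MB", "MP")


@dataclass(frozen=True)
class NormalizationFactor:
    """A positive scale factor with its provenance.

    ``basis`` is one of {"sensilla_ratio", "orco_rpkm_ratio", "fixed"};
    numerator/denominator record the underlying quantities when known.
    ``rounded`` reports the conventional one-decimal form; ``factor`` keeps
    full precision.
    """

    factor: float
    basis: str
    numerator: float | None = None
    denominator: float | None = None

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValueError("factor must be positive")

    @property
    def rounded(self) -> float:
        return round(self.factor, 1)


# Female:male trichoid sensilla counts — AgOr-bearing sensilla on the antenna.
TRICHOID_NORMALIZATION = NormalizationFactor(
    factor=630 / 225, basis="sensilla_ratio", numerator=630, denominator=225
)
# Female:male grooved-peg sensilla fold difference (underlying counts unpublished).
GP_NORMALIZATION = NormalizationFactor(factor=4.2, basis="fixed")
# Female:male palp capitate-peg chemosensilla fold difference.
PALP_NORMALIZATION = NormalizationFactor(factor=4.0, basis="fixed")


def sensilla_factor(count_num: float, count_den: float) -> NormalizationFactor:
    """Normalization factor from two sensilla counts."""
    if count_num <= 0 or count_den <= 0:
        raise ValueError("sensilla counts must be positive")
    return NormalizationFactor(
        factor=count_num / count_den,
        basis="sensilla_ratio",
        numerator=count_num,
        denominator=count_den,
    )


@dataclass(frozen=True)
class VennResult:
    """Two-set overlap with exact and report-rounded percentages."""

    a_only: int
    shared: int
    b_only: int
    pct_shared_of_a: float
    pct_shared_of_b: float

    @property
    def pct_of_a_rounded(self) -> int:
        return int(round(self.pct_shared_of_a))

    @property
    def pct_of_b_rounded(self) -> int:
        return int(round(self.pct_shared_of_b))


def venn(set_a: set[str], set_b: set[str]) -> VennResult:
    """Pairwise overlap of two gene sets."""
    shared = len(set_a & set_b)
    return VennResult(
        a_only=len(set_a) - shared,
        shared=shared,
        b_only=len(set_b) - shared,
        pct_shared_of_a=100.0 * shared / len(set_a) if set_a else 0.0,
        pct_shared_of_b=100.0 * shared / len(set_b) if set_b else 0.0,
    )


def family_profile(
    expr: ExpressionTable,
    annotation: pd.DataFrame,
    family: str,
    sample_order: tuple[str, ...] = PROFILE_SAMPLE_ORDER,
) -> pd.DataFrame:
    """RPKM matrix for one gene family, rows ordered by gene ID.

    Values are the stored RPKMs untransformed; any heatmap rendering should
    use a scale monotone in RPKM.
    """
    members = annotation.index[annotation["family"] == family]
    if len(members) == 0:
        raise KeyError(f"family {family!r} not present in annotation")
    order = [s for s in sample_order if s in expr.samples]
    return expr.rpkm.loc[sorted(members), order]


def pfam_tally(
    enhanced_sets: dict[str, set[str]], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Per-Pfam-family enhancement tally ranked by representation.

    Genes without a Pfam best hit drop out. Columns: ``n_annotated`` plus
    one count per enhanced-set label; rows sorted by total enhanced count
    descending, ties broken by accession.
    """
    with_pfam = annotation[annotation["pfam"] != ""]
    if with_pfam.empty:
        return pd.DataFrame(
            columns=["n_annotated", *enhanced_sets.keys()]
        ).rename_axis("pfam")
    rows = []
    for acc, members in with_pfam.groupby("pfam").groups.items():
        member_set = set(members)
        row = {"pfam": acc, "n_annotated": len(member_set)}
        for label, genes in enhanced_sets.items():
            row[label] = len(member_set & genes)
        rows.append(row)
    out = pd.DataFrame(rows).set_index("pfam")
    total = out[list(enhanced_sets.keys())].sum(axis=1) if enhanced_sets else 0
    out = out.assign(_total=total).sort_values(
        ["_total", "pfam"], ascending=[False, True]
    )
    return out.drop(columns="_total")


def normalize_profile(
    rows: pd.DataFrame | pd.Series, factor: NormalizationFactor, sample: str | None = None
) -> pd.DataFrame:
    """Scale one sample's RPKMs by a normalization factor.

    For a DataFrame input, ``sample`` names the column to scale; a
    ``<sample>_scaled`` column is appended and the original retained. For a
    Series input the result has columns ``original`` and ``scaled``.
    """
    if isinstance(rows, pd.Series):
        return pd.DataFrame(
            {"original": rows, "scaled": rows * factor.factor}
        )
    if sample is None or sample not in rows.columns:
        raise KeyError("sample column to scale must be named and present")
    out = rows.copy()
    out[f"{sample}_scaled"] = out[sample] * factor.factor
    return out


def derive_orco_factor(
    expr: ExpressionTable, reference_gene: str, sample_num: str, sample_den: str
) -> NormalizationFactor:
    """Cross-sex factor from a reference gene's RPKM ratio between samples."""
    if reference_gene not in expr.genes:
        raise KeyError(f"reference gene {reference_gene!r} not in expression table")
    num = float(expr.rpkm.loc[reference_gene, sample_num])
    den = float(expr.rpkm.loc[reference_gene, sample_den])
    if den == 0:
        raise ValueError("reference gene has zero RPKM in denominator sample")
    return NormalizationFactor(
        factor=num / den, basis="orco_rpkm_ratio", numerator=num, denominator=den
    )


def library_summary(
    total_reads: list[float], transcriptome_mapped: list[float]
) -> dict:
    """Across-library sequencing summary.

    Returns the mean of the per-library total read counts in millions
    (one decimal) and the pooled transcriptome-mapped percentage (one
    decimal), with full-precision values alongside.
    """
    if len(total_reads) != len(transcriptome_mapped) or not total_reads:
        raise ValueError("need matching, nonempty read/mapped lists")
    mean_reads = sum(total_reads) / len(total_reads)
    pooled = 100.0 * sum(transcriptome_mapped) / sum(total_reads)
    return {
        "n_libraries": len(total_reads),
        "mean_reads": mean_reads,
        "mean_reads_millions_1dp": round(mean_reads / 1e6, 1),
        "pooled_mapped_pct": pooled,
        "pooled_mapped_pct_1dp": round(pooled, 1),
    }


@dataclass(frozen=True)
class RecoveryMetrics:
    """Caller performance against ground truth for one comparison."""

    sensitivity: float
    false_discovery_proportion: float
    direction_errors: int
    n_true: int
    n_called: int


def recovery_metrics(
    records: pd.DataFrame, truth: GroundTruth, comparison: str
) -> RecoveryMetrics:
    """Score enhancement calls against simulated truth.

    ``comparison`` names a truth column like "FA_vs_FB"; record calls equal
    to the first (tissue) sample count toward the "tissue" label and calls
    equal to the second toward "body". A call whose direction contradicts a
    non-none truth label is a direction error (and counts as false).
    """
    if comparison not in truth.enhanced_labels.columns:
        raise KeyError(f"comparison {comparison!r} not covered by truth")
    sample_1, _, sample_2 = comparison.partition("_vs_")
    labels = truth.enhanced_labels[comparison]
    if set(records.index) != set(labels.index):
        raise ValueError("gene IDs in records and truth do not match")
    labels = labels.loc[records.index]

    call_dir = records["call"].map({sample_1: "tissue", sample_2: "body"}).fillna("none")
    called = call_dir != "none"
    true_enhanced = labels != "none"
    correct = called & (call_dir == labels)
    direction_err = called & true_enhanced & (call_dir != labels)

    n_true = int(true_enhanced.sum())
    n_called = int(called.sum())
    n_correct = int(correct.sum())
    return RecoveryMetrics(
        sensitivity=n_correct / n_true if n_true else 0.0,
        false_discovery_proportion=(n_called - n_correct) / n_called if n_called else 0.0,
        direction_errors=int(direction_err.sum()),
        n_true=n_true,
        n_called=n_called,
    )
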