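import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chemoseq import (
    GP_NORMALIZATION,
    PALP_NORMALIZATION,
    TRICHOID_NORMALIZATION,
    NormalizationFactor,
    derive_orco_factor,
    family_profile,
    library_summary,
    normalize_profile,
    pfam_tally,
    recovery_metrics,
    sensilla_factor,
    venn,
)
from chemoseq.quantify import ExpressionTable
from chemoseq.simulate import GroundTruth


def expr_from(rpkm: dict, genes) -> ExpressionTable:
    df = pd.DataFrame(rpkm, index=genes)
    return ExpressionTable(
        rpkm=df,
        lengths=pd.Series(1000.0, index=genes),
        totals=pd.Series(1e6, index=df.columns),
    )


class TestVenn:
    def test_reported_palp_antennae_overlap(self):
        a = {f"g{i}" for i in range(1906)}
        b = {f"g{i}" for i in range(1158)} | {f"h{i}" for i in range(2023 - 1158)}
        v = venn(a, b)
        assert v.shared == 1158
        assert v.pct_of_a_rounded == 61

    def test_disjoint(self):
        v = venn({"a", "b"}, {"c"})
        assert (v.a_only, v.shared, v.b_only) == (2, 0, 1)
        assert v.pct_of_a_rounded == 0

    def test_identity(self):
        v = venn({"a", "b"}, {"a", "b"})
        assert v.shared == 2
        assert v.pct_of_a_rounded == v.pct_of_b_rounded == 100

    def test_empty_sets(self):
        v = venn(set(), set())
        assert v.pct_shared_of_a == 0.0

    @given(st.sets(st.integers(0, 50)), st.sets(st.integers(0, 50)))
    @settings(max_examples=100, deadline=None)
    def test_partition_identity(self, a, b):
        a = {str(x) for x in a}
        b = {str(x) for x in b}
        v = venn(a, b)
        assert v.a_only + v.shared == len(a)
        assert v.b_only + v.shared == len(b)


class TestFamilyProfile:
    def make(self):
        genes = ["g0", "g1", "g2"]
        ann = pd.DataFrame(
            {"length": [1000] * 3, "family": ["Or", "Or", ""], "pfam": [""] * 3},
            index=pd.Index(genes, name="gene_id"),
        )
        rpkm = {s: [float(i) for i in range(3)] for s in
                ("FP", "FB", "FA", "MA", "MB", "MP")}
        rpkm["FA"] = [50.0, 60.0, 1.0]
        return expr_from(rpkm, genes), ann

    def test_row_values_untransformed_and_ordered(self):
        expr, ann = self.make()
        mat = family_profile(expr, ann, "Or")
        assert list(mat.index) == ["g0", "g1"]
        assert list(mat.columns) == ["FP", "FB", "FA", "MA", "MB", "MP"]
        assert mat.loc["g0", "FA"] == 50.0

    def test_unknown_family_rejected(self):
        expr, ann = self.make()
        with pytest.raises(KeyError, match="not present"):
            family_profile(expr, ann, "Gr")

    def test_single_all_zero_gene(self):
        genes = ["g0"]
        ann = pd.DataFrame(
            {"length": [1000], "family": ["Obp"], "pfam": [""]},
            index=pd.Index(genes, name="gene_id"),
        )
        expr = expr_from({s: [0.0] for s in ("FP", "FB", "FA", "MA", "MB", "MP")},
                         genes)
        mat = family_profile(expr, ann, "Obp")
        assert mat.shape == (1, 6)
        assert (mat.values == 0).all()

    def test_enhanced_family_dominates_designed_column(self, tiny_world):
        # simulated Or genes are designed FA-enhanced; FA column must dominate
        truth = tiny_world["truth"]
        ann = tiny_world["annotation"]
        expr = ExpressionTable(
            rpkm=truth.abundance * 1e6,
            lengths=ann["length"].astype(float),
            totals=truth.abundance.sum() * 1e6,
        )
        mat = family_profile(expr, ann, "Or", sample_order=tuple(expr.samples))
        assert (mat["FA"] > mat["FB"]).all()


class TestPfamTally:
    def make_annotation(self):
        return pd.DataFrame(
            {
                "length": [1000] * 5,
                "family": [""] * 5,
                "pfam": ["PFX", "PFX", "PFX", "PFY", ""],
            },
            index=pd.Index([f"g{i}" for i in range(5)], name="gene_id"),
        )

    def test_direct_count(self):
        tally = pfam_tally({"FA-enhanced": {"g0", "g2"}}, self.make_annotation())
        assert tally.loc["PFX", "FA-enhanced"] == 2
        assert tally.loc["PFX", "n_annotated"] == 3
        assert tally.loc["PFY", "FA-enhanced"] == 0

    def test_no_pfam_annotation_empty(self):
        ann = self.make_annotation()
        ann["pfam"] = ""
        assert pfam_tally({"FA-enhanced": {"g0"}}, ann).empty

    def test_counts_bounded_by_family_size(self):
        tally = pfam_tally(
            {"FA-enhanced": {"g0", "g1", "g2", "g3", "g4"}}, self.make_annotation()
        )
        assert (tally["FA-enhanced"] <= tally["n_annotated"]).all()

    def test_column_sum_bounded_by_enhanced_set(self):
        enhanced = {"FA-enhanced": {"g0", "g3", "g4"}}  # g4 has no pfam
        tally = pfam_tally(enhanced, self.make_annotation())
        assert tally["FA-enhanced"].sum() <= len(enhanced["FA-enhanced"])

    def test_ranking_descending_total(self):
        tally = pfam_tally(
            {"FA-enhanced": {"g3"}, "MA-enhanced": {"g3", "g0"}},
            self.make_annotation(),
        )
        assert list(tally.index) == ["PFY", "PFX"]


class TestNormalization:
    def test_trichoid_factor_one_decimal(self):
        assert TRICHOID_NORMALIZATION.rounded == 2.8
        assert sensilla_factor(630, 225).rounded == 2.8

    def test_fixed_factors(self):
        assert GP_NORMALIZATION.factor == 4.2
        assert PALP_NORMALIZATION.factor == 4.0

    def test_orco_style_scaling_recovers_reference(self):
        nf = NormalizationFactor(916 / 186, basis="orco_rpkm_ratio",
                                 numerator=916, denominator=186)
        assert nf.rounded == 4.9
        scaled = normalize_profile(pd.Series({"orco": 186.0}), nf)
        assert scaled.loc["orco", "scaled"] == pytest.approx(916.0)
        # the paper-style one-decimal factor lands near the female value
        assert 186 * 4.9 == pytest.approx(911.4)

    def test_factor_one_identity(self):
        rows = pd.Series({"g0": 3.0, "g1": 7.0})
        out = normalize_profile(rows, NormalizationFactor(1.0, "fixed"))
        assert (out["scaled"] == out["original"]).all()

    def test_original_retained_in_dataframe_form(self):
        df = pd.DataFrame({"MA": [1.0, 2.0], "FA": [5.0, 6.0]}, index=["g0", "g1"])
        out = normalize_profile(df, NormalizationFactor(2.0, "fixed"), sample="MA")
        assert list(out.columns) == ["MA", "FA", "MA_scaled"]
        assert out["MA_scaled"].tolist() == [2.0, 4.0]

    def test_rank_preservation(self):
        rng = np.random.default_rng(0)
        vals = pd.Series(rng.lognormal(0, 2, size=30),
                         index=[f"g{i}" for i in range(30)])
        out = normalize_profile(vals, NormalizationFactor(3.7, "fixed"))
        assert (out["original"].rank() == out["scaled"].rank()).all()

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            NormalizationFactor(0.0, "fixed")

    def test_derive_orco_factor(self):
        genes = ["orco", "g1"]
        expr = expr_from({"FA": [916.0, 1.0], "MA": [186.0, 1.0]}, genes)
        nf = derive_orco_factor(expr, "orco", "FA", "MA")
        assert nf.rounded == 4.9
        assert nf.basis == "orco_rpkm_ratio"
        assert nf.factor == pytest.approx(916 / 186)

    def test_derive_equal_rpkms_gives_one(self):
        expr = expr_from({"FA": [10.0], "MA": [10.0]}, ["orco"])
        assert derive_orco_factor(expr, "orco", "FA", "MA").factor == 1.0

    def test_derive_constructed_fivefold(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        female = rng.lognormal(2, 1, size=10)
        expr = expr_from({"FA": female, "MA": female / 5.0}, genes)
        assert derive_orco_factor(expr, "g3", "FA", "MA").factor == pytest.approx(5.0)

    def test_derive_zero_denominator_rejected(self):
        expr = expr_from({"FA": [10.0], "MA": [0.0]}, ["orco"])
        with pytest.raises(ValueError, match="zero"):
            derive_orco_factor(expr, "orco", "FA", "MA")

    def test_derive_unknown_gene_rejected(self):
        expr = expr_from({"FA": [10.0], "MA": [1.0]}, ["orco"])
        with pytest.raises(KeyError):
            derive_orco_factor(expr, "nope", "FA", "MA")


class TestLibrarySummary:
    def test_requires_matching_lists(self):
        with pytest.raises(ValueError):
            library_summary([1.0], [1.0, 2.0])

    def test_mean_and_pooled_fraction(self):
        out = library_summary([2e6, 4e6], [1e6, 3e6])
        assert out["mean_reads_millions_1dp"] == 3.0
        assert out["pooled_mapped_pct_1dp"] == pytest.approx(66.7)


def make_truth(labels: dict, comparison="FA_vs_FB"):
    genes = list(labels)
    return GroundTruth(
        abundance=pd.DataFrame(index=genes),
        enhanced_labels=pd.DataFrame({comparison: pd.Series(labels)}),
        designed_folds=pd.DataFrame(index=genes),
    )


def make_records(calls: dict):
    return pd.DataFrame(
        {"call": pd.Series(calls), "p_value": 0.5, "ratio": 1.0,
         "log2_ratio": 0.0, "rpkm_1": 1.0, "rpkm_2": 1.0}
    ).rename_axis("gene_id")


class TestRecoveryMetrics:
    def test_perfect_caller(self):
        truth = make_truth({"g0": "tissue", "g1": "none", "g2": "body"})
        records = make_records({"g0": "FA", "g1": "none", "g2": "FB"})
        m = recovery_metrics(records, truth, "FA_vs_FB")
        assert m.sensitivity == 1.0
        assert m.false_discovery_proportion == 0.0
        assert m.direction_errors == 0

    def test_silent_caller(self):
        truth = make_truth({"g0": "tissue", "g1": "none"})
        records = make_records({"g0": "none", "g1": "none"})
        m = recovery_metrics(records, truth, "FA_vs_FB")
        assert m.sensitivity == 0.0
        assert m.false_discovery_proportion == 0.0

    def test_direction_error_counted(self):
        truth = make_truth({"g0": "tissue", "g1": "none"})
        records = make_records({"g0": "FB", "g1": "none"})
        m = recovery_metrics(records, truth, "FA_vs_FB")
        assert m.direction_errors == 1
        assert m.sensitivity == 0.0
        assert m.false_discovery_proportion == 1.0

    def test_gene_mismatch_rejected(self):
        truth = make_truth({"g0": "tissue"})
        records = make_records({"gX": "FA"})
        with pytest.raises(ValueError, match="do not match"):
            recovery_metrics(records, truth, "FA_vs_FB")

    def test_unknown_comparison_rejected(self):
        truth = make_truth({"g0": "tissue"})
        records = make_records({"g0": "FA"})
        with pytest.raises(KeyError, match="not covered"):
            recovery_metrics(records, truth, "MA_vs_MB")
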