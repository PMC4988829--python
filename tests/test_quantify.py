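import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailte import quantify as qt
from tailte.errors import ConfigError, SchemaError
from tailte.gene_models import GeneModel, IsoformEnd, Transcript


def tag_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "tail_length"])


class TestSummarizeTails:
    def test_basic_mean(self):
        (s,) = qt.summarize_tails(tag_df([("g1", 10), ("g1", 20), ("g1", 30)]), "s1")
        assert s.mean_tail_nt == 20 and s.tag_count == 3

    def test_reported_floor_at_4(self):
        (s,) = qt.summarize_tails(tag_df([("g1", 2), ("g1", 2)]), "s1")
        assert s.mean_tail_nt == 2 and s.reported_mean_nt == 4

    def test_pooled_isoform_mean(self):
        # one isoform contributes [10], another [30, 30]: pooled mean is 70/3
        (s,) = qt.summarize_tails(tag_df([("g1", 10), ("g1", 30), ("g1", 30)]), "s1")
        assert s.mean_tail_nt == pytest.approx(70 / 3)

    def test_zero_tag_gene_absent(self):
        out = qt.summarize_tails(tag_df([("g1", 10)]), "s1")
        assert [s.gene_id for s in out] == ["g1"]

    def test_histogram_totals(self):
        rng = np.random.default_rng(0)
        df = tag_df([("g1", int(t)) for t in rng.integers(0, 200, 500)])
        (s,) = qt.summarize_tails(df, "s1")
        assert sum(s.histogram) == s.tag_count == 500
        assert s.bin_width == 5

    def test_missing_column_raises(self):
        with pytest.raises(SchemaError):
            qt.summarize_tails(pd.DataFrame({"tail_length": [1]}), "s1")

    def test_pooled_mean_property(self):
        rng = np.random.default_rng(1)
        a = rng.integers(1, 100, 20)
        b = rng.integers(1, 100, 35)
        df = tag_df([("g1", int(t)) for t in np.concatenate([a, b])])
        (s,) = qt.summarize_tails(df, "s1")
        expected = (a.mean() * len(a) + b.mean() * len(b)) / (len(a) + len(b))
        assert s.mean_tail_nt == pytest.approx(expected)


class TestNormalizeExpression:
    def frame(self, rna, rpf):
        return pd.DataFrame(
            {"rna_count": rna, "rpf_count": rpf},
            index=pd.Index([f"g{i}" for i in range(len(rna))], name="gene_id"),
        )

    def test_rpm(self):
        out = qt.normalize_expression(
            self.frame([5], [5]), {"rna": 20, "rpf": 20}, pd.Series({"g0": 1000})
        )
        assert out["rna_rpm"].iloc[0] == pytest.approx(250_000)

    def test_rpkm(self):
        out = qt.normalize_expression(
            self.frame([10], [0]), {"rna": 1_000_000, "rpf": 1}, pd.Series({"g0": 2000})
        )
        assert out["rna_rpm"].iloc[0] == pytest.approx(10)
        assert out["rna_rpkm"].iloc[0] == pytest.approx(5)

    def test_rpm_conservation(self):
        rng = np.random.default_rng(2)
        counts = rng.integers(0, 1000, 50)
        out = qt.normalize_expression(
            self.frame(counts, counts),
            {"rna": counts.sum(), "rpf": counts.sum()},
            pd.Series(1000.0, index=[f"g{i}" for i in range(50)]),
        )
        assert out["rna_rpm"].sum() == pytest.approx(1e6, rel=1e-6)

    def test_zero_total_error(self):
        with pytest.raises(ConfigError):
            qt.normalize_expression(
                self.frame([1], [1]), {"rna": 0, "rpf": 1}, pd.Series({"g0": 100})
            )


class TestComputeTE:
    def test_basic(self):
        rec = qt.compute_te(20.0, 10.0, 100, rpf_total=1e6)
        assert rec.log2_te == pytest.approx(1.0)
        assert not rec.pseudocount_used and not rec.low_evidence

    def test_pseudocount(self):
        rec = qt.compute_te(0.0, 10.0, 0, rpf_total=1e6)
        # rpf RPM recomputed from a count of 1 at 1e6 total -> 1.0
        assert rec.log2_te == pytest.approx(np.log2(1.0 / 10.0))
        assert rec.pseudocount_used and rec.low_evidence

    def test_low_evidence_threshold(self):
        assert qt.compute_te(5.0, 5.0, 24, rpf_total=1e6).low_evidence
        assert not qt.compute_te(5.0, 5.0, 25, rpf_total=1e6).low_evidence

    def test_zero_rna_error(self):
        with pytest.raises(ConfigError):
            qt.compute_te(1.0, 0.0, 10, rpf_total=1e6)

    def test_hybrid_mode(self):
        # mutant footprints over wild-type RNA: rpf 4 RPM / rna 8 RPM -> -1
        expr = pd.DataFrame(
            {"rna_count": [99], "rpf_count": [4], "rna_rpm": [99.0], "rpf_rpm": [4.0]},
            index=pd.Index(["g0"], name="gene_id"),
        )
        out = qt.te_table(expr, rpf_total=1e6, rna_rpm=pd.Series({"g0": 8.0}))
        assert out["log2_te"].iloc[0] == pytest.approx(-1.0)

    def test_hybrid_reduces_to_standard_when_identical(self):
        expr = pd.DataFrame(
            {
                "rna_count": [10, 20],
                "rpf_count": [30, 40],
                "rna_rpm": [10.0, 20.0],
                "rpf_rpm": [30.0, 40.0],
            },
            index=pd.Index(["g0", "g1"], name="gene_id"),
        )
        std = qt.te_table(expr, rpf_total=1e6)
        hyb = qt.te_table(expr, rpf_total=1e6, rna_rpm=expr["rna_rpm"])
        pd.testing.assert_frame_equal(std, hyb)


class TestMedianCenter:
    def test_odd_n(self):
        centered, const = qt.median_center(
            pd.Series({"a": 0.6, "b": 1.0, "c": 3.0}), ["a", "b", "c"]
        )
        assert const == 1.0
        assert centered.tolist() == pytest.approx([-0.4, 0.0, 2.0])

    def test_all_equal(self):
        centered, _ = qt.median_center(pd.Series({"a": 2.0, "b": 2.0}), ["a", "b"])
        assert (centered == 0).all()

    def test_even_n_midpoint(self):
        vals = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        centered, const = qt.median_center(vals, list(vals.index))
        assert const == 2.5
        assert centered.median() == 0.0

    def test_empty_set_error(self):
        with pytest.raises(ConfigError):
            qt.median_center(pd.Series({"a": 1.0}), [])

    def test_centering_subset_only(self):
        vals = pd.Series({"a": 1.0, "b": 5.0, "c": 100.0})
        centered, const = qt.median_center(vals, ["a", "b"])
        assert const == 3.0 and centered["c"] == 97.0

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=30))
    def test_idempotent(self, values):
        s = pd.Series({f"g{i}": v for i, v in enumerate(values)})
        once, _ = qt.median_center(s, list(s.index))
        twice, const2 = qt.median_center(once, list(s.index))
        assert const2 == pytest.approx(0.0, abs=1e-12)
        pd.testing.assert_series_equal(once, twice)


def _random_tables(rng, n=500, samples=("s1", "s2", "s3")):
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    rna = pd.DataFrame(
        rng.choice([0.0, 5.0, 10.0, 50.0], size=(n, len(samples))), index=idx, columns=samples
    )
    rpf = pd.DataFrame(
        rng.choice([0.0, 0.5, 10.0, 40.0], size=(n, len(samples))), index=idx, columns=samples
    )
    tags = pd.DataFrame(
        rng.choice([0, 99, 100, 500], size=(n, len(samples))), index=idx, columns=samples
    )
    return rna, rpf, tags


class TestApplyCutoffs:
    def test_single_boundaries(self):
        idx = pd.Index(["g0", "g1"], name="gene_id")
        rna = pd.DataFrame({"s": [10.0, 10.0]}, index=idx)
        rpf = pd.DataFrame({"s": [0.1, 0.1]}, index=idx)
        tags = pd.DataFrame({"s": [99, 100]}, index=idx)
        assert qt.apply_cutoffs("single", rna, rpf, tags) == {"g1"}

    def test_pairwise_rpf_rule(self):
        idx = pd.Index(["g0", "g1"], name="gene_id")
        rna = pd.DataFrame({"a": [10.0, 10.0], "b": [10.0, 10.0]}, index=idx)
        rpf = pd.DataFrame({"a": [12.0, 12.0], "b": [0.0, 0.5]}, index=idx)
        tags = pd.DataFrame({"a": [100, 100], "b": [100, 100]}, index=idx)
        assert qt.apply_cutoffs("pairwise", rna, rpf, tags) == {"g1"}

    def test_multistage_rule(self):
        idx = pd.Index(["g0", "g1", "g2"], name="gene_id")
        rna = pd.DataFrame(10.0, index=idx, columns=["a", "b", "c"])
        rpf = pd.DataFrame(
            {"a": [10.0, 5.0, 10.0], "b": [0.5, 5.0, 0.5], "c": [0.5, 5.0, 0.0]},
            index=idx,
        )
        assert qt.apply_cutoffs("multistage", rna, rpf) == {"g0"}

    def test_random_brute_force(self):
        rng = np.random.default_rng(3)
        rna, rpf, tags = _random_tables(rng)
        got = qt.apply_cutoffs(
            "pairwise", rna[["s1", "s2"]], rpf[["s1", "s2"]], tags[["s1", "s2"]]
        )
        expect = set()
        for g in rna.index:
            r1, r2 = rna.loc[g, "s1"], rna.loc[g, "s2"]
            p1, p2 = rpf.loc[g, "s1"], rpf.loc[g, "s2"]
            t1, t2 = tags.loc[g, "s1"], tags.loc[g, "s2"]
            if (
                t1 >= 100
                and t2 >= 100
                and r1 >= 10
                and r2 >= 10
                and ((p1 >= 10 and p2 > 0) or (p2 >= 10 and p1 > 0))
            ):
                expect.add(g)
        assert got == expect

    def test_multistage_brute_force(self):
        rng = np.random.default_rng(4)
        rna, rpf, _ = _random_tables(rng)
        got = qt.apply_cutoffs("multistage", rna, rpf)
        expect = {
            g
            for g in rna.index
            if (rna.loc[g] >= 10).all()
            and (rpf.loc[g] >= 10).any()
            and (rpf.loc[g] > 0).all()
        }
        assert got == expect

    def test_bad_mode(self):
        rna = pd.DataFrame({"s": [1.0]})
        with pytest.raises(ConfigError):
            qt.apply_cutoffs("weekly", rna, rna)


class TestFoldChanges:
    def test_tail_change_columns(self):
        te_a = pd.Series({"g0": 1.0, "g1": 0.0})
        te_b = pd.Series({"g0": 3.0, "g1": 0.0})
        ta = pd.Series({"g0": 40.0, "g1": 40.0})
        tb = pd.Series({"g0": 60.0, "g1": 40.0})
        df = qt.compute_fold_changes(te_a, te_b, ta, tb, {"g0", "g1"})
        assert df.loc["g0", "log2_fc_tail"] == pytest.approx(np.log2(1.5))
        assert df.loc["g0", "delta_tail_nt"] == pytest.approx(20.0)
        # raw fcs are (2, 0); centering constant is the midpoint median 1.0
        assert df.attrs["te_centering_constant"] == pytest.approx(1.0)
        assert df["log2_fc_te"].median() == pytest.approx(0.0)

    def test_identical_stages(self):
        te = pd.Series({"g0": 1.0, "g1": 2.0, "g2": 0.5})
        tails = pd.Series({"g0": 30.0, "g1": 50.0, "g2": 70.0})
        df = qt.compute_fold_changes(te, te, tails, tails, set(te.index))
        assert (df["log2_fc_te"] == 0).all()
        assert (df["log2_fc_tail"] == 0).all()
        assert (df["delta_tail_nt"] == 0).all()

    def test_unreliable_tail_flag(self):
        te = pd.Series({"g0": 1.0, "g1": 1.0, "g2": 1.0})
        ta = pd.Series({"g0": 7.9, "g1": 8.0, "g2": 50.0})
        tb = pd.Series({"g0": 20.0, "g1": 20.0, "g2": 7.0})
        df = qt.compute_fold_changes(te, te, ta, tb, set(te.index))
        assert df["unreliable_tail"].tolist() == [True, False, True]

    def test_missing_gene_excluded(self):
        te_a = pd.Series({"g0": 1.0, "g1": 1.0})
        te_b = pd.Series({"g0": 1.0})
        tails = pd.Series({"g0": 30.0, "g1": 30.0})
        df = qt.compute_fold_changes(te_a, te_b, tails, tails, {"g0", "g1"})
        assert list(df.index) == ["g0"]


class TestAssignTags:
    def make_model(self, gene, end_pos, chrom="chr1", strand="+"):
        t = Transcript(gene, gene + ".t", chrom, strand, 0, 1000, 100, 900)
        return GeneModel(
            gene_id=gene,
            transcript=t,
            isoform_ends=(IsoformEnd(end_pos, 5),),
            final_3p_end=end_pos,
        )

    def test_within_tolerance(self):
        models = [self.make_model("g1", 500), self.make_model("g2", 900)]
        tags = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1", "chr1"],
                "site": [505, 520, 898],
                "strand": ["+", "+", "+"],
                "tail_length": [30, 30, 30],
                "sample": ["s", "s", "s"],
            }
        )
        out = qt.assign_tags_to_genes(tags, models, tolerance_nt=10)
        assert out["gene_id"].tolist() == ["g1", "g2"]
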