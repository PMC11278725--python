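"""Depth aggregation, normalization, and copy-number score properties."""

import io
import warnings

import numpy as np
import pandas as pd
import pytest

from genedepth.depth_io import DepthTable
from genedepth.fixtures import generate_tblout_lines
from genedepth.hmmer import HitTable, parse_tblout
from genedepth.linking import contig_linker, link_hits
from genedepth.scoring import (
    ScoreTable,
    ScoringError,
    TaxonomyTable,
    aggregate_depth,
    compute_scores,
    normalize,
    scores_to_long,
)


def make_depths(rows, samples=("S1", "S2")):
    df = pd.DataFrame(rows, columns=list(samples)).astype(float)
    df.index = [f"c{i + 1}" for i in range(len(rows))]
    return DepthTable(df=df, mode="contig")


def make_hits(records, source="S.faa"):
    return parse_tblout(
        io.StringIO(generate_tblout_lines(records)), source_file=source
    )


def linked(records, source="S.faa"):
    return link_hits(make_hits(records, source), contig_linker)


class TestAggregateDepth:
    def test_single_feature_vector(self):
        depths = make_depths([[5.0, 0.5]])
        agg = aggregate_depth(linked([("c1_1", "K1", 99.0, 1e-9)]), depths)
        assert agg.tolist() == [5.0, 0.5]

    def test_per_feature_vs_per_gene_on_multicopy(self):
        depths = make_depths([[5.0, 5.0]])
        hits = linked([("c1_1", "K1", 99.0, 1e-9), ("c1_2", "K1", 98.0, 1e-9)])
        assert aggregate_depth(hits, depths, "per_feature").tolist() == [5.0, 5.0]
        assert aggregate_depth(hits, depths, "per_gene").tolist() == [10.0, 10.0]

    def test_no_hits_gives_zero_vector(self):
        depths = make_depths([[5.0, 0.5]])
        agg = aggregate_depth(linked([]), depths)
        assert agg.tolist() == [0.0, 0.0]

    def test_unknown_feature_listed(self):
        depths = make_depths([[5.0, 0.5]])
        with pytest.raises(ScoringError, match="c9"):
            aggregate_depth(linked([("c9_1", "K1", 99.0, 1e-9)]), depths)


class TestNormalize:
    def test_elementwise_ratio(self):
        t = pd.Series([5.0, 1.0], index=["S1", "S2"])
        c = pd.Series([2.5, 1.0], index=["S1", "S2"])
        assert normalize(t, c).tolist() == [2.0, 1.0]

    def test_self_normalization_is_ones(self):
        v = pd.Series([3.0, 7.0], index=["S1", "S2"])
        assert normalize(v, v.copy()).tolist() == [1.0, 1.0]

    def test_zero_control_is_undefined_with_warning(self):
        t = pd.Series([5.0, 1.0], index=["S1", "S2"])
        c = pd.Series([2.5, 0.0], index=["S1", "S2"])
        with pytest.warns(UserWarning, match="S2"):
            out = normalize(t, c)
        assert out["S1"] == 2.0
        assert np.isnan(out["S2"])

    def test_mismatched_axes_error(self):
        with pytest.raises(ScoringError):
            normalize(
                pd.Series([1.0], index=["S1"]), pd.Series([1.0], index=["S2"])
            )


def two_taxon_setup():
    """c1 in taxon A (depth 4), c2 in taxon B (depth 4); query hits only c1."""
    depths = make_depths([[4.0], [4.0]], samples=("S1",))
    hits = make_hits([("c1_1", "K00927", 99.0, 1e-9)])
    control = make_hits([("c1_2", "CTRL", 99.0, 1e-9), ("c2_1", "CTRL", 99.0, 1e-9)])
    tax = TaxonomyTable(
        pd.DataFrame({"phylum": ["A", "B"]}, index=["c1", "c2"])
    )
    return depths, hits, control, tax


class TestComputeScores:
    def test_unstratified_ratio(self):
        depths, hits, control, _ = two_taxon_setup()
        table = compute_scores(["K00927"], hits, control, depths, contig_linker)
        assert table.df.loc["K00927", "S1"] == 0.5  # 4 / (4+4)

    def test_stratified_global_denominator_sums_to_total(self):
        depths, hits, control, tax = two_taxon_setup()
        table = compute_scores(
            ["K00927"], hits, control, depths, contig_linker, taxonomy=tax
        )
        assert table.df.loc[("K00927", "A"), "S1"] == 0.5
        assert table.df.loc[("K00927", "B"), "S1"] == 0.0
        assert table.query_row("K00927")["S1"] == 0.5

    def test_per_taxon_denominator(self):
        depths, hits, control, tax = two_taxon_setup()
        table = compute_scores(
            ["K00927"], hits, control, depths, contig_linker,
            taxonomy=tax, denominator="per_taxon",
        )
        assert table.df.loc[("K00927", "A"), "S1"] == 1.0
        assert table.df.loc[("K00927", "B"), "S1"] == 0.0

    def test_unknown_query_zero_row_with_warning(self):
        depths, hits, control, _ = two_taxon_setup()
        with pytest.warns(UserWarning, match="K99999"):
            table = compute_scores(["K00927", "K99999"], hits, control, depths, contig_linker)
        assert table.df.loc["K99999", "S1"] == 0.0

    def test_unclassified_features_kept_for_additivity(self):
        depths, hits, control, _ = two_taxon_setup()
        tax = TaxonomyTable(pd.DataFrame({"phylum": ["A"]}, index=["c1"]))  # c2 unknown
        table = compute_scores(
            ["K00927"], hits, control, depths, contig_linker, taxonomy=tax
        )
        assert ("K00927", "Unclassified") in table.df.index
        assert table.query_row("K00927")["S1"] == 0.5

    def test_empty_control_errors(self):
        depths, hits, _, _ = two_taxon_setup()
        with pytest.raises(ScoringError, match="control"):
            compute_scores(["K00927"], hits, HitTable(), depths, contig_linker)


class TestScoreProperties:
    def test_self_normalization_identity(self, small_community):
        """Scoring the control against itself gives exactly 1.0 everywhere."""
        from genedepth.workflow import parse_tblout_files
        from genedepth.depth_io import read_contig_depths

        manifest, _ = small_community
        depths = read_contig_depths(manifest.contig_depth_files, manifest.header_rule)
        all_hits = parse_tblout_files(manifest.contig_tblouts)
        control = HitTable(all_hits.df[all_hits.df.query_id == manifest.control_id])
        table = compute_scores(
            [manifest.control_id], control, control, depths, contig_linker
        )
        assert (table.df.to_numpy() == 1.0).all()

    def test_depth_scale_invariance(self):
        """Multiplying one sample's depths by c leaves its scores unchanged."""
        depths, hits, control, _ = two_taxon_setup()
        base = compute_scores(["K00927"], hits, control, depths, contig_linker)
        scaled = DepthTable(df=depths.df * 17.3, mode="contig")
        rescored = compute_scores(["K00927"], hits, control, scaled, contig_linker)
        assert abs(
            base.df.loc["K00927", "S1"] - rescored.df.loc["K00927", "S1"]
        ) < 1e-12

    def test_adding_hit_on_unhit_feature_never_decreases(self):
        depths, hits, control, _ = two_taxon_setup()
        before = compute_scores(["K00927"], hits, control, depths, contig_linker)
        more = make_hits(
            [("c1_1", "K00927", 99.0, 1e-9), ("c2_9", "K00927", 99.0, 1e-9)]
        )
        after = compute_scores(["K00927"], more, control, depths, contig_linker)
        assert (after.df.to_numpy() >= before.df.to_numpy()).all()


class TestScoresToLong:
    def test_round_trip_unstratified(self):
        df = pd.DataFrame([[0.5, 1.5]], index=pd.Index(["K1"], name="query"), columns=["S1", "S2"])
        long = scores_to_long(ScoreTable(df=df))
        assert len(long) == 2
        wide = long.pivot(index="query", columns="sample", values="score")
        assert wide.loc["K1"].tolist() == [0.5, 1.5]

    def test_empty_table_no_records(self):
        df = pd.DataFrame(columns=["S1"], index=pd.Index([], name="query"), dtype=float)
        assert len(scores_to_long(ScoreTable(df=df))) == 0

    def test_undefined_cells_omitted_with_count(self):
        df = pd.DataFrame(
            [[0.5, np.nan]], index=pd.Index(["K1"], name="query"), columns=["S1", "S2"]
        )
        with pytest.warns(UserWarning, match="1 undefined"):
            long = scores_to_long(ScoreTable(df=df))
        assert len(long) == 1
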