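"""Chamber classification, QC filter semantics, channel z-scoring, alignment."""

import numpy as np
import pandas as pd
import pytest

from cidmem import ConfigurationError
from cidmem.preprocess import (AlignmentError, ManifestParseError,
                               ZeroVarianceError, align_inputs, apply_filters,
                               classify_chambers, filter_cells, filter_genes,
                               zscore_channels)


def manifest_row(chamber, start, end, sequenced=True):
    return {"chamber_id": chamber, "start_composition": start,
            "end_composition": end, "run_id": "run1", "sequenced": sequenced}


class TestClassifyChambers:
    def test_reproduces_printed_bookkeeping(self, default_classified):
        _, report = default_classified
        assert report["n_total"] == 336
        assert report["n_excluded"] == 46
        assert report["n_retained"] == 290
        c = report["counts"]
        assert (c["NK"], c["cancer"], c["CID"], c["CID_NK_only"]) == (77, 71, 132, 10)
        assert c["excluded_empty"] == 4
        assert c["excluded_cancer_to_empty"] == 8
        assert c["excluded_nk_to_empty"] == 10
        assert c["excluded_nk_start_cid"] == 2
        assert c["excluded_cid_to_cancer"] == 22

    def test_partition_every_chamber_exactly_one_category(self, default_classified):
        classified, report = default_classified
        assert classified["category"].notna().all()
        assert sum(report["counts"].values()) == report["n_total"]

    def test_empty_manifest_gives_empty_report(self):
        empty = pd.DataFrame(columns=["chamber_id", "start_composition",
                                      "end_composition"])
        classified, report = classify_chambers(empty)
        assert len(classified) == 0
        assert report["n_total"] == 0 and report["n_excluded"] == 0

    def test_unknown_composition_label_names_the_row(self):
        bad = pd.DataFrame([manifest_row("CH1", "NK", "NK"),
                            manifest_row("CH2", "blob", "NK")])
        with pytest.raises(ManifestParseError, match="CH2"):
            classify_chambers(bad)

    def test_unclassifiable_combination_names_the_row(self):
        bad = pd.DataFrame([manifest_row("CH9", "cancer", "CID")])
        with pytest.raises(ManifestParseError, match="CH9"):
            classify_chambers(bad)

    @pytest.mark.parametrize("start,end,expected", [
        ("empty", "empty", "excluded_empty"),
        ("cancer", "empty", "excluded_cancer_to_empty"),
        ("NK", "empty", "excluded_nk_to_empty"),
        ("NK", "CID", "excluded_nk_start_cid"),
        ("CID", "cancer", "excluded_cid_to_cancer"),
        ("NK", "NK", "NK"),
        ("cancer", "cancer", "cancer"),
        ("CID", "CID", "CID"),
        ("CID", "NK", "CID_NK_only"),
    ])
    def test_each_rule(self, start, end, expected):
        classified, _ = classify_chambers(
            pd.DataFrame([manifest_row("CH1", start, end)]))
        assert classified["category"].iloc[0] == expected


class TestCellFilter:
    def test_boundary_is_strict_less_than(self):
        # cell A: exactly 3 expressed genes (kept at threshold 3);
        # cell B: 2 expressed genes (dropped)
        expr = pd.DataFrame(
            {"A": [1.0, 2.0, 0.5, 0.0], "B": [1.0, 0.0, 3.0, 0.0]},
            index=list("wxyz"))
        out = filter_cells(expr, min_expressed_genes=3)
        assert list(out.columns) == ["A"]

    def test_matches_brute_force_count(self, make_expression):
        expr = make_expression(n_genes=30, n_cells=25, sparsity=0.6)
        thr = 12
        out = filter_cells(expr, thr)
        survivors = [c for c in expr.columns
                     if sum(1 for v in expr[c] if v > 0) >= thr]
        assert list(out.columns) == survivors

    def test_idempotent(self, make_expression):
        expr = make_expression()
        once = filter_cells(expr, 5)
        twice = filter_cells(once, 5)
        pd.testing.assert_frame_equal(once, twice)

    def test_negative_threshold_rejected(self, make_expression):
        with pytest.raises(ConfigurationError):
            filter_cells(make_expression(), -1)


class TestGeneFilter:
    def test_value_boundary_is_strict(self):
        # value exactly 5.0 in 10 cells -> not "> 5" -> removed;
        # 5.1 in 10 cells -> retained
        cells = [f"c{i}" for i in range(12)]
        expr = pd.DataFrame(
            [[5.0] * 10 + [0.0] * 2, [5.1] * 10 + [0.0] * 2],
            index=["at_thr", "above_thr"], columns=cells)
        out = filter_genes(expr, min_value=5, min_cells=10)
        assert list(out.index) == ["above_thr"]

    def test_cell_count_boundary_is_inclusive(self):
        cells = [f"c{i}" for i in range(12)]
        expr = pd.DataFrame(
            [[6.0] * 10 + [0.0] * 2, [6.0] * 9 + [0.0] * 3],
            index=["ten_cells", "nine_cells"], columns=cells)
        out = filter_genes(expr, min_value=5, min_cells=10)
        assert list(out.index) == ["ten_cells"]

    def test_matches_brute_force_double_loop(self, make_expression):
        expr = make_expression(n_genes=40, n_cells=30, sparsity=0.5)
        out = filter_genes(expr, min_value=5, min_cells=4)
        survivors = []
        for g in expr.index:
            n = 0
            for c in expr.columns:
                if expr.loc[g, c] > 5:
                    n += 1
            if n >= 4:
                survivors.append(g)
        assert list(out.index) == survivors

    def test_idempotent(self, make_expression):
        expr = make_expression()
        once = filter_genes(expr, 5, 3)
        pd.testing.assert_frame_equal(once, filter_genes(once, 5, 3))


class TestFilterOrder:
    def test_cells_first_then_genes_differs_from_reverse(self):
        """The documented order (cells, then genes) is observable: a crafted
        matrix gives different survivors if genes were filtered first."""
        cells = [f"c{i}" for i in range(12)]
        # low-complexity cell c0 carries the only high values of gene "dep"
        data = pd.DataFrame(0.0, index=["dep"] + [f"g{i}" for i in range(6)],
                            columns=cells)
        data.loc["dep", cells[:10]] = 6.0
        for g in data.index[1:]:
            data.loc[g, cells[1:]] = 6.0
        # cells need >= 2 expressed genes: c0 expresses only "dep" -> dropped
        ordered = apply_filters(data, min_expressed_genes=2, min_value=5,
                                min_cells=10)
        reverse = filter_cells(filter_genes(data, 5, 10), 2)
        assert "dep" not in ordered.index      # loses c0, only 9 cells > 5
        assert "dep" in reverse.index
        assert not ordered.equals(reverse)


class TestZscore:
    def test_closed_form_three_values(self):
        df = pd.DataFrame({"cell_id": list("abc"),
                           "nk_channel": [1.0, 2.0, 3.0],
                           "cancer_channel": [10.0, 20.0, 30.0]})
        out = zscore_channels(df)
        assert np.allclose(out["nk_channel"], [-1, 0, 1])
        assert np.allclose(out["cancer_channel"], [-1, 0, 1])

    def test_normalization_contract(self, rng):
        df = pd.DataFrame({"nk_channel": rng.normal(5, 3, 50),
                           "cancer_channel": rng.gamma(2, 2, 50)})
        out = zscore_channels(df)
        for ch in ("nk_channel", "cancer_channel"):
            assert abs(out[ch].mean()) < 1e-12
            assert abs(out[ch].std(ddof=1) - 1) < 1e-12

    def test_constant_channel_error_names_channel(self):
        df = pd.DataFrame({"nk_channel": [1.0, 1.0, 1.0],
                           "cancer_channel": [1.0, 2.0, 3.0]})
        with pytest.raises(ZeroVarianceError, match="nk_channel"):
            zscore_channels(df)


class TestAlignInputs:
    def test_full_fixture_pairs_102_sequenced_doublets(
            self, default_bundle, default_classified):
        classified, _ = default_classified
        bundle = align_inputs(default_bundle.expression,
                              default_bundle.distances, classified)
        assert bundle.n_cid == 102
        assert list(bundle.expression.columns) == list(bundle.distances.index)

    def test_unknown_distance_row_ignored_with_warning(
            self, default_bundle, default_classified, caplog):
        classified, _ = default_classified
        extra = default_bundle.distances.copy()
        extra.loc["CH9999"] = extra.iloc[0]
        with caplog.at_level("WARNING", logger="cidmem.preprocess"):
            bundle = align_inputs(default_bundle.expression, extra, classified)
        assert bundle.n_cid == 102
        assert any("CH9999" in r.message or "not sequenced doublets" in r.message
                   for r in caplog.records)

    def test_row_order_invariance(self, default_bundle, default_classified, rng):
        classified, _ = default_classified
        shuffled_expr = default_bundle.expression.sample(
            frac=1, axis=1, random_state=0)
        shuffled_dist = default_bundle.distances.sample(frac=1, random_state=1)
        a = align_inputs(default_bundle.expression, default_bundle.distances,
                         classified)
        b = align_inputs(shuffled_expr, shuffled_dist, classified)
        pd.testing.assert_frame_equal(a.expression, b.expression)
        pd.testing.assert_frame_equal(a.distances, b.distances)

    def test_zero_overlap_is_fatal(self, default_bundle, default_classified):
        classified, _ = default_classified
        renamed = default_bundle.distances.copy()
        renamed.index = [f"X{i}" for i in range(len(renamed))]
        with pytest.raises(AlignmentError):
            align_inputs(default_bundle.expression, renamed, classified)

    def test_doublet_missing_distance_dropped(self, default_bundle,
                                              default_classified):
        classified, _ = default_classified
        full = align_inputs(default_bundle.expression,
                            default_bundle.distances, classified)
        dropped_id = full.distances.index[0]
        trimmed = default_bundle.distances.drop(index=dropped_id)
        bundle = align_inputs(default_bundle.expression, trimmed, classified)
        assert bundle.n_cid == 101
        assert dropped_id in bundle.dropped_expression
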