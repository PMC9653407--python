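"""Correlation map, memory-gene retention, module clustering, frame policy."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cidmem import ConfigurationError
from cidmem.correlation import (DistanceCorrelationMap, ModuleClusterer,
                                VariableGeneSelector,
                                correlate_distance_expression,
                                select_memory_genes, select_variable_genes,
                                timepoint_policy)

FRAMES_16 = ["T0", "T1", "T2", "T3", "T4", "T5", "T5p", "T6", "T7", "T8",
             "T9", "T10", "T10p", "T11", "T12", "T13"]


class TestTimepointPolicy:
    def test_default_selects_13_pre_exchange_hours(self):
        tps = timepoint_policy(FRAMES_16)
        assert len(tps) == 13
        assert tps[0] == "T1" and tps[-1] == "T13"
        assert "T0" not in tps and "T5p" not in tps and "T10p" not in tps
        assert "T5" in tps and "T10" in tps

    def test_post_exchange_swaps_duplicate_frames(self):
        tps = timepoint_policy(FRAMES_16, "post-exchange")
        assert "T5p" in tps and "T10p" in tps
        assert "T5" not in tps and "T10" not in tps
        assert len(tps) == 13

    def test_include_t0(self):
        tps = timepoint_policy(FRAMES_16, "include-T0")
        assert tps[0] == "T0" and len(tps) == 14

    def test_missing_frame_error_names_it(self):
        frames = [f for f in FRAMES_16 if f != "T7"]
        with pytest.raises(ValueError, match="T7"):
            timepoint_policy(frames)

    def test_unknown_policy_rejected(self):
        with pytest.raises(ConfigurationError):
            timepoint_policy(FRAMES_16, "whatever")


class TestVariableGeneSelection:
    def test_k_equals_total_is_identity(self, make_expression):
        expr = make_expression(n_genes=10)
        assert select_variable_genes(expr, 10) == list(expr.index)

    def test_dominant_gene_selected_first(self, rng):
        expr = pd.DataFrame(rng.normal(10, 0.1, size=(5, 30)).clip(0),
                            index=list("abcde"))
        expr.loc["c"] = rng.normal(10, 9, 30).clip(0)
        assert select_variable_genes(expr, 1) == ["c"]

    def test_matches_brute_force_sort(self, make_expression):
        expr = make_expression(n_genes=60, n_cells=20)
        k = 25
        var = {g: np.var(np.log1p(expr.loc[g].to_numpy()), ddof=1)
               for g in expr.index}
        expected = set(sorted(var, key=lambda g: (-var[g], g))[:k])
        assert set(select_variable_genes(expr, k)) == expected

    def test_oversized_k_warns_and_keeps_all(self, make_expression):
        expr = make_expression(n_genes=8)
        with pytest.warns(UserWarning, match="exceeds"):
            got = select_variable_genes(expr, 100)
        assert got == list(expr.index)

    def test_sklearn_transform_selects_columns(self, make_expression):
        expr = make_expression(n_genes=12, n_cells=9)
        sel = VariableGeneSelector(n_top=4).fit(expr.T)
        out = sel.transform(expr.T)
        assert out.shape == (9, 4)
        assert list(out.columns) == sel.selected_genes_


class TestCorrelationMap:
    def test_expression_equal_to_distance_gives_rho_one(self, rng):
        d = pd.DataFrame(rng.uniform(0, 80, size=(8, 4)),
                         index=[f"c{i}" for i in range(8)],
                         columns=["T1", "T2", "T3", "T4"])
        expr = pd.DataFrame([d["T3"].to_numpy()], index=["g"],
                            columns=d.index)
        cm = correlate_distance_expression(expr, d, ["T1", "T2", "T3", "T4"],
                                           n_min=2)
        assert cm.rho.loc["g", "T3"] == pytest.approx(1.0, abs=1e-12)

    def test_constant_gene_row_is_missing(self, rng):
        d = pd.DataFrame(rng.uniform(0, 80, size=(6, 3)),
                         columns=["T1", "T2", "T3"],
                         index=[f"c{i}" for i in range(6)])
        expr = pd.DataFrame([[7.0] * 6], index=["flat"], columns=d.index)
        cm = correlate_distance_expression(expr, d, n_min=2)
        assert cm.rho.loc["flat"].isna().all()

    def test_matches_elementwise_pearson_oracle(self, rng, pearson_oracle):
        n_g, n_c, n_t = 20, 8, 5
        expr = pd.DataFrame(rng.gamma(2, 10, size=(n_g, n_c)),
                            index=[f"g{i}" for i in range(n_g)],
                            columns=[f"c{j}" for j in range(n_c)])
        d = pd.DataFrame(rng.uniform(0, 80, size=(n_c, n_t)),
                         index=expr.columns,
                         columns=[f"T{t + 1}" for t in range(n_t)])
        # truncate two trajectories to exercise pairwise-complete handling
        d.iloc[0, 3:] = np.nan
        d.iloc[1, 2:] = np.nan
        cm = correlate_distance_expression(expr, d, n_min=2)
        for g in expr.index:
            for t in d.columns:
                mask = d[t].notna()
                expected = pearson_oracle(expr.loc[g, mask.to_numpy()],
                                          d.loc[mask, t])
                got = cm.rho.loc[g, t]
                assert got == pytest.approx(expected, abs=1e-10)
                assert cm.n_used.loc[g, t] == int(mask.sum())

    def test_affine_invariance(self, rng):
        n_c = 10
        expr = pd.DataFrame(rng.gamma(2, 10, size=(4, n_c)),
                            index=list("wxyz"),
                            columns=[f"c{j}" for j in range(n_c)])
        d = pd.DataFrame(rng.uniform(0, 80, size=(n_c, 3)),
                         index=expr.columns, columns=["T1", "T2", "T3"])
        base = correlate_distance_expression(expr, d, n_min=2).rho
        scaled = correlate_distance_expression(expr * 3.7 + 11.0, d * 0.2 + 5,
                                               n_min=2).rho
        pd.testing.assert_frame_equal(base, scaled, atol=1e-10, rtol=0)
        flipped = correlate_distance_expression(expr * -2.0 + 100.0, d,
                                                n_min=2).rho
        pd.testing.assert_frame_equal(base, -flipped, atol=1e-10, rtol=0)

    def test_n_min_masks_sparse_timepoints(self, rng):
        d = pd.DataFrame(rng.uniform(0, 80, size=(8, 2)),
                         index=[f"c{i}" for i in range(8)],
                         columns=["T1", "T2"])
        d.loc[d.index[3:], "T2"] = np.nan       # only 3 complete pairs
        expr = pd.DataFrame(rng.gamma(2, 10, size=(3, 8)),
                            index=list("abc"), columns=d.index)
        cm = correlate_distance_expression(expr, d, n_min=5)
        assert cm.rho["T2"].isna().all()
        assert cm.rho["T1"].notna().all()

    def test_everything_missing_is_fatal(self):
        d = pd.DataFrame(np.nan, index=["c1", "c2", "c3"], columns=["T1"])
        expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=d.index)
        with pytest.raises(ValueError, match="fewer than 3"):
            DistanceCorrelationMap(n_min=2).fit(expr.T, d)


class TestMemoryGeneSelection:
    def test_threshold_is_inclusive(self):
        rho = pd.DataFrame({"T1": [0.25, 0.249, -0.3],
                            "T2": [0.1, 0.2, 0.0]},
                           index=["at", "below", "neg"])
        got = select_memory_genes(rho, 0.25)
        assert got == ["at", "neg"]

    def test_all_nan_row_never_retained(self):
        rho = pd.DataFrame({"T1": [np.nan], "T2": [np.nan]}, index=["g"])
        assert select_memory_genes(rho, 0.25) == []

    @given(thr_lo=st.floats(0.05, 0.5), delta=st.floats(0.01, 0.4))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, thr_lo, delta):
        rng = np.random.default_rng(77)
        rho = pd.DataFrame(rng.uniform(-1, 1, size=(30, 5)),
                           index=[f"g{i}" for i in range(30)])
        lo = set(select_memory_genes(rho, thr_lo))
        hi = set(select_memory_genes(rho, min(thr_lo + delta, 1.0)))
        assert hi <= lo

    @pytest.mark.parametrize("thr", [0.0, -0.1, 1.5])
    def test_threshold_range_validated(self, thr):
        rho = pd.DataFrame({"T1": [0.5]}, index=["g"])
        with pytest.raises(ConfigurationError):
            select_memory_genes(rho, thr)


class TestModuleClustering:
    def _block_rho(self, n_a=6, n_b=5):
        rows = [[0.9, 0.8, 0.0, 0.0]] * n_a + [[0.0, 0.0, 0.85, 0.9]] * n_b
        idx = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        rng = np.random.default_rng(0)
        noisy = np.array(rows) + rng.normal(0, 0.02, size=(n_a + n_b, 4))
        return pd.DataFrame(noisy, index=idx,
                            columns=["T1", "T2", "T3", "T4"])

    def test_separates_orthogonal_blocks(self):
        rho = self._block_rho()
        cl = ModuleClusterer(n_clusters=2).fit(rho)
        mods = cl.modules_
        assert len(set(mods[:6])) == 1 and len(set(mods[6:])) == 1
        assert mods.iloc[0] != mods.iloc[-1]

    def test_labels_ordered_by_peak_hour(self):
        cl = ModuleClusterer(n_clusters=2).fit(self._block_rho())
        # early-peak block (T1/T2) must be M1
        assert cl.modules_.iloc[0] == "M1"
        assert cl.modules_.iloc[-1] == "M2"
        assert cl.peak_hours_["M1"] in ("T1", "T2")

    def test_k_equals_n_gives_singletons(self):
        rho = self._block_rho(3, 3)
        cl = ModuleClusterer(n_clusters=6).fit(rho)
        assert len(set(cl.labels_)) == 6

    def test_deterministic(self):
        rho = self._block_rho()
        a = ModuleClusterer(n_clusters=2).fit(rho).labels_
        b = ModuleClusterer(n_clusters=2).fit(rho).labels_
        assert (a == b).all()

    def test_k_larger_than_genes_rejected(self):
        with pytest.raises(ValueError):
            ModuleClusterer(n_clusters=10).fit(self._block_rho(3, 3))

    def test_missing_entries_imputed_and_counted(self):
        rho = self._block_rho()
        rho.iloc[0, 0] = np.nan
        cl = ModuleClusterer(n_clusters=2).fit(rho)
        assert cl.imputed_entries_ == 1
        assert len(cl.modules_) == len(rho)
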