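"""Clone status calling, group statistics and the visualization suite."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from bsptrace.errors import BsptraceError
from bsptrace.grouped import (METHYLATED, NOT_AVAILABLE, UNMETHYLATED,
                              CloneStatusParams, PlotParams, _ordered_samples,
                              call_clone_status, clone_group_proportions,
                              flag_mixed_clone, gather, group_statistics,
                              kruskal_test, observation_matrix, render_plots,
                              significance_symbol, welch_t_test, write_outputs)
from bsptrace.methylation import CSV_COLUMNS


class TestCloneStatus:
    @pytest.mark.parametrize("meth,expected", [
        (5.0, UNMETHYLATED),
        (95.0, METHYLATED),
        (50.0, NOT_AVAILABLE),
        (20.0, UNMETHYLATED),   # boundary inclusive
        (80.0, METHYLATED),     # boundary inclusive
        (None, NOT_AVAILABLE),
        (float("nan"), NOT_AVAILABLE),
    ])
    def test_examples(self, meth, expected):
        assert call_clone_status(meth) == expected

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=100, allow_nan=False))
    def test_partition_of_0_100(self, meth):
        """Every methylation level maps to exactly one status."""
        status = call_clone_status(meth)
        assert status in (UNMETHYLATED, METHYLATED, NOT_AVAILABLE)
        expected = (UNMETHYLATED if meth <= 20
                    else METHYLATED if meth >= 80 else NOT_AVAILABLE)
        assert status == expected


class TestFlagMixedClone:
    def test_three_partial_of_ten_masks_all(self):
        statuses = [METHYLATED] * 7 + [NOT_AVAILABLE] * 3
        assert flag_mixed_clone(statuses) == [NOT_AVAILABLE] * 10

    def test_two_partial_of_ten_unchanged(self):
        """0.2 is not strictly above the 0.2 threshold."""
        statuses = [METHYLATED] * 8 + [NOT_AVAILABLE] * 2
        assert flag_mixed_clone(statuses) == statuses

    def test_no_partial_unchanged(self):
        statuses = [METHYLATED, UNMETHYLATED] * 5
        assert flag_mixed_clone(statuses) == statuses

    def test_missing_coverage_does_not_count_with_meth_values(self):
        """Uncovered CpGs are not evidence of a clone mix."""
        statuses = [METHYLATED] * 7 + [NOT_AVAILABLE] * 3
        values = [100.0] * 7 + [None] * 3
        assert flag_mixed_clone(statuses, meth_values=values) == statuses
        values = [100.0] * 7 + [50.0] * 3
        assert flag_mixed_clone(statuses, meth_values=values) == \
            [NOT_AVAILABLE] * 10

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            flag_mixed_clone([])


def sample_csv_frame(collection, group, rep, coords, meths,
                     sequence_name="seqA", experiment_type="direct"):
    rows = []
    for i, (c, m) in enumerate(zip(coords, meths), start=1):
        rows.append({
            "sequence_name": sequence_name, "collection": collection,
            "group": group, "replicate_or_clone": str(rep),
            "experiment_type": experiment_type, "cpg_index": i,
            "c_coordinate": c,
            "meth_fwd": m, "meth_rev": m, "meth_mean": m,
            "meth_sd": 0.0 if m is not None else None,
            "n_reads": 2 if m is not None else 0,
            "qc_pass_fwd": m is not None, "qc_pass_rev": m is not None,
            "conversion_rate_fwd": 0.99, "conversion_rate_rev": 0.99,
        })
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


@pytest.fixture
def results_dir(tmp_path):
    """2 groups x 3 replicates, 5 CpGs; one replicate misses the first CpG."""
    coords = [6010, 6050, 6120, 6200, 6390]
    rng = np.random.default_rng(0)
    for group, base in (("ctrl", 10.0), ("treated", 70.0)):
        for rep in range(1, 4):
            meths = [min(100, max(0, base + rng.normal(0, 3)))
                     for _ in coords]
            if group == "ctrl" and rep == 1:
                meths[0] = None
            df = sample_csv_frame("colA", group, rep, coords, meths)
            df.to_csv(tmp_path / f"colA_{group}_{rep}.csv", index=False)
    return tmp_path


class TestGather:
    def test_renumbering_contiguous_and_increasing(self, results_dir):
        ds = gather(results_dir, "seqA")
        ordinals = sorted(ds.coord_of_ordinal)
        assert ordinals == list(range(1, 6))
        coords = [ds.coord_of_ordinal[k] for k in ordinals]
        assert coords == sorted(coords)
        assert len(set(coords)) == len(coords)

    def test_missing_sequence_raises(self, results_dir):
        with pytest.raises(BsptraceError):
            gather(results_dir, "nope")

    def test_uncovered_cpg_is_nan_in_matrix(self, results_dir):
        ds = gather(results_dir, "seqA")
        assert ds.matrix.loc["colA_ctrl_1"].isna().sum() == 1

    def test_cloning_statuses_built(self, tmp_path):
        coords = [10, 20, 30, 40, 50]
        for rep, meths in enumerate(
                ([0, 0, 100, 100, 100], [0, 50, 100, 100, 100],
                 [50, 50, 50, 0, 100]), start=1):
            df = sample_csv_frame("colA", "g1", rep, coords,
                                  [float(m) for m in meths],
                                  experiment_type="cloning")
            df.to_csv(tmp_path / f"c{rep}.csv", index=False)
        ds = gather(tmp_path, "seqA")
        sm = ds.status_matrix
        assert list(sm.loc["colA_g1_1"]) == [
            UNMETHYLATED, UNMETHYLATED, METHYLATED, METHYLATED, METHYLATED]
        # one partial of five -> kept (0.2 not > 0.2)
        assert list(sm.loc["colA_g1_2"]) == [
            UNMETHYLATED, NOT_AVAILABLE, METHYLATED, METHYLATED, METHYLATED]
        # three partial of five -> masked as potential clone mix
        assert list(sm.loc["colA_g1_3"]) == [NOT_AVAILABLE] * 5


class TestStatistics:
    def test_identical_groups_p_is_one(self):
        assert welch_t_test([50, 50, 50], [50, 50, 50]) == 1.0

    def test_perfect_separation(self):
        """Zero variance in both groups but distinct means: p < 0.001."""
        p = welch_t_test([0, 0, 0], [100, 100, 100])
        assert p is not None and p < 0.001

    def test_matches_scipy_on_regular_data(self, rng):
        a = rng.normal(30, 5, 6)
        b = rng.normal(60, 5, 6)
        assert welch_t_test(a, b) == pytest.approx(
            sps.ttest_ind(a, b, equal_var=False).pvalue)

    def test_small_group_skipped(self):
        assert welch_t_test([1.0], [2.0, 3.0]) is None

    def test_kruskal_two_group_rank_ordering(self, rng):
        """More separated groups give smaller p for KW and rank-sum alike."""
        a = rng.normal(50, 5, 8)
        close = a + 2
        far = a + 40
        kw_close = kruskal_test([a, close])
        kw_far = kruskal_test([a, far])
        mw_close = sps.mannwhitneyu(a, close).pvalue
        mw_far = sps.mannwhitneyu(a, far).pvalue
        assert kw_far < kw_close
        assert mw_far < mw_close

    def test_symbols(self):
        assert significance_symbol(0.04) == "*"
        assert significance_symbol(0.009) == "**"
        assert significance_symbol(0.0009) == "***"
        assert significance_symbol(0.00009) == "****"
        assert significance_symbol(0.2) == "ns"
        assert significance_symbol(None) == ""

    def test_bundle_structure_three_groups(self, tmp_path, rng):
        coords = [10, 20, 30]
        for group, base in (("a", 10), ("b", 50), ("c", 90)):
            for rep in range(1, 4):
                meths = [min(100, max(0, base + rng.normal(0, 4)))
                         for _ in coords]
                sample_csv_frame("colA", group, rep, coords, meths).to_csv(
                    tmp_path / f"{group}{rep}.csv", index=False)
        ds = gather(tmp_path, "seqA")
        stats = group_statistics(ds)
        assert len(stats["per_cpg_kruskal"]) == 3
        # all 3 group pairs at each CpG
        assert len(stats["per_cpg_pairwise"]) == 3 * 3
        got_pairs = {tuple(sorted(p)) for p in
                     stats["per_cpg_pairwise"][["group1", "group2"]].itertuples(
                         index=False)}
        assert got_pairs == {tuple(sorted(p))
                             for p in itertools.combinations("abc", 2)}
        assert stats["per_cpg_kruskal"]["p_value"].notna().all()

    def test_group_mean_conservation(self, results_dir):
        """Group-mean lollipop values equal the mean of sample values."""
        ds = gather(results_dir, "seqA")
        stats = group_statistics(ds)
        for g in ds.groups:
            manual = ds.matrix.loc[
                ds.matrix.index.isin(ds.group_samples(g))].mean(skipna=True)
            assert np.allclose(stats["group_mean"][g], manual, equal_nan=True)

    def test_strong_difference_significant(self, results_dir):
        ds = gather(results_dir, "seqA")
        stats = group_statistics(ds)
        # ctrl ~10% vs treated ~70%: every covered CpG should be significant
        complete = stats["per_cpg_pairwise"].dropna(subset=["p_value"])
        assert (complete["p_value"] < 0.05).all()

    def test_clone_proportions(self, tmp_path):
        coords = [10, 20]
        patterns = ([0, 100], [0, 100], [100, 100], [0, 0])
        for rep, meths in enumerate(patterns, start=1):
            sample_csv_frame("colA", "g1", rep, coords,
                             [float(m) for m in meths],
                             experiment_type="cloning").to_csv(
                tmp_path / f"c{rep}.csv", index=False)
        ds = gather(tmp_path, "seqA")
        props = clone_group_proportions(ds)
        assert props.loc[1, "g1"] == pytest.approx(25.0)  # 1 of 4 methylated
        assert props.loc[2, "g1"] == pytest.approx(75.0)


class TestPlots:
    def test_all_figures_rendered(self, results_dir, tmp_path):
        ds = gather(results_dir, "seqA")
        stats = group_statistics(ds)
        out = render_plots(ds, stats, PlotParams(), tmp_path / "figs")
        assert set(out) == {"lollipop_samples", "lollipop_groups", "profile",
                            "boxplots", "heatmap"}
        for path in out.values():
            assert path.exists() and path.stat().st_size > 0
        # the matrix driving the samples plot carries the unavailable point
        assert observation_matrix(ds).isna().any().any()

    def test_order_by_methylation(self, results_dir):
        ds = gather(results_dir, "seqA")
        order = _ordered_samples(ds, ds.matrix, PlotParams(
            sample_order="methylation"))
        means = ds.matrix.mean(axis=1, skipna=True)
        assert order == list(means.sort_values(ascending=False).index)

    def test_order_by_cluster_returns_permutation(self, results_dir):
        ds = gather(results_dir, "seqA")
        order = _ordered_samples(ds, ds.matrix, PlotParams(
            sample_order="cluster"))
        assert sorted(order) == sorted(ds.matrix.index)

    def test_outputs_written(self, results_dir, tmp_path):
        ds = gather(results_dir, "seqA")
        stats = group_statistics(ds)
        paths = write_outputs(ds, stats, tmp_path / "out")
        for p in paths.values():
            assert p.exists() and p.stat().st_size > 0
        import json
        summary = json.loads(paths["summary"].read_text())
        assert summary["n_cpg"] == 5
        assert set(summary["groups"]) == {"ctrl", "treated"}
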