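"""Contingency tables, threshold sweeps, the accuracy surface, concordance."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cvrconcord.containers import TissueLabelVolume, map_from_voi
from cvrconcord.overlap import (
    ContingencyTable,
    accuracy,
    classify_vs_mask,
    cross_metric_surface,
    dice,
    percentile_grid,
    self_concordance,
    sweep_thresholds,
    sweep_vs_gray,
    unthresholded_compare,
)


class TestContingency:
    def test_formulas_on_published_row(self):
        t = ContingencyTable(tp=45, tn=32, fp=15, fn=8)
        assert accuracy(t) == pytest.approx(0.77)
        assert dice(t) == pytest.approx(90 / 113)

    def test_perfect_and_worst_cases(self):
        assert accuracy(ContingencyTable(10, 5, 0, 0)) == 1.0
        assert accuracy(ContingencyTable(0, 0, 3, 7)) == 0.0
        assert dice(ContingencyTable(4, 0, 0, 0)) == 1.0

    def test_degenerate_tables_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            accuracy(ContingencyTable(0, 0, 0, 0))
        with pytest.raises(ValueError, match="Dice undefined"):
            dice(ContingencyTable(0, 5, 0, 0))

    def test_percentages_sum_to_100(self):
        pct = ContingencyTable(13, 7, 5, 2).as_percent()
        assert pct.total == pytest.approx(100.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 500)] * 4).filter(lambda t: sum(t) > 0))
    def test_count_conservation(self, cells):
        t = ContingencyTable(*map(float, cells))
        assert t.total == sum(cells)
        assert t.as_percent().total == pytest.approx(100.0)


class TestClassifyVsMask:
    def test_four_voxel_enumeration(self):
        metric = np.array([1.0, 1.0, 0.0, 0.0]).reshape(4, 1, 1)
        reference = np.array([1, 0, 1, 0]).reshape(4, 1, 1)
        voi = np.ones((4, 1, 1), bool)
        t = classify_vs_mask(metric, 0.5, reference, voi)
        assert (t.tp, t.fp, t.fn, t.tn) == (1, 1, 1, 1)

    def test_extreme_thresholds_force_cells(self):
        metric = np.arange(8.0).reshape(2, 2, 2)
        reference = metric >= 4
        voi = np.ones((2, 2, 2), bool)
        low = classify_vs_mask(metric, -1.0, reference, voi)
        assert low.fn == 0 and low.tn == 0
        high = classify_vs_mask(metric, 100.0, reference, voi)
        assert high.tp == 0 and high.fp == 0

    def test_boundary_counts_as_responsive(self):
        metric = np.array([[[2.0]]])
        t = classify_vs_mask(metric, 2.0, np.array([[[1]]]), np.ones((1, 1, 1), bool))
        assert t.tp == 1

    def test_role_swap_symmetry(self):
        """Swapping predictor and reference preserves accuracy and Dice
        and swaps FP with FN."""
        rng = np.random.default_rng(0)
        a = rng.normal(size=(5, 5, 5))
        b = rng.normal(size=(5, 5, 5))
        voi = np.ones((5, 5, 5), bool)
        t_ab = classify_vs_mask(a, 0.0, b >= 0.0, voi)
        t_ba = classify_vs_mask(b, 0.0, a >= 0.0, voi)
        assert t_ab.accuracy == t_ba.accuracy
        assert (t_ab.fp, t_ab.fn) == (t_ba.fn, t_ba.fp)
        assert t_ab.dice == t_ba.dice

    def test_empty_voi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            classify_vs_mask(np.ones((2, 2, 2)), 0.5, np.ones((2, 2, 2)), np.zeros((2, 2, 2), bool))


def _separable_instance(rng, n_gray=400, n_white=300):
    """A toy tissue column with well-separated gray/white metric values."""
    n = n_gray + n_white
    labels = np.array([1] * n_gray + [2] * n_white).reshape(n, 1, 1)
    tissue = TissueLabelVolume(labels)
    vals = np.concatenate(
        [rng.normal(2.0, 0.3, n_gray), rng.normal(0.0, 0.3, n_white)]
    )
    metric = map_from_voi(vals, tissue.gwm_mask, "breathhold_beta")
    return tissue, metric


def _exhaustive_best_threshold(values, reference):
    """Independent oracle: try every distinct metric value as a threshold."""
    best_acc, best_thr = -1.0, None
    for thr in np.unique(values):
        pred = values >= thr
        acc = (pred & reference).sum() + (~pred & ~reference).sum()
        acc = acc / values.size
        if acc > best_acc:
            best_acc, best_thr = acc, thr
    return best_thr, best_acc


class TestSweep:
    def test_separable_phantom_has_interior_optimum(self, rng):
        tissue, metric = _separable_instance(rng)
        sweep = sweep_vs_gray(metric, tissue)
        assert sweep.max_accuracy > 0.95
        # argmax sits between the two modes, not at the grid edges
        assert 0.5 < sweep.argmax_threshold < 1.5
        assert sweep.accuracy[0] < sweep.max_accuracy
        assert sweep.accuracy[-1] < sweep.max_accuracy

    def test_grid_argmax_matches_exhaustive_oracle(self, rng):
        tissue, metric = _separable_instance(rng)
        sweep = sweep_vs_gray(metric, tissue)
        vals = metric.voi_values
        ref = tissue.gray_mask[tissue.gwm_mask]
        thr_star, acc_star = _exhaustive_best_threshold(vals, ref)
        # grid optimum within one grid step of the exhaustive optimum
        step = np.max(np.diff(sweep.thresholds))
        assert abs(sweep.argmax_threshold - thr_star) <= step + 1e-12
        # 101 percentile thresholds: at most ~1% of voxels sit between
        # adjacent grid points, bounding the accuracy shortfall
        assert sweep.max_accuracy >= acc_star - 0.0101

    def test_all_responsive_below_grid(self, rng):
        tissue, metric = _separable_instance(rng)
        grid = np.array([metric.voi_values.min() - 1.0])
        sweep = sweep_thresholds(
            metric, tissue.gray_mask, tissue.gwm_mask, grid=grid
        )
        gray_fraction = tissue.gray_mask.sum() / tissue.gwm_mask.sum()
        assert sweep.accuracy[0] == pytest.approx(gray_fraction)

    def test_responsive_count_monotone_in_threshold(self, rng):
        tissue, metric = _separable_instance(rng)
        sweep = sweep_vs_gray(metric, tissue)
        n_pos = [t.tp + t.fp for t in sweep.tables]
        assert np.all(np.diff(n_pos) <= 0)

    def test_missing_tissue_class_rejected(self, rng):
        labels = np.ones((10, 1, 1), dtype=int)
        tissue = TissueLabelVolume(labels)
        metric = map_from_voi(rng.normal(size=10), tissue.gwm_mask, "breathhold_beta")
        with pytest.raises(ValueError, match="gray and white"):
            sweep_vs_gray(metric, tissue)


class TestSurface:
    def _maps(self, rng, n=500):
        voi = np.ones((n, 1, 1), bool)
        bh = map_from_voi(rng.normal(size=n), voi, "breathhold_beta")
        rs = map_from_voi(rng.normal(size=n), voi, "resting_alff")
        return bh, rs, voi

    def test_corner_forcing(self, rng):
        bh, rs, voi = self._maps(rng)
        surf = cross_metric_surface(bh, rs, voi)
        assert surf.corners == {"A1": 1.0, "A2": 0.0, "A3": 0.0, "A4": 1.0}

    def test_extreme_grid_cells_match_corners(self, rng):
        bh, rs, voi = self._maps(rng)
        lo_b, hi_b = bh.voi_values.min() - 1, bh.voi_values.max() + 1
        lo_r, hi_r = rs.voi_values.min() - 1, rs.voi_values.max() + 1
        surf = cross_metric_surface(
            bh, rs, voi,
            bh_grid=np.array([lo_b, hi_b]),
            rs_grid=np.array([lo_r, hi_r]),
        )
        # [i_bh, j_rs]: both below -> all TP; both above -> all TN
        assert surf.accuracy[0, 0] == 1.0
        assert surf.accuracy[1, 1] == 1.0
        assert surf.accuracy[1, 0] == 0.0  # rs below, bh above: all FP
        assert surf.accuracy[0, 1] == 0.0  # rs above, bh below: all FN

    def test_saddle_value_matches_direct_classification(self, rng):
        bh, rs, voi = self._maps(rng)
        surf = cross_metric_surface(bh, rs, voi, saddle_thresholds=(0.0, 0.0))
        direct = classify_vs_mask(rs, 0.0, bh.values >= 0.0, voi)
        assert surf.saddle_accuracy == pytest.approx(direct.accuracy)

    def test_matrix_agrees_with_per_pair_classification(self, rng):
        bh, rs, voi = self._maps(rng, n=200)
        bh_grid = percentile_grid(bh.voi_values, 5)
        rs_grid = percentile_grid(rs.voi_values, 5)
        surf = cross_metric_surface(bh, rs, voi, bh_grid=bh_grid, rs_grid=rs_grid)
        for i, bt in enumerate(bh_grid):
            for j, rt in enumerate(rs_grid):
                t = classify_vs_mask(rs, rt, bh.values >= bt, voi)
                assert surf.accuracy[i, j] == pytest.approx(t.accuracy)


class TestConcordance:
    def test_identical_maps_fully_concordant(self, rng):
        tissue, metric = _separable_instance(rng)
        res = self_concordance(metric, metric, tissue)
        assert res.accuracy == 1.0
        assert res.dice == 1.0

    def test_independent_noise_maps_near_chance(self, rng):
        """Independent pure-noise maps thresholded at their medians agree
        on about half the voxels."""
        n = 4000
        voi = np.ones((n, 1, 1), bool)
        accs = []
        for _ in range(5):
            a = rng.normal(size=n)
            b = rng.normal(size=n)
            t = classify_vs_mask(
                a.reshape(n, 1, 1), np.median(a), b.reshape(n, 1, 1) >= np.median(b), voi
            )
            accs.append(t.accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.05

    def test_resting_beats_breathhold_when_task_noise_higher(self):
        """With breath-hold noise raised well above resting noise, the
        split-run concordance ordering flips toward resting."""
        from cvrconcord.phantom import PhantomSpec, simulate_subject
        from cvrconcord.pipeline import analyze_subject

        spec = PhantomSpec(shape=(16, 16, 16), noise_sd=4.0, rs_noise_sd=0.4, seed=21)
        res = analyze_subject(simulate_subject(spec))
        assert res.concord_rs.accuracy > res.concord_bh.accuracy


class TestUnthresholded:
    def test_affine_relation_gives_unit_correlation(self, rng):
        n = 500
        voi = np.ones((n, 1, 1), bool)
        b = rng.normal(size=n)
        bh = map_from_voi(b, voi, "breathhold_beta")
        rs = map_from_voi(3.0 * b + 7.0, voi, "resting_alff")
        cmp = unthresholded_compare(bh, rs, voi)
        assert cmp.pearson_r == pytest.approx(1.0, abs=1e-9)
        # after range normalization the difference is (nearly) constant
        assert np.nanstd(cmp.difference) < 0.02

    def test_independent_maps_near_zero_correlation(self, rng):
        n = 5000
        voi = np.ones((n, 1, 1), bool)
        rs_vals = rng.normal(size=n)
        bh = map_from_voi(rng.normal(size=n), voi, "breathhold_beta")
        rs = map_from_voi(rs_vals, voi, "resting_alff")
        cmp = unthresholded_compare(bh, rs, voi)
        assert abs(cmp.pearson_r) < 0.05

    def test_constant_map_rejected(self, rng):
        n = 50
        voi = np.ones((n, 1, 1), bool)
        bh = map_from_voi(np.ones(n), voi, "breathhold_beta")
        rs = map_from_voi(rng.normal(size=n), voi, "resting_alff")
        with pytest.raises(ValueError, match="constant"):
            unthresholded_compare(bh, rs, voi)

    def test_coupled_truth_fields_raise_map_correlation(self):
        """When the two metrics share their gray-matter truth structure,
        the unthresholded maps correlate more strongly than for
        independent truth fields."""
        from cvrconcord.phantom import PhantomSpec, simulate_subject
        from cvrconcord.pipeline import analyze_subject

        base = dict(shape=(16, 16, 16), amplitude_cv=0.4, noise_sd=0.1, seed=31)
        r_indep = analyze_subject(
            simulate_subject(PhantomSpec(metric_coupling=0.0, **base))
        ).unthresholded.pearson_r
        r_coupled = analyze_subject(
            simulate_subject(PhantomSpec(metric_coupling=1.0, **base))
        ).unthresholded.pearson_r
        assert r_coupled > max(r_indep, 0.3)

    def test_scatter_mask_keeps_central_voxels(self, rng):
        n = 2000
        voi = np.ones((n, 1, 1), bool)
        bh = map_from_voi(rng.normal(size=n), voi, "breathhold_beta")
        rs = map_from_voi(rng.normal(size=n), voi, "resting_alff")
        cmp = unthresholded_compare(bh, rs, voi)
        assert 0.85 <= cmp.scatter_mask.mean() <= 0.96
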