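"""Fluorescence quantification: ellipse-annulus measurement, synthetic
fields, median/bootstrap summaries, Wilcoxon/Holm inference."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from pmscreen.imaging import (
    Ellipse,
    EllipsePair,
    compare_conditions,
    detect_cells,
    holm_adjust,
    measure_cell,
    measure_field,
    normalize_to_baseline,
    read_image,
    read_rois,
    summarize_condition,
    synthesize_field,
    wilcoxon_rank_sum,
    write_image,
)


def _pair(cx=20.0, cy=20.0, a=12.0, b=9.0, theta=0.3, margin=4.0, cell_id="c1"):
    return EllipsePair(cell_id, Ellipse(cx, cy, a, b, theta),
                       Ellipse(cx, cy, a - margin, b - margin, theta))


class TestGeometry:
    def test_inner_must_be_contained(self):
        with pytest.raises(ValueError, match="contained"):
            EllipsePair("bad", Ellipse(20, 20, 5, 5), Ellipse(27, 20, 5, 5))

    def test_semi_axes_positive(self):
        with pytest.raises(ValueError, match="semi-axes"):
            Ellipse(0, 0, -1, 2)


class TestSynthesizeAndMeasure:
    def test_uniform_levels_give_unit_ratio(self):
        pair = _pair()
        img, _ = synthesize_field([(pair, 100, 100)], 0.0, 0.0, 0)
        assert measure_cell(img, pair)["ratio"] == 1.0

    def test_noiseless_two_to_one(self):
        pair = _pair()
        img, truth = synthesize_field([(pair, 200, 100)], 0.0, 0.0, 0)
        m = measure_cell(img, pair)
        assert m["ratio"] == 2.0
        assert truth["true_ratio"].iloc[0] == 2.0
        assert m["internal_intensity"] == 200.0 and m["pm_intensity"] == 100.0

    def test_constant_image_unit_ratio(self):
        img = np.full((40, 40), 3.14)
        assert measure_cell(img, _pair())["ratio"] == pytest.approx(1.0)

    def test_gain_invariance(self):
        pair = _pair()
        img, _ = synthesize_field([(pair, 180, 90)], 5.0, 10.0, 3)
        r1 = measure_cell(img, pair)["ratio"]
        r2 = measure_cell(img * 7.3, pair)["ratio"]
        assert abs(r1 - r2) < 1e-12

    def test_additive_offset_shifts_ratio(self):
        """Regression: an additive pedestal compresses the ratio toward 1,
        so images must be dark-level corrected upstream."""
        pair = _pair()
        img, _ = synthesize_field([(pair, 200, 100)], 0.0, 0.0, 0)
        shifted = measure_cell(img + 100.0, pair)["ratio"]
        assert shifted == pytest.approx(1.5)

    def test_seeded_field_reproducible(self):
        cells = [(_pair(), 200, 100)]
        a, _ = synthesize_field(cells, 10.0, 5.0, seed=11)
        b, _ = synthesize_field(cells, 10.0, 5.0, seed=11)
        assert np.array_equal(a, b)
        c, _ = synthesize_field(cells, 10.0, 5.0, seed=12)
        assert not np.array_equal(a, c)

    def test_overlapping_cells_rejected(self):
        cells = [(_pair(cell_id="a"), 200, 100),
                 (_pair(cx=24, cell_id="b"), 200, 100)]
        with pytest.raises(ValueError, match="overlap"):
            synthesize_field(cells, 0.0, 0.0, 0)

    def test_levels_must_exceed_background(self):
        with pytest.raises(ValueError, match="background"):
            synthesize_field([(_pair(), 50, 100)], 0.0, 60.0, 0)

    def test_empty_annulus_error(self):
        # ring thinner than pixel spacing at a lattice-offset center: no
        # pixel center falls between the two boundaries
        pair = EllipsePair("c", Ellipse(20.5, 20.5, 5.3, 5.3),
                           Ellipse(20.5, 20.5, 5.28, 5.28))
        img = np.full((41, 41), 5.0)
        with pytest.raises(ValueError, match="annulus"):
            measure_cell(img, pair)

    def test_out_of_bounds_error(self):
        img = np.ones((20, 20))
        with pytest.raises(ValueError, match="bounds"):
            measure_cell(img, _pair())

    def test_noisy_recovery_within_5_percent(self):
        """≥30 cells, noise sd = 10% of ring level: the per-condition median
        ratio stays within 5% of the generator's truth."""
        cells = []
        for i in range(36):
            r, c = divmod(i, 6)
            cells.append((_pair(cx=20 + 44 * c, cy=20 + 44 * r, theta=0.1 * i,
                                cell_id=f"c{i}"), 200.0, 100.0))
        img, truth = synthesize_field(cells, noise_sd=10.0, background=0.0, seed=5)
        measured = measure_field(img, [p for p, _, _ in cells], condition="wt")
        med = measured["ratio"].median()
        assert abs(med - 2.0) / 2.0 < 0.05
        assert len(measured) == 36


class TestDetectCells:
    def test_single_cell_center_recovered(self):
        pair = _pair(theta=0.0)
        img, _ = synthesize_field([(pair, 200, 100)], 0.0, 0.0, 0)
        detected = detect_cells(img, threshold_quantile=0.5)
        assert len(detected) == 1
        assert abs(detected[0].outer.cx - 20.0) <= 1.0
        assert abs(detected[0].outer.cy - 20.0) <= 1.0

    def test_blank_image_empty_list(self):
        assert detect_cells(np.zeros((30, 30))) == []

    def test_two_separated_cells(self):
        cells = [(_pair(cell_id="a"), 200, 100),
                 (_pair(cx=70, cy=60, cell_id="b"), 200, 100)]
        img, _ = synthesize_field(cells, 0.0, 0.0, 0)
        assert len(detect_cells(img, 0.6)) == 2


class TestSummaries:
    def test_median_simple(self):
        out = summarize_condition([1.0, 2.0, 3.0], n_bootstrap=200, seed=0)
        assert out["median"] == 2.0 and out["n_cells"] == 3

    def test_degenerate_ci_collapses(self):
        out = summarize_condition([1.7] * 20, n_bootstrap=200, seed=0)
        assert out["ci_low"] == out["ci_high"] == 1.7

    def test_ci_seeded_reproducible(self):
        rng = np.random.default_rng(0)
        ratios = rng.lognormal(0.3, 0.4, size=50)
        a = summarize_condition(ratios, n_bootstrap=500, seed=3)
        b = summarize_condition(ratios, n_bootstrap=500, seed=3)
        assert (a["ci_low"], a["ci_high"]) == (b["ci_low"], b["ci_high"])
        assert a["ci_low"] <= a["median"] <= a["ci_high"]

    def test_empty_condition_errors(self):
        with pytest.raises(ValueError, match="no cells"):
            summarize_condition([])

    def test_normalize_to_baseline(self):
        df = pd.DataFrame({
            "condition": ["m1"] * 4 + ["m2"] * 2,
            "time": [0, 0, 180, 180, 0, 180],
            "ratio": [0.4, 0.6, 1.5, 1.7, 1.0, 3.0],
        })
        out = normalize_to_baseline(df)
        m1_t0 = out[(out["condition"] == "m1") & (out["time"] == 0)]["ratio"]
        assert m1_t0.median() == pytest.approx(1.0)
        assert out["ratio"].iloc[5] == pytest.approx(3.0)  # 3.0 / t0 median 1.0
        # variant with t0 median 0.5 and a t180 ratio of 1.5 → normalized 3.0
        assert out["ratio"].iloc[2] == pytest.approx(3.0)

    def test_missing_baseline_names_variant(self):
        df = pd.DataFrame({"condition": ["mX"], "time": [180], "ratio": [1.0]})
        with pytest.raises(ValueError, match="mX"):
            normalize_to_baseline(df)


def _brute_force_rank_sum_p(x, y):
    """Independent oracle: enumerate every assignment of the pooled values
    to the two groups and tally rank sums at least as extreme."""
    pooled = np.concatenate([x, y])
    ranks = spstats.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[i] for i in comb)
            for comb in itertools.combinations(range(len(pooled)), n1)]
    lo = sum(1 for s in sums if s <= w_obs + 1e-9) / len(sums)
    hi = sum(1 for s in sums if s >= w_obs - 1e-9) / len(sums)
    return min(1.0, 2.0 * min(lo, hi))


class TestWilcoxonHolm:
    def test_extreme_separation_exact(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_p_one(self):
        assert wilcoxon_rank_sum([1, 2, 3], [1, 2, 3]) == 1.0

    def test_matches_scipy_exact_when_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            n1, n2 = rng.integers(3, 9, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(0.5, size=n2)
            ours = wilcoxon_rank_sum(x, y)
            ref = spstats.mannwhitneyu(x, y, method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_exhaustive_enumeration_all_sizes_up_to_6(self):
        """Exact path equals brute-force permutation enumeration for every
        pair of group sizes ≤ 6, with and without ties."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 7):
            for n2 in range(1, 7):
                x = rng.normal(size=n1)
                y = rng.normal(0.8, size=n2)
                assert wilcoxon_rank_sum(x, y) == pytest.approx(
                    _brute_force_rank_sum_p(x, y), abs=1e-12)
                # tied variant: round to one decimal to force shared values
                xt, yt = np.round(x, 0), np.round(y, 0)
                assert wilcoxon_rank_sum(xt, yt) == pytest.approx(
                    _brute_force_rank_sum_p(xt, yt), abs=1e-12)

    def test_large_sample_normal_approximation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=40)
        y = rng.normal(0.8, size=35)
        p = wilcoxon_rank_sum(x, y)
        ref = spstats.mannwhitneyu(x, y, method="asymptotic",
                                   use_continuity=False).pvalue
        assert p == pytest.approx(ref, rel=1e-9)

    def test_holm_closed_form(self):
        assert holm_adjust([0.01, 0.04]) == pytest.approx([0.02, 0.04])

    def test_holm_monotone_and_at_least_raw(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=12)
        adj = holm_adjust(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_compare_conditions_family(self):
        groups = {
            "ctrl": [1.0, 1.1, 0.9, 1.2, 1.05],
            "chx": [2.0, 2.2, 1.9, 2.4, 2.1],
            "mut": [1.0, 1.15, 0.95, 1.1, 1.0],
        }
        out = compare_conditions(groups)
        assert len(out) == 3
        assert (out["p_holm"] >= out["p"]).all()
        row = out[(out["group1"] == "ctrl") & (out["group2"] == "chx")]
        assert row["p"].iloc[0] < 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_conditions({"a": [1.0], "b": []})


class TestFileIO:
    def test_image_round_trip_png_and_tiff(self, tmp_path):
        img, _ = synthesize_field([(_pair(), 200, 100)], 0.0, 10.0, 0)
        for name in ("field.png", "field.tif"):
            path = tmp_path / name
            write_image(img, path)
            back = read_image(path)
            assert back.shape == img.shape
            assert np.allclose(back, np.rint(img))

    def test_roi_table_round_trip(self, tmp_path):
        pair = _pair()
        rows = pd.DataFrame([{
            "cell_id": "c1", "condition": "wt", "time": 0,
            "outer_cx": pair.outer.cx, "outer_cy": pair.outer.cy,
            "outer_a": pair.outer.a, "outer_b": pair.outer.b,
            "outer_theta": pair.outer.theta,
            "inner_cx": pair.inner.cx, "inner_cy": pair.inner.cy,
            "inner_a": pair.inner.a, "inner_b": pair.inner.b,
            "inner_theta": pair.inner.theta,
        }])
        path = tmp_path / "rois.tsv"
        rows.to_csv(path, sep="\t", index=False)
        rois = read_rois(path)
        assert rois["pair"].iloc[0].outer == pair.outer

    def test_roi_table_missing_column(self, tmp_path):
        path = tmp_path / "rois.tsv"
        path.write_text("cell_id\tcondition\ttime\n")
        with pytest.raises(ValueError, match="outer_cx"):
            read_rois(path)
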