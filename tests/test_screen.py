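"""Colony filtering, strain scoring, LOESS normalization, Z-scores, hits."""

import numpy as np
import pandas as pd
import pytest

import ngdtools as ngd
from ngdtools.screen import call_hits, score_plate
from ngdtools.simulate import PlateGradient


def toy_grid(rows):
    return pd.DataFrame(
        rows, columns=["plate_id", "row", "col", "strain", "gfp", "rfp", "size_px", "is_border"]
    )


class TestFilterColonies:
    @pytest.mark.parametrize(
        "size,kept", [(1499, False), (1500, True), (6000, True), (6001, False)]
    )
    def test_size_boundaries(self, size, kept):
        grid = toy_grid([["p", 5, 5, "s1", 100.0, 80.0, float(size), False]])
        filtered, report = ngd.filter_colonies(grid)
        assert (len(filtered) == 1) is kept

    def test_border_removed(self):
        grid = toy_grid(
            [
                ["p", 0, 0, "BORDER", 100.0, 80.0, 3000.0, True],
                ["p", 5, 5, "s1", 100.0, 80.0, 3000.0, False],
            ]
        )
        filtered, report = ngd.filter_colonies(grid)
        assert report == {"total": 2, "border": 1, "size_outlier": 0, "kept": 1}

    def test_all_border_warns_empty(self):
        grid = toy_grid([["p", 0, c, "BORDER", 1.0, 1.0, 3000.0, True] for c in range(4)])
        with pytest.warns(UserWarning, match="no colonies"):
            filtered, _ = ngd.filter_colonies(grid)
        assert len(filtered) == 0

    def test_positional_border_fallback_without_flag_column(self):
        grid = toy_grid(
            [["p", r, c, f"s{r}{c}", 100.0, 80.0, 3000.0, False]
             for r in range(32) for c in range(48)]
        ).drop(columns=["is_border"])
        filtered, report = ngd.filter_colonies(grid)
        assert report["border"] == 32 * 48 - 28 * 44


class TestScoreStrains:
    def test_median_aggregation(self):
        grid = toy_grid(
            [["p", 5, 5 + i, "s1", g, 100.0, 3000.0, False]
             for i, g in enumerate([100.0, 200.0, 300.0, 400.0])]
        )
        scores = ngd.score_strains(grid)
        assert scores.loc[0, "med_gfp"] == 250.0
        assert scores.loc[0, "n_colonies_used"] == 4

    def test_equal_medians_zero_log_ratio(self):
        grid = toy_grid([["p", 5, 5, "s1", 128.0, 128.0, 3000.0, False]])
        assert ngd.score_strains(grid).loc[0, "log2_ratio"] == 0.0

    def test_single_colony_degenerate_median(self):
        grid = toy_grid([["p", 5, 5, "s1", 100.0, 50.0, 3000.0, False]])
        s = ngd.score_strains(grid)
        assert s.loc[0, "n_colonies_used"] == 1 and s.loc[0, "log2_ratio"] == 1.0

    def test_mean_aggregator_selectable(self):
        grid = toy_grid(
            [["p", 5, 5 + i, "s1", g, 100.0, 3000.0, False]
             for i, g in enumerate([100.0, 200.0, 300.0, 1000.0])]
        )
        assert ngd.score_strains(grid, "mean").loc[0, "med_gfp"] == 400.0

    def test_border_removal_does_not_change_other_strains(self):
        rows = [["p", 5, c, f"s{c}", 100.0 + c, 80.0, 3000.0, False] for c in range(5, 9)]
        grid_with = toy_grid(rows + [["p", 0, 0, "BORDER", 1.0, 1.0, 3000.0, True]])
        grid_without = toy_grid(rows)
        a = ngd.score_strains(ngd.filter_colonies(grid_with)[0])
        b = ngd.score_strains(ngd.filter_colonies(grid_without)[0])
        pd.testing.assert_frame_equal(a, b)


class TestLoessNormalize:
    @staticmethod
    def flat_scores(n=300, seed=0, noise_sd=0.02):
        # noise at the level of replicate-aggregated measurement error, so the
        # smoother's own fit variance stays well below the spatial structure
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "strain_id": [f"s{i}" for i in range(n)],
                "row": rng.integers(2, 30, n).astype(float),
                "col": rng.integers(2, 46, n).astype(float),
                "log2_ratio": rng.normal(0.5, noise_sd, n),
            }
        )

    def test_flat_plate_adjustment_is_centering(self):
        scores = self.flat_scores()
        adj = ngd.loess_normalize(scores)
        centered = scores["log2_ratio"] - scores["log2_ratio"].mean()
        assert np.max(np.abs(adj["loess_adjusted"] - centered)) < 0.01

    def test_linear_column_gradient_removed(self):
        scores = self.flat_scores(seed=1)
        scores["log2_ratio"] = scores["log2_ratio"] + 0.05 * scores["col"]
        adj = ngd.loess_normalize(scores)
        col_means = adj.groupby(adj["col"] // 6)["loess_adjusted"].mean()
        assert np.abs(col_means).max() < 0.02

    def test_location_invariance(self):
        scores = self.flat_scores(seed=2)
        a = ngd.loess_normalize(scores)["loess_adjusted"]
        scores_shift = scores.copy()
        scores_shift["log2_ratio"] = scores["log2_ratio"] + 5.0
        b = ngd.loess_normalize(scores_shift)["loess_adjusted"]
        np.testing.assert_allclose(a - a.mean(), b - b.mean(), atol=1e-8)

    def test_small_plate_falls_back_to_median_centering(self):
        scores = self.flat_scores(n=5)
        with pytest.warns(UserWarning, match="fewer than 10"):
            adj = ngd.loess_normalize(scores)
        expected = scores["log2_ratio"] - scores["log2_ratio"].median()
        np.testing.assert_allclose(adj["loess_adjusted"], expected)


class TestZscore:
    def test_two_strains(self):
        df = pd.DataFrame({"loess_adjusted": [-1.0, 1.0]})
        z = ngd.zscore_plate(df)["z"]
        np.testing.assert_allclose(sorted(z), [-0.7071067, 0.7071067], rtol=1e-6)

    def test_standardization_identity(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame({"loess_adjusted": rng.normal(3, 2, 200)})
        z = ngd.zscore_plate(df)["z"]
        assert abs(z.mean()) < 1e-9 and abs(z.std(ddof=1) - 1) < 1e-9

    def test_outlier_strain_z_matches_effect(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0, 0.1, 400)
        vals[7] = 0.1 * 3  # 3 sd above
        df = pd.DataFrame({"loess_adjusted": vals})
        assert ngd.zscore_plate(df)["z"][7] == pytest.approx(3.0, abs=0.2)

    def test_zero_sd_errors(self):
        with pytest.raises(ValueError):
            ngd.zscore_plate(pd.DataFrame({"loess_adjusted": [1.0, 1.0, 1.0]}))


class TestCallHits:
    def test_cue2_like_signature(self):
        hits = call_hits({"s": -4.0, "t": 0.1}, {"s": 0.3, "t": 0.2})
        row = hits.set_index("strain_id").loc["s"]
        assert row["is_hit"] and row["direction"] == "decreased"

    @pytest.mark.parametrize(
        "zn,zo,expected",
        [
            (-4.0, -3.0, False),  # OPT affected
            (2.5, 0.0, False),    # boundary is strict
            (-2.5, 0.0, False),
            (2.6, 2.5, False),    # OPT boundary also strict
            (2.6, 2.4, True),
            (4.0, 0.0, True),
        ],
    )
    def test_cutoff_boundaries(self, zn, zo, expected):
        hits = call_hits({"s": zn, "x": 0.0}, {"s": zo, "x": 0.0})
        assert bool(hits.set_index("strain_id").loc["s", "is_hit"]) is expected

    def test_missing_strains_excluded(self):
        hits = call_hits({"a": 3.0, "b": 0.0}, {"b": 0.0, "c": 1.0})
        assert set(hits["strain_id"]) == {"b"}
        assert hits.attrs["n_excluded"] == 2

    def test_empty_intersection_errors(self):
        with pytest.raises(ValueError):
            call_hits({"a": 1.0}, {"b": 1.0})


class TestEndToEndRecovery:
    def test_spiked_hits_recovered_with_gradients(self):
        """Precision and recall >= 0.95 for 6-sd spikes over 10 seeded plates."""
        tp = fp = fn = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            layout = ngd.make_strain_layout(300)
            # 6 x the ~0.13 log2 sd of strain-level scores
            spiked = {s: -0.78 for s in rng.choice(sorted(layout), 10, replace=False)}
            ngd_plate, opt_plate = ngd.simulate_plate_pair(layout, spiked, seed=seed)
            hits = call_hits(score_plate(ngd_plate), score_plate(opt_plate))
            called = set(hits.loc[hits["is_hit"], "strain_id"])
            true = set(spiked)
            tp += len(called & true)
            fp += len(called - true)
            fn += len(true - called)
        precision = tp / (tp + fp)
        recall = tp / (tp + fn)
        assert precision >= 0.95 and recall >= 0.95

    def test_intensity_scale_invariance(self):
        layout = ngd.make_strain_layout(100)
        plate, _ = ngd.simulate_plate_pair(layout, seed=4)
        scaled = plate.copy()
        scaled[["gfp", "rfp"]] = scaled[["gfp", "rfp"]] * 7.0
        a = score_plate(plate).set_index("strain_id")["z"]
        b = score_plate(scaled).set_index("strain_id")["z"]
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_flat_no_spike_z_standardized(self):
        layout = ngd.make_strain_layout(200)
        plate, _ = ngd.simulate_plate_pair(layout, {}, PlateGradient.flat(), seed=5)
        scores = score_plate(plate)
        assert abs(scores["z"].mean()) < 1e-9
        assert abs(scores["z"].std(ddof=1) - 1) < 1e-9


class TestCandidateOverlaps:
    def test_identical_and_disjoint(self):
        a = {f"s{i}" for i in range(5)}
        out = ngd.candidate_overlaps({"CGA": a, "AAA": set(a)})
        assert out["AAA&CGA"] == 5
        out = ngd.candidate_overlaps({"CGA": a, "AAA": {"x"}})
        assert out["AAA&CGA"] == 0

    def test_designed_shared_hits(self):
        shared = {f"h{i}" for i in range(8)}
        out = ngd.candidate_overlaps(
            {"CGA": shared | {"c1", "c2"}, "AAA": shared | {"a1", "a2"}}
        )
        assert out == {"CGA": 10, "AAA": 10, "AAA&CGA": 8}
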