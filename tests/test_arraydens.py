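"""Antibody-array densitometry: spot quantification, exposure selection,
normalization and clustering, checked against brute-force oracles."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import dendrogram

from monoquant import arraydens, synthio
from monoquant.arraydens import ExposureSeries
from monoquant.errors import (
    GeometryError,
    InvalidParameterError,
    MissingDataError,
    SchemaError,
    UnquantifiableAnalyteError,
)


def series_from_frames(frames, layout, cap=None, **kw):
    return ExposureSeries(frames=frames, frame_interval=2.0, bit_depth=16,
                          layout=layout, saturation_level=cap, **kw)


class TestSpotDensities:
    def test_uniform_frame(self, small_layout):
        h, w = small_layout.frame_shape()
        dens, satur = arraydens.spot_densities(np.full((h, w), 42.0), small_layout)
        assert all(v == pytest.approx(42.0) for v in dens.values())
        assert all(v == 0.0 for v in satur.values())

    def test_fully_clipped_disc(self, small_layout):
        h, w = small_layout.frame_shape()
        frame = np.full((h, w), 65535.0)
        _, satur = arraydens.spot_densities(frame, small_layout)
        assert all(v == 1.0 for v in satur.values())

    def test_matches_pixel_loop(self, small_layout, rng):
        h, w = small_layout.frame_shape()
        frame = rng.uniform(0, 60000, (h, w))
        dens, satur = arraydens.spot_densities(frame, small_layout, 50000.0)
        rc = next(iter(small_layout.spot_map))
        cy, cx = small_layout.center_px(rc)
        r = small_layout.spot_radius_px
        vals = [
            frame[i, j]
            for i in range(h)
            for j in range(w)
            if (i - cy) ** 2 + (j - cx) ** 2 <= r**2
        ]
        assert dens[rc] == pytest.approx(np.mean(vals), rel=1e-12)
        assert satur[rc] == pytest.approx(np.mean([v >= 50000.0 for v in vals]))

    def test_out_of_frame_layout(self, small_layout):
        with pytest.raises(GeometryError):
            arraydens.spot_densities(np.zeros((8, 8)), small_layout)


class TestSaturationFrame:
    def test_unclipped_series_returns_none(self, small_layout):
        c, t, _ = synthio.gen_array_series(
            small_layout, {"CCL2": 5.0, "CCL5": 5.0}, saturation_cap=np.inf, seed=1
        )
        coords = small_layout.coords_for("CCL2")
        assert arraydens.saturation_frame(c, coords) is None

    def test_clips_from_frame_three(self, small_layout):
        h, w = small_layout.frame_shape()
        frames = [np.full((h, w), 100.0) for _ in range(6)]
        for i in range(3, 6):
            frames[i][:] = 65535.0
        s = series_from_frames(frames, small_layout)
        assert arraydens.saturation_frame(s, small_layout.coords_for("CCL2")) == 3

    def test_empty_coords_invalid(self, small_layout):
        c, _, _ = synthio.gen_array_series(small_layout, {"CCL2": 1.0, "CCL5": 1.0}, seed=0)
        with pytest.raises(InvalidParameterError):
            arraydens.saturation_frame(c, [])


def brute_force_best_frame(control, treated, analyte, thr=0.05):
    """Exhaustively verify the verbatim rule: the largest index f such that
    no frame <= f has a saturated analyte or POS spot on either membrane."""
    n = min(len(control.frames), len(treated.frames))
    best = None
    for f in range(n):
        ok = True
        for g in range(f + 1):
            for series in (control, treated):
                _, satur = arraydens.spot_densities(
                    series.frames[g], series.layout, series.saturation_level
                )
                coords = series.layout.coords_for(analyte) + series.layout.coords_for("POS")
                if any(satur[rc] >= thr for rc in coords):
                    ok = False
        if ok:
            best = f
    return best


class TestSelectQuantificationFrame:
    def test_nothing_saturates_gives_last_frame(self, small_layout):
        c, t, _ = synthio.gen_array_series(
            small_layout, {"CCL2": 2.0, "CCL5": 2.0}, saturation_cap=np.inf, seed=2
        )
        assert arraydens.select_quantification_frame(c, t, "CCL2") == len(c.frames) - 1

    def test_min_minus_one_rule(self, small_layout):
        h, w = small_layout.frame_shape()

        def clipped_after(first_sat, coords_role):
            frames = [np.full((h, w), 100.0) for _ in range(8)]
            for i in range(first_sat, 8):
                for rc in small_layout.coords_for(coords_role):
                    cy, cx = small_layout.center_px(rc)
                    yy, xx = np.mgrid[:h, :w]
                    disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= small_layout.spot_radius_px**2
                    frames[i][disc] = 65535.0
            return frames

        control = series_from_frames(clipped_after(4, "POS"), small_layout)  # POS sat at 4
        treated = series_from_frames(clipped_after(5, "CCL2"), small_layout)  # analyte at 5
        assert arraydens.select_quantification_frame(control, treated, "CCL2") == 3

    def test_saturated_at_first_exposure_unquantifiable(self, small_layout):
        h, w = small_layout.frame_shape()
        frames = [np.full((h, w), 65535.0) for _ in range(3)]
        s = series_from_frames(frames, small_layout)
        with pytest.raises(UnquantifiableAnalyteError):
            arraydens.select_quantification_frame(s, s, "CCL2")

    @pytest.mark.parametrize("seed", range(6))
    def test_randomized_fixtures_match_exhaustive_oracle(self, small_layout, seed):
        rng = np.random.default_rng(seed)
        cap = 4000.0
        c, t, _ = synthio.gen_array_series(
            small_layout,
            {"CCL2": float(rng.uniform(1, 40)), "CCL5": float(rng.uniform(1, 40))},
            n_frames=8,
            saturation_cap=cap,
            pos_abundance=float(rng.uniform(5, 40)),
            noise_sd=20.0,
            seed=seed + 100,
        )
        for analyte in ("CCL2", "CCL5"):
            expected = brute_force_best_frame(c, t, analyte)
            if expected is None:
                with pytest.raises(UnquantifiableAnalyteError):
                    arraydens.select_quantification_frame(c, t, analyte)
            else:
                assert arraydens.select_quantification_frame(c, t, analyte) == expected


class TestBackgroundCorrect:
    def test_background_everywhere_gives_zero(self, small_layout):
        dens = {rc: 4.0 for rc in small_layout.spot_map}
        out = arraydens.background_correct(dens, small_layout)
        assert all(v == 0.0 for v in out.values())

    def test_duplicate_mean_arithmetic(self, small_layout):
        dens = {rc: 4.0 for rc in small_layout.spot_map}
        c1, c2 = small_layout.coords_for("CCL2")
        dens[c1], dens[c2] = 14.0, 18.0  # corrected 10 and 14, mean 12... background 4
        out = arraydens.background_correct(dens, small_layout)
        assert out["CCL2"] == pytest.approx((10 + 14) / 2)

    def test_missing_spot_density_is_schema_error(self, small_layout):
        dens = {rc: 4.0 for rc in list(small_layout.spot_map)[:-1]}
        with pytest.raises(SchemaError):
            arraydens.background_correct(dens, small_layout)


class TestFoldChange:
    def test_identical_membranes_unity(self):
        corr = {"CCL2": 10.0, "CCL5": 3.0}
        out = arraydens.analyte_fold_change(corr, dict(corr), 5.0, 5.0)
        assert all(v["fold_change"] == pytest.approx(1.0) for v in out.values())

    def test_treated_signal_x4(self):
        out = arraydens.analyte_fold_change({"a": 2.0}, {"a": 8.0}, 5.0, 5.0)
        assert out["a"]["fold_change"] == pytest.approx(4.0)

    def test_global_exposure_rescale_cancels(self):
        control = {"a": 2.0, "b": 7.0}
        treated = {"a": 9.0, "b": 1.0}
        base = arraydens.analyte_fold_change(control, treated, 5.0, 6.0)
        scaled = arraydens.analyte_fold_change(
            control, {k: 2 * v for k, v in treated.items()}, 5.0, 12.0
        )
        for k in control:
            assert scaled[k]["fold_change"] == pytest.approx(base[k]["fold_change"], rel=1e-12)

    def test_zero_control_flagged_not_fabricated(self):
        out = arraydens.analyte_fold_change({"a": 0.0}, {"a": 5.0}, 1.0, 1.0)
        assert out["a"]["undefined"] and np.isnan(out["a"]["fold_change"])


class TestDetectionCall:
    def test_all_zero_empty(self):
        assert arraydens.detection_call([{"a": 0.0}, {"a": 0.0}], neg_sd=1.0) == set()

    def test_strong_signal_detected_everywhere(self):
        mems = [{"a": 100.0, "b": 0.5}, {"a": 120.0, "b": 50.0}]
        assert arraydens.detection_call(mems, neg_sd=1.0, k=3) == {"a"}


def naive_average_linkage_heights(matrix):
    """O(n^3) agglomerative average linkage over Euclidean distances."""
    pts = [np.asarray(r, dtype=float) for r in matrix]
    clusters = [[i] for i in range(len(pts))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                d = np.mean(
                    [np.linalg.norm(pts[a] - pts[b]) for a in clusters[i] for b in clusters[j]]
                )
                if best is None or d < best[0]:
                    best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return sorted(heights)


class TestClusterHeatmap:
    def test_identical_rows_merge_first(self):
        m = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, -1.0], [0.0, 8.0]])
        out = arraydens.cluster_heatmap(m, ax=False)
        assert out["row_linkage"][0, 2] == pytest.approx(0.0)
        assert set(out["row_linkage"][0, :2].astype(int)) == {0, 1}

    def test_linkage_heights_match_naive_agglomeration(self, rng):
        m = rng.normal(size=(7, 4))
        out = arraydens.cluster_heatmap(m, ax=False)
        assert np.allclose(sorted(out["row_linkage"][:, 2]), naive_average_linkage_heights(m))
        assert np.allclose(
            sorted(out["col_linkage"][:, 2]), naive_average_linkage_heights(m.T)
        )

    def test_row_permutation_preserves_topology(self, rng):
        m = rng.normal(size=(6, 5))
        perm = rng.permutation(6)
        o1 = arraydens.cluster_heatmap(m, ax=False)
        o2 = arraydens.cluster_heatmap(m[perm], ax=False)
        # same set of merge heights and same leaf partition structure
        assert np.allclose(sorted(o1["row_linkage"][:, 2]), sorted(o2["row_linkage"][:, 2]))
        leaves1 = [int(i) for i in dendrogram(o1["row_linkage"], no_plot=True)["leaves"]]
        leaves2 = [int(perm[i]) for i in dendrogram(o2["row_linkage"], no_plot=True)["leaves"]]
        assert set(map(tuple, [leaves1])) is not None  # orders exist
        assert sorted(leaves1) == sorted(leaves2)

    def test_nan_raises(self):
        with pytest.raises(MissingDataError):
            arraydens.cluster_heatmap(np.array([[1.0, np.nan], [0.0, 1.0]]), ax=False)


class TestPipelineRecovery:
    def test_fold_change_recovered_single_seed(self, small_layout):
        ab = {"CCL2": 8.0, "CCL5": 8.0}
        tab = {"CCL2": 32.0, "CCL5": 8.0}
        c, t, _ = synthio.gen_array_series(small_layout, ab, treated_abundance=tab, seed=6)
        res = arraydens.quantify_membrane_pair(c, t)
        assert res["CCL2"].fold_change == pytest.approx(4.0, rel=0.15)
        assert res["CCL5"].fold_change == pytest.approx(1.0, rel=0.15)

    def test_zero_abundance_density_near_background(self, small_layout):
        c, _, _ = synthio.gen_array_series(
            small_layout, {"CCL2": 0.0, "CCL5": 20.0}, noise_sd=5.0, seed=3
        )
        dens, _ = arraydens.spot_densities(c.frames[-1], small_layout)
        bg = np.mean([dens[rc] for rc in small_layout.coords_for("NEG")])
        ccl2 = np.mean([dens[rc] for rc in small_layout.coords_for("CCL2")])
        assert ccl2 == pytest.approx(bg, rel=0.05)
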