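"""Cell/nucleus morphometrics: segmentation, shapes, spacing, height, fold change."""

import numpy as np
import pytest
from skimage import morphology

from epimech import synthetic
from epimech.cells import (
    cell_height,
    cell_height_from_stack,
    fold_change,
    internuclear_distances,
    segment_cells,
    segment_nuclei,
    shape_features,
)
from epimech.datatypes import HeightMap, LabelImage
from epimech.exceptions import (
    EmptySegmentationError,
    InsufficientObjectsError,
    UndefinedRatioError,
)


class TestNucleusSegmentation:
    def test_counts_match_truth(self, monolayer):
        image, _, truth = monolayer
        nuclei = segment_nuclei(image[0], pixel_size=truth.parameters["pixel_size_um"])
        assert nuclei.n_objects == truth.parameters["n_cells"]

    def test_touching_discs_are_split(self):
        img = np.zeros((120, 120))
        yy, xx = np.mgrid[0:120, 0:120]
        img[(xx - 45) ** 2 + (yy - 60) ** 2 <= 20**2] = 100.0
        img[(xx - 80) ** 2 + (yy - 60) ** 2 <= 20**2] = 100.0
        nuclei = segment_nuclei(img)
        assert nuclei.n_objects == 2

    def test_blank_channel_raises(self):
        with pytest.raises(EmptySegmentationError):
            segment_nuclei(np.zeros((64, 64)))


class TestCellSegmentation:
    def test_one_cell_per_nucleus_and_iou(self, monolayer):
        image, labels_true, truth = monolayer
        nuclei = segment_nuclei(image[0], pixel_size=labels_true.pixel_size)
        cells = segment_cells(image[1], nuclei)
        assert cells.n_objects == nuclei.n_objects
        # match each true cell to the predicted label under its centroid
        ious = []
        for _, row in truth.per_object_truth.iterrows():
            r, c = int(row["centroid_row_px"]), int(row["centroid_col_px"])
            pred = cells.labels == cells.labels[r, c]
            true = labels_true.labels == row["object_id"]
            ious.append((pred & true).sum() / (pred | true).sum())
        assert np.mean(ious) >= 0.8

    def test_single_isolated_cell(self):
        image, _, truth = synthetic.gen_monolayer_image(1, 300, 0.3, 80.0, 0.5, seed=3)
        nuclei = segment_nuclei(image[0], pixel_size=0.5)
        cells = segment_cells(image[1], nuclei)
        assert cells.n_objects == 1
        r, c = nuclei.labels.nonzero()
        assert cells.labels[r[0], c[0]] > 0  # the cell contains its nucleus


class TestShapeFeatures:
    def test_disc_circle_metrics(self):
        disc = np.pad(morphology.disk(50).astype(np.int32), 5)
        df = shape_features(LabelImage(disc, 1.0))
        assert df["eccentricity"].iloc[0] <= 0.05
        assert df["compactness"].iloc[0] >= 0.95

    def test_two_to_one_ellipse_eccentricity(self):
        yy, xx = np.mgrid[0:260, 0:260]
        ell = ((((xx - 130) / 100.0) ** 2 + ((yy - 130) / 50.0) ** 2) <= 1).astype(np.int32)
        df = shape_features(LabelImage(ell, 1.0))
        assert df["eccentricity"].iloc[0] == pytest.approx(0.866, abs=0.02)

    def test_square_compactness(self):
        sq = np.zeros((120, 120), np.int32)
        sq[10:110, 10:110] = 1
        df = shape_features(LabelImage(sq, 1.0))
        assert df["compactness"].iloc[0] == pytest.approx(np.pi / 4, abs=0.03)

    def test_scale_law(self):
        def ellipse(scale):
            n = 130 * scale
            yy, xx = np.mgrid[0:n, 0:n]
            a, b = 50.0 * scale, 25.0 * scale
            return ((((xx - n / 2) / a) ** 2 + ((yy - n / 2) / b) ** 2) <= 1).astype(np.int32)

        small_df = shape_features(LabelImage(ellipse(1), 1.0))
        big_df = shape_features(LabelImage(ellipse(2), 1.0))
        assert big_df["area_um2"].iloc[0] == pytest.approx(4 * small_df["area_um2"].iloc[0], rel=0.01)
        assert big_df["perimeter_um"].iloc[0] == pytest.approx(2 * small_df["perimeter_um"].iloc[0], rel=0.02)
        assert abs(big_df["eccentricity"].iloc[0] - small_df["eccentricity"].iloc[0]) < 0.03
        assert abs(big_df["compactness"].iloc[0] - small_df["compactness"].iloc[0]) < 0.03

    def test_per_cell_truth_recovery(self, monolayer):
        image, labels_true, truth = monolayer
        df = shape_features(labels_true, intensity_image=image[1])
        merged = df.merge(truth.per_object_truth, on="object_id")
        np.testing.assert_allclose(merged["area_um2_x"], merged["area_um2_y"], rtol=0.05)
        np.testing.assert_allclose(merged["mean_grey"], merged["mean_intensity"], rtol=0.02)

    def test_nucleus_matching_by_containment(self, monolayer):
        image, labels_true, truth = monolayer
        nuclei = segment_nuclei(image[0], pixel_size=labels_true.pixel_size)
        df = shape_features(labels_true, nuclei=nuclei)
        frac = truth.parameters["nucleus_area_frac"]
        assert df["nc_ratio"].mean() == pytest.approx(frac, rel=0.15)


class TestInternuclearDistances:
    def test_three_four_five(self):
        lab = np.zeros((20, 20), np.int32)
        lab[0, 0] = 1
        lab[3, 4] = 2
        out = internuclear_distances(LabelImage(lab, 1.0))
        np.testing.assert_allclose(out["distances_um"], [5.0, 5.0])

    def test_square_lattice(self):
        lab = np.zeros((50, 50), np.int32)
        k = 1
        for r in range(5, 50, 10):
            for c in range(5, 50, 10):
                lab[r, c] = k
                k += 1
        out = internuclear_distances(LabelImage(lab, 2.0))
        np.testing.assert_allclose(out["distances_um"], 20.0)

    def test_matches_generator_truth(self, monolayer):
        image, labels_true, truth = monolayer
        t = truth.per_object_truth
        px = labels_true.pixel_size
        pts = t[["centroid_row_px", "centroid_col_px"]].to_numpy() * px
        from scipy.spatial import cKDTree

        d, _ = cKDTree(pts).query(pts, k=2)
        lab = np.zeros(labels_true.labels.shape, np.int32)
        for i, (r, c) in enumerate(t[["centroid_row_px", "centroid_col_px"]].to_numpy(), 1):
            lab[int(round(r)), int(round(c))] = i
        out = internuclear_distances(LabelImage(lab, px))
        np.testing.assert_allclose(np.sort(out["distances_um"]), np.sort(d[:, 1]), atol=2 * px)

    def test_single_nucleus_raises(self):
        lab = np.zeros((10, 10), np.int32)
        lab[5, 5] = 1
        with pytest.raises(InsufficientObjectsError):
            internuclear_distances(LabelImage(lab, 1.0))

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(20, 80, (8, 2))

        def dists(points):
            lab = np.zeros((120, 120), np.int32)
            for i, (r, c) in enumerate(points, 1):
                lab[int(round(r)), int(round(c))] = i
            return np.sort(internuclear_distances(LabelImage(lab, 1.0))["distances_um"])

        base = dists(pts)
        shifted = dists(pts + [15.0, -7.0])
        c, s = np.cos(np.pi / 2), np.sin(np.pi / 2)
        rotated = dists((pts - 50) @ np.array([[c, -s], [s, c]]).T + 55)
        np.testing.assert_allclose(shifted, base, atol=1.5)
        np.testing.assert_allclose(rotated, base, atol=1.5)


class TestCellHeight:
    @staticmethod
    def _dome(apex, base=0.0, r=40, size=160):
        yy, xx = np.mgrid[0:size, 0:size]
        d2 = ((xx - size / 2) ** 2 + (yy - size / 2) ** 2) / r**2
        h = np.where(d2 <= 1, apex * np.sqrt(np.clip(1 - d2, 0, None)), 0.0) + base
        return HeightMap(h, 0.5)

    def test_dome_apex_recovered(self):
        assert cell_height(self._dome(10.0)) == pytest.approx(10.0, abs=0.2)

    def test_flat_map_zero(self):
        assert cell_height(HeightMap(np.full((64, 64), 3.3), 0.5)) == 0.0

    def test_reported_height_ratio(self):
        # cells on the nanofibrous insert (15.56 um) vs TCPS (8.99 um)
        ratio = cell_height(self._dome(15.56)) / cell_height(self._dome(8.99))
        assert ratio == pytest.approx(15.56 / 8.99, rel=0.05)

    def test_stack_variant(self):
        occ = np.zeros((30, 8, 8), bool)
        occ[0:21, 2:6, 2:6] = True
        assert cell_height_from_stack(occ, slice_spacing=0.5) == pytest.approx(10.0)


class TestFoldChange:
    def test_identical_groups_unity(self):
        out = fold_change([5.0, 6.0, 7.0], [5.0, 6.0, 7.0], n_boot=200, seed=0)
        assert out["fold_change"] == 1.0

    def test_reciprocity(self):
        a, b = [10.0, 12.0, 11.0], [2.0, 2.5, 2.2]
        f_ab = fold_change(a, b, n_boot=100, seed=0)["fold_change"]
        f_ba = fold_change(b, a, n_boot=100, seed=0)["fold_change"]
        assert f_ab == pytest.approx(1.0 / f_ba, rel=1e-12)

    def test_prescribed_ratio_recovery(self):
        rng = np.random.default_rng(5)
        a = 680.0 * np.exp(rng.normal(0, 0.1, 30) - 0.005)
        b = 100.0 * np.exp(rng.normal(0, 0.1, 30) - 0.005)
        out = fold_change(a, b, seed=1)
        assert out["fold_change"] == pytest.approx(6.8, rel=0.1)
        assert out["ci_low"] < out["fold_change"] < out["ci_high"]

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedRatioError):
            fold_change([1.0, 2.0], [0.0, 0.0])
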