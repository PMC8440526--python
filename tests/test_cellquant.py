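"""Image preprocessing, ratio image, segmentation, vacuole statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage, stats as sps
from skimage.filters import gaussian, threshold_otsu

from idrfret import cellquant, synth
from idrfret.cellquant import CellImageStack
from idrfret.errors import DegenerateDesignError, ShapeError


def disk_stack(shape=(64, 64), center=(32, 32), radius=20, vac_radius=0,
               dxdm=100.0, dxam=100.0, axam=200.0, background=0.0):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    d2 = (rr - center[0]) ** 2 + (cc - center[1]) ** 2
    cell = d2 <= radius**2
    vac = d2 <= vac_radius**2
    cyto = cell & ~vac
    def ch(level):
        img = np.full(shape, background)
        img[cyto] = level
        return img
    return CellImageStack(DxDm=ch(dxdm), DxAm=ch(dxam), AxAm=ch(axam))


class TestPreprocess:
    def test_single_plane_zero_background_identity(self):
        stack = disk_stack()
        out = cellquant.preprocess_stack(stack, background=0.0)
        np.testing.assert_array_equal(out.DxDm, stack.DxDm)

    def test_z_summation(self):
        planes = np.full((3, 16, 16), 10.0)
        stack = CellImageStack(DxDm=planes, DxAm=planes, AxAm=planes, z_planes=3)
        out = cellquant.preprocess_stack(stack, background=0.0)
        np.testing.assert_allclose(out.DxDm, 30.0)

    def test_roi_background_subtraction_and_floor(self):
        stack = disk_stack(background=50.0, dxdm=150.0, dxam=150.0, axam=250.0)
        roi = (slice(0, 5), slice(0, 5))  # pure background corner
        out = cellquant.preprocess_stack(stack, background=roi)
        assert out.DxDm.min() == 0.0
        assert out.DxDm.max() == pytest.approx(100.0)

    def test_roi_out_of_bounds(self):
        with pytest.raises(IndexError):
            cellquant.preprocess_stack(
                disk_stack(), background=(slice(100, 200), slice(0, 5)))

    def test_planted_background_recovered_on_population(self):
        truth = synth.PopulationTruth(n_cells=12, image_shape=(384, 384),
                                      channel_noise_sd=0.0, seed=4)
        pre, _, _ = synth.gen_cell_population(truth)
        shifted = CellImageStack(DxDm=pre.DxDm + 50, DxAm=pre.DxAm + 50,
                                 AxAm=pre.AxAm + 50, lifetime=pre.lifetime)
        out = cellquant.preprocess_stack(shifted)  # 5th-percentile default
        cyto = pre.AxAm > 100
        # generator cytoplasm AxAm level is background(5) + 200
        assert abs(out.AxAm[cyto].mean() - 200.0) / 200.0 < 0.01


class TestRatiometricImage:
    def test_equal_channels_give_unit_ratio(self):
        stack = disk_stack()
        res = cellquant.ratiometric_image(stack, blur_sigma=0)
        inside = res.mask == 1
        np.testing.assert_allclose(res.ratio[inside], 1.0)
        assert (res.ratio[~inside] == 0).all()

    def test_empty_mask_gives_zero_image(self):
        stack = disk_stack()
        res = cellquant.ratiometric_image(stack, mask_threshold=1e9)
        assert (res.ratio == 0).all()

    def test_pixel_exact_vs_naive_recipe(self, rng):
        """Independently coded naive blur/mask/divide recipe must agree
        pixel-for-pixel."""
        for _ in range(5):
            raw = rng.uniform(0, 300, size=(3, 64, 64))
            stack = CellImageStack(DxDm=raw[0], DxAm=raw[1], AxAm=raw[2])
            res = cellquant.ratiometric_image(stack, blur_sigma=1.0)
            # naive re-implementation
            bl = [gaussian(c, sigma=1.0, preserve_range=True) for c in raw]
            mask = (bl[2] > threshold_otsu(bl[2])).astype(float)
            with np.errstate(divide="ignore", invalid="ignore"):
                naive = np.where((mask == 1) & (bl[0] > 0), bl[1] / bl[0], 0.0)
            np.testing.assert_array_equal(res.ratio, naive)


class TestSegmentCells:
    def test_two_disjoint_cells(self):
        rr, cc = np.mgrid[0:96, 0:96]
        axam = np.zeros((96, 96))
        axam[(rr - 25) ** 2 + (cc - 25) ** 2 <= 144] = 200.0
        axam[(rr - 70) ** 2 + (cc - 70) ** 2 <= 144] = 200.0
        stack = CellImageStack(DxDm=axam, DxAm=axam, AxAm=axam)
        labels = cellquant.segment_cells(stack)
        assert labels.max() == 2

    def test_blank_image(self):
        z = np.zeros((32, 32))
        labels = cellquant.segment_cells(CellImageStack(DxDm=z, DxAm=z, AxAm=z))
        assert labels.max() == 0

    def test_population_count_and_iou(self):
        truth = synth.PopulationTruth(n_cells=30, image_shape=(512, 512), seed=13)
        pre, _, table = synth.gen_cell_population(truth)
        labels = cellquant.segment_cells(pre)
        assert labels.max() == 30
        rr, cc = np.mgrid[0:512, 0:512]
        for row in table.itertuples():
            gt_mask = (rr - row.center_row) ** 2 + (cc - row.center_col) ** 2 \
                <= row.radius**2
            lbls = labels[gt_mask]
            lab = np.bincount(lbls[lbls > 0]).argmax()
            seg_mask = labels == lab
            iou = (gt_mask & seg_mask).sum() / (gt_mask | seg_mask).sum()
            assert iou >= 0.9


class TestVacuolarRatio:
    def test_quarter_area_vacuole(self):
        stack = disk_stack(radius=20, vac_radius=10)
        labels = ndimage.binary_fill_holes(stack.AxAm > 0).astype(np.int32)
        table = cellquant.vacuolar_ratio_stats(stack, labels)
        assert abs(table.vacuolar_ratio.item() - 0.25) < 0.02

    def test_no_dark_region_gives_zero(self):
        stack = disk_stack(radius=20, vac_radius=0)
        labels = (stack.AxAm > 0).astype(np.int32)
        table = cellquant.vacuolar_ratio_stats(stack, labels)
        assert table.vacuolar_ratio.item() == 0.0

    def test_population_recovery_within_003(self):
        truth = synth.PopulationTruth(n_cells=30, image_shape=(512, 512), seed=19)
        pre, _, table = synth.gen_cell_population(truth)
        labels = cellquant.segment_cells(pre)
        stats = cellquant.vacuolar_ratio_stats(pre, labels)
        # match measured cells to planted cells by centroid
        cents = ndimage.center_of_mass(np.ones_like(labels), labels,
                                       stats.cell_id.tolist())
        gtpos = table[["center_row", "center_col"]].to_numpy()
        idx = [int(np.argmin(((gtpos - np.array(c)) ** 2).sum(1))) for c in cents]
        planted = table.vacuolar_ratio.to_numpy()[idx]
        err = np.abs(stats.vacuolar_ratio.to_numpy() - planted)
        assert (err <= 0.03).mean() >= 0.95
        assert (stats.vacuolar_ratio >= 0).all()
        assert (stats.vacuole_area <= stats.cell_area).all()

    def test_shape_mismatch(self):
        stack = disk_stack()
        with pytest.raises(ShapeError):
            cellquant.vacuolar_ratio_stats(stack, np.zeros((10, 10), dtype=int))


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(10.0)
        res = cellquant.pearson_correlate(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p_value < 1e-12

    def test_orthogonal_vectors_give_zero(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        x = x - x.mean()
        y = y - y.mean()
        y = y - (y @ x) / (x @ x) * x  # Gram-Schmidt
        res = cellquant.pearson_correlate(x, y)
        assert abs(res.r) < 1e-12

    def test_matches_scipy_exactly(self, rng):
        x = rng.normal(size=40)
        y = 0.4 * x + rng.normal(size=40)
        res = cellquant.pearson_correlate(x, y)
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-9)

    def test_monte_carlo_recovery_of_planted_rho(self, rng):
        rs = []
        for _ in range(200):
            cov = [[1, 0.44], [0.44, 1]]
            xy = rng.multivariate_normal([0, 0], cov, size=100)
            rs.append(cellquant.pearson_correlate(xy[:, 0], xy[:, 1]).r)
        assert abs(np.median(rs) - 0.44) < 0.05

    def test_degenerate_input(self):
        with pytest.raises(DegenerateDesignError):
            cellquant.pearson_correlate([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRoiAnalysis:
    @staticmethod
    def rois_for(center, cell_id=1):
        r, c = center
        return {
            "cell_id": cell_id,
            "background": {"center": (5, 5), "radius": 3},
            "cytoplasm": [
                {"center": (r - 4, c), "radius": 2},
                {"center": (r + 4, c), "radius": 2},
                {"center": (r, c - 4), "radius": 2},
                {"center": (r, c + 4), "radius": 2},
            ],
        }

    def test_unit_ratio_with_zero_background(self):
        stack = disk_stack(center=(32, 32), radius=12, dxdm=100, dxam=100)
        out = cellquant.roi_ratio_analysis(stack, [self.rois_for((32, 32))])
        assert out.raw_ratio.item() == pytest.approx(1.0)

    def test_background_subtraction_exact(self):
        stack = disk_stack(center=(32, 32), radius=12, dxdm=100, dxam=160)
        shifted = CellImageStack(DxDm=stack.DxDm + 100, DxAm=stack.DxAm + 100,
                                 AxAm=stack.AxAm + 100)
        a = cellquant.roi_ratio_analysis(stack, [self.rois_for((32, 32))])
        b = cellquant.roi_ratio_analysis(shifted, [self.rois_for((32, 32))])
        assert a.raw_ratio.item() == pytest.approx(b.raw_ratio.item())

    def test_planted_efficiency_gradient_rank_preserved(self):
        effs = [0.05, 0.15, 0.25, 0.35]
        shape = (64, 256)
        dxdm = np.zeros(shape); dxam = np.zeros(shape); axam = np.zeros(shape)
        rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
        rois = []
        for i, e in enumerate(effs):
            center = (32, 32 + 64 * i)
            cell = (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= 12**2
            dxdm[cell] = 300 * (1 - e)
            dxam[cell] = 300 * e
            axam[cell] = 200
            rois.append(self.rois_for(center, cell_id=i))
        stack = CellImageStack(DxDm=dxdm, DxAm=dxam, AxAm=axam)
        out = cellquant.roi_ratio_analysis(stack, rois)
        rho, _ = sps.spearmanr(effs, out.raw_ratio)
        assert rho == pytest.approx(1.0)

    def test_overlapping_background_warns(self):
        stack = disk_stack(center=(32, 32), radius=12)
        rois = self.rois_for((32, 32))
        rois["background"] = {"center": (32, 28), "radius": 3}
        with pytest.warns(RuntimeWarning):
            cellquant.roi_ratio_analysis(stack, [rois])


def test_end_to_end_correlation_recovery():
    """Full pipeline (segment -> vacuole -> lifetime -> correlate) recovers
    the planted baseline and buffering correlations in sign and size."""
    truth = synth.PopulationTruth.with_target_correlations(
        0.44, -0.47, n_cells=100, seed=2)
    pre, post, _ = synth.gen_cell_population(truth)
    labels = cellquant.segment_cells(pre)
    stats_pre = cellquant.vacuolar_ratio_stats(pre, labels)
    stats_post = cellquant.vacuolar_ratio_stats(post, labels)
    base = cellquant.pearson_correlate(stats_pre.vacuolar_ratio,
                                       stats_pre.mean_lifetime)
    dl = (stats_post.mean_lifetime - stats_pre.mean_lifetime) / stats_pre.mean_lifetime
    buff = cellquant.pearson_correlate(stats_pre.vacuolar_ratio, dl)
    assert base.r > 0 and base.p_value < 0.01
    assert buff.r < 0 and buff.p_value < 0.01
    assert abs(base.r - 0.44) <= 0.15
    assert abs(buff.r - (-0.47)) <= 0.15
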