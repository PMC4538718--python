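import numpy as np
import pytest
from scipy import ndimage

from petasbench.grids import GridSpec, cover_grid
from petasbench.phantom import BinaryMask, LesionSpec, PETImage, extract_ground_truth, rasterise
from petasbench.pipeline import ExperimentConfig, LesionCase, build_case_template, simulate_case
from petasbench.evaluation import crop_roi, dice
from petasbench.segmentation import (
    GCMParams,
    SegmentationRequest,
    estimate_background,
    find_seed,
    segment,
)


def threshold_oracle(values, level):
    """Brute-force reference: largest 26-connected component above a level."""
    mask = values >= level
    labels, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


@pytest.fixture()
def sharp_roi(fixtures):
    b = fixtures["sphere_sharp"]
    return crop_roi(b["image"], b["truth"])


@pytest.fixture()
def noisy_roi(fixtures):
    b = fixtures["sphere_noisy"]
    return crop_roi(b["image"], b["truth"])


class TestFindSeed:
    def test_single_hot_voxel(self):
        g = GridSpec((9, 9, 9), (1, 1, 1))
        v = np.zeros(g.shape)
        v[4, 5, 6] = 1.0
        assert find_seed(PETImage(g, v)) == (4, 5, 6)

    def test_tie_breaks_to_lowest_linear_index(self):
        g = GridSpec((9, 9, 9), (1, 1, 1))
        v = np.zeros(g.shape)
        v[1, 1, 1] = 1.0
        v[7, 7, 7] = 1.0
        assert find_seed(PETImage(g, v)) == (1, 1, 1)

    def test_constant_image_rejected(self):
        g = GridSpec((5, 5, 5), (1, 1, 1))
        with pytest.raises(ValueError):
            find_seed(PETImage(g, np.ones(g.shape)))

    def test_seed_lands_inside_lesion_under_noise(self, fixtures):
        # Monte-Carlo over noise realisations of the two-level sphere
        tpl = fixtures["sphere_noisy"]["template"]
        cfg = ExperimentConfig(
            (LesionCase("S3", LesionSpec("sphere", 17.0, "two_level"), ("AT",)),),
        )
        truth = extract_ground_truth(tpl, cover_grid(tpl.grid, cfg.pet_spacing))
        hits = 0
        for seed in range(100):
            img = simulate_case(tpl, cfg, seed)
            roi = crop_roi(img, truth)
            hits += bool(roi.truth.voxels[find_seed(roi.image)])
        assert hits >= 95


class TestEstimateBackground:
    def test_uniform_image(self):
        g = GridSpec((6, 6, 6), (1, 1, 1))
        assert estimate_background(PETImage(g, np.full(g.shape, 3.3))) == pytest.approx(3.3)

    def test_shell_unaffected_by_central_lesion(self, sharp_roi):
        assert estimate_background(sharp_roi.image) == pytest.approx(1.0)

    def test_tiny_roi_rejected(self):
        g = GridSpec((2, 5, 5), (1, 1, 1))
        with pytest.raises(ValueError):
            estimate_background(PETImage(g, np.ones(g.shape)))


class TestOracleEquivalence:
    """On a sharp two-valued sphere every method must return exactly the
    high-value connected component."""

    @pytest.mark.parametrize("method", ["AT", "RG", "GCM2", "WT"])
    def test_exact_recovery(self, sharp_roi, method):
        res = segment(SegmentationRequest(sharp_roi.image, method))
        oracle = threshold_oracle(sharp_roi.image.values, 2.5)
        assert np.array_equal(res.mask.voxels, oracle)
        assert dice(sharp_roi.truth, res.mask) == 1.0


class TestAT:
    def test_constant_image_empty_mask(self):
        g = GridSpec((8, 8, 8), (1, 1, 1))
        res = segment(SegmentationRequest(PETImage(g, np.ones(g.shape)), "AT"))
        assert res.mask.count == 0
        assert not res.converged

    def test_threshold_diagnostic_between_background_and_max(self, noisy_roi):
        res = segment(SegmentationRequest(noisy_roi.image, "AT"))
        thr = res.diagnostics["final_threshold"]
        assert res.diagnostics["background"] < thr < noisy_roi.image.values.max()


class TestRG:
    def test_only_seeded_component_grown(self):
        # two disjoint hot blocks: region growing must stay on the seeded one
        g = GridSpec((20, 20, 8), (1, 1, 1))
        v = np.ones(g.shape)
        v[2:6, 2:6, 2:6] = 4.0
        v[12:17, 12:17, 2:7] = 4.0  # larger block, higher linear index
        res = segment(SegmentationRequest(PETImage(g, v), "RG"))
        blob = np.zeros(g.shape, dtype=bool)
        blob[12:17, 12:17, 2:7] = True  # seed = smoothed max, tie -> larger block wins smoothing
        seed = find_seed(PETImage(g, v))
        assert res.mask.voxels[seed]
        labels, _ = ndimage.label(res.mask.voxels, structure=np.ones((3, 3, 3)))
        assert labels.max() == 1

    def test_annular_lesion_delivered_filled(self, fixtures):
        b = fixtures["necrotic_spheroid"]
        roi = crop_roi(b["image"], b["truth"])
        core = b["core"].voxels[roi.slices]
        res = segment(SegmentationRequest(roi.image, "RG"))
        assert (res.mask.voxels & core).sum() / core.sum() > 0.9


class TestGCM:
    def test_three_level_image_unions_upper_clusters(self):
        # concentric two-level sphere: background, low rim, high centre
        g = GridSpec((22, 22, 18), (2.73, 2.73, 3.27))
        c = g.centre
        outer = rasterise(g, lambda x, y, z: (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= 11**2)
        inner = rasterise(g, lambda x, y, z: (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 <= 5.5**2)
        v = np.ones(g.shape)
        v[outer] = 4.0
        v[inner] = 7.0
        res = segment(SegmentationRequest(PETImage(g, v), "GCM3"))
        assert np.array_equal(res.mask.voxels, outer)
        means = res.diagnostics["cluster_means"]
        assert np.allclose(means, [1.0, 4.0, 7.0], atol=1e-3)

    def test_cluster_labels_partition_roi(self, noisy_roi):
        res = segment(SegmentationRequest(noisy_roi.image, "GCM4"))
        labels = res.diagnostics["labels"]
        assert labels.shape == noisy_roi.image.values.shape
        assert set(np.unique(labels)) <= set(range(4))

    def test_background_cluster_has_lowest_mean(self, noisy_roi):
        res = segment(SegmentationRequest(noisy_roi.image, "GCM5"))
        means = res.diagnostics["cluster_means"]
        assert res.diagnostics["background_cluster_mean"] == min(means)

    def test_constant_image_rejected(self):
        g = GridSpec((6, 6, 6), (1, 1, 1))
        with pytest.raises(ValueError):
            segment(SegmentationRequest(PETImage(g, np.ones(g.shape)), "GCM2"))

    def test_cluster_count_validated(self):
        with pytest.raises(ValueError):
            GCMParams(n_clusters=9)


class TestWT:
    def test_empty_roi_empty_mask(self):
        g = GridSpec((10, 10, 6), (1, 1, 1))
        res = segment(SegmentationRequest(PETImage(g, np.zeros(g.shape)), "WT"))
        assert res.mask.count == 0

    def test_necrotic_core_mostly_excluded_relative_to_rg(self, fixtures):
        b = fixtures["necrotic_spheroid"]
        roi = crop_roi(b["image"], b["truth"])
        core = b["core"].voxels[roi.slices]
        wt = segment(SegmentationRequest(roi.image, "WT"))
        rg = segment(SegmentationRequest(roi.image, "RG"))
        frac_wt = (wt.mask.voxels & core).sum() / core.sum()
        frac_rg = (rg.mask.voxels & core).sum() / core.sum()
        assert frac_wt < frac_rg  # edge-seeking watershed leaves (part of) the core out


class TestDeterminism:
    @pytest.mark.parametrize("method", ["AT", "RG", "GCM3", "WT"])
    def test_same_request_same_mask(self, noisy_roi, method):
        a = segment(SegmentationRequest(noisy_roi.image, method, seed=5))
        b = segment(SegmentationRequest(noisy_roi.image, method, seed=5))
        assert np.array_equal(a.mask.voxels, b.mask.voxels)
        assert a.mask.grid.same_geometry(noisy_roi.image.grid)
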