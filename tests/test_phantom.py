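import numpy as np
import pytest

from petasbench.grids import GridSpec, cover_grid
from petasbench.phantom import (
    SPHERE_DIAMETERS_MM,
    BackgroundStructure,
    BinaryMask,
    LesionSpec,
    PETImage,
    ScannerConfig,
    UptakeTemplate,
    export_printout_pages,
    extract_ground_truth,
    locate_markers,
    make_background,
    make_irregular_shape,
    make_lesion_template,
    scale_mask,
    simulate_pet,
)


def sphere_volume(d):
    return 4.0 / 3.0 * np.pi * (d / 2.0) ** 3


@pytest.fixture()
def template_grid():
    return GridSpec((70, 70, 35), (1.0, 1.0, 2.0))


@pytest.fixture()
def background(template_grid):
    return make_background(template_grid)


class TestBackground:
    def test_empty_structure_list_is_uniform_unity(self, template_grid):
        t = make_background(template_grid)
        assert np.all(t.values == 1.0)
        assert t.lesion_mask.count == 0

    def test_single_ellipsoid_level(self, template_grid):
        s = BackgroundStructure((35.0, 35.0, 34.0), (15.0, 10.0, 8.0), 0.5)
        t = make_background(template_grid, [s])
        x, y, z = template_grid.meshgrid()
        inside = s.inside(x, y, z)
        assert np.isclose(t.values[inside].mean(), 0.5, atol=0.02)
        # rasterisation only moves the boundary; away from it the map is 1.0
        well_outside = ~np.broadcast_to(
            s.inside(x * 1.0, y * 1.0, z * 1.0), t.values.shape
        ) & (t.values != 0.5)
        assert np.all(t.values[well_outside] == 1.0)
        assert set(np.unique(t.values)) == {0.5, 1.0}

    def test_two_disjoint_structures_three_levels(self, template_grid):
        structs = [
            BackgroundStructure((20.0, 20.0, 20.0), (8.0, 8.0, 6.0), 0.5),
            BackgroundStructure((50.0, 50.0, 48.0), (8.0, 8.0, 6.0), 1.8),
        ]
        t = make_background(template_grid, structs)
        assert np.unique(t.values).size == 3

    def test_overlapping_structures_warn_later_wins(self, template_grid):
        structs = [
            BackgroundStructure((35.0, 35.0, 34.0), (10.0, 10.0, 8.0), 0.5),
            BackgroundStructure((38.0, 35.0, 34.0), (10.0, 10.0, 8.0), 1.5),
        ]
        with pytest.warns(UserWarning, match="overlap"):
            t = make_background(template_grid, structs)
        centre2 = t.grid.world_to_voxel((38.0, 35.0, 34.0))
        assert t.values[tuple(centre2)] == 1.5


class TestLesionSpec:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(shape_kind="cube", size=10),
            dict(shape_kind="sphere", size=10, pattern="striped"),
            dict(shape_kind="sphere", size=-1),
            dict(shape_kind="sphere", size=10, tbr=1.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LesionSpec(**kwargs)


class TestLesionTemplate:
    def test_homogeneous_sphere_level_and_volume(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 38.0, "homogeneous", tbr=4.0))
        assert np.all(t.values[t.lesion_mask.voxels] == 4.0)
        assert abs(t.lesion_mask.volume_mm3 - sphere_volume(38.0)) < 0.02 * sphere_volume(38.0)

    def test_two_level_contrast_rule(self, background):
        # equal contrast steps: high - low == low - background, exactly
        t = make_lesion_template(background, LesionSpec("sphere", 22.0, "two_level", tbr=4.0))
        vals = np.unique(t.values[t.lesion_mask.voxels])
        assert set(vals) == {4.0, 7.0}
        assert (7.0 - 4.0) == (4.0 - t.background_level)

    def test_two_level_inner_region_is_concentric_smaller(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 22.0, "two_level"))
        high = t.values == 7.0
        assert high.sum() > 0
        assert np.all(t.lesion_mask.voxels[high])
        # half-diameter inner sphere holds one eighth of the volume
        assert high.sum() / t.lesion_mask.count == pytest.approx(1 / 8, rel=0.15)

    def test_gaussian_pattern_peaks_centrally(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 28.0, "gaussian"))
        centre = tuple(t.grid.world_to_voxel(t.grid.centre))
        assert t.values[centre] == t.values.max()
        assert t.values.max() < 4.0  # smoothing spreads the homogeneous excess
        assert np.all(t.values >= 1.0 - 1e-12)

    def test_necrotic_core_inside_lesion_and_ground_truth_excludes_it(self, background):
        t = make_lesion_template(background, LesionSpec("spheroid", 11.0, "necrotic"))
        core = t.core_mask
        assert core is not None and core.count > 0
        # core strictly inside the outer shape, which still includes it
        assert np.all(t.lesion_mask.voxels[core.voxels])
        assert core.count < t.lesion_mask.count
        assert np.all(t.values[core.voxels] == t.background_level)
        gt = t.ground_truth
        assert gt.count == t.lesion_mask.count - core.count
        assert not np.any(gt.voxels & core.voxels)
        assert core.volume_mm3 / t.lesion_mask.volume_mm3 == pytest.approx(0.4, rel=0.1)

    def test_necrotic_gaussian_core_stays_cold(self, background):
        t = make_lesion_template(background, LesionSpec("spheroid", 11.0, "necrotic_gaussian"))
        centre = tuple(t.grid.world_to_voxel(t.grid.centre))
        # smoothing spills rim uptake inwards, but the core centre stays the
        # coldest part of the lesion
        assert t.values[centre] < t.values[t.ground_truth.voxels].mean()
        assert t.values[centre] == t.values[t.lesion_mask.voxels].min()
        assert t.values.max() > 2.0

    def test_lesion_without_clearance_rejected(self, background):
        with pytest.raises(ValueError, match="clearance"):
            make_lesion_template(background, LesionSpec("sphere", 60.0, "homogeneous"))

    def test_core_fraction_validated(self, background):
        with pytest.raises(ValueError, match="core"):
            make_lesion_template(
                background, LesionSpec("spheroid", 11.0, "necrotic"), core_volume_fraction=1.2
            )

    def test_scale_mask_volume_ratio(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 28.0, "homogeneous"))
        half = scale_mask(t.lesion_mask, 0.5)
        assert half.count / t.lesion_mask.count == pytest.approx(1 / 8, rel=0.15)


class TestIrregularShape:
    def test_volume_determinism_and_asphericity(self):
        from scipy import ndimage
        from skimage import measure

        g = GridSpec((90, 90, 45), (1, 1, 2))
        m1 = make_irregular_shape(g, 11.0, shape_seed=1)
        m2 = make_irregular_shape(g, 11.0, shape_seed=1)
        m3 = make_irregular_shape(g, 11.0, shape_seed=2)
        assert 10.45 <= m1.volume_ml <= 11.55
        assert np.array_equal(m1.voxels, m2.voxels)
        assert not np.array_equal(m1.voxels, m3.voxels)
        _, n = ndimage.label(m1.voxels, structure=np.ones((3, 3, 3)))
        assert n == 1
        verts, faces, _, _ = measure.marching_cubes(
            m1.voxels.astype(float), 0.5, spacing=g.spacing
        )
        area = measure.mesh_surface_area(verts, faces)
        sphericity = np.pi ** (1 / 3) * (6 * m1.volume_mm3) ** (2 / 3) / area
        assert sphericity < 0.95


class TestSimulatePET:
    def test_zero_template_noiseless_zero_image(self):
        g = GridSpec((20, 20, 10), (1, 1, 2))
        t = UptakeTemplate(g, np.zeros(g.shape))
        img = simulate_pet(t, ScannerConfig(noiseless=True))
        assert np.all(img.values == 0)

    def test_uniform_template_blur_invariant(self):
        g = GridSpec((40, 40, 20), (1, 1, 2))
        t = UptakeTemplate(g, np.full(g.shape, 2.0))
        img = simulate_pet(t, ScannerConfig(noiseless=True))
        interior = img.values[3:-3, 3:-3, 3:-3]
        assert np.all(np.abs(interior - 2.0) / 2.0 < 1e-6)

    def test_point_source_fwhm_matches_psf(self):
        g = GridSpec((61, 61, 31), (1, 1, 2))
        v = np.zeros(g.shape)
        v[30, 30, 15] = 1000.0
        img = simulate_pet(UptakeTemplate(g, v), ScannerConfig(noiseless=True))
        ci = np.unravel_index(np.argmax(img.values), img.values.shape)
        line = img.values[:, ci[1], ci[2]]
        xs = img.grid.axis_centres(0)
        half = line.max() / 2
        above = np.where(line >= half)[0]
        i0, i1 = above[0], above[-1]
        left = np.interp(half, [line[i0 - 1], line[i0]], [xs[i0 - 1], xs[i0]])
        right = np.interp(half, [line[i1 + 1], line[i1]], [xs[i1 + 1], xs[i1]])
        assert abs((right - left) - 6.4) < img.grid.spacing[0]  # within one PET voxel

    def test_excess_activity_conserved(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 22.0, "homogeneous"))
        pg = cover_grid(t.grid, (2.73, 2.73, 3.27))
        img = simulate_pet(t, ScannerConfig(pet_grid=pg, noiseless=True))
        t_excess = (t.values - 1.0).sum() * t.grid.voxel_volume
        p_excess = (img.values - 1.0).sum() * pg.voxel_volume
        assert abs(p_excess - t_excess) / t_excess < 1e-3

    def test_noise_deterministic_per_seed(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 22.0, "homogeneous"))
        a = simulate_pet(t, ScannerConfig(noise_seed=7))
        b = simulate_pet(t, ScannerConfig(noise_seed=7))
        c = simulate_pet(t, ScannerConfig(noise_seed=8))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)


class TestGroundTruthExtraction:
    def test_identity_grid_returns_lesion_mask(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 22.0, "homogeneous"))
        gt = extract_ground_truth(t, t.grid)
        assert gt.same_as(t.lesion_mask)

    def test_large_sphere_volume_on_pet_grid(self, background):
        t = make_lesion_template(background, LesionSpec("sphere", 38.0, "homogeneous"),
                                 min_edge_clearance_mm=10.0)
        gt = extract_ground_truth(t, cover_grid(t.grid, (2.73, 2.73, 3.27)))
        assert abs(gt.volume_mm3 - sphere_volume(38.0)) < 0.05 * sphere_volume(38.0)

    def test_empty_lesion_rejected(self, background):
        with pytest.raises(ValueError):
            extract_ground_truth(background, background.grid)

    def test_necrotic_selects_mask_kind(self, background):
        t = make_lesion_template(background, LesionSpec("spheroid", 11.0, "necrotic"))
        pg = cover_grid(t.grid, (2.73, 2.73, 3.27))
        gt = extract_ground_truth(t, pg)
        outer = extract_ground_truth(t, pg, which="outer")
        core = extract_ground_truth(t, pg, which="core")
        assert outer.count > gt.count
        assert core.count > 0
        assert not np.any(gt.voxels & core.voxels)


class TestPrintoutPages:
    def test_one_page_per_slice_and_blank_pages(self):
        g = GridSpec((60, 60, 5), (1, 1, 2))
        t = make_background(g)
        pages = export_printout_pages(t)
        assert len(pages) == 5
        zt = UptakeTemplate(g, np.zeros(g.shape))
        blank = export_printout_pages(zt)[0]
        assert blank.pixels.max() == 1.0  # markers only
        marked = np.argwhere(blank.pixels > 0)
        assert len(marked) < 100

    def test_markers_disjoint_from_pattern_region(self):
        g = GridSpec((60, 60, 3), (1, 1, 2))
        t = make_background(g)
        page = export_printout_pages(t, marker_offset_mm=20.0)[0]
        pitch = 1.0
        npx, npy = page.pixels.shape
        off_x = (npx - 60) // 2
        off_y = (npy - 60) // 2
        x0, x1 = off_x * pitch, (off_x + 60) * pitch
        y0, y1 = off_y * pitch, (off_y + 60) * pitch
        for mx, my in page.marker_positions:
            assert not (x0 <= mx <= x1 and y0 <= my <= y1)

    def test_wrong_axial_spacing_rejected(self):
        g = GridSpec((40, 40, 4), (1, 1, 3))
        with pytest.raises(ValueError, match="2-mm"):
            export_printout_pages(make_background(g))

    def test_oversized_pattern_rejected(self):
        g = GridSpec((180, 180, 2), (1, 1, 2))
        with pytest.raises(ValueError, match="printable"):
            export_printout_pages(make_background(g))


class TestLocateMarkers:
    def _marker_image(self, shift=None):
        g = GridSpec((40, 40, 5), (2.73, 2.73, 3.27))
        v = np.zeros(g.shape)
        pos = [(20, 5), (5, 20), (35, 20)]
        for i, j in pos:
            v[i, j, :] = 10.0
        if shift is not None:
            i, j = pos[0]
            v[i, j, :] = 0.0
            v[i + shift, j, :] = 10.0
        expected = [tuple(g.index_to_world([i, j, 0])[:2]) for i, j in pos]
        return PETImage(g, v), expected

    def test_exact_markers_zero_offsets(self):
        img, expected = self._marker_image()
        res = locate_markers(img, expected)
        for lab in res.labels:
            assert np.allclose(res.offsets_mm[lab], 0.0)
            assert np.allclose(res.deviation_from_expected_mm[lab], 0.0)
            assert not res.low_confidence[lab].any()

    def test_one_voxel_shift_detected(self):
        img, expected = self._marker_image(shift=1)
        res = locate_markers(img, expected)
        dev = res.deviation_from_expected_mm["T"]
        assert np.allclose(np.abs(dev[:, 0]), img.grid.spacing[0])

    def test_flat_window_low_confidence_tie_lowest_index(self):
        g = GridSpec((20, 20, 2), (2.73, 2.73, 3.27))
        img = PETImage(g, np.ones(g.shape))
        expected = [tuple(g.index_to_world([10, 10, 0])[:2])]
        res = locate_markers(img, expected, labels=("M0",))
        assert res.low_confidence["M0"].all()
        # ties break to the lowest linear index = window corner
        assert np.allclose(res.positions_mm["M0"][0], g.index_to_world([8, 8, 0])[:2])

    def test_boundary_window_warns(self):
        g = GridSpec((20, 20, 2), (2.73, 2.73, 3.27))
        v = np.zeros(g.shape)
        v[0, 0, :] = 5.0
        img = PETImage(g, v)
        with pytest.warns(UserWarning, match="clipped"):
            locate_markers(img, [tuple(g.index_to_world([0, 0, 0])[:2])])
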