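"""Rasterization tests: supercover coverage, CT surrogate, grid accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhizofract import raster
from rhizofract.raster import (
    BinaryImage2D,
    BinaryVolume3D,
    VoxelGrid,
    grid_volume,
    paper_ct_grid,
    rasterize_2d,
    simulate_ct,
    supercover,
    voxelize_3d,
)
from rhizofract.synthetic import Domain, ground_truth_length

from conftest import straight_system


# ---------------------------------------------------------------------------
# supercover
# ---------------------------------------------------------------------------

coord = st.floats(min_value=0.2, max_value=19.8, allow_nan=False)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.tuples(coord, coord), st.tuples(coord, coord))
def test_supercover_covers_every_sampled_point_2d(p0, p1):
    """Dense-sampling oracle: each point of the segment lies in a marked cell."""
    cells = {tuple(c) for c in supercover(np.array(p0), np.array(p1))}
    for t in np.linspace(0, 1, 257):
        pt = (1 - t) * np.array(p0) + t * np.array(p1)
        assert tuple(np.floor(pt).astype(int)) in cells


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    st.tuples(coord, coord, coord),
    st.tuples(coord, coord, coord),
)
def test_supercover_covers_every_sampled_point_3d(p0, p1):
    cells = {tuple(c) for c in supercover(np.array(p0), np.array(p1))}
    for t in np.linspace(0, 1, 257):
        pt = (1 - t) * np.array(p0) + t * np.array(p1)
        assert tuple(np.floor(pt).astype(int)) in cells


def test_supercover_degenerate_segment_is_one_cell():
    assert supercover([2.3, 4.7], [2.3, 4.7]).tolist() == [[2, 4]]


# ---------------------------------------------------------------------------
# 2-D rasterization
# ---------------------------------------------------------------------------

class TestRasterize2D:
    def test_vertical_taproot_is_one_column(self, rhizobox):
        system = straight_system([0, 0, 0], [0, 0, 10.0], rhizobox)
        img = rasterize_2d(system, pitch_cm_per_px=0.1, thickness_px=1)
        cols = np.flatnonzero(img.pixels.any(axis=0))
        assert len(cols) == 1
        rows = np.flatnonzero(img.pixels[:, cols[0]])
        # 10 cm / 0.1 cm per px, endpoints inclusive (fp boundary may drop one)
        assert len(rows) in (100, 101)
        assert np.all(np.diff(rows) == 1)

    def test_pot_domain_rejected(self, pot):
        system = straight_system([0, 0, 0], [0, 0, 5.0], pot)
        with pytest.raises(ValueError, match="rhizobox"):
            rasterize_2d(system, 0.1)

    def test_foreground_count_lower_bound(self, rhizobox):
        """Supercover marks at least ceil(L / (pitch * sqrt(2))) pixels."""
        system = straight_system([-3.0, 0, 1.0], [4.0, 0, 9.0], rhizobox)
        pitch = 0.1
        img = rasterize_2d(system, pitch, 1)
        length = ground_truth_length(system)
        assert img.pixels.sum() >= math.ceil(length / (pitch * math.sqrt(2)))

    def test_translation_consistency(self, rhizobox):
        """Shifting by whole pitches shifts the raster identically."""
        pitch = 0.1
        a = rasterize_2d(straight_system([-1.97, 0, 2.03], [1.33, 0, 8.41], rhizobox), pitch)
        b = rasterize_2d(
            straight_system([-1.97 + 5 * pitch, 0, 2.03 + 3 * pitch],
                            [1.33 + 5 * pitch, 0, 8.41 + 3 * pitch], rhizobox),
            pitch,
        )
        assert np.array_equal(np.roll(a.pixels, (3, 5), axis=(0, 1)), b.pixels)

    def test_thickness_dilation_monotone(self, rhizobox):
        system = straight_system([-3.0, 0, 1.0], [4.0, 0, 9.0], rhizobox)
        thin = rasterize_2d(system, 0.1, 1)
        thick = rasterize_2d(system, 0.1, 3)
        assert np.all(thick.pixels[thin.pixels])
        assert thick.pixels.sum() > thin.pixels.sum()

    def test_invalid_arguments(self, rhizobox):
        system = straight_system([0, 0, 0], [0, 0, 5.0], rhizobox)
        with pytest.raises(ValueError):
            rasterize_2d(system, -0.1)
        with pytest.raises(ValueError):
            rasterize_2d(system, 0.1, thickness_px=0)


# ---------------------------------------------------------------------------
# 3-D voxelization
# ---------------------------------------------------------------------------

class TestVoxelize3D:
    def test_straight_root_spans_101_slices(self, pot):
        """A 20 mm z-aligned root at 0.2 mm slice spacing touches 101 slices."""
        grid = VoxelGrid(32, 32, 128, 0.21, 0.21, 0.2)
        system = straight_system([0, 0, 0], [0, 0, 2.0], pot)
        mask = voxelize_3d(system, grid, radius_voxels=0)
        occupied = np.flatnonzero(mask.mask.any(axis=(1, 2)))
        assert len(occupied) == 101
        assert occupied[0] == 0 and np.all(np.diff(occupied) == 1)

    def test_dilation_monotonicity(self, pot):
        grid = raster.pot_grid(n=48)
        system = straight_system([-2.0, 1.0, 0.5], [3.0, -2.0, 9.0], pot)
        r0 = voxelize_3d(system, grid, 0)
        r1 = voxelize_3d(system, grid, 1)
        assert np.all(r1.mask[r0.mask])
        assert r1.mask.sum() > r0.mask.sum()

    def test_determinism(self, pot):
        grid = raster.pot_grid(n=48)
        system = straight_system([-2.0, 1.0, 0.5], [3.0, -2.0, 9.0], pot)
        assert np.array_equal(voxelize_3d(system, grid, 1).mask, voxelize_3d(system, grid, 1).mask)

    def test_out_of_extent_names_coordinate(self):
        big_pot = Domain.pot(diameter_cm=15.0, height_cm=50.0)
        grid = raster.pot_grid(n=32)  # only 13 cm deep
        system = straight_system([0, 0, 0], [0, 0, 40.0], big_pot)
        with pytest.raises(ValueError, match=r"40\.0*"):
            voxelize_3d(system, grid, 0)


# ---------------------------------------------------------------------------
# CT surrogate and grid accounting
# ---------------------------------------------------------------------------

class TestSimulateCT:
    @pytest.fixture
    def small_mask(self, pot):
        grid = raster.pot_grid(n=32)
        return voxelize_3d(straight_system([0, 0, 0], [2.0, 1.0, 8.0], pot), grid, 1)

    def test_noiseless_volume_is_two_valued(self, small_mask):
        vol = simulate_ct(small_mask, 60.0, 10.0, 0.0, seed=1)
        assert set(np.unique(vol.intensities)) == {10.0, 60.0}

    def test_seeded_determinism(self, small_mask):
        a = simulate_ct(small_mask, 60.0, 0.0, 5.0, seed=4)
        b = simulate_ct(small_mask, 60.0, 0.0, 5.0, seed=4)
        assert np.array_equal(a.intensities, b.intensities)

    def test_mean_root_intensity_clt(self, small_mask):
        """Mean over root voxels within 3 sd / sqrt(n) of the nominal value."""
        sd = 5.0
        vol = simulate_ct(small_mask, 60.0, 0.0, sd, seed=8)
        vals = vol.intensities[small_mask.mask]
        assert abs(vals.mean() - 60.0) <= 3 * sd / math.sqrt(len(vals))

    def test_zero_contrast_rejected(self, small_mask):
        with pytest.raises(ValueError, match="contrast"):
            simulate_ct(small_mask, 5.0, 5.0, 1.0, seed=1)


class TestGridVolume:
    def test_clinical_ct_volume(self):
        """512 x 512 x 500 voxels of 0.21 x 0.21 x 0.2 mm scan 1.156 dm^3."""
        assert grid_volume(paper_ct_grid()) == pytest.approx(1.156, abs=5e-4)

    def test_unit_conversion(self):
        assert grid_volume(VoxelGrid(1, 1, 1, 1, 1, 1)) == pytest.approx(1e-6)

    def test_linearity_in_slice_count(self):
        g1 = VoxelGrid(64, 64, 50, 0.21, 0.21, 0.2)
        g2 = VoxelGrid(64, 64, 100, 0.21, 0.21, 0.2)
        assert grid_volume(g2) == pytest.approx(2 * grid_volume(g1))


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def test_png_round_trip(tmp_path, rhizobox):
    img = rasterize_2d(straight_system([-3.0, 0, 1.0], [4.0, 0, 9.0], rhizobox), 0.1)
    path = tmp_path / "img.png"
    raster.save_image_png(img, path)
    back = raster.load_image_png(path)
    assert np.array_equal(back.pixels, img.pixels)
    assert back.pitch_cm_per_px == img.pitch_cm_per_px


def test_tiff_round_trips(tmp_path, pot):
    grid = raster.pot_grid(n=24)
    mask = voxelize_3d(straight_system([0, 0, 0], [2.0, 1.0, 8.0], pot), grid, 1)
    vol = simulate_ct(mask, 60.0, 0.0, 5.0, seed=3)
    mpath, vpath = tmp_path / "mask.tif", tmp_path / "vol.tif"
    raster.save_volume_tiff(mask, mpath)
    raster.save_volume_tiff(vol, vpath)
    mback = raster.load_binary_volume_tiff(mpath)
    vback = raster.load_gray_volume_tiff(vpath)
    assert np.array_equal(mback.mask, mask.mask)
    assert mback.grid == grid and vback.grid == grid
    assert np.allclose(vback.intensities, vol.intensities, atol=1e-4)


def test_invalid_containers():
    with pytest.raises(ValueError):
        VoxelGrid(0, 1, 1, 1, 1, 1)
    with pytest.raises(ValueError):
        VoxelGrid(1, 1, 1, -1, 1, 1)
    with pytest.raises(ValueError):
        BinaryImage2D(np.zeros((4, 4), bool), pitch_cm_per_px=0.0)
    with pytest.raises(ValueError):
        BinaryVolume3D(raster.pot_grid(n=8), np.zeros((4, 4, 4), bool))
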