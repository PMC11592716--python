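import numpy as np
import pytest

from radiomaps.features import FEATURE_NAMES, compute_feature_vector
from radiomaps.image import ImageVolume, SegmentationMask
from radiomaps.maps import (
    build_grid,
    compute_maps,
    extract_map_means,
    transfer_voi,
)

from oracles import oracle_block_means


def _volume(rng, shape=(16, 16, 4), spacing=(0.5, 0.5, 3.0)):
    return ImageVolume(rng.normal(300, 60, shape), spacing)


# ---------------------------------------------------------------------------
# grid construction

def test_grid_shape_and_interior_cell_size(rng):
    vol = ImageVolume(rng.normal(0, 1, (64, 64, 10)), (0.5, 0.5, 3.0))
    grid = build_grid(vol, (2.0, 2.0, 3.0))
    assert grid.shape == (16, 16, 10)
    assert grid.cell_voxel_count((5, 5, 5)) == 16  # 4 x 4 x 1 voxels


def test_single_cell_covers_whole_volume(rng):
    vol = _volume(rng, (8, 8, 2))
    grid = build_grid(vol, (8 * 0.5, 8 * 0.5, 2 * 3.0))
    assert grid.shape == (1, 1, 1)
    assert grid.cell_voxel_count((0, 0, 0)) == vol.data.size


def test_cells_partition_all_voxels(rng):
    vol = ImageVolume(rng.normal(0, 1, (13, 9, 5)), (0.7, 0.9, 2.1))
    grid = build_grid(vol, (2.0, 2.0, 3.0))
    total = sum(grid.cell_voxel_count(idx) for idx in grid.iter_cells())
    assert total == vol.data.size


def test_cell_smaller_than_voxel_rejected(rng):
    vol = _volume(rng)
    with pytest.raises(ValueError):
        build_grid(vol, (0.25, 2.0, 3.0))


# ---------------------------------------------------------------------------
# map computation

def test_stack_has_93_maps(rng):
    vol = _volume(rng, (8, 8, 1))
    stack = compute_maps(vol)
    assert stack.data.shape[0] == 93
    assert stack.names == FEATURE_NAMES


def test_constant_volume_entropy_zero_uniformity_one():
    vol = ImageVolume(np.full((8, 8, 2), 400.0), (0.5, 0.5, 3.0))
    stack = compute_maps(vol)
    assert np.all(stack.map_for("firstorder.Entropy") == 0.0)
    assert np.all(stack.map_for("firstorder.Uniformity") == 1.0)


def test_mean_map_equals_block_average_oracle(rng):
    vol = _volume(rng, (12, 10, 3))
    grid = build_grid(vol)
    stack = compute_maps(vol, grid)
    expected = oracle_block_means(vol.data, grid.starts)
    np.testing.assert_allclose(stack.map_for("firstorder.Mean"), expected, rtol=1e-12)


def test_maps_finite_on_multilevel_cells(rng):
    vol = _volume(rng, (8, 8, 2))
    stack = compute_maps(vol)
    # Gaussian noise at SD 60 with bin width 25: every 4x4 cell has >= 2 levels
    assert np.isfinite(stack.data).all()


def test_translation_by_one_cell_shifts_maps(rng):
    data = rng.normal(300, 60, (16, 8, 1))
    vol_a = ImageVolume(data, (0.5, 0.5, 3.0))
    shifted = np.roll(data, 4, axis=0)  # one 2 mm cell = 4 voxels
    vol_b = ImageVolume(shifted, (0.5, 0.5, 3.0))
    maps_a = compute_maps(vol_a)
    maps_b = compute_maps(vol_b)
    # interior cells: everything except the wrap-around column
    np.testing.assert_allclose(
        maps_b.data[:, 1:, :, :], maps_a.data[:, :-1, :, :], rtol=1e-12
    )


# ---------------------------------------------------------------------------
# VOI transfer

def test_mask_of_one_full_cell_any_threshold(rng):
    vol = _volume(rng, (8, 8, 2))
    grid = build_grid(vol)
    mask_data = np.zeros(vol.shape, dtype=bool)
    mask_data[grid.cell_slices((1, 1, 1))] = True
    for thr in (0.1, 0.5, 1.0):
        voi = transfer_voi(SegmentationMask(mask_data, vol.spacing), grid, thr)
        assert voi.n_cells == 1
        assert voi.cells[1, 1, 1]
        assert not voi.used_fallback


def test_half_covered_cells_threshold_and_fallback(rng):
    vol = _volume(rng, (8, 4, 1))
    grid = build_grid(vol)  # 2 x 1 x 1 cells of 4x4x1 voxels
    mask_data = np.zeros(vol.shape, dtype=bool)
    mask_data[2:6, :, :] = True  # half of each of the two cells
    mask = SegmentationMask(mask_data, vol.spacing)
    voi = transfer_voi(mask, grid, overlap_threshold=0.5)
    assert voi.n_cells == 2 and not voi.used_fallback
    voi_hi = transfer_voi(mask, grid, overlap_threshold=0.6)
    assert voi_hi.used_fallback  # nothing reaches 0.6 -> any-overlap fallback
    assert voi_hi.n_cells == 2


def test_threshold_monotonicity(rng):
    vol = _volume(rng, (16, 16, 2))
    grid = build_grid(vol)
    mask_data = rng.random(vol.shape) < 0.3
    mask_data[0, 0, 0] = True
    mask = SegmentationMask(mask_data, vol.spacing)
    previous = None
    for thr in (0.9, 0.6, 0.3, 0.1):
        voi = transfer_voi(mask, grid, thr)
        if voi.used_fallback:
            continue
        if previous is not None:
            assert np.all(voi.cells | ~previous)  # lowering never removes cells
        previous = voi.cells


def test_empty_mask_rejected(rng):
    vol = _volume(rng, (8, 8, 1))
    grid = build_grid(vol)
    with pytest.raises(ValueError):
        transfer_voi(SegmentationMask(np.zeros(vol.shape, bool), vol.spacing), grid)


# ---------------------------------------------------------------------------
# extraction

def test_single_cell_voi_roundtrip_bit_identical(rng):
    vol = _volume(rng, (8, 8, 2))
    grid = build_grid(vol)
    stack = compute_maps(vol, grid)
    mask_data = np.zeros(vol.shape, dtype=bool)
    mask_data[grid.cell_slices((0, 1, 1))] = True
    voi = transfer_voi(SegmentationMask(mask_data, vol.spacing), grid)
    means = extract_map_means(stack, voi)
    patch = vol.data[grid.cell_slices((0, 1, 1))]
    direct = compute_feature_vector(patch, voxel_volume=vol.voxel_volume)
    assert np.array_equal(means.to_numpy(), direct.to_numpy())


def test_two_cell_mean(rng):
    vol = _volume(rng, (8, 4, 1))
    grid = build_grid(vol)
    stack = compute_maps(vol, grid)
    stack.data[:, 0, 0, 0] = 1.0
    stack.data[:, 1, 0, 0] = 3.0
    voi = transfer_voi(
        SegmentationMask(np.ones(vol.shape, bool), vol.spacing), grid
    )
    assert np.all(extract_map_means(stack, voi) == 2.0)


def test_extraction_matches_masked_mean_oracle(rng):
    vol = _volume(rng, (16, 16, 4))
    grid = build_grid(vol)
    stack = compute_maps(vol, grid)
    # random VOI over cells, punch in some NaNs
    cells = rng.random(grid.shape) < 0.4
    cells[0, 0, 0] = True
    stack.data[5, 0, 0, 0] = np.nan
    from radiomaps.maps import TransferredVOI

    voi = TransferredVOI(cells=cells, overlap_threshold=0.5)
    means = extract_map_means(stack, voi)
    for i in [0, 5, 40, 92]:
        vals = stack.data[i][cells]
        expected = np.mean(vals[~np.isnan(vals)])
        assert means.iloc[i] == pytest.approx(expected, rel=1e-12)
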