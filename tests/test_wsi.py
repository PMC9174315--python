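"""Tiling arithmetic, background filtering and slide readers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from slidemil import (ArraySlide, SyntheticConfig, filter_background,
                      generate_cohort, open_slide, tile_slide, write_cohort)
from slidemil.wsi import background_mask, get_level, patch_thumbnails


def _slide(w, h, mag=20, fill=120):
    rng = np.random.default_rng(w * 1000 + h)
    img = np.full((h, w, 3), fill, dtype=np.uint8)
    img += rng.integers(0, 40, size=img.shape, dtype=np.uint8)
    return ArraySlide("s", {mag: img})


@pytest.mark.parametrize("w,h,expected", [
    (2048, 1536, 12),
    (512, 512, 1),
    (500, 500, 0),
    (1025, 512, 2),
])
def test_patch_counts_follow_floor_arithmetic(w, h, expected):
    grid = tile_slide(_slide(w, h), 20)
    assert len(grid) == expected
    assert grid.n_rows == h // 512 and grid.n_cols == w // 512


@settings(max_examples=60, deadline=None)
@given(w=st.integers(1, 2600), h=st.integers(1, 2600))
def test_patch_count_property(w, h):
    grid = tile_slide(_slide(w, h), 20, compute_background=False)
    assert len(grid) == (w // 512) * (h // 512)


def test_tiling_is_a_partition():
    grid = tile_slide(_slide(1536, 1024), 20)
    foots = set()
    for p in grid.kept_patches:
        assert p.origin_x == 512 * p.grid_col
        assert p.origin_y == 512 * p.grid_row
        assert p.origin_x + 512 <= 1536 and p.origin_y + 512 <= 1024
        foots.add((p.origin_y, p.origin_x))
    assert len(foots) == len(grid)           # pairwise disjoint footprints


def test_unreadable_slide_raises_ioerror_with_slide_id(tmp_path):
    bad = tmp_path / "broken.tiff"
    bad.write_text("not a tiff")
    with pytest.raises(IOError, match="broken"):
        open_slide(bad)


def test_magnification_synthesized_by_area_averaging():
    img = (np.arange(1024 * 1024 * 3) % 251).astype(np.uint8)
    img = img.reshape(1024, 1024, 3)
    slide = ArraySlide("s", {20: img})
    lv10 = get_level(slide, 10)
    manual = img.reshape(512, 2, 512, 2, 3).mean((1, 3))
    assert np.array_equal(lv10, (manual + 0.5).astype(np.uint8))


def test_physical_footprint_consistent_across_magnifications():
    """A 5x patch covers the same physical field (in base 40x pixels) as
    the corresponding 8x8 block of 40x patches."""
    r, c = 1, 2                               # a 5x patch position
    scale = 40 // 5
    base_y = (512 * r) * scale, (512 * (r + 1)) * scale
    base_x = (512 * c) * scale, (512 * (c + 1)) * scale
    block_y = (512 * (r * 8), 512 * (r * 8 + 8))
    block_x = (512 * (c * 8), 512 * (c * 8 + 8))
    assert base_y == block_y and base_x == block_x
    assert (base_y[1] - base_y[0]) * (base_x[1] - base_x[0]) \
        == 64 * 512 * 512


# -- background -------------------------------------------------------------


def test_white_patch_is_background_and_tissue_is_not():
    white = np.full((64, 64, 3), 245, np.uint8)
    tissue = np.full((64, 64, 3), 120, np.uint8)
    tissue[..., 0] = 180                      # saturated pink
    assert background_mask(white).all()
    assert not background_mask(tissue).any()


def test_filter_background_strict_over_semantics():
    h = w = 1024
    img = np.full((h, w, 3), 130, np.uint8)
    img[..., 0] = 190
    img[:512, :512] = 250                     # patch (0,0): all background
    img[:256, 512:1024] = 250                 # patch (0,1): exactly 50%
    grid = tile_slide(ArraySlide("s", {20: img}), 20)
    by_pos = {(p.grid_row, p.grid_col): p for p in grid.kept_patches}
    assert by_pos[(0, 0)].background_fraction == 1.0
    assert by_pos[(0, 1)].background_fraction == 0.5
    kept = filter_background(grid, 0.5)
    kept_pos = {(p.grid_row, p.grid_col) for p in kept.kept_patches}
    assert (0, 0) not in kept_pos             # over 50% -> excluded
    assert (0, 1) in kept_pos                 # exactly 50% -> kept
    assert len(filter_background(grid, 1.0)) == len(grid)   # identity


@settings(max_examples=30, deadline=None)
@given(st.lists(st.floats(0, 1), min_size=1, max_size=30),
       st.floats(0, 1), st.floats(0, 1))
def test_filter_background_monotone_in_threshold(fracs, t1, t2):
    from slidemil.wsi import Patch, PatchGrid

    t1, t2 = min(t1, t2), max(t1, t2)
    patches = [Patch("s", 20, 0, i, f) for i, f in enumerate(fracs)]
    grid = PatchGrid("s", 20, 1, len(fracs), patches)
    kept1 = {p.grid_col for p in filter_background(grid, t1).kept_patches}
    kept2 = {p.grid_col for p in filter_background(grid, t2).kept_patches}
    assert kept1 <= kept2


def test_patch_thumbnails_are_blockwise_means():
    rng = np.random.default_rng(0)
    img = rng.integers(0, 255, (1024, 512, 3), dtype=np.uint8)
    grid = tile_slide(ArraySlide("s", {20: img}), 20)
    thumbs = patch_thumbnails(grid, thumb=32)
    assert thumbs.shape == (2, 32, 32, 3)
    manual = img[:512, :512].reshape(32, 16, 32, 16, 3).astype(np.float32)
    assert np.allclose(thumbs[0], manual.mean((1, 3)) / 255.0, atol=1e-6)


# -- persistence round-trips -----------------------------------------------


@pytest.mark.parametrize("fmt", ["tiff", "tiles"])
def test_cohort_roundtrip(tmp_path, fmt):
    cfg = SyntheticConfig(n_patients=1, slides_per_patient=(1, 1), seed=3,
                          slide_width_px=2048, slide_height_px=2048,
                          background_margin_px=128)
    manifest, slides = generate_cohort(cfg)
    write_cohort(manifest, slides, tmp_path / fmt, image_format=fmt,
                 magnifications=(10, 20))
    sid = slides[0].slide_id
    path = (tmp_path / fmt / f"{sid}.tiff" if fmt == "tiff"
            else tmp_path / fmt / sid)
    reader = open_slide(path, base_magnification=20)
    for m in (10, 20):
        assert np.array_equal(get_level(reader, m), slides[0].level(m))
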