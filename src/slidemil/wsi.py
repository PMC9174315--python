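"""Pyramidal slide reading and non-overlapping 512x512 patch grids.

Readers implement a small protocol — ``slide_id``, ``base_magnification``,
``magnifications`` and ``level(mag) -> (H, W, 3) uint8`` — with three
backends: in-memory arrays, pyramidal TIFF (via tifffile) and a
directory-of-PNG-tiles fallback. Magnification levels missing from a pyramid
are synthesized by area-averaging from the nearest higher level.

Tiling enumerates the full grid row-major with 0-based (grid_row, grid_col)
coordinates, pixel origins at ``512 * index`` (half-open intervals), and
discards partial edge tiles, so the patch count is exactly
``floor(H/512) * floor(W/512)``. Background is detected with a white-glass
HSV rule (low saturation, high brightness); patches with *over* ``threshold``
background coverage are excluded — a patch at exactly the threshold is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

MAGNIFICATIONS = (5, 10, 20, 40)
PATCH_SIZE = 512

# white-glass background rule (HSV): low saturation AND high brightness
BG_SATURATION_MAX = 0.08
BG_VALUE_MIN = 0.85


class ArraySlide:
    """Slide backed by in-memory rasters, one per magnification."""

    def __init__(self, slide_id: str, levels: dict[int, np.ndarray],
                 base_magnification: int | None = None):
        if not levels:
            raise ValueError("levels must be non-empty")
        for m, a in levels.items():
            if m not in MAGNIFICATIONS:
                raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
            if a.ndim != 3 or a.shape[2] != 3:
                raise ValueError("levels must be (H, W, 3) arrays")
        self.slide_id = slide_id
        self._levels = dict(levels)
        self.base_magnification = base_magnification or max(levels)

    @property
    def magnifications(self):
        return tuple(sorted(self._levels))

    def level(self, magnification: int) -> np.ndarray:
        return self._levels[magnification]


class TiffSlide:
    """Pyramidal TIFF reader. Levels are matched to magnifications by their
    size ratio to the base level (assumed ``base_magnification``)."""

    def __init__(self, path, slide_id: str | None = None,
                 base_magnification: int = 40):
        import tifffile

        self.path = Path(path)
        self.slide_id = slide_id or self.path.stem
        self.base_magnification = base_magnification
        try:
            self._tif = tifffile.TiffFile(self.path)
        except Exception as exc:  # pragma: no cover - exercised via tests
            raise IOError(f"cannot read slide {self.slide_id}: {exc}") from exc
        series = self._tif.series[0]
        self._level_index = {}
        base_shape = series.levels[0].shape
        for i, lv in enumerate(series.levels):
            ratio = base_shape[0] / lv.shape[0]
            mag = base_magnification / ratio
            mag_i = int(round(mag))
            if mag_i in MAGNIFICATIONS and abs(mag - mag_i) < 0.01:
                self._level_index[mag_i] = i

    @property
    def magnifications(self):
        return tuple(sorted(self._level_index))

    def level(self, magnification: int) -> np.ndarray:
        arr = self._tif.series[0].levels[self._level_index[magnification]].asarray()
        return np.asarray(arr)


class TileDirSlide:
    """Reads the ``level_{mag}x/tile_r{r}_c{c}.png`` directory layout."""

    def __init__(self, root, slide_id: str | None = None,
                 base_magnification: int = 40):
        self.root = Path(root)
        self.slide_id = slide_id or self.root.name
        self.base_magnification = base_magnification
        self._mags = tuple(sorted(
            int(d.name[len("level_"):-1]) for d in self.root.glob("level_*x")
        ))
        if not self._mags:
            raise IOError(f"cannot read slide {self.slide_id}: no level dirs")

    @property
    def magnifications(self):
        return self._mags

    def level(self, magnification: int) -> np.ndarray:
        from PIL import Image

        d = self.root / f"level_{magnification}x"
        tiles = {}
        for p in d.glob("tile_r*_c*.png"):
            r, c = p.stem.split("_")[1:]
            tiles[(int(r[1:]), int(c[1:]))] = np.asarray(Image.open(p))
        n_rows = max(r for r, _ in tiles) + 1
        n_cols = max(c for _, c in tiles) + 1
        ps = PATCH_SIZE
        out = np.zeros((n_rows * ps, n_cols * ps, 3), dtype=np.uint8)
        for (r, c), t in tiles.items():
            out[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps] = t
        return out


def open_slide(path, **kwargs):
    path = Path(path)
    if path.is_dir():
        return TileDirSlide(path, **kwargs)
    return TiffSlide(path, **kwargs)


def get_level(slide, magnification: int) -> np.ndarray:
    """Fetch a level, synthesizing it by area-average downsampling from the
    nearest higher magnification when absent from the pyramid."""
    if magnification not in MAGNIFICATIONS:
        raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
    if magnification in slide.magnifications:
        return slide.level(magnification)
    higher = [m for m in slide.magnifications if m > magnification]
    if not higher:
        raise ValueError(
            f"slide {slide.slide_id}: no level at or above {magnification}x"
        )
    src_mag = min(higher)
    k = src_mag // magnification
    src = slide.level(src_mag)
    h, w = (src.shape[0] // k) * k, (src.shape[1] // k) * k
    ds = src[:h, :w].reshape(h // k, k, w // k, k, 3).mean(axis=(1, 3))
    return (ds + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# patches
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Patch:
    slide_id: str
    magnification: int
    grid_row: int
    grid_col: int
    background_fraction: float
    size: int = PATCH_SIZE

    @property
    def origin_x(self) -> int:
        return self.size * self.grid_col

    @property
    def origin_y(self) -> int:
        return self.size * self.grid_row


@dataclass
class PatchGrid:
    slide_id: str
    magnification: int
    n_rows: int
    n_cols: int
    kept_patches: list[Patch]
    level_image: np.ndarray | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.kept_patches)

    def patch_pixels(self, patch: Patch) -> np.ndarray:
        if self.level_image is None:
            raise ValueError("grid carries no pixel data")
        y, x, s = patch.origin_y, patch.origin_x, patch.size
        return self.level_image[y:y + s, x:x + s]

    def to_frame(self, kept_only: bool = True) -> pd.DataFrame:
        rows = [
            {
                "slide_id": p.slide_id,
                "magnification": p.magnification,
                "grid_row": p.grid_row,
                "grid_col": p.grid_col,
                "origin_x": p.origin_x,
                "origin_y": p.origin_y,
                "background_fraction": p.background_fraction,
                "kept": True,
            }
            for p in self.kept_patches
        ]
        return pd.DataFrame(
            rows,
            columns=["slide_id", "magnification", "grid_row", "grid_col",
                     "origin_x", "origin_y", "background_fraction", "kept"],
        )


def background_mask(image: np.ndarray,
                    saturation_max: float = BG_SATURATION_MAX,
                    value_min: float = BG_VALUE_MIN) -> np.ndarray:
    """Boolean white-glass mask: saturation < s_max AND brightness > v_min."""
    img = image.astype(np.float32) / 255.0
    mx = img.max(axis=2)
    mn = img.min(axis=2)
    sat = np.where(mx > 0, (mx - mn) / np.maximum(mx, 1e-9), 0.0)
    return (sat < saturation_max) & (mx > value_min)


def tile_slide(slide, magnification: int, patch_size: int = PATCH_SIZE,
               compute_background: bool = True,
               saturation_max: float = BG_SATURATION_MAX,
               value_min: float = BG_VALUE_MIN,
               keep_pixels: bool = True) -> PatchGrid:
    """Enumerate the full non-overlapping patch grid of one level.

    Partial edge tiles are discarded: ``n_rows = floor(H / patch_size)`` and
    likewise for columns. Patches are listed row-major.
    """
    try:
        level = get_level(slide, magnification)
    except (KeyError, OSError, ValueError) as exc:
        raise IOError(f"cannot read slide {slide.slide_id}: {exc}") from exc
    h, w = level.shape[:2]
    n_rows, n_cols = h // patch_size, w // patch_size

    if compute_background and n_rows and n_cols:
        bg = background_mask(
            level[: n_rows * patch_size, : n_cols * patch_size],
            saturation_max, value_min,
        )
        bg_frac = bg.reshape(n_rows, patch_size, n_cols, patch_size).mean(
            axis=(1, 3)
        )
    else:
        bg_frac = np.zeros((n_rows, n_cols))

    patches = [
        Patch(slide.slide_id, magnification, r, c, float(bg_frac[r, c]),
              patch_size)
        for r in range(n_rows)
        for c in range(n_cols)
    ]
    return PatchGrid(slide.slide_id, magnification, n_rows, n_cols, patches,
                     level if keep_pixels else None)


def filter_background(grid: PatchGrid, threshold: float = 0.5) -> PatchGrid:
    """Drop patches with background fraction strictly over ``threshold``."""
    kept = [p for p in grid.kept_patches if p.background_fraction <= threshold]
    return PatchGrid(grid.slide_id, grid.magnification, grid.n_rows,
                     grid.n_cols, kept, grid.level_image)


def patch_thumbnails(grid: PatchGrid, thumb: int = 32) -> np.ndarray:
    """Block-mean each kept patch down to ``thumb`` pixels on a side.

    Returns float32 ``(n_kept, thumb, thumb, 3)`` in [0, 1].
    """
    if grid.level_image is None:
        raise ValueError("grid carries no pixel data")
    ps = grid.kept_patches[0].size if grid.kept_patches else PATCH_SIZE
    if ps % thumb:
        raise ValueError("patch size must be divisible by thumb")
    k = ps // thumb
    lv = grid.level_image[: grid.n_rows * ps, : grid.n_cols * ps]
    tiles = lv.reshape(grid.n_rows, thumb, k, grid.n_cols, thumb, k, 3)
    thumbs = tiles.astype(np.float32).mean(axis=(2, 5)) / 255.0
    # (n_rows, thumb, n_cols, thumb, 3) -> per-patch lookup
    out = np.stack([
        thumbs[p.grid_row, :, p.grid_col] for p in grid.kept_patches
    ]) if grid.kept_patches else np.zeros((0, thumb, thumb, 3), np.float32)
    return out


def write_patch_inventory(grids, path) -> None:
    frames = [g.to_frame() for g in grids]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
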