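"""Synthetic slide cohorts with planted class-conditional tumor textures.

The generator emulates the structure that weak slide-level supervision relies
on: each patient contributes several pyramidal slides that all share the
patient's binary label, every slide contains a contiguous tumor region
surrounded by peri-tumor tissue, and a procedural texture signal — a small
mean color shift plus coarser blob granularity, scaled by ``effect_size`` —
is planted *only* in tumor regions of positive patients. Peri-tumor texture
is identical across classes, so models restricted to tumor tissue can win
while peri-tumor-only models stay at chance.

Slides are rendered lazily: any pyramid level (5x/10x/20x/40x equivalents)
can be materialized on demand, and identical ``(config, seed)`` always
reproduces bit-identical rasters because every slide draws from its own
deterministic substream keyed by ``(seed, patient_id, slide_id)``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

MAGNIFICATIONS = (5, 10, 20, 40)
BASE_MAGNIFICATION = 40

# region codes in the low-resolution mask
BACKGROUND, TUMOR, PERI_TUMOR = 0, 1, 2

# base colors (RGB in [0,1]) per region; tumor is purple-ish, peri-tumor
# pink-ish so a small classifier can separate them from hue alone
_COLORS = np.array(
    [
        [0.965, 0.960, 0.970],  # background glass
        [0.580, 0.440, 0.700],  # tumor
        [0.880, 0.660, 0.780],  # peri-tumor
    ],
    dtype=np.float32,
)
_BLOB_AMPS = np.array([0.005, 0.060, 0.040], dtype=np.float32)
# per-unit-effect mean shift applied to signal-bearing tumor pixels
_SIGNAL_SHIFT = np.array([-0.015, 0.022, -0.012], dtype=np.float32)
_SIGNAL_BLOB_AMP = 0.020
_CHANNEL_WEIGHTS = np.array([1.0, 0.9, 1.05], dtype=np.float32)

# low-resolution grids relative to the 40x base raster
_FIELD_DS = 8   # blob/field resolution = base / 8 (i.e. 5x-equivalent)
_NOISE_DS = 4   # fine-noise resolution = base / 4 (i.e. 10x-equivalent)


def _stable_hash(*parts) -> int:
    h = hashlib.sha256("\x1f".join(str(p) for p in parts).encode()).digest()
    return int.from_bytes(h[:4], "big")


def _block_mean(a: np.ndarray, k: int) -> np.ndarray:
    h, w = a.shape[:2]
    return a.reshape(h // k, k, w // k, k, *a.shape[2:]).mean(axis=(1, 3))


def _upsample(a: np.ndarray, k: int) -> np.ndarray:
    if k == 1:
        return a
    return np.repeat(np.repeat(a, k, axis=0), k, axis=1)


@dataclass
class SyntheticConfig:
    """Study-condition knobs for the synthetic cohort.

    ``effect_size`` scales the class-conditional tumor-texture shift
    (0 means positives and negatives are drawn from the same distribution);
    ``signal_fraction`` is the fraction of the tumor area that carries the
    shift (1.0 = the whole tumor).
    """

    n_patients: int = 64
    slides_per_patient: tuple[int, int] = (2, 4)
    prevalence: float = 0.5
    slide_width_px: int = 8192
    slide_height_px: int = 8192
    tumor_fraction: float = 0.5
    effect_size: float = 1.0
    noise_sd: float = 0.05
    signal_fraction: float = 1.0
    background_margin_px: int = 512
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        lo, hi = self.slides_per_patient
        if lo < 1 or hi < lo:
            raise ValueError("slides_per_patient must be a range with min >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        if not 0.1 <= self.tumor_fraction <= 0.9:
            raise ValueError("tumor_fraction must be in [0.1, 0.9]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.signal_fraction <= 1.0:
            raise ValueError("signal_fraction must be in (0, 1]")
        for name in ("slide_width_px", "slide_height_px"):
            v = getattr(self, name)
            if v < 64 or v % 64:
                raise ValueError(f"{name} must be a positive multiple of 64")
        if not 0 <= self.background_margin_px < min(
            self.slide_width_px, self.slide_height_px
        ) // 2:
            raise ValueError("background_margin_px must fit inside the slide")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        d = json.loads(Path(path).read_text())
        d["slides_per_patient"] = tuple(d["slides_per_patient"])
        return cls(**d)


class SyntheticSlide:
    """One procedural pyramidal slide. Rasters are rendered on demand.

    Satisfies the reader protocol used by :mod:`slidemil.wsi`
    (``slide_id``, ``base_magnification``, ``magnifications``, ``level``).
    """

    base_magnification = BASE_MAGNIFICATION
    magnifications = MAGNIFICATIONS

    def __init__(self, slide_id: str, patient_id: str, label: int,
                 config: SyntheticConfig):
        self.slide_id = slide_id
        self.patient_id = patient_id
        self.label = int(label)
        self.config = config
        self._geom = None
        self._mask = None

    # -- geometry ----------------------------------------------------------
    def _rng(self, tag: str) -> np.random.Generator:
        c = self.config
        ss = np.random.SeedSequence(
            [c.seed, _stable_hash(self.patient_id), _stable_hash(self.slide_id),
             _stable_hash(tag)]
        )
        return np.random.default_rng(ss)

    def level_shape(self, magnification: int) -> tuple[int, int]:
        if magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
        s = BASE_MAGNIFICATION // magnification
        return (self.config.slide_height_px // s, self.config.slide_width_px // s)

    def region_mask(self) -> np.ndarray:
        """Region labels at base/8 resolution (constant on 8x8 base blocks)."""
        if self._mask is not None:
            return self._mask
        c = self.config
        h = c.slide_height_px // _FIELD_DS
        w = c.slide_width_px // _FIELD_DS
        m = c.background_margin_px // _FIELD_DS
        rng = self._rng("geometry")

        mask = np.full((h, w), PERI_TUMOR, dtype=np.uint8)
        if m:
            mask[:m, :] = BACKGROUND
            mask[-m:, :] = BACKGROUND
            mask[:, :m] = BACKGROUND
            mask[:, -m:] = BACKGROUND

        tissue_area = (h - 2 * m) * (w - 2 * m)
        area = c.tumor_fraction * tissue_area
        aspect = rng.uniform(0.7, 1.4)
        a = np.sqrt(area * aspect / np.pi)   # semi-axis along x
        b = area / (np.pi * a)               # semi-axis along y
        a = min(a, (w - 2 * m) / 2 - 1)
        b = min(b, (h - 2 * m) / 2 - 1)
        cx_lo, cx_hi = m + a, w - m - a
        cy_lo, cy_hi = m + b, h - m - b
        cx = rng.uniform(cx_lo, cx_hi) if cx_hi > cx_lo else w / 2
        cy = rng.uniform(cy_lo, cy_hi) if cy_hi > cy_lo else h / 2

        yy, xx = np.mgrid[0:h, 0:w]
        inside = (((xx + 0.5 - cx) / a) ** 2 + ((yy + 0.5 - cy) / b) ** 2) <= 1.0
        mask[inside & (mask == PERI_TUMOR)] = TUMOR

        self._geom = {"cx": cx, "cy": cy, "a": a, "b": b}
        self._mask = mask
        return mask

    def signal_mask(self) -> np.ndarray:
        """Boolean mask (base/8 res) of tumor pixels carrying the signal.

        For negative patients or effect_size == 0 this is all-False. When
        ``signal_fraction < 1`` only the left part of the tumor (by x
        quantile) carries the shift, giving patch-level signal/non-signal
        contrast inside positive slides.
        """
        mask = self.region_mask()
        out = np.zeros_like(mask, dtype=bool)
        c = self.config
        if not self.label or c.effect_size == 0:
            return out
        tum = mask == TUMOR
        if c.signal_fraction >= 1.0:
            return tum
        xs = np.nonzero(tum)[1]
        cut = np.quantile(xs, c.signal_fraction)
        return tum & (np.arange(mask.shape[1])[None, :] <= cut)

    # -- rasters -----------------------------------------------------------
    def level(self, magnification: int) -> np.ndarray:
        """Render the RGB raster (uint8) for one pyramid level.

        Levels are mutually consistent: up to clipping and uint8
        quantization, level k equals the block-mean of level k-1.
        """
        return self.levels((magnification,))[magnification]

    def _texture_fields(self):
        """(mask, blobs, shift) at field resolution (base/8)."""
        c = self.config
        mask = self.region_mask()
        sig = self.signal_mask()
        rng_f = self._rng("fields")

        def blob(sigma):  # standardized smooth blob field at field resolution
            g = gaussian_filter(
                rng_f.standard_normal(mask.shape).astype(np.float32), sigma
            )
            sd = g.std()
            return g / sd if sd > 0 else g

        f_peri = blob(2.0)
        f_tum = blob(6.0)
        f_sig = blob(12.0)
        blobs = np.where(mask == TUMOR, f_tum, f_peri) * _BLOB_AMPS[mask]
        blobs += sig * (_SIGNAL_BLOB_AMP * c.effect_size) * f_sig
        shift = sig.astype(np.float32)[..., None] * (_SIGNAL_SHIFT * c.effect_size)
        return mask, blobs, shift

    def levels(self, magnifications) -> dict[int, np.ndarray]:
        """Render several pyramid levels sharing one texture computation."""
        c = self.config
        mask, blobs, shift = self._texture_fields()

        noise = None
        if c.noise_sd > 0:
            noise = self._rng("noise").standard_normal(
                (c.slide_height_px // _NOISE_DS, c.slide_width_px // _NOISE_DS, 3)
            ).astype(np.float32)

        out = {}
        for magnification in magnifications:
            hl, wl = self.level_shape(magnification)
            s = BASE_MAGNIFICATION // magnification       # downscale vs base
            f_up = _FIELD_DS // s                         # field -> level
            mask_l = _upsample(mask, f_up)
            img = _COLORS[mask_l].copy()
            img += _upsample(blobs, f_up)[..., None] * _CHANNEL_WEIGHTS
            img += _upsample(shift, f_up)
            if noise is not None:
                if s <= _NOISE_DS:
                    img += c.noise_sd * _upsample(noise, _NOISE_DS // s)
                else:
                    img += c.noise_sd * _block_mean(noise, s // _NOISE_DS)
            np.clip(img, 0.0, 1.0, out=img)
            lv = (img * 255.0 + 0.5).astype(np.uint8)
            assert lv.shape[:2] == (hl, wl)
            out[magnification] = lv
        return out

    def thumbnails(self, magnifications, scale: int = 16) -> dict[int, np.ndarray]:
        """Reduced-resolution renders for several levels, sharing one
        texture computation (see :meth:`render_scaled`)."""
        fields = self._texture_fields()
        return {
            m: self.render_scaled(m, scale, _fields=fields)
            for m in magnifications
        }

    def render_scaled(self, magnification: int, scale: int = 16,
                      _fields=None) -> np.ndarray:
        """Fast reduced-resolution render of one level (float32 in [0, 1]).

        Returns the level raster downsampled by ``scale`` (so a 512x512 patch
        becomes ``512/scale`` pixels on a side), composed directly from the
        coarse procedural grids instead of block-averaging the full raster.
        The smooth texture content (regions, blobs, signal shift) is the
        exact block mean of the full render; the per-pixel noise is drawn at
        the reduced resolution from a dedicated substream with its standard
        deviation scaled by the aggregation factor, and values are not
        clipped/quantized — so this path matches the block-mean of
        :meth:`level` statistically (to ~noise_sd/scale) rather than
        bit-for-bit.
        """
        c = self.config
        s = BASE_MAGNIFICATION // magnification
        S = s * scale                      # total downscale vs base
        mask, blobs, shift = _fields if _fields is not None \
            else self._texture_fields()
        if S >= _FIELD_DS:
            k = S // _FIELD_DS
            maskf = _block_mean(
                np.eye(3, dtype=np.float32)[mask], k
            )                              # soft region fractions
            img = maskf @ _COLORS
            img += _block_mean(blobs, k)[..., None] * _CHANNEL_WEIGHTS
            img += _block_mean(shift, k)
        else:
            f = _FIELD_DS // S
            mask_l = _upsample(mask, f)
            img = _COLORS[mask_l].copy()
            img += _upsample(blobs, f)[..., None] * _CHANNEL_WEIGHTS
            img += _upsample(shift, f)
        if c.noise_sd > 0:
            agg = S / _NOISE_DS            # pixels averaged per axis
            eff_sd = c.noise_sd / agg if agg > 1 else c.noise_sd
            rng = self._rng(f"noise-thumb-{magnification}-{scale}")
            img += eff_sd * rng.standard_normal(img.shape).astype(np.float32)
        return img.astype(np.float32)

    def clear_cache(self) -> None:
        self._geom = None
        self._mask = None

    # -- per-patch bookkeeping --------------------------------------------
    def patch_fractions(self, magnification: int, patch_size: int = 512):
        """Per-patch (tumor, peri_tumor, background, signal) area fractions.

        Computed exactly from the low-resolution region mask (the mask is
        constant on 8x8 base-pixel blocks). Returns four (n_rows, n_cols)
        arrays aligned with the patch grid of :func:`slidemil.wsi.tile_slide`.
        """
        s = BASE_MAGNIFICATION // magnification
        k = patch_size * s // _FIELD_DS  # mask pixels per patch side
        mask = self.region_mask()
        sig = self.signal_mask()
        hl, wl = self.level_shape(magnification)
        n_rows, n_cols = hl // patch_size, wl // patch_size
        mh, mw = n_rows * k, n_cols * k
        sub = mask[:mh, :mw]
        sg = sig[:mh, :mw]

        def frac(v):
            return _block_mean((sub == v).astype(np.float32), k)

        return frac(TUMOR), frac(PERI_TUMOR), frac(BACKGROUND), _block_mean(
            sg.astype(np.float32), k
        )


class SlideManifest:
    """Patient -> slides -> label hierarchy, with optional split assignment."""

    COLUMNS = ["patient_id", "slide_id", "label", "split"]

    def __init__(self, frame: pd.DataFrame):
        missing = {"patient_id", "slide_id", "label"} - set(frame.columns)
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        frame = frame.copy()
        if "split" not in frame.columns:
            frame["split"] = pd.NA
        if frame["slide_id"].duplicated().any():
            raise ValueError("manifest contains duplicate slide_id entries")
        per_patient = frame.groupby("patient_id")["label"].nunique()
        if (per_patient > 1).any():
            raise ValueError("a patient has conflicting labels")
        self.frame = frame[self.COLUMNS].reset_index(drop=True)

    @property
    def patients(self) -> list[str]:
        return list(dict.fromkeys(self.frame["patient_id"]))

    def label_of(self, patient_id: str) -> int:
        rows = self.frame[self.frame["patient_id"] == patient_id]
        if rows.empty:
            raise KeyError(patient_id)
        return int(rows["label"].iloc[0])

    def slides_of(self, patient_id: str) -> list[str]:
        return list(self.frame.loc[
            self.frame["patient_id"] == patient_id, "slide_id"
        ])

    def patient_labels(self) -> pd.Series:
        return self.frame.groupby("patient_id")["label"].first()

    def with_split(self, split: pd.Series) -> "SlideManifest":
        frame = self.frame.copy()
        frame["split"] = frame["patient_id"].map(split)
        return SlideManifest(frame)

    def patients_in(self, split: str) -> list[str]:
        sub = self.frame[self.frame["split"] == split]
        return list(dict.fromkeys(sub["patient_id"]))

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "SlideManifest":
        return cls(pd.read_csv(path))


def generate_cohort(config: SyntheticConfig):
    """Generate a cohort manifest plus lazily-rendered synthetic slides.

    Positive-patient count is ``round(prevalence * n_patients)`` with the
    assignment determined by a seeded shuffle of the patient order.
    """
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, _stable_hash("cohort")])
    )
    n = config.n_patients
    n_pos = int(round(config.prevalence * n))
    order = rng.permutation(n)
    labels = np.zeros(n, dtype=int)
    labels[order[:n_pos]] = 1

    lo, hi = config.slides_per_patient
    rows = []
    slides = []
    width = max(3, len(str(n - 1)))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        n_slides = int(rng.integers(lo, hi + 1))
        for j in range(n_slides):
            sid = f"{pid}_S{j}"
            rows.append({"patient_id": pid, "slide_id": sid,
                         "label": int(labels[i])})
            slides.append(SyntheticSlide(sid, pid, int(labels[i]), config))
    manifest = SlideManifest(pd.DataFrame(rows))
    return manifest, slides


def split_by_patient(manifest: SlideManifest, train_frac: float = 0.7,
                     finetune_frac: float = 0.2, seed: int = 0) -> pd.Series:
    """Assign each patient to train / finetune / test (all slides together).

    ``finetune_frac`` is the fraction of *training* patients carved out as
    the fine-tune (checkpoint-selection) set.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if not 0.0 <= finetune_frac < 1.0:
        raise ValueError("finetune_frac must be in [0, 1)")
    counts = manifest.frame.groupby("patient_id")["slide_id"].count()
    if (counts < 1).any():
        raise ValueError("every patient must have at least one slide")
    patients = np.array(manifest.patients)
    n = len(patients)
    rng = np.random.default_rng(np.random.SeedSequence([seed, _stable_hash("split")]))
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    if n_train >= n:
        raise ValueError("train_frac leaves an empty test set")
    if n_train < 1:
        raise ValueError("train_frac leaves an empty training set")
    n_ft = int(round(finetune_frac * n_train))
    if n_train - n_ft < 1:
        raise ValueError("finetune_frac leaves an empty training set")
    assign = {}
    for k, i in enumerate(order):
        if k < n_ft:
            assign[patients[i]] = "finetune"
        elif k < n_train:
            assign[patients[i]] = "train"
        else:
            assign[patients[i]] = "test"
    return pd.Series(assign, name="split")


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def write_cohort(manifest: SlideManifest, slides, out_dir,
                 image_format: str = "tiff",
                 magnifications=MAGNIFICATIONS) -> None:
    """Write slides (pyramidal TIFF or per-level PNG tile directories),
    the manifest CSV and the config JSON under ``out_dir``."""
    import tifffile
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out / "manifest.csv")
    if slides and isinstance(slides[0], SyntheticSlide):
        slides[0].config.to_json(out / "config.json")
    mags = sorted(magnifications, reverse=True)
    for slide in slides:
        if image_format == "tiff":
            path = out / f"{slide.slide_id}.tiff"
            with tifffile.TiffWriter(path) as tw:
                base = slide.level(mags[0])
                tw.write(base, subifds=len(mags) - 1,
                         metadata={"magnification": mags[0]})
                for m in mags[1:]:
                    tw.write(slide.level(m), subfiletype=1,
                             metadata={"magnification": m})
        elif image_format == "tiles":
            for m in mags:
                lv = slide.level(m)
                d = out / slide.slide_id / f"level_{m}x"
                d.mkdir(parents=True, exist_ok=True)
                ps = 512
                for r in range(lv.shape[0] // ps):
                    for c in range(lv.shape[1] // ps):
                        Image.fromarray(
                            lv[r * ps:(r + 1) * ps, c * ps:(c + 1) * ps]
                        ).save(d / f"tile_r{r}_c{c}.png")
        else:
            raise ValueError("image_format must be 'tiff' or 'tiles'")
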