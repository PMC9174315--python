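"""End-to-end orchestration: features -> per-magnification MIL ensembles ->
hierarchical scores.

``prepare_features`` turns slides into per-(slide, magnification) patch
tables plus 32x32 patch thumbnails (the network input), with background
filtering and tumor / peri-tumor assignment — either from a trained
segmenter or from the synthetic generator's planted masks ("oracle" mode).
``MILPipeline`` then trains one checkpoint ensemble per magnification on
the tumor pools of training patients and produces the ScoreTable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mil import AttentionMILClassifier
from .scoring import DEFAULT_CUTOFF, DEFAULT_MAGNIFICATIONS, build_score_table
from .segmentation import majority_vote_labels
from .synthetic import SyntheticSlide
from .wsi import filter_background, patch_thumbnails, tile_slide


@dataclass
class SlideFeatures:
    """Kept patches of one slide at one magnification."""

    slide_id: str
    magnification: int
    thumbs: np.ndarray          # (n_kept, t, t, 3) float32
    meta: pd.DataFrame          # grid_row, grid_col, background_fraction,
                                # tissue_class, tumor_prob [, *_fraction]
    n_rows: int
    n_cols: int

    def pool(self, tissue: str = "tumor", pure: bool = False) -> np.ndarray:
        """Patch pool for one tissue category.

        ``pure=True`` additionally excludes boundary patches that contain
        *any* pixels of the other tissue (available when mask-derived
        coverage fractions are present, i.e. with oracle gating). A
        majority-vote peri-tumor patch can straddle the tumor margin and
        carry tumor pixels; purity is what makes a peri-tumor-only
        ablation genuinely signal-free on synthetic cohorts.
        """
        if tissue == "whole":
            return self.thumbs
        sel = (self.meta["tissue_class"] == tissue).to_numpy()
        if pure and "tumor_fraction" in self.meta.columns:
            tf = self.meta["tumor_fraction"].to_numpy()
            sel &= (tf == 0.0) if tissue == "peri_tumor" else (tf == 1.0)
        return self.thumbs[sel]

    def tumor_grid(self) -> set[tuple[int, int]]:
        sub = self.meta[self.meta["tissue_class"] == "tumor"]
        return set(zip(sub["grid_row"], sub["grid_col"]))


@dataclass
class CohortFeatures:
    manifest: object                      # SlideManifest
    magnifications: tuple
    slides: dict = field(default_factory=dict)  # (slide_id, mag) -> SlideFeatures

    def get(self, slide_id: str, magnification: int) -> SlideFeatures | None:
        return self.slides.get((slide_id, magnification))

    def pools_for(self, patient_ids, magnification: int, tissue="tumor",
                  pure=False):
        """Per-slide tumor pools and labels for a set of patients.

        Returns (pools, labels, slide_ids, patient_ids); slides with an
        empty pool at this magnification are skipped.
        """
        pools, labels, sids, pids = [], [], [], []
        lab = self.manifest.patient_labels()
        for pid in patient_ids:
            for sid in self.manifest.slides_of(pid):
                sf = self.get(sid, magnification)
                if sf is None:
                    continue
                pool = sf.pool(tissue, pure=pure)
                if len(pool) == 0:
                    continue
                pools.append(pool)
                labels.append(int(lab[pid]))
                sids.append(sid)
                pids.append(pid)
        return pools, np.asarray(labels), sids, pids


def prepare_features(slides, manifest, magnifications=DEFAULT_MAGNIFICATIONS,
                     segmenter="oracle", thumb: int = 32,
                     background_threshold: float = 0.5,
                     pixel_path: bool = False) -> CohortFeatures:
    """Tile, background-filter, segment and thumbnail every slide.

    ``segmenter`` is "oracle" (planted synthetic masks, majority vote), a
    fitted ``PatchSegmenter``, or a dict magnification -> segmenter.
    ``pixel_path=True`` renders full-resolution levels and goes through
    ``tile_slide`` / HSV background filtering; the default fast path uses
    the synthetic slides' reduced-resolution render and exact mask-based
    background bookkeeping (equivalent up to noise; see docs/methods.md).
    """
    feats = CohortFeatures(manifest=manifest,
                           magnifications=tuple(magnifications))
    for slide in slides:
        if pixel_path or not isinstance(slide, SyntheticSlide):
            _prepare_slide_pixels(feats, slide, magnifications, segmenter,
                                  thumb, background_threshold)
        else:
            _prepare_slide_fast(feats, slide, magnifications, segmenter,
                                thumb, background_threshold)
        if isinstance(slide, SyntheticSlide):
            slide.clear_cache()
    return feats


def _tissue_for(segmenter, magnification, thumbs, tumor_fraction):
    if segmenter == "oracle":
        if tumor_fraction is None:
            raise ValueError("oracle segmentation needs synthetic masks")
        return majority_vote_labels(tumor_fraction), np.asarray(
            tumor_fraction, dtype=float
        )
    seg = segmenter[magnification] if isinstance(segmenter, dict) else segmenter
    if getattr(seg, "magnification", None) is not None and \
            seg.magnification != magnification:
        raise ValueError(
            f"segmenter trained at {seg.magnification}x applied to "
            f"{magnification}x patches"
        )
    prob = seg.tumor_probability(thumbs)
    return np.where(prob > 0.5, "tumor", "peri_tumor"), prob


def _prepare_slide_fast(feats, slide, magnifications, segmenter, thumb,
                        background_threshold):
    scale = 512 // thumb
    renders = slide.thumbnails(magnifications, scale=scale)
    for m in magnifications:
        tf, pf, bf, sf = slide.patch_fractions(m)
        n_rows, n_cols = tf.shape
        arr = renders[m]
        rows = []
        thumbs = []
        for r in range(n_rows):
            for c in range(n_cols):
                if bf[r, c] > background_threshold:
                    continue
                rows.append({
                    "grid_row": r, "grid_col": c,
                    "background_fraction": float(bf[r, c]),
                    "tumor_fraction": float(tf[r, c]),
                    "signal_fraction": float(sf[r, c]),
                })
                thumbs.append(arr[r * thumb:(r + 1) * thumb,
                                  c * thumb:(c + 1) * thumb])
        meta = pd.DataFrame(rows, columns=["grid_row", "grid_col",
                                           "background_fraction",
                                           "tumor_fraction",
                                           "signal_fraction"])
        thumbs = (np.stack(thumbs).astype(np.float32) if thumbs
                  else np.zeros((0, thumb, thumb, 3), np.float32))
        np.clip(thumbs, 0.0, 1.0, out=thumbs)
        if meta.empty:
            meta["tissue_class"] = pd.Series(dtype=object)
            meta["tumor_prob"] = pd.Series(dtype=float)
        else:
            cls, prob = _tissue_for(
                segmenter, m, thumbs, meta["tumor_fraction"].to_numpy()
            )
            meta["tissue_class"] = cls
            meta["tumor_prob"] = prob
        feats.slides[(slide.slide_id, m)] = SlideFeatures(
            slide.slide_id, m, thumbs, meta, n_rows, n_cols
        )


def _prepare_slide_pixels(feats, slide, magnifications, segmenter, thumb,
                          background_threshold):
    for m in magnifications:
        grid = tile_slide(slide, m)
        kept = filter_background(grid, background_threshold)
        thumbs = patch_thumbnails(kept, thumb)
        meta = kept.to_frame()[["grid_row", "grid_col",
                                "background_fraction"]].reset_index(drop=True)
        if isinstance(slide, SyntheticSlide):
            tf, _, _, sf = slide.patch_fractions(m)
            meta["tumor_fraction"] = [
                float(tf[p.grid_row, p.grid_col]) for p in kept.kept_patches
            ]
            meta["signal_fraction"] = [
                float(sf[p.grid_row, p.grid_col]) for p in kept.kept_patches
            ]
            tfrac = meta["tumor_fraction"].to_numpy()
        else:
            tfrac = None
        if meta.empty:
            meta["tissue_class"] = pd.Series(dtype=object)
            meta["tumor_prob"] = pd.Series(dtype=float)
        else:
            cls, prob = _tissue_for(segmenter, m, thumbs, tfrac)
            meta["tissue_class"] = cls
            meta["tumor_prob"] = prob
        feats.slides[(slide.slide_id, m)] = SlideFeatures(
            slide.slide_id, m, thumbs, meta, grid.n_rows, grid.n_cols
        )


class MILPipeline:
    """Per-magnification checkpoint ensembles plus hierarchical scoring.

    Parameters mirror :class:`AttentionMILClassifier`; ``magnifications``
    defaults to (5, 10, 20) and must not contain 40.
    """

    def __init__(self, magnifications=DEFAULT_MAGNIFICATIONS,
                 cutoff: float = DEFAULT_CUTOFF, tissue: str = "tumor",
                 tissue_pure: bool = False, random_state: int = 0,
                 **mil_params):
        if 40 in magnifications:
            raise ValueError(
                "40x is excluded from the prediction model (poor predictive "
                "performance); use magnifications within {5, 10, 20}"
            )
        self.magnifications = tuple(magnifications)
        self.cutoff = cutoff
        self.tissue = tissue
        self.tissue_pure = tissue_pure
        self.random_state = random_state
        self.mil_params = mil_params

    def fit(self, features: CohortFeatures, labels=None):
        """Train one MIL ensemble per magnification.

        Training/fine-tune membership comes from the manifest's split
        column. ``labels`` optionally overrides patient labels (e.g. for
        permutation nulls) as a mapping patient_id -> {0, 1}.
        """
        man = features.manifest
        train_p = man.patients_in("train")
        ft_p = man.patients_in("finetune")
        if not train_p or not ft_p:
            raise ValueError("manifest must assign train and finetune patients")
        self.models_ = {}
        self.skipped_magnifications_ = []
        for m in self.magnifications:
            pools, y, _, pids = features.pools_for(
                train_p, m, self.tissue, pure=self.tissue_pure)
            fpools, fy, _, fpids = features.pools_for(
                ft_p, m, self.tissue, pure=self.tissue_pure)
            if labels is not None:
                y = np.array([labels[p] for p in pids])
                fy = np.array([labels[p] for p in fpids])
            if (len(pools) == 0 or len(fpools) == 0
                    or len(np.unique(y)) < 2 or len(np.unique(fy)) < 2):
                import logging

                logging.getLogger(__name__).warning(
                    "skipping %dx: no usable %s pools for training", m,
                    self.tissue,
                )
                self.skipped_magnifications_.append(m)
                continue
            clf = AttentionMILClassifier(
                magnification=m,
                random_state=self.random_state * 1000 + m,
                **self.mil_params,
            )
            clf.fit(pools, y, fpools, fy, groups=pids, finetune_groups=fpids)
            self.models_[m] = clf
        if not self.models_:
            raise ValueError(
                f"no magnification had usable {self.tissue} pools"
            )
        return self

    def score(self, features: CohortFeatures, patients=None) -> pd.DataFrame:
        """ScoreTable for a set of patients (default: the test split)."""
        man = features.manifest
        if patients is None:
            patients = man.patients_in("test") or man.patients
        mag_scores = {}
        for m in self.magnifications:
            if m not in self.models_:
                continue
            pools, _, sids, _ = features.pools_for(
                patients, m, self.tissue, pure=self.tissue_pure)
            if pools:
                scores = self.models_[m].predict_proba(pools)[:, 1]
                for sid, s in zip(sids, scores):
                    mag_scores[(sid, m)] = float(s)
        sub = man.frame[man.frame["patient_id"].isin(set(patients))]
        from .synthetic import SlideManifest

        return build_score_table(
            mag_scores, SlideManifest(sub), self.magnifications, self.cutoff
        )

    def score_pools(self, pools_by_mag: dict) -> float:
        """Score one WSI from explicit per-magnification patch pools
        (used by the biopsy simulator). Missing/empty pools are skipped."""
        per_mag = {}
        for m in self.magnifications:
            pool = pools_by_mag.get(m)
            if m not in self.models_ or pool is None or len(pool) == 0:
                per_mag[m] = float("nan")
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([self.random_state, 303, m])
            )
            from .bags import draw_bag

            clf = self.models_[m]
            bag = np.asarray(pool, dtype=np.float32)[
                draw_bag(len(pool), clf.sample_count_, rng)
            ]
            per_mag[m] = clf.ensemble_score(bag)
        from .scoring import score_wsi

        return score_wsi(per_mag)[0]
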