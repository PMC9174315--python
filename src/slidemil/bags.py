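"""Weakly-labelled patch bags.

Every slide yields one bag per draw: a fixed-size uniform sample of its
tumor patches carrying the *patient's* label (all bags of a positive patient
are positive regardless of where the evidence actually sits). Sample counts
follow the magnification: 8 at 5x, 32 at 10x, 64 at 20x. Slides with fewer
tumor patches than the bag size are padded by sampling with replacement so
the attention layer sees a fixed shape; 40x bags are refused for the final
model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

SAMPLE_COUNTS = {5: 8, 10: 32, 20: 64}


def sample_count_for(magnification: int) -> int:
    if magnification == 40:
        raise ValueError(
            "40x bags are excluded from the prediction model "
            "(low predictive performance); use 5x/10x/20x"
        )
    try:
        return SAMPLE_COUNTS[magnification]
    except KeyError:
        raise ValueError(f"no sample count defined for {magnification}x")


@dataclass
class Bag:
    slide_id: str
    patient_id: str
    magnification: int
    patch_indices: np.ndarray  # indices into the slide's tumor-patch pool
    label: int
    sample_count: int

    def __post_init__(self):
        self.patch_indices = np.asarray(self.patch_indices)
        if len(self.patch_indices) != self.sample_count:
            raise ValueError("bag size must equal sample_count")


def draw_bag(pool_size: int, sample_count: int,
             rng: np.random.Generator) -> np.ndarray:
    """Uniform sample of patch indices; with replacement iff the pool is
    smaller than the bag."""
    if pool_size < 1:
        raise ValueError("cannot draw a bag from an empty patch pool")
    replace = pool_size < sample_count
    return rng.choice(pool_size, size=sample_count, replace=replace)


def make_bags(tumor_pools, manifest, magnification: int,
              n_bags_per_slide: int = 1, seed: int = 0) -> list[Bag]:
    """Build bags for every slide with tumor patches at one magnification.

    Parameters
    ----------
    tumor_pools : mapping slide_id -> pool size (int) or sized collection.
    manifest : SlideManifest supplying patient ids and labels.
    n_bags_per_slide : fresh uniform resamples per slide.

    Slides with an empty pool are skipped with a logged warning.
    """
    count = sample_count_for(magnification)
    rng = np.random.default_rng(seed)
    labels = manifest.patient_labels()
    slide_to_patient = dict(
        zip(manifest.frame["slide_id"], manifest.frame["patient_id"])
    )
    bags = []
    for slide_id in manifest.frame["slide_id"]:
        if slide_id not in tumor_pools:
            continue
        pool = tumor_pools[slide_id]
        pool_size = pool if isinstance(pool, (int, np.integer)) else len(pool)
        if pool_size == 0:
            log.warning("slide %s has no tumor patches at %dx; skipped",
                        slide_id, magnification)
            continue
        pid = slide_to_patient[slide_id]
        for _ in range(n_bags_per_slide):
            idx = draw_bag(pool_size, count, rng)
            bags.append(Bag(slide_id, pid, magnification, idx,
                            int(labels[pid]), count))
    return bags


def bags_to_frame(bags):
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "bag_id": i,
                "slide_id": b.slide_id,
                "patient_id": b.patient_id,
                "magnification": b.magnification,
                "patch_ids": " ".join(map(str, b.patch_indices)),
                "label": b.label,
            }
            for i, b in enumerate(bags)
        ]
    )
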