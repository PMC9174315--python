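"""Synthetic cohort generator: determinism, prevalence, planted signal,
pyramid geometry and patient-level splitting."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from slidemil import SyntheticConfig, generate_cohort, split_by_patient
from slidemil.synthetic import _SIGNAL_SHIFT, TUMOR

SMALL = dict(slide_width_px=2048, slide_height_px=2048,
             background_margin_px=128)


def test_prevalence_rounding_is_exact():
    cfg = SyntheticConfig(n_patients=10, prevalence=0.5, seed=1, **SMALL)
    manifest, _ = generate_cohort(cfg)
    assert manifest.patient_labels().sum() == 5


@pytest.mark.parametrize("prevalence", [0.0, 0.3, 0.37, 0.5, 0.8, 1.0])
def test_prevalence_conservation(prevalence):
    cfg = SyntheticConfig(n_patients=21, prevalence=prevalence, seed=3,
                          **SMALL)
    manifest, _ = generate_cohort(cfg)
    frac = manifest.patient_labels().mean()
    assert abs(frac - prevalence) <= 1.0 / 21


def test_cohort_is_deterministic_and_rasters_bit_identical():
    cfg = SyntheticConfig(n_patients=4, seed=9, **SMALL)
    man1, slides1 = generate_cohort(cfg)
    man2, slides2 = generate_cohort(cfg)
    assert man1.frame.equals(man2.frame)
    for m in (5, 10, 20):
        assert np.array_equal(slides1[0].level(m), slides2[0].level(m))
    assert np.array_equal(slides1[0].render_scaled(20),
                          slides2[0].render_scaled(20))


def test_different_slides_differ():
    cfg = SyntheticConfig(n_patients=4, seed=9, **SMALL)
    _, slides = generate_cohort(cfg)
    assert not np.array_equal(slides[0].level(10), slides[1].level(10))


def test_pyramid_dimensions_scale_with_magnification():
    cfg = SyntheticConfig(n_patients=1, seed=0, **SMALL)
    _, slides = generate_cohort(cfg)
    s = slides[0]
    for m in (5, 10, 20, 40):
        h, w = s.level_shape(m)
        assert (h, w) == (2048 * m // 40, 2048 * m // 40)


def test_levels_are_blockmean_consistent():
    """Level k equals the block-mean of level k-1 up to clip/quantization."""
    cfg = SyntheticConfig(n_patients=1, seed=2, **SMALL)
    _, slides = generate_cohort(cfg)
    lv = slides[0].levels((10, 20))
    bm = lv[20].astype(float).reshape(512, 2, 512, 2, 3).mean((1, 3))
    # quantization of 4 averaged uint8 values: < 1 grey level; clipping at
    # the white margin can add a little more
    assert np.abs(bm - lv[10]).max() <= 3.0


def test_region_mask_covers_full_raster_and_has_all_regions():
    cfg = SyntheticConfig(n_patients=1, seed=4, **SMALL)
    _, slides = generate_cohort(cfg)
    mask = slides[0].region_mask()
    assert mask.shape == (2048 // 8, 2048 // 8)
    assert set(np.unique(mask)) == {0, 1, 2}


def test_zero_effect_size_gives_no_planted_signal():
    cfg = SyntheticConfig(n_patients=6, effect_size=0.0, prevalence=0.5,
                          seed=5, **SMALL)
    _, slides = generate_cohort(cfg)
    pos = [s for s in slides if s.label == 1]
    assert pos and not any(s.signal_mask().any() for s in pos)


def _tumor_patch_stat_auc(effect_size, seed=17, n_patients=12):
    """Brute-force texture-statistic AUC over generated tumor patches:
    project each tumor patch's mean color onto the signal direction.

    Uses full-size slide rasters so each slide contributes several tumor
    patches (patch statistics are correlated within a slide)."""
    cfg = SyntheticConfig(n_patients=n_patients, effect_size=effect_size,
                          prevalence=0.5, seed=seed, slide_width_px=4096,
                          slide_height_px=4096, background_margin_px=256)
    _, slides = generate_cohort(cfg)
    stats, labels = [], []
    direction = _SIGNAL_SHIFT / np.linalg.norm(_SIGNAL_SHIFT)
    for s in slides:
        img = s.render_scaled(20)
        tf, _, _, _ = s.patch_fractions(20)
        for r, c in zip(*np.nonzero(tf > 0.5)):
            patch = img[r * 32:(r + 1) * 32, c * 32:(c + 1) * 32]
            stats.append(float(patch.mean(axis=(0, 1)) @ direction))
            labels.append(s.label)
        s.clear_cache()
    return roc_auc_score(labels, stats)


def test_planted_signal_monotone_in_effect_size():
    aucs = [_tumor_patch_stat_auc(e) for e in (0.0, 0.5, 1.0, 2.0)]
    assert abs(aucs[0] - 0.5) < 0.12          # no signal at zero effect
    for lo, hi in zip(aucs, aucs[1:]):
        assert hi >= lo - 0.03                # non-decreasing (MC tolerance)
    assert aucs[-1] > 0.95


def test_signal_fraction_limits_signal_to_part_of_tumor():
    cfg = SyntheticConfig(n_patients=4, effect_size=2.0, signal_fraction=0.25,
                          prevalence=1.0, seed=6, **SMALL)
    _, slides = generate_cohort(cfg)
    s = slides[0]
    sig, tum = s.signal_mask(), s.region_mask() == TUMOR
    assert sig.sum() > 0 and not sig[~tum].any()
    assert 0.1 < sig.sum() / tum.sum() < 0.4


@pytest.mark.parametrize("bad,msg", [
    (dict(prevalence=1.5), "prevalence"),
    (dict(effect_size=-1), "effect_size"),
    (dict(slides_per_patient=(0, 2)), "slides_per_patient"),
    (dict(tumor_fraction=0.95), "tumor_fraction"),
    (dict(noise_sd=-0.1), "noise_sd"),
    (dict(slide_width_px=1000), "slide_width_px"),
    (dict(n_patients=0), "n_patients"),
])
def test_invalid_config_rejected_with_field_name(bad, msg):
    cfg = SyntheticConfig(**{**SMALL, **bad})
    with pytest.raises(ValueError, match=msg):
        cfg.validate()


# -- splitting --------------------------------------------------------------


def _manifest(n=100, seed=0):
    cfg = SyntheticConfig(n_patients=n, seed=seed, **SMALL)
    manifest, _ = generate_cohort(cfg)
    return manifest


def test_split_keeps_patients_together():
    manifest = _manifest(100)
    split = split_by_patient(manifest, train_frac=0.7, seed=1)
    withsplit = manifest.with_split(split)
    per_patient = withsplit.frame.groupby("patient_id")["split"].nunique()
    assert (per_patient == 1).all()


def test_split_patient_disjoint_over_many_seeds():
    manifest = _manifest(30)
    for seed in range(200):
        split = split_by_patient(manifest, seed=seed)
        assert set(split.index) == set(manifest.patients)
        assert set(split.unique()) <= {"train", "finetune", "test"}
        assert (split == "test").sum() >= 1
        assert (split == "train").sum() >= 1


def test_split_determinism():
    manifest = _manifest(40)
    s1 = split_by_patient(manifest, seed=7)
    s2 = split_by_patient(manifest, seed=7)
    assert s1.equals(s2)


def test_degenerate_split_raises():
    manifest = _manifest(10)
    with pytest.raises(ValueError, match="test"):
        split_by_patient(manifest, train_frac=0.999)
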