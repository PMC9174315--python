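"""Shared fixtures.

The small cohort uses reduced slide rasters so synthetic rendering stays in
the seconds range; the fitted-but-untrained MIL model gives the forward-pass
contract tests a valid parameter set without a training run.
"""

import numpy as np
import pytest

from slidemil import (SyntheticConfig, generate_cohort, prepare_features,
                      split_by_patient)
from slidemil.mil import AttentionMILClassifier


SMALL_SLIDE = dict(slide_width_px=4096, slide_height_px=4096)


@pytest.fixture(scope="session")
def small_cohort():
    """12 patients, strong signal, reduced slides: manifest + slides."""
    cfg = SyntheticConfig(n_patients=12, effect_size=2.0, seed=11,
                          **SMALL_SLIDE)
    manifest, slides = generate_cohort(cfg)
    manifest = manifest.with_split(split_by_patient(manifest, seed=11))
    return cfg, manifest, slides


@pytest.fixture(scope="session")
def small_features(small_cohort):
    cfg, manifest, slides = small_cohort
    return prepare_features(slides, manifest, magnifications=(10, 20))


def untrained_mil(sample_count=16, conv_channels=(4, 8), seed=0,
                  n_checkpoints=5):
    """An AttentionMILClassifier with valid random parameters but no
    training, for forward-pass contract tests."""
    clf = AttentionMILClassifier(sample_count=sample_count,
                                 conv_channels=conv_channels,
                                 random_state=seed)
    rng = np.random.default_rng(seed)
    params = clf._build(rng)
    clf.checkpoints_ = [
        {g: {k: v + 0.01 * i for k, v in p.items()} for g, p in params.items()}
        for i in range(n_checkpoints)
    ]
    clf.checkpoint_epochs_ = list(range(n_checkpoints))
    clf.checkpoint_aucs_ = [0.5] * n_checkpoints
    clf.overfit_epoch_ = None
    clf.sample_count_ = sample_count
    clf.classes_ = np.array([0, 1])
    return clf


@pytest.fixture()
def mil_model():
    return untrained_mil()
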