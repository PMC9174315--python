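"""The reference desk-scale synthetic study.

One place defines the cohort conditions used to validate the whole
pipeline: 64 patients with 2-4 slides each, balanced prevalence, a strong
planted tumor-texture signal (effect size 2.0), tumor covering half the
tissue. Helpers train the full multi-magnification checkpoint-ensemble
pipeline on the patient-level split and report held-out patient AUCs for
the main model, the peri-tumor ablation and label-permutation nulls.

The permutation null is reported as the mean over several independent
label permutations: a single replicate's held-out AUC has Monte-Carlo sd
of roughly 0.13 at ~19 test patients, so averaging replicates is what
makes "chance level" a stable, testable quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evaluation import roc_auc
from .pipeline import MILPipeline, prepare_features
from .scoring import patient_scores
from .synthetic import (SlideManifest, SyntheticConfig, generate_cohort,
                        split_by_patient)

STUDY_CONDITIONS = dict(
    n_patients=64,
    slides_per_patient=(2, 4),
    prevalence=0.5,
    effect_size=2.0,
    tumor_fraction=0.5,
    noise_sd=0.05,
    slide_width_px=8192,
    slide_height_px=8192,
)

DEFAULT_EPOCHS = 12
NULL_REPLICATES = 5


def study_config(seed: int, **overrides) -> SyntheticConfig:
    params = dict(STUDY_CONDITIONS)
    params.update(overrides)
    return SyntheticConfig(seed=seed, **params)


@dataclass
class Study:
    manifest: SlideManifest
    features: object            # CohortFeatures
    seed: int

    @property
    def labels(self):
        return self.manifest.patient_labels()


def build_study(seed: int, magnifications=(5, 10, 20), **overrides) -> Study:
    """Generate the reference cohort and prepare its features (oracle
    tissue gating, so MIL results do not depend on segmenter quality)."""
    cfg = study_config(seed, **overrides)
    manifest, slides = generate_cohort(cfg)
    manifest = manifest.with_split(split_by_patient(manifest, seed=seed))
    features = prepare_features(slides, manifest,
                                magnifications=magnifications)
    return Study(manifest=manifest, features=features, seed=seed)


def train_and_score(study: Study, tissue: str = "tumor", labels=None,
                    epochs: int = DEFAULT_EPOCHS, seed_offset: int = 0):
    """Train the full pipeline and score the held-out test patients.

    Returns ``(pipeline, score_table, auc)``; ``labels`` optionally remaps
    patient labels (permutation nulls), in which case the AUC is computed
    against the remapped labels.
    """
    # the peri-tumor ablation uses pure pools: boundary patches straddling
    # the tumor margin would otherwise leak planted signal into "peri" bags
    pipe = MILPipeline(random_state=study.seed + seed_offset, epochs=epochs,
                       tissue=tissue, tissue_pure=(tissue == "peri_tumor"))
    pipe.fit(study.features, labels=labels)
    table = pipe.score(study.features)
    ps = patient_scores(table)
    if labels is None:
        y = study.labels[ps.index].to_numpy()
    else:
        y = np.array([labels[p] for p in ps.index])
    auc = roc_auc(ps.to_numpy(), y).auc
    return pipe, table, auc


def permutation_null_aucs(study: Study, n_replicates: int = NULL_REPLICATES,
                          epochs: int = DEFAULT_EPOCHS) -> list[float]:
    """Held-out AUCs after training on independently permuted labels."""
    rng = np.random.default_rng(np.random.SeedSequence([study.seed, 909]))
    out = []
    for r in range(n_replicates):
        lab = study.labels
        perm = dict(zip(lab.index, rng.permutation(lab.to_numpy())))
        _, _, auc = train_and_score(study, labels=perm, epochs=epochs,
                                    seed_offset=101 + r)
        out.append(auc)
    return out
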