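"""Tumor / peri-tumor patch classification.

A small trainable CNN classifier (`PatchSegmenter`) assigns each kept,
background-filtered patch to tumor or peri-tumor tissue so that downstream
bags can be restricted to the tumor area. Patch ground truth comes from
pixel region masks by majority vote (> 50% tumor pixels => tumor). An
`OracleSegmenter` that reads synthetic masks directly is provided so MIL
experiments do not depend on segmenter quality.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn

TISSUE_CLASSES = ("peri_tumor", "tumor")


class TinyCNNClassifier(BaseEstimator, ClassifierMixin):
    """Binary image classifier: TinyCNN features + logistic head.

    Trained end-to-end with minibatch Adam on binary cross-entropy.

    Parameters
    ----------
    conv_channels : (int, int)
        Channel widths of the two conv blocks; the second is the feature dim.
    epochs, batch_size, learning_rate : training schedule.
    random_state : seeds parameter init and data order.
    """

    def __init__(self, conv_channels=(8, 16), epochs=12, batch_size=32,
                 learning_rate=3e-3, random_state=0):
        self.conv_channels = conv_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 4 or X.shape[3] != 3:
            raise ValueError("X must be (n, h, w, 3)")
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("training data contains a single class")
        if len(self.classes_) > 2:
            raise ValueError("binary classifier got more than two classes")
        yb = (y == self.classes_[1]).astype(np.float32)

        rng = np.random.default_rng(self.random_state)
        self._cnn = nn.TinyCNN(self.conv_channels)
        self._head = nn.LogisticHead(self._cnn.feature_dim)
        self.params_ = {
            "cnn": self._cnn.init_params(rng),
            "head": self._head.init_params(rng),
        }
        opt_c = nn.Adam(self.learning_rate)
        opt_h = nn.Adam(self.learning_rate)
        n = len(X)
        history = []
        for epoch in range(self.epochs):
            order = rng.permutation(n)
            total = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                xb, tb = X[idx], yb[idx]
                feats, c1 = self._cnn.forward(self.params_["cnn"], xb)
                logits, c2 = self._head.forward(self.params_["head"], feats)
                p = nn.sigmoid(logits)
                eps = 1e-12
                total += float(-(tb * np.log(p + eps)
                                 + (1 - tb) * np.log(1 - p + eps)).sum())
                dlogits = (p - tb) / len(idx)
                gh, dfeat = self._head.backward(self.params_["head"], dlogits, c2)
                gc, _ = self._cnn.backward(
                    self.params_["cnn"], dfeat.astype(np.float32), c1
                )
                opt_h.step(self.params_["head"], gh)
                opt_c.step(self.params_["cnn"], gc)
            history.append(total / n)
        self.loss_curve_ = history
        return self

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise ValueError("classifier is not fitted")

    def decision_function(self, X):
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        out = np.empty(len(X))
        for start in range(0, len(X), 256):
            xb = X[start:start + 256]
            feats, _ = self._cnn.forward(self.params_["cnn"], xb)
            logits, _ = self._head.forward(self.params_["head"], feats)
            out[start:start + len(xb)] = logits
        return out

    def predict_proba(self, X):
        p1 = nn.sigmoid(self.decision_function(X))
        return np.column_stack([1 - p1, p1])

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]

    def features(self, X):
        """Backbone feature vectors (used for patch clustering)."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float32)
        feats, _ = self._cnn.forward(self.params_["cnn"], X)
        return feats


class PatchSegmenter(BaseEstimator, ClassifierMixin):
    """Tumor vs peri-tumor patch classifier.

    A thin wrapper around :class:`TinyCNNClassifier` that carries the
    magnification it was trained for; segmenting a grid at a different
    magnification is an error. ``y`` is either string class names from
    ``TISSUE_CLASSES`` or {0, 1} with 1 = tumor.
    """

    def __init__(self, magnification=None, conv_channels=(8, 16), epochs=12,
                 batch_size=32, learning_rate=3e-3, random_state=0):
        self.magnification = magnification
        self.conv_channels = conv_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.random_state = random_state

    def fit(self, X, y):
        y = np.asarray(y)
        if y.dtype.kind in "UO":
            unknown = set(y) - set(TISSUE_CLASSES)
            if unknown:
                raise ValueError(f"unknown tissue classes: {sorted(unknown)}")
            y = (y == "tumor").astype(int)
        self._clf = TinyCNNClassifier(
            conv_channels=self.conv_channels, epochs=self.epochs,
            batch_size=self.batch_size, learning_rate=self.learning_rate,
            random_state=self.random_state,
        ).fit(X, y)
        self.classes_ = np.array(TISSUE_CLASSES)
        return self

    def predict_proba(self, X):
        return self._clf.predict_proba(X)

    def predict(self, X):
        return self.classes_[(self._clf.decision_function(X) > 0).astype(int)]

    def tumor_probability(self, X):
        return self.predict_proba(X)[:, 1]


    def save(self, directory) -> None:
        """Write the classifier weights (npz) plus a JSON sidecar."""
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        np.savez(d / "segmenter.npz",
                 **{f"{g}.{k}": v for g, p in self._clf.params_.items()
                    for k, v in p.items()})
        sidecar = {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in self.get_params().items()}
        (d / "segmenter.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "PatchSegmenter":
        import json
        from pathlib import Path

        d = Path(directory)
        params = json.loads((d / "segmenter.json").read_text())
        params["conv_channels"] = tuple(params["conv_channels"])
        seg = cls(**params)
        clf = TinyCNNClassifier(
            conv_channels=seg.conv_channels, epochs=seg.epochs,
            batch_size=seg.batch_size, learning_rate=seg.learning_rate,
            random_state=seg.random_state,
        )
        clf._cnn = nn.TinyCNN(seg.conv_channels)
        clf._head = nn.LogisticHead(clf._cnn.feature_dim)
        data = np.load(d / "segmenter.npz")
        clf.params_ = {"cnn": {}, "head": {}}
        for key in data.files:
            g, k = key.split(".", 1)
            clf.params_[g][k] = data[key]
        clf.classes_ = np.array([0, 1])
        seg._clf = clf
        seg.classes_ = np.array(TISSUE_CLASSES)
        return seg


def render_mask_png(class_map: pd.DataFrame, n_rows: int, n_cols: int,
                    path, cell_px: int = 16) -> np.ndarray:
    """Render a PatchClassMap as a small RGB mask image (tumor = purple,
    peri-tumor = pink, unclassified = white) and optionally save it."""
    colors = {"tumor": (148, 112, 178), "peri_tumor": (224, 168, 199)}
    img = np.full((n_rows, n_cols, 3), 255, dtype=np.uint8)
    for _, row in class_map.iterrows():
        img[int(row["grid_row"]), int(row["grid_col"])] = \
            colors[row["tissue_class"]]
    img = np.repeat(np.repeat(img, cell_px, axis=0), cell_px, axis=1)
    if path is not None:
        from PIL import Image

        Image.fromarray(img).save(path)
    return img


class OracleSegmenter:
    """Reads planted region masks instead of classifying pixels: the
    per-patch tumor coverage from the synthetic generator's bookkeeping is
    used directly as the tumor probability (the majority-vote rule then
    thresholds it at 0.5)."""

    magnification = None

    def tumor_probability_from_fractions(self, tumor_fraction):
        return np.asarray(tumor_fraction, dtype=float)


def majority_vote_labels(tumor_fraction) -> np.ndarray:
    """Patch labels from pixel-mask coverage: > 50% tumor pixels => tumor."""
    tf = np.asarray(tumor_fraction, dtype=float)
    return np.where(tf > 0.5, "tumor", "peri_tumor")


def train_segmenter(patches, labels, magnification=None, holdout_frac=0.25,
                    random_state=0, **clf_params):
    """Train a :class:`PatchSegmenter` and report held-out accuracy and AUC.

    Returns ``(segmenter, metrics)`` where metrics has keys
    ``accuracy``, ``auc`` and ``n_holdout``.
    """
    from sklearn.metrics import roc_auc_score

    X = np.asarray(patches, dtype=np.float32)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    rng = np.random.default_rng(random_state)
    order = rng.permutation(len(X))
    n_hold = max(1, int(round(holdout_frac * len(X))))
    hold, train = order[:n_hold], order[n_hold:]
    seg = PatchSegmenter(magnification=magnification,
                         random_state=random_state, **clf_params)
    seg.fit(X[train], y[train])
    yh = (y[hold] == "tumor").astype(int) if y.dtype.kind in "UO" else y[hold]
    prob = seg.tumor_probability(X[hold])
    metrics = {
        "accuracy": float(((prob > 0.5).astype(int) == yh).mean()),
        "auc": float(roc_auc_score(yh, prob)) if len(np.unique(yh)) == 2
        else float("nan"),
        "n_holdout": int(n_hold),
    }
    return seg, metrics


def segment_slide(model, grid, thumbs=None, thumb: int = 32) -> pd.DataFrame:
    """Classify each kept patch of a grid as tumor or peri-tumor.

    Returns a PatchClassMap frame with one row per kept patch:
    ``slide_id, magnification, grid_row, grid_col, tissue_class, tumor_prob``.
    """
    from .wsi import patch_thumbnails

    if getattr(model, "magnification", None) is not None and \
            model.magnification != grid.magnification:
        raise ValueError(
            f"segmenter trained at {model.magnification}x cannot segment a "
            f"{grid.magnification}x grid"
        )
    frame = grid.to_frame()[["slide_id", "magnification", "grid_row",
                             "grid_col"]]
    if frame.empty:
        frame["tissue_class"] = pd.Series(dtype=object)
        frame["tumor_prob"] = pd.Series(dtype=float)
        return frame
    if thumbs is None:
        thumbs = patch_thumbnails(grid, thumb)
    prob = model.tumor_probability(thumbs)
    frame["tissue_class"] = np.where(prob > 0.5, "tumor", "peri_tumor")
    frame["tumor_prob"] = prob
    return frame


def select_tissue(class_map: pd.DataFrame, category: str) -> pd.DataFrame:
    """Subset a PatchClassMap by tissue category ('whole' keeps everything)."""
    if category == "whole":
        return class_map
    if category not in TISSUE_CLASSES:
        raise ValueError(
            f"category must be one of {TISSUE_CLASSES + ('whole',)}"
        )
    return class_map[class_map["tissue_class"] == category]
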