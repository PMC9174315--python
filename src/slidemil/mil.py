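"""Attention-based multiple-instance learning with checkpoint ensembling.

One model per magnification: a small CNN embeds each patch of a bag, gated
attention pooling (tanh x sigmoid gating, softmax over instances) collapses
the bag to a single embedding, and a linear head scores it. Training is
bag-level binary cross-entropy with one fresh uniformly resampled bag per
slide per epoch. A fine-tune set (patient-disjoint part of the training
pool) is scored after every epoch; the five checkpoints with the best
fine-tune AUC recorded before the overfitting point are kept, and the final
score of a bag is the arithmetic mean of the five members' scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from . import nn
from .bags import draw_bag, sample_count_for

N_CHECKPOINTS = 5


@dataclass
class AttentionOutput:
    """Per-instance attention weights, bag embedding and bag score."""

    weights: np.ndarray      # (K,), non-negative, sums to 1
    embedding: np.ndarray    # (feature_dim,)
    logit: float
    score: float             # sigmoid(logit), in [0, 1]


class AttentionMILClassifier(BaseEstimator, ClassifierMixin):
    """Bag-level binary classifier with gated attention pooling.

    Parameters
    ----------
    magnification : 5, 10 or 20; fixes the bag size via the standard
        sample counts (8/32/64) unless ``sample_count`` is given. 40 is
        refused for the prediction model.
    backbone : only ``"tiny_cnn"`` ships; other names raise, and
        ``BACKBONES`` can be extended with objects implementing the
        TinyCNN forward/backward contract.
    epochs : total training epochs; must be >= ``n_checkpoints``.
    smoothing_window / rise_patience : overfitting detection on the
        fine-tune loss curve (first epoch where the smoothed loss has risen
        for ``rise_patience`` consecutive epochs).
    """

    BACKBONES = {"tiny_cnn": nn.TinyCNN}

    def __init__(self, magnification=None, sample_count=None,
                 backbone="tiny_cnn", conv_channels=(8, 16),
                 attention_hidden_dim=8, learning_rate=3e-3, epochs=12,
                 n_bags_per_slide=1, n_checkpoints=N_CHECKPOINTS,
                 smoothing_window=3, rise_patience=3, random_state=0):
        self.magnification = magnification
        self.sample_count = sample_count
        self.backbone = backbone
        self.conv_channels = conv_channels
        self.attention_hidden_dim = attention_hidden_dim
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.n_bags_per_slide = n_bags_per_slide
        self.n_checkpoints = n_checkpoints
        self.smoothing_window = smoothing_window
        self.rise_patience = rise_patience
        self.random_state = random_state

    # -- internals ---------------------------------------------------------
    def _resolve_sample_count(self):
        if self.sample_count is not None:
            return int(self.sample_count)
        if self.magnification is None:
            raise ValueError("either magnification or sample_count is required")
        return sample_count_for(self.magnification)

    def _build(self, rng):
        if self.backbone not in self.BACKBONES:
            raise ValueError(
                f"unknown backbone {self.backbone!r}; available: "
                f"{sorted(self.BACKBONES)}"
            )
        self._cnn = self.BACKBONES[self.backbone](self.conv_channels)
        self._head = nn.GatedAttentionHead(
            self._cnn.feature_dim, self.attention_hidden_dim
        )
        return {
            "cnn": self._cnn.init_params(rng),
            "head": self._head.init_params(rng),
        }

    def _forward(self, params, instances):
        feats, c1 = self._cnn.forward(params["cnn"], instances)
        a, z, logit, c2 = self._head.forward(params["head"], feats)
        return a, z, logit, (c1, c2)

    # -- training ----------------------------------------------------------
    def fit(self, X, y, finetune_X=None, finetune_y=None,
            groups=None, finetune_groups=None):
        """Train and select the checkpoint ensemble.

        X, finetune_X : lists of per-slide tumor-patch pools, each a float
            array (P_i, h, w, 3) in [0, 1]; y the per-slide (= patient)
            labels in {0, 1}. When patient groups are given for both sets
            they must be disjoint.
        """
        if finetune_X is None or finetune_y is None:
            raise ValueError("a fine-tune set is required for checkpoint "
                             "selection")
        y = np.asarray(y, dtype=float)
        fy = np.asarray(finetune_y, dtype=float)
        if len(X) == 0 or len(finetune_X) == 0:
            raise ValueError("train and finetune bag sets must be non-empty")
        if len(np.unique(fy)) < 2:
            raise ValueError("finetune set must contain both classes")
        if len(np.unique(y)) < 2:
            raise ValueError("training set must contain both classes")
        if groups is not None and finetune_groups is not None:
            overlap = set(groups) & set(finetune_groups)
            if overlap:
                raise ValueError(
                    f"train and finetune sets share patients: {sorted(overlap)[:5]}"
                )
        if self.epochs < self.n_checkpoints:
            raise ValueError("epochs must be >= n_checkpoints")
        count = self._resolve_sample_count()

        rng = np.random.default_rng(
            np.random.SeedSequence([int(self.random_state), 101])
        )
        params = self._build(rng)
        opt_c = nn.Adam(self.learning_rate)
        opt_h = nn.Adam(self.learning_rate)

        # fixed fine-tune bags: one seeded draw per slide, reused each epoch
        ft_bags = [
            np.asarray(pool, dtype=np.float32)[
                draw_bag(len(pool), count, rng)
            ]
            for pool in finetune_X
        ]

        pools = [np.asarray(p, dtype=np.float32) for p in X]
        if any(len(p) == 0 for p in pools):
            raise ValueError("empty tumor-patch pool in training set")

        snapshots, history = [], []
        n = len(pools)
        for epoch in range(self.epochs):
            order = rng.permutation(n * self.n_bags_per_slide) % n
            train_loss = 0.0
            for i in order:
                pool = pools[i]
                bag = pool[draw_bag(len(pool), count, rng)]
                a, z, logit, (c1, c2) = self._forward(params, bag)
                loss, dlogit = nn.bce_with_logits(logit, y[i])
                train_loss += loss
                gh, dfeat = self._head.backward(params["head"], dlogit, c2)
                gc, _ = self._cnn.backward(
                    params["cnn"], dfeat.astype(np.float32), c1
                )
                opt_h.step(params["head"], gh)
                opt_c.step(params["cnn"], gc)

            ft_scores, ft_loss = [], 0.0
            for bag, t in zip(ft_bags, fy):
                _, _, logit, _ = self._forward(params, bag)
                ft_loss += nn.bce_with_logits(logit, t)[0]
                ft_scores.append(nn.sigmoid(np.asarray([logit]))[0])
            ft_auc = float(roc_auc_score(fy, ft_scores))
            snapshots.append({
                k: {kk: vv.copy() for kk, vv in p.items()}
                for k, p in params.items()
            })
            history.append({
                "epoch": epoch,
                "train_loss": train_loss / len(order),
                "finetune_loss": ft_loss / len(ft_bags),
                "finetune_auc": ft_auc,
            })

        hist = pd.DataFrame(history)
        chosen, overfit = _select_checkpoints(
            hist["finetune_loss"].to_numpy(), hist["finetune_auc"].to_numpy(),
            self.n_checkpoints, self.smoothing_window, self.rise_patience,
        )
        self.history_ = hist
        self.overfit_epoch_ = overfit
        self.checkpoint_epochs_ = chosen
        self.checkpoints_ = [snapshots[e] for e in chosen]
        self.checkpoint_aucs_ = [float(hist["finetune_auc"][e]) for e in chosen]
        self.classes_ = np.array([0, 1])
        self.sample_count_ = count
        return self

    # -- inference ---------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "checkpoints_"):
            raise ValueError("model is not fitted")

    def forward_bag(self, instances, checkpoint: int | None = None
                    ) -> AttentionOutput:
        """Score one bag (K, h, w, 3). ``checkpoint=None`` averages the
        ensemble's weights/scores; an integer selects one member."""
        self._check_fitted()
        instances = np.asarray(instances, dtype=np.float32)
        if instances.ndim != 4 or instances.shape[3] != 3:
            raise ValueError("bag must be (K, h, w, 3)")
        members = (self.checkpoints_ if checkpoint is None
                   else [self.checkpoints_[checkpoint]])
        ws, zs, logits = [], [], []
        for p in members:
            a, z, logit, _ = self._forward(p, instances)
            ws.append(a)
            zs.append(z)
            logits.append(logit)
        w = np.mean(ws, axis=0)
        score = float(np.mean(nn.sigmoid(np.asarray(logits))))
        return AttentionOutput(w, np.mean(zs, axis=0),
                               float(np.mean(logits)), score)

    def member_scores(self, instances) -> np.ndarray:
        """Per-checkpoint scores for one bag."""
        self._check_fitted()
        instances = np.asarray(instances, dtype=np.float32)
        return np.array([
            nn.sigmoid(np.asarray([self._forward(p, instances)[2]]))[0]
            for p in self.checkpoints_
        ])

    def ensemble_score(self, instances) -> float:
        """Arithmetic mean of the five member scores for one bag."""
        if len(self.checkpoints_) != self.n_checkpoints:
            raise ValueError("checkpoint ensemble is incomplete")
        return float(self.member_scores(instances).mean())

    def predict_proba(self, X):
        """Ensemble score per slide pool, using one seeded eval bag each."""
        self._check_fitted()
        count = self.sample_count_
        scores = np.empty(len(X))
        for i, pool in enumerate(X):
            pool = np.asarray(pool, dtype=np.float32)
            rng = np.random.default_rng(
                np.random.SeedSequence([int(self.random_state), 202, i])
            )
            bag = pool[draw_bag(len(pool), count, rng)]
            scores[i] = self.ensemble_score(bag)
        return np.column_stack([1 - scores, scores])

    def predict(self, X, cutoff: float = 0.5):
        return (self.predict_proba(X)[:, 1] >= cutoff).astype(int)

    # -- persistence -------------------------------------------------------
    def save(self, directory):
        """Write checkpoints (npz) plus a JSON sidecar and the training log."""
        self._check_fitted()
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for i, ckpt in enumerate(self.checkpoints_):
            flat = {f"{g}.{k}": v for g, p in ckpt.items()
                    for k, v in p.items()}
            np.savez(d / f"checkpoint_{i}.npz", **flat)
        sidecar = {
            "params": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in self.get_params().items()},
            "checkpoint_epochs": [int(e) for e in self.checkpoint_epochs_],
            "checkpoint_finetune_aucs": self.checkpoint_aucs_,
            "overfit_epoch": (None if self.overfit_epoch_ is None
                              else int(self.overfit_epoch_)),
            "sample_count": int(self.sample_count_),
        }
        (d / "ensemble.json").write_text(json.dumps(sidecar, indent=2))
        self.history_.to_csv(d / "training_log.csv", index=False)

    @classmethod
    def load(cls, directory) -> "AttentionMILClassifier":
        d = Path(directory)
        sidecar = json.loads((d / "ensemble.json").read_text())
        params = sidecar["params"]
        params["conv_channels"] = tuple(params["conv_channels"])
        est = cls(**params)
        rng = np.random.default_rng(0)
        est._build(rng)
        ckpts = []
        for i in range(est.n_checkpoints):
            data = np.load(d / f"checkpoint_{i}.npz")
            ckpt = {"cnn": {}, "head": {}}
            for key in data.files:
                g, k = key.split(".", 1)
                ckpt[g][k] = data[key]
            ckpts.append(ckpt)
        est.checkpoints_ = ckpts
        est.checkpoint_epochs_ = sidecar["checkpoint_epochs"]
        est.checkpoint_aucs_ = sidecar["checkpoint_finetune_aucs"]
        est.overfit_epoch_ = sidecar["overfit_epoch"]
        est.sample_count_ = sidecar["sample_count"]
        est.history_ = pd.read_csv(d / "training_log.csv")
        est.classes_ = np.array([0, 1])
        return est


def _select_checkpoints(ft_loss, ft_auc, n_checkpoints, window, patience):
    """Five best fine-tune-AUC epochs strictly before the overfitting point.

    The overfitting point is the first epoch at which the moving-average
    fine-tune loss has risen for ``patience`` consecutive epochs; ties in
    AUC break toward the earlier epoch. When fewer than ``n_checkpoints``
    epochs precede the overfitting point, all epochs become candidates.
    """
    n = len(ft_loss)
    kernel = np.ones(window) / window
    smooth = np.convolve(
        np.pad(ft_loss, (window - 1, 0), mode="edge"), kernel, mode="valid"
    )
    overfit = None
    rises = 0
    for t in range(1, n):
        rises = rises + 1 if smooth[t] > smooth[t - 1] else 0
        if rises >= patience:
            overfit = t - patience + 1  # first epoch of the sustained rise
            break
    candidates = np.arange(overfit) if overfit is not None else np.arange(n)
    if len(candidates) < n_checkpoints:
        candidates = np.arange(n)
    # sort by (-auc, epoch): best AUC first, earlier epoch on ties
    order = sorted(candidates, key=lambda e: (-ft_auc[e], e))
    chosen = sorted(order[:n_checkpoints])
    return [int(e) for e in chosen], overfit


# ---------------------------------------------------------------------------
# functional wrappers mirroring the operation-level API
# ---------------------------------------------------------------------------


def train_mil(train_pools, train_labels, finetune_pools, finetune_labels,
              **params) -> AttentionMILClassifier:
    return AttentionMILClassifier(**params).fit(
        train_pools, train_labels, finetune_pools, finetune_labels
    )


def forward_bag(model: AttentionMILClassifier, instances) -> AttentionOutput:
    return model.forward_bag(instances)


def ensemble_score(model: AttentionMILClassifier, instances) -> float:
    return model.ensemble_score(instances)
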