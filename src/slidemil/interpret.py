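"""Attention heatmaps, ranked-patch extraction, cluster labelling, Grad-CAM.

The heatmap maps per-patch attention scores back onto grid coordinates
(cell (r, c) <-> patch (r, c), exactly). Cohort-wide ranking extracts the
top/bottom-N patches by attention score; clusters of those patches are
labelled by the over-60% origin rule: a cluster whose members come from
positive patients' slides in a fraction strictly greater than 0.6 is
positive-related, strictly greater than 0.6 negative-origin fraction is
negative-related, anything else stays unassigned. Grad-CAM weights the
last conv feature map of the backbone by the gradient of the positive
logit (the patch scored as a singleton bag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import nn


@dataclass
class HeatmapLayer:
    slide_id: str
    magnification: int
    scores: np.ndarray          # (n_rows, n_cols), NaN where unscored
    overlay: np.ndarray         # (n_rows*cell, n_cols*cell, 4) RGBA uint8
    cell_px: int


@dataclass
class ClusterReport:
    cluster_id: int
    member_index: np.ndarray
    n_members: int
    positive_fraction: float
    label: str                  # MVI_pos_related | MVI_neg_related | unassigned


def render_heatmap(patch_scores: pd.DataFrame, slide_id: str,
                   magnification: int, n_rows: int, n_cols: int,
                   cell_px: int = 16, cmap: str = "jet",
                   path=None) -> HeatmapLayer:
    """Rasterize per-patch attention scores onto the patch grid.

    ``patch_scores`` needs columns grid_row, grid_col, attention. Cells
    without a score are fully transparent. Scores are min-max normalized
    over the slide for display (uniform scores render mid-scale).
    """
    import matplotlib

    grid = np.full((n_rows, n_cols), np.nan)
    for _, row in patch_scores.iterrows():
        grid[int(row["grid_row"]), int(row["grid_col"])] = row["attention"]
    finite = np.isfinite(grid)
    norm = np.full_like(grid, np.nan)
    if finite.any():
        lo, hi = np.nanmin(grid), np.nanmax(grid)
        norm[finite] = 0.5 if hi == lo else (grid[finite] - lo) / (hi - lo)
    mapper = matplotlib.colormaps[cmap]
    rgba = np.zeros((n_rows, n_cols, 4), dtype=np.uint8)
    if finite.any():
        colored = (mapper(np.nan_to_num(norm)) * 255).astype(np.uint8)
        colored[..., 3] = np.where(finite, 255, 0)
        rgba = colored
    overlay = np.repeat(np.repeat(rgba, cell_px, axis=0), cell_px, axis=1)
    layer = HeatmapLayer(slide_id, magnification, grid, overlay, cell_px)
    if path is not None:
        from PIL import Image

        Image.fromarray(overlay).save(path)
    return layer


def extract_ranked_patches(scores: pd.DataFrame, n_top: int = 4000,
                           n_bottom: int = 4000,
                           score_column: str = "attention"
                           ) -> tuple[pd.DataFrame, bool]:
    """Top- and bottom-N patches by attention score, cohort-wide.

    Returns ``(frame, truncated)``: the frame gains a ``rank_group`` column
    ("top" / "bottom"); ``truncated`` is True when the cohort has fewer
    than ``n_top + n_bottom`` patches so everything was returned. Ties are
    broken by original order (stable sort).
    """
    n = len(scores)
    order = scores[score_column].to_numpy().argsort(kind="stable")
    if n <= n_top + n_bottom:
        half = scores.copy()
        med = np.median(half[score_column]) if n else 0.0
        half["rank_group"] = np.where(
            half[score_column] >= med, "top", "bottom"
        )
        return half, True
    bottom = scores.iloc[order[:n_bottom]].copy()
    bottom["rank_group"] = "bottom"
    top = scores.iloc[order[-n_top:]].copy()
    top["rank_group"] = "top"
    return pd.concat([top, bottom]), False


def label_cluster(positive_fraction: float, threshold: float = 0.6) -> str:
    """Strict over-threshold origin rule; exactly at threshold -> unassigned."""
    if positive_fraction > threshold:
        return "MVI_pos_related"
    if (1.0 - positive_fraction) > threshold:
        return "MVI_neg_related"
    return "unassigned"


def cluster_and_label(features, positive_origin, n_clusters: int = 8,
                      seed: int = 0, threshold: float = 0.6,
                      embed: str | None = None) -> list[ClusterReport]:
    """K-means on backbone features + the over-60% origin labelling rule.

    ``positive_origin`` is a boolean vector: patch comes from a slide of a
    positive patient. ``embed`` ("tsne" | "pca") additionally attaches a
    2-D display embedding to each report via the ``embedding`` attribute.
    """
    from sklearn.cluster import KMeans

    X = np.asarray(features, dtype=float)
    origin = np.asarray(positive_origin, dtype=bool)
    if n_clusters > len(X):
        raise ValueError("n_clusters cannot exceed the number of patches")
    km = KMeans(n_clusters=n_clusters, random_state=seed, n_init=10)
    assign = km.fit_predict(X)
    emb = None
    if embed == "pca":
        from sklearn.decomposition import PCA

        emb = PCA(n_components=2, random_state=seed).fit_transform(X)
    elif embed == "tsne":
        from sklearn.manifold import TSNE

        emb = TSNE(n_components=2, random_state=seed,
                   perplexity=min(30, max(5, len(X) // 4))).fit_transform(X)
    reports = []
    for k in range(n_clusters):
        members = np.nonzero(assign == k)[0]
        frac = float(origin[members].mean()) if len(members) else 0.0
        rep = ClusterReport(
            cluster_id=k, member_index=members, n_members=len(members),
            positive_fraction=frac, label=label_cluster(frac, threshold),
        )
        if emb is not None:
            rep.embedding = emb[members]
        reports.append(rep)
    return reports


def cluster_report_frame(reports) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": r.cluster_id,
                "n_members": r.n_members,
                "positive_fraction": r.positive_fraction,
                "label": r.label,
            }
            for r in reports
        ]
    )


def plot_embedding(reports, path) -> None:
    """Scatter the 2-D display embedding of clustered patches, colored by
    cluster label (requires reports built with ``embed=...``)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"MVI_pos_related": "tab:red", "MVI_neg_related": "tab:blue",
              "unassigned": "tab:gray"}
    fig, ax = plt.subplots(figsize=(5, 5))
    for r in reports:
        emb = getattr(r, "embedding", None)
        if emb is None or not len(emb):
            continue
        ax.scatter(emb[:, 0], emb[:, 1], s=8, alpha=0.7,
                   color=colors[r.label], label=f"c{r.cluster_id} {r.label}")
    ax.legend(fontsize=6, markerscale=1.5)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def grad_cam(model, patch, target_size: int = 512,
             checkpoint: int = 0) -> np.ndarray:
    """Class-activation map for one patch scored as a singleton bag.

    Gradients of the positive-class logit are taken at the backbone's last
    conv feature map; channel weights are the spatial means of those
    gradients; the ReLU'd weighted sum is normalized to [0, 1] and
    upsampled to ``target_size`` square.
    """
    patch = np.asarray(patch, dtype=np.float32)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError("patch must be (h, w, 3)")
    if hasattr(model, "checkpoints_"):
        params = model.checkpoints_[checkpoint]
        cnn, head = model._cnn, model._head
    else:  # patch-level classifier
        params = model.params_ if not hasattr(model, "_clf") else \
            model._clf.params_
        clf = model._clf if hasattr(model, "_clf") else model
        cnn, head = clf._cnn, clf._head
    if not hasattr(cnn, "grad_wrt_last_conv"):
        raise ValueError("backbone does not expose a conv feature layer")
    x = patch[None]
    if x.shape[1] != 32:  # network input resolution
        k = x.shape[1] // 32
        x = x[:, : k * 32, : k * 32].reshape(
            1, 32, k, 32, k, 3
        ).mean(axis=(2, 4))
    feats, cache = cnn.forward(params["cnn"], x)
    if isinstance(head, nn.GatedAttentionHead):
        _, _, _, hcache = head.forward(params["head"], feats)
        _, dfeat = head.backward(params["head"], 1.0, hcache)
    else:
        _, hcache = head.forward(params["head"], feats)
        _, dfeat = head.backward(params["head"], np.ones(1, np.float32),
                                 hcache)
    dA = cnn.grad_wrt_last_conv(params["cnn"], dfeat.astype(np.float32),
                                cache)
    A = cache["A2"]
    weights = dA.mean(axis=(1, 2))          # (1, C)
    cam = np.maximum((A * weights[:, None, None, :]).sum(axis=3), 0.0)[0]
    lo, hi = cam.min(), cam.max()
    cam = np.zeros_like(cam) if hi == lo else (cam - lo) / (hi - lo)
    k = target_size // cam.shape[0]
    return np.repeat(np.repeat(cam, k, axis=0), k, axis=1)
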