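"""Visual analyses: gradient-weighted class-activation heatmaps per view and
a 2-D t-SNE embedding of the fused 64-d feature vector.

Plain CAM is not well defined here because three FC layers separate the
final conv features from the logits, so the gradient-weighted variant
(channel weights = spatially averaged gradients of the class score at the
final conv stage) is used as the activation-mapping method.  The embedding
input is the fused 64-d concatenation fed to the final FC layer; per-stream
32-d vectors are available via ``feature="stream"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as _sktransform

from .model import TwoStreamNet
from .training import prepare_arrays


@dataclass
class HeatmapResult:
    heatmap: np.ndarray  # (H, W) in [0, 1], input resolution
    target_class: int
    view: str


@dataclass
class EmbeddingResult:
    coords: np.ndarray  # (n, 2)
    labels: list
    perplexity: float
    seed: int


def _grad_cam(activation, grad) -> np.ndarray:
    weights = grad.mean(axis=(1, 2))  # (C,)
    cam = np.tensordot(weights, activation, axes=(0, 0))
    cam = np.maximum(cam, 0.0)
    lo, hi = cam.min(), cam.max()
    if hi > lo:
        cam = (cam - lo) / (hi - lo)
    else:
        cam = np.zeros_like(cam)
    return cam


def class_activation_map(model: TwoStreamNet, view_pair, target_class: int):
    """Per-view gradient-weighted activation maps for ``target_class``.

    Returns a (front HeatmapResult, back HeatmapResult) pair, each map
    min-max normalized to [0, 1] and upsampled to the input size.
    """
    n_classes = model.spec.num_classes
    if not (0 <= target_class < n_classes):
        raise ValueError(f"target class {target_class} out of range [0, {n_classes})")
    front = np.asarray(view_pair.front, dtype=np.float64).transpose(2, 0, 1)[None]
    back = np.asarray(view_pair.back, dtype=np.float64).transpose(2, 0, 1)[None]
    size = front.shape[2]
    model.eval()
    cache: dict = {}
    logits = model.forward(front, back, cache=cache)
    seed = np.zeros_like(logits.data)
    seed[0, target_class] = 1.0
    logits.backward(seed)
    results = []
    if model.spec.single_stream:
        keys = [("stage4", model.spec.mode.replace("_only", ""))]
    else:
        keys = [("stage4_front", "front"), ("stage4_back", "back")]
    for key, view in keys:
        act = cache[key]
        cam = _grad_cam(act.data[0], act.grad[0])
        cam = _sktransform.resize(cam, (size, size), order=1, preserve_range=True)
        cam = np.clip(cam, 0.0, 1.0)
        results.append(HeatmapResult(heatmap=cam, target_class=target_class, view=view))
    return tuple(results)


def fused_features(model: TwoStreamNet, data) -> np.ndarray:
    """The 64-d fused vectors (concat before the final FC) for a data triple."""
    fronts, backs, labels = data
    model.eval()
    feats = []
    for i in range(0, len(labels), 32):
        cache: dict = {}
        model.forward(fronts[i : i + 32], backs[i : i + 32], cache=cache)
        feats.append(cache["embedding"].data)
    return np.concatenate(feats)


def embed_features(model: TwoStreamNet, manifest, config, seed: int = 0,
                   data=None, feature: str = "fused") -> EmbeddingResult:
    """2-D t-SNE of the fused features; deterministic under ``seed``."""
    from sklearn.manifold import TSNE

    if data is None:
        data = prepare_arrays(manifest, config)
    feats = fused_features(model, data)
    if feature == "stream":
        feats = feats[:, : feats.shape[1] // 2]
    n = feats.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 samples to embed, got {n}")
    perplexity = float(min(30.0, max(2.0, (n - 1) / 3.0)))
    tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed, init="pca")
    coords = tsne.fit_transform(feats)
    labels = [manifest.classes[i] for i in data[2]] if manifest is not None else list(data[2])
    return EmbeddingResult(coords=np.asarray(coords), labels=labels,
                           perplexity=perplexity, seed=seed)


def save_heatmap_overlay(image_hwc_uint8: np.ndarray, heatmap: np.ndarray, path):
    """Write a red-overlay PNG of a heatmap on top of its (raw) input image."""
    from PIL import Image

    base = np.asarray(image_hwc_uint8, dtype=np.float64)
    hm = _sktransform.resize(heatmap, base.shape[:2], order=1, preserve_range=True)
    overlay = base.copy()
    overlay[..., 0] = np.clip(base[..., 0] * 0.5 + 255.0 * hm * 0.7, 0, 255)
    Image.fromarray(overlay.astype(np.uint8)).save(path)


def save_embedding_csv(result: EmbeddingResult, path):
    import pandas as pd

    pd.DataFrame(
        {"x": result.coords[:, 0], "y": result.coords[:, 1], "label": result.labels}
    ).to_csv(path, index=False)


def save_embedding_scatter(result: EmbeddingResult, path):
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    labels = sorted(set(result.labels))
    for lab in labels:
        idx = [i for i, l in enumerate(result.labels) if l == lab]
        ax.scatter(result.coords[idx, 0], result.coords[idx, 1], s=12, label=lab)
    ax.legend(fontsize=7, markerscale=1.5)
    ax.set_xlabel("t-SNE 1")
    ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
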