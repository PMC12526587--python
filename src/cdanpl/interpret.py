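"""Model interpretation: 1-D Grad-CAM attributions and t-SNE alignment views.

Grad-CAM here operates on the multi-scale convolution branch of the feature
extractor (the only branch with positional feature maps).  For a chosen class
score, the per-channel weights are the position-averaged gradients of the
score with respect to the last convolutional feature maps; the attribution
map is the rectified channel-weighted sum, linearly mapped onto the
wavenumber grid and min-max normalized to [0, 1].  Wavenumbers whose local
maxima exceed 0.5 contribution are reported as key characteristic peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .autodiff import Tensor
from .networks import ModelBundle
from .spectra import DomainPair

__all__ = ["AttributionMap", "gradcam_spectrum", "extract_key_peaks", "tsne_export"]

KEY_PEAK_THRESHOLD = 0.5


@dataclass
class AttributionMap:
    """Per-wavenumber contribution in [0, 1] plus extracted key peaks."""

    contributions: np.ndarray
    wavenumbers: np.ndarray
    key_peaks: list = field(default_factory=list)
    target_class: int = 1
    degenerate: bool = False

    def __post_init__(self):
        c = self.contributions
        if len(c) and (c.min() < -1e-12 or c.max() > 1 + 1e-12):
            raise ValueError("contributions must lie in [0, 1]")


def extract_key_peaks(
    contributions: np.ndarray,
    wavenumbers: np.ndarray,
    threshold: float = KEY_PEAK_THRESHOLD,
) -> list[tuple[float, float]]:
    """Local maxima of the contribution curve exceeding ``threshold``."""
    idx, _ = find_peaks(contributions)
    # an endpoint can carry the global maximum; include plateau-free endpoints
    for end in (0, len(contributions) - 1):
        inner = 1 if end == 0 else len(contributions) - 2
        if contributions[end] > contributions[inner]:
            idx = np.sort(np.append(idx, end))
    return [
        (float(wavenumbers[i]), float(contributions[i]))
        for i in idx
        if contributions[i] > threshold
    ]


def gradcam_spectrum(
    bundle: ModelBundle, spectra: np.ndarray, target_class: int = 1
) -> AttributionMap:
    """Gradient-weighted class activation map over the wavenumber axis.

    ``spectra`` is a (batch, grid) matrix; the map is averaged over the batch
    before normalization.  All-zero gradients yield a degenerate-map warning
    and a zero attribution.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=np.float64))
    bundle.eval_mode()
    x = Tensor(X, requires_grad=False)
    feats, maps = bundle.G(x, return_conv_maps=True)
    logits = bundle.C(feats)
    score = logits[:, target_class].sum()
    score.backward()
    grads = maps.grad  # (batch, channels, positions)
    if grads is None or not np.any(grads):
        warnings.warn("Grad-CAM gradients are all zero; attribution map is degenerate",
                      UserWarning, stacklevel=2)
        grid = _grid_of(bundle, X.shape[1])
        return AttributionMap(np.zeros(X.shape[1]), grid, [], target_class, degenerate=True)
    alpha = grads.mean(axis=2)  # (batch, channels)
    cam = np.maximum(np.einsum("bc,bcl->bl", alpha, maps.data), 0.0)
    cam = cam.mean(axis=0)
    grid = _grid_of(bundle, X.shape[1])
    # feature maps are position-aligned with the input grid ('same' conv);
    # linear interpolation handles any length mismatch
    if len(cam) != len(grid):
        cam = np.interp(np.linspace(0, 1, len(grid)), np.linspace(0, 1, len(cam)), cam)
    lo, hi = cam.min(), cam.max()
    if hi == lo:
        warnings.warn("Grad-CAM map is constant; attribution is degenerate",
                      UserWarning, stacklevel=2)
        return AttributionMap(np.zeros_like(cam), grid, [], target_class, degenerate=True)
    cam = (cam - lo) / (hi - lo)
    peaks = extract_key_peaks(cam, grid)
    return AttributionMap(cam, grid, peaks, target_class)


def _grid_of(bundle: ModelBundle, n: int) -> np.ndarray:
    grid = bundle.meta.get("wavenumbers")
    if grid is not None and len(grid) == n:
        return np.asarray(grid, dtype=np.float64)
    return np.arange(n, dtype=np.float64)


def tsne_export(
    bundle: ModelBundle,
    pair: DomainPair,
    path: str | None = None,
    seed: int = 0,
    perplexity: float = 30.0,
    n_iter: int = 1000,
) -> tuple[pd.DataFrame, dict]:
    """2-D t-SNE embedding of G-features for all source and target samples.

    Returns the embedding table (x, y, domain, class, split) and a score dict
    with the silhouette of the pooled embedding grouped by class versus by
    domain — after successful adaptation classes should separate more than
    domains.  Deterministic under ``seed``.
    """
    from sklearn.manifold import TSNE
    from sklearn.metrics import silhouette_score

    from .pseudo_labels import forward_in_batches

    blocks, domains, classes, splits = [], [], [], []
    for name in ("source_train", "source_test", "target_train", "target_test"):
        ds = getattr(pair, name)
        feats = forward_in_batches(bundle.G, ds.X)
        blocks.append(feats)
        domain, split = name.split("_")
        domains += [domain] * ds.n_samples
        splits += [split] * ds.n_samples
        if ds.y is not None:
            classes += ds.y.tolist()
        elif split in pair.sealed_target_labels:
            classes += pair.sealed_labels(split).tolist()
        else:
            classes += [-1] * ds.n_samples
    feats = np.vstack(blocks)
    perp = min(perplexity, max(2.0, (len(feats) - 1) / 3.0))
    emb = TSNE(
        n_components=2, perplexity=perp, max_iter=n_iter, random_state=seed, init="pca"
    ).fit_transform(feats)
    frame = pd.DataFrame({
        "x": emb[:, 0], "y": emb[:, 1],
        "domain": domains, "class": classes, "split": splits,
    })
    scores = {}
    labeled = frame["class"].to_numpy() >= 0
    if labeled.sum() > 2 and len(set(frame.loc[labeled, "class"])) > 1:
        scores["class_silhouette"] = float(
            silhouette_score(emb[labeled], frame.loc[labeled, "class"]))
    if len(set(domains)) > 1:
        scores["domain_silhouette"] = float(silhouette_score(emb, frame["domain"]))
    if path is not None:
        frame.to_csv(path, index=False)
    return frame, scores
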