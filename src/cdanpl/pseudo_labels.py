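"""Target-domain pseudo-labels: KNN votes, confidence filtering, fusion.

Pseudo-labels are produced in three stages and regenerated every epoch from
the current model state:

1. *neuron* predictions — softmax probabilities of the classifier head on
   target features;
2. *KNN* predictions — class frequencies among the K Euclidean nearest
   labeled source samples in the shared feature space;
3. *decision fusion* — a ``w``-weighted sum of the two probability tables;
   the fused argmax is the pseudo-label and the fused maximum is the
   confidence, which a strict threshold kappa then filters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, no_grad
from .networks import ModelBundle
from .spectra import SpectralDataset

__all__ = [
    "PseudoLabelSet",
    "knn_pseudo_labels",
    "filter_by_confidence",
    "fuse_decisions",
    "generate_pseudo_labels",
    "forward_in_batches",
]


@dataclass
class PseudoLabelSet:
    """Fused per-target-sample labels, confidences and the kappa keep-mask."""

    labels: np.ndarray
    confidence: np.ndarray
    keep_mask: np.ndarray
    components: dict = field(default_factory=dict)
    all_filtered: bool = False

    def __post_init__(self):
        n = len(self.labels)
        if not (len(self.confidence) == len(self.keep_mask) == n):
            raise ValueError("labels, confidence and keep_mask must share length")
        if len(self.confidence) and (self.confidence.min() < 0 or self.confidence.max() > 1):
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def n_kept(self) -> int:
        return int(self.keep_mask.sum())


def knn_pseudo_labels(
    target_features: np.ndarray,
    source_features: np.ndarray,
    source_labels: np.ndarray,
    K: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Majority vote among the K nearest source neighbors of each target row.

    Returns ``(labels, knn_probs)`` where ``knn_probs`` rows are neighbor
    class frequencies (summing to 1).  Vote ties are broken by the smallest
    summed neighbor distance among the tied classes, then by the lowest class
    code.  Neighbor-set boundary ties resolve by source index order (stable
    sort), matching an exhaustive-oracle convention.
    """
    ft = np.atleast_2d(np.asarray(target_features, dtype=np.float64))
    fs = np.atleast_2d(np.asarray(source_features, dtype=np.float64))
    ys = np.asarray(source_labels, dtype=np.int64)
    if fs.shape[0] == 0:
        raise ValueError("source feature set is empty")
    if ft.shape[1] != fs.shape[1]:
        raise ValueError("feature dimensions of target and source must match")
    if not 1 <= K <= fs.shape[0]:
        raise ValueError(f"K must be in [1, {fs.shape[0]}]")
    n_classes = int(ys.max()) + 1
    d2 = ((ft[:, None, :] - fs[None, :, :]) ** 2).sum(-1)
    order = np.argsort(d2, axis=1, kind="stable")[:, :K]
    labels = np.empty(ft.shape[0], dtype=np.int64)
    probs = np.zeros((ft.shape[0], n_classes))
    for i in range(ft.shape[0]):
        neigh = order[i]
        neigh_labels = ys[neigh]
        counts = np.bincount(neigh_labels, minlength=n_classes)
        probs[i] = counts / K
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if len(tied) == 1:
            labels[i] = tied[0]
        else:
            dist = np.sqrt(d2[i])
            sums = np.array([dist[neigh[neigh_labels == c]].sum() for c in tied])
            # smallest summed neighbor distance, then lowest class code
            labels[i] = tied[np.argmin(sums)]
    return labels, probs


def filter_by_confidence(probs: np.ndarray, kappa: float) -> np.ndarray:
    """Keep rows whose maximum probability strictly exceeds kappa."""
    probs = np.atleast_2d(np.asarray(probs, dtype=np.float64))
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must be in [0, 1]")
    return probs.max(axis=1) > kappa


def fuse_decisions(
    neuron_probs: np.ndarray, knn_probs: np.ndarray, w: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Decision-level fusion: ``w * neuron + (1 - w) * knn``; argmax labels."""
    neuron = np.asarray(neuron_probs, dtype=np.float64)
    knn = np.asarray(knn_probs, dtype=np.float64)
    if neuron.shape != knn.shape:
        raise ValueError("probability tables must share shape")
    if not 0.0 <= w <= 1.0:
        raise ValueError("fusion weight w must be in [0, 1]")
    fused = w * neuron + (1.0 - w) * knn
    return fused, fused.argmax(axis=1)


def forward_in_batches(module, X: np.ndarray, batch: int = 128) -> np.ndarray:
    """Evaluation-mode forward pass of a network over a matrix, in chunks."""
    outs = []
    with no_grad():
        for i in range(0, len(X), batch):
            outs.append(module(Tensor(X[i:i + batch], requires_grad=False)).data)
    return np.vstack(outs) if outs else np.empty((0,))


def generate_pseudo_labels(
    bundle: ModelBundle,
    source_ds: SpectralDataset,
    target_ds: SpectralDataset,
    K: int = 5,
    kappa: float = 0.9,
    w: float = 0.5,
) -> PseudoLabelSet:
    """Compose neuron prediction, KNN voting, fusion and kappa filtering.

    Pure evaluation: no parameters change, and the result is deterministic
    given the bundle and the data.  If the filter removes every target sample
    the ``all_filtered`` flag is set and training skips the CE term that
    round.
    """
    if source_ds.y is None:
        raise ValueError("source dataset must be labeled")
    bundle.eval_mode()
    feats_s = forward_in_batches(bundle.G, source_ds.X)
    feats_t = forward_in_batches(bundle.G, target_ds.X)
    neuron_probs = forward_in_batches(lambda x: bundle.C.probs(bundle.G(x)), target_ds.X)
    _, knn_probs = knn_pseudo_labels(feats_t, feats_s, source_ds.y, K=K)
    fused, labels = fuse_decisions(neuron_probs, knn_probs, w)
    keep = filter_by_confidence(fused, kappa)
    return PseudoLabelSet(
        labels=labels,
        confidence=fused.max(axis=1),
        keep_mask=keep,
        components={"neuron_probs": neuron_probs, "knn_probs": knn_probs, "fusion_weight": w},
        all_filtered=not keep.any(),
    )
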