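"""Training losses of the conditional adversarial adaptation objective.

The model optimizes, over feature extractor G, classifier C and domain
discriminator D::

    max_{G,C} min_{D}  lambda * (L_adv - L_MC) - L_cls        (- L_CE)

realized as the standard conditional-adversarial game: D minimizes its
domain-classification loss on multilinear feature x prediction vectors, G
receives the reversed adversarial gradient (gradient reversal), and G/C
additionally descend on the source cross-entropy, the pseudo-label
cross-entropy over confidence-kept target samples, and the metric-constraint
(MC) loss — a Fisher-style pairwise-distance ratio that keeps classes
separated while the domains are being confused.

All functions accept :class:`~cdanpl.autodiff.Tensor` or plain arrays and
return Tensors, so the same code path serves training and the closed-form
unit checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor

__all__ = [
    "LossReport",
    "multilinear_map",
    "adversarial_loss",
    "cross_entropy",
    "classification_loss",
    "pseudo_ce_loss",
    "mc_loss",
    "combined_objective",
    "PROB_CLAMP",
]

#: probabilities are clamped into [PROB_CLAMP, 1 - PROB_CLAMP] inside logs so
#: every loss stays finite on saturated outputs
PROB_CLAMP = 1e-7


def _tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64),
                                                  requires_grad=False)


@dataclass
class LossReport:
    """Per-step loss components, as streamed to the training log."""

    L_cls: float = 0.0
    L_CE: float = 0.0
    L_adv: float = 0.0
    L_MC: float = 0.0
    T_m: float = 0.0
    combined: float = 0.0
    lam: float = 1.0
    B_m: int = 0
    kept_count: int = 0
    ce_skipped: bool = False
    mc_skipped: bool = False


def multilinear_map(f, g) -> Tensor:
    """Row-wise flattened outer product phi(f, g) = f (x) g.

    ``f``: batch x d features, ``g``: batch x c probabilities; output row i is
    ``f_i (x) g_i`` flattened to length d*c (flat index of (a, b) is a*c + b).
    """
    f, g = _tensor(f), _tensor(g)
    if f.shape[0] != g.shape[0]:
        raise ValueError("f and g must have equal batch sizes")
    B, d = f.shape
    c = g.shape[1]
    return (f.reshape(B, d, 1) * g.reshape(B, 1, c)).reshape(B, d * c)


def adversarial_loss(D, feats_s, probs_s, feats_t, probs_t, lam_grl: float = 0.0) -> Tensor:
    """Conditional adversarial loss on multilinear vectors.

    ``L_adv = -mean_s log(1 - D(phi(f_s, p_s))) - mean_t log(D(phi(f_t, p_t)))``
    so D is driven toward 0 on source and 1 on target.  With ``lam_grl > 0``
    the multilinear inputs pass through a gradient-reversal layer, sending the
    confusion gradient (scaled by ``-lam_grl``) into the feature extractor.
    """
    from .networks import grad_reverse

    from .autodiff import concatenate

    phi_s = multilinear_map(feats_s, probs_s)
    phi_t = multilinear_map(feats_t, probs_t)
    n_s = phi_s.shape[0]
    phi = concatenate([phi_s, phi_t], axis=0)
    # the reversal layer always guards the feature path: lam_grl scales the
    # confusion gradient into G (0 blocks it entirely, it never leaks forward)
    phi = grad_reverse(phi, lam_grl)
    d = D(phi).clip(PROB_CLAMP, 1.0 - PROB_CLAMP)
    d_s, d_t = d[:n_s], d[n_s:]
    return -((1.0 - d_s).log().mean()) - d_t.log().mean()


def cross_entropy(probs, labels) -> Tensor:
    """Mean negative log-likelihood of integer ``labels`` under ``probs`` rows."""
    probs = _tensor(probs)
    labels = np.asarray(labels, dtype=np.int64)
    n, c = probs.shape
    if len(labels) != n:
        raise ValueError("labels length must match batch size")
    if labels.min() < 0 or labels.max() >= c:
        raise ValueError(f"label codes must lie in [0, {c})")
    onehot = np.zeros((n, c))
    onehot[np.arange(n), labels] = 1.0
    p = probs.clip(PROB_CLAMP, 1.0)
    return -(p.log() * Tensor(onehot, requires_grad=False)).sum(axis=1).mean()


def classification_loss(C, G, X, y) -> Tensor:
    """Source-domain supervision: CE of ground-truth labels under C(G(x))."""
    return cross_entropy(C.probs(G(_tensor(X))), y)


def pseudo_ce_loss(C, G, X_kept, pseudo_labels) -> Tensor:
    """Pseudo-label supervision: CE of kept target samples under C(G(x))."""
    X_kept = _tensor(X_kept)
    if X_kept.shape[0] == 0:
        raise ValueError("kept target batch is empty; skip the CE term instead")
    return cross_entropy(C.probs(G(X_kept)), pseudo_labels)


def mc_loss(features, labels, pair_mean: bool = False):
    """Metric-constraint loss and its normalization coefficient.

    ``T_m = (1/B_m) * sum_{u != v} ||f_u - f_v||^2`` (ordered pairs; set
    ``pair_mean=True`` for the conventional mean over the B_m*(B_m-1) pairs —
    the two conventions only rescale T_m and leave every invariance intact).

    ``L_MC = log[ sum_{y_u != y_v} exp(-d_uv / T_m)
                 / sum_{y_u == y_v, u != v} exp(-d_uv / T_m) ]``

    decreases as classes separate and same-class points tighten.  Returns
    ``(L_MC, T_m, skipped)``; when the batch has no cross-class or no
    same-class pair (or all points coincide) the term is skipped: (0, T_m,
    True).
    """
    f = _tensor(features)
    labels = np.asarray(labels, dtype=np.int64)
    B = f.shape[0]
    if B < 2:
        raise ValueError("mc_loss needs at least 2 samples")
    sq = (f * f).sum(axis=1)
    d2 = sq.reshape(B, 1) + sq.reshape(1, B) - 2.0 * (f @ f.transpose())
    d2 = d2.clip(0.0, np.inf)  # guard tiny negative rounding
    off = ~np.eye(B, dtype=bool)
    denom = B if not pair_mean else B * (B - 1)
    T_m = d2.sum() * (1.0 / denom)
    same = (labels[:, None] == labels[None, :]) & off
    diff = labels[:, None] != labels[None, :]
    if not same.any() or not diff.any() or T_m.data <= 0:
        return Tensor(0.0, requires_grad=False), T_m, True
    e = (-(d2 / T_m)).exp()
    num = (e * Tensor(diff.astype(float), requires_grad=False)).sum()
    den = (e * Tensor(same.astype(float), requires_grad=False)).sum()
    return (num / den).log(), T_m, False


def combined_objective(report: LossReport, lam: float | None = None) -> float:
    """Logged scalar of the full objective: lam*(L_adv - L_MC) - L_cls - L_CE."""
    lam = report.lam if lam is None else lam
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return lam * (report.L_adv - report.L_MC) - report.L_cls - report.L_CE
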