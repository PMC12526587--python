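"""Spectral preprocessing stack and transfer-dataset construction.

The pipeline order is fixed: iterative polynomial baseline correction, then
mean smoothing, then per-spectrum min-max normalization.  Dataset-level
helpers build the source/target split (controls partitioned 1:1 between the
domains, then a stratified 7:3 train/test split per domain), SMOTE-balance
the training sets, and — for tasks whose instruments produced different
feature grids — harmonize both domains into one shared PCA basis.

Baseline correction is the classic modified polynomial fit: a least-squares
polynomial of fixed degree is fitted repeatedly, and after every round the
working spectrum is clipped to the current fit so that peaks stop attracting
the baseline; iteration ends when the relative change of the fit residual
falls below ``loss_gradient`` or after ``max_iter`` rounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from sklearn.decomposition import PCA
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .spectra import DomainPair, SpectralDataset, Spectrum

__all__ = [
    "SplitSpec",
    "PreprocessParams",
    "correct_baseline",
    "smooth_mean",
    "minmax_normalize",
    "preprocess_spectrum",
    "preprocess_dataset",
    "make_domain_split",
    "smote_balance",
    "pca_harmonize",
    "resample_to_grid",
]


@dataclass(frozen=True)
class SplitSpec:
    """Control 1:1 partition ratio, 7:3 train/test ratio, and the split seed."""

    control_split_ratio: float = 0.5
    train_test_ratio: float = 0.7
    seed: int = 0
    stratify: bool = True

    def __post_init__(self):
        for name in ("control_split_ratio", "train_test_ratio"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the fixed baseline -> smooth -> normalize pipeline."""

    baseline_degree: int = 3
    baseline_max_iter: int = 100
    baseline_loss_gradient: float = 1e-3
    smooth_window: int = 9


# ---------------------------------------------------------------------------
# per-spectrum operations
# ---------------------------------------------------------------------------

def _fit_baseline(
    w: np.ndarray, x: np.ndarray, degree: int, max_iter: int, loss_gradient: float
) -> np.ndarray:
    # map the grid to [-1, 1] for numerical conditioning
    t = 2.0 * (w - w[0]) / (w[-1] - w[0]) - 1.0
    work = x.copy()
    prev_resid = None
    fit = work
    for _ in range(max_iter):
        coeffs = np.polynomial.polynomial.polyfit(t, work, degree)
        fit = np.polynomial.polynomial.polyval(t, coeffs)
        resid = float(np.linalg.norm(work - fit))
        if prev_resid is not None:
            denom = max(prev_resid, 1e-300)
            if abs(prev_resid - resid) / denom < loss_gradient:
                break
        prev_resid = resid
        work = np.minimum(work, fit)
    return fit


def correct_baseline(
    spec: Spectrum, degree: int = 3, max_iter: int = 100, loss_gradient: float = 1e-3
) -> Spectrum:
    """Subtract an iteratively re-fitted polynomial baseline.

    Each round fits a least-squares polynomial of ``degree`` to the working
    spectrum and clips points above the fit down to it, so the polynomial
    converges onto the slowly varying background under the peaks.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    if loss_gradient <= 0:
        raise ValueError("loss_gradient must be > 0")
    if len(spec) <= degree + 1:
        raise ValueError(f"spectrum length {len(spec)} too short for degree {degree}")
    baseline = _fit_baseline(spec.wavenumbers, spec.intensities, degree, max_iter, loss_gradient)
    return spec.with_intensities(spec.intensities - baseline)


def smooth_mean(spec: Spectrum, window: int = 9) -> Spectrum:
    """Centered moving average; the window shrinks to valid points at edges."""
    n = len(spec)
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}]")
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(spec.intensities)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return spec.with_intensities((csum[hi] - csum[lo]) / (hi - lo))


def minmax_normalize(spec: Spectrum, row: int | None = None) -> Spectrum:
    """Affine rescale to [0, 1]; errors on a constant spectrum."""
    x = spec.intensities
    lo, hi = x.min(), x.max()
    if hi == lo:
        where = f" (row {row})" if row is not None else ""
        raise ValueError(f"cannot min-max normalize a constant spectrum{where}")
    return spec.with_intensities((x - lo) / (hi - lo))


def preprocess_spectrum(spec: Spectrum, params: PreprocessParams | None = None,
                        row: int | None = None) -> Spectrum:
    """The fixed pipeline: baseline correction -> smoothing -> normalization."""
    p = params or PreprocessParams()
    spec = correct_baseline(
        spec, p.baseline_degree, p.baseline_max_iter, p.baseline_loss_gradient
    )
    spec = smooth_mean(spec, p.smooth_window)
    return minmax_normalize(spec, row=row)


def preprocess_dataset(ds: SpectralDataset, params: PreprocessParams | None = None) -> SpectralDataset:
    """Apply the per-spectrum pipeline to every row of a dataset."""
    out = np.empty_like(ds.X)
    for i in range(ds.n_samples):
        out[i] = preprocess_spectrum(ds.spectrum(i), params, row=i).intensities
    return replace(ds, X=out)


# ---------------------------------------------------------------------------
# dataset construction
# ---------------------------------------------------------------------------

def _check_grids(*datasets: SpectralDataset) -> None:
    ref = datasets[0]
    for ds in datasets[1:]:
        if ds.n_features != ref.n_features:
            raise ValueError("datasets must share one feature grid")
        if ds.wavenumbers is not None and ref.wavenumbers is not None:
            if not np.allclose(ds.wavenumbers, ref.wavenumbers):
                raise ValueError("datasets must share one wavenumber grid")


def _split_7_3(X, y, spec: SplitSpec, seed: int):
    strat = y if spec.stratify else None
    idx = np.arange(len(X))
    tr, te = train_test_split(
        idx, train_size=spec.train_test_ratio, random_state=seed, stratify=strat
    )
    return np.sort(tr), np.sort(te)


def make_domain_split(
    controls: SpectralDataset,
    disease_source: SpectralDataset,
    disease_target: SpectralDataset,
    split: SplitSpec | None = None,
) -> DomainPair:
    """Build a transfer task from a shared control pool and two disease sets.

    Controls are partitioned disjointly (``control_split_ratio``, default 1:1)
    between the source and target domains; each domain (its disease samples +
    its controls, coded control=0 / disease=1) is then split 7:3 into train
    and test, stratified by class by default.  Target labels are sealed for
    evaluation only.
    """
    split = split or SplitSpec()
    _check_grids(controls, disease_source, disease_target)
    rng = np.random.default_rng(split.seed)
    perm = rng.permutation(controls.n_samples)
    n_src = int(round(controls.n_samples * split.control_split_ratio))
    ctrl_src = controls.subset(np.sort(perm[:n_src]))
    ctrl_tgt = controls.subset(np.sort(perm[n_src:]))

    names = {0: "control", 1: "disease"}

    def assemble(ctrl, disease, domain):
        X = np.vstack([ctrl.X, disease.X])
        y = np.concatenate([np.zeros(ctrl.n_samples, int), np.ones(disease.n_samples, int)])
        return SpectralDataset(X=X, y=y, domain=domain,
                               wavenumbers=controls.wavenumbers, class_names=names)

    src = assemble(ctrl_src, disease_source, "source")
    tgt = assemble(ctrl_tgt, disease_target, "target")

    s_tr, s_te = _split_7_3(src.X, src.y, split, seed=split.seed)
    t_tr, t_te = _split_7_3(tgt.X, tgt.y, split, seed=split.seed + 1)

    sealed = {"train": tgt.y[t_tr].copy(), "test": tgt.y[t_te].copy()}
    return DomainPair(
        source_train=src.subset(s_tr),
        source_test=src.subset(s_te),
        target_train=tgt.subset(t_tr).unlabeled(),
        target_test=tgt.subset(t_te).unlabeled(),
        sealed_target_labels=sealed,
        manifest={
            "control_split_ratio": split.control_split_ratio,
            "train_test_ratio": split.train_test_ratio,
            "seed": split.seed,
            "stratify": split.stratify,
        },
    )


def smote_balance(
    ds: SpectralDataset, target_count: int = 300, k_neighbors: int = 5, seed: int = 0
) -> SpectralDataset:
    """Oversample every class to ``target_count`` rows by SMOTE interpolation.

    Each synthetic row is ``x_i + u * (x_nn - x_i)`` with ``u ~ U[0, 1]``,
    where ``x_nn`` is one of the ``k_neighbors`` same-class nearest neighbors
    of a randomly chosen real row.  Classes already at or above the target are
    left unchanged; originals are always preserved.
    """
    if ds.y is None:
        raise ValueError("smote_balance requires a labeled dataset")
    rng = np.random.default_rng(seed)
    blocks_X, blocks_y = [ds.X], [ds.y]
    for cls, count in sorted(ds.class_counts().items()):
        if count >= target_count:
            continue
        if count < 2:
            raise ValueError(f"class {cls} has {count} sample(s); SMOTE needs >= 2")
        Xc = ds.X[ds.y == cls]
        k = min(k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        _, neigh = nn.kneighbors(Xc)  # col 0 is the point itself
        n_new = target_count - count
        base = rng.integers(0, count, size=n_new)
        pick = rng.integers(1, k + 1, size=n_new)
        u = rng.random(n_new)
        partners = neigh[base, pick]
        synth = Xc[base] + u[:, None] * (Xc[partners] - Xc[base])
        blocks_X.append(synth)
        blocks_y.append(np.full(n_new, cls, dtype=np.int64))
    X = np.vstack(blocks_X)
    y = np.concatenate(blocks_y)
    return replace(ds, X=X, y=y, sample_ids=np.arange(len(y)))


def resample_to_grid(ds: SpectralDataset, grid: np.ndarray) -> SpectralDataset:
    """Linear interpolation of every row onto a new wavenumber grid."""
    if ds.wavenumbers is None:
        raise ValueError("dataset has no wavenumber grid to resample from")
    grid = np.asarray(grid, dtype=np.float64)
    X = np.vstack([np.interp(grid, ds.wavenumbers, row) for row in ds.X])
    return replace(ds, X=X, wavenumbers=grid)


def pca_harmonize(
    source: SpectralDataset, target: SpectralDataset, n_components: int = 50
) -> tuple[SpectralDataset, SpectralDataset, float]:
    """Project both domains into one shared PCA basis.

    The basis is fitted on the pooled rows of both datasets so the
    adversarial game sees a single coordinate system.  Returns the two
    projected datasets and the cumulative explained-variance ratio; warns
    (does not error) when that ratio is below 0.99.
    """
    if source.n_samples == 0 or target.n_samples == 0:
        raise ValueError("both datasets must be nonempty")
    if source.n_features != target.n_features:
        raise ValueError(
            "feature grids differ; resample_to_grid both domains to a common "
            "grid before pca_harmonize"
        )
    pooled = np.vstack([source.X, target.X])
    feasible = min(pooled.shape)
    if n_components > feasible:
        raise ValueError(f"n_components={n_components} exceeds feasible rank {feasible}")
    pca = PCA(n_components=n_components, svd_solver="full")
    pca.fit(pooled)
    explained = float(pca.explained_variance_ratio_.sum())
    if explained < 0.99:
        warnings.warn(
            f"PCA harmonization keeps only {explained:.4f} of the variance "
            f"with {n_components} components",
            UserWarning,
            stacklevel=2,
        )
    out_s = replace(source, X=pca.transform(source.X), wavenumbers=None)
    out_t = replace(target, X=pca.transform(target.X), wavenumbers=None)
    return out_s, out_t, explained
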