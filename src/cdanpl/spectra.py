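"""Core data containers for 1-D spectral transfer tasks, plus file I/O.

A :class:`Spectrum` is one trace on a strictly increasing wavenumber grid.
A :class:`SpectralDataset` is a sample x feature intensity matrix sharing one
grid, with optional integer class labels and a domain tag.  A
:class:`DomainPair` holds a labeled source dataset and an unlabeled target
dataset (train/test splits of each) — the unit of a transfer task.  Target
labels, when the task is synthetic, are sealed away for evaluation only and
are never visible to training code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum", "SpectralDataset", "DomainPair",
    "load_dataset", "save_dataset", "load_pair", "save_pair",
]


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace: intensities on a strictly increasing grid (cm^-1)."""

    wavenumbers: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.wavenumbers, dtype=np.float64)
        x = np.asarray(self.intensities, dtype=np.float64)
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", x)
        if w.ndim != 1 or x.ndim != 1 or len(w) != len(x):
            raise ValueError("wavenumbers and intensities must be equal-length 1-D arrays")
        if not np.all(np.isfinite(x)):
            raise ValueError("intensities must be finite")
        if not np.all(np.isfinite(w)) or np.any(np.diff(w) <= 0):
            raise ValueError("wavenumbers must be finite and strictly increasing")

    def __len__(self) -> int:
        return len(self.wavenumbers)

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        return Spectrum(self.wavenumbers, intensities)


@dataclass
class SpectralDataset:
    """Sample x feature intensity matrix on one shared grid.

    ``y`` carries integer class codes (contiguous from 0) or ``None`` for an
    unlabeled dataset; ``class_names`` maps code -> name.  ``domain`` tags the
    dataset as ``"source"`` or ``"target"``.
    """

    X: np.ndarray
    y: np.ndarray | None = None
    domain: str = "source"
    wavenumbers: np.ndarray | None = None
    class_names: dict = field(default_factory=dict)
    sample_ids: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=np.float64))
        if not np.all(np.isfinite(self.X)):
            raise ValueError("all rows of X must be finite")
        if self.domain not in ("source", "target"):
            raise ValueError(f"domain must be 'source' or 'target', got {self.domain!r}")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int64)
            if len(self.y) != self.X.shape[0]:
                raise ValueError("len(y) must equal number of rows of X")
            if len(self.y) and (self.y.min() < 0 or
                                set(range(self.y.max() + 1)) - set(np.unique(self.y))):
                raise ValueError("class codes must be contiguous integers from 0")
        if self.wavenumbers is not None:
            self.wavenumbers = np.asarray(self.wavenumbers, dtype=np.float64)
            if len(self.wavenumbers) != self.X.shape[1]:
                raise ValueError("wavenumber grid length must match feature count")
            if np.any(np.diff(self.wavenumbers) <= 0):
                raise ValueError("wavenumbers must be strictly increasing")
        if self.sample_ids is None:
            self.sample_ids = np.arange(self.X.shape[0])
        else:
            self.sample_ids = np.asarray(self.sample_ids)

    @property
    def n_samples(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def n_classes(self) -> int:
        if self.y is None or not len(self.y):
            return 0
        return int(self.y.max()) + 1

    def spectrum(self, i: int) -> Spectrum:
        w = self.wavenumbers
        if w is None:
            w = np.arange(self.n_features, dtype=np.float64)
        return Spectrum(w, self.X[i])

    def subset(self, idx) -> "SpectralDataset":
        idx = np.asarray(idx)
        return replace(
            self,
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            sample_ids=self.sample_ids[idx],
        )

    def unlabeled(self) -> "SpectralDataset":
        return replace(self, y=None)

    def class_counts(self) -> dict:
        if self.y is None:
            return {}
        codes, counts = np.unique(self.y, return_counts=True)
        return dict(zip(codes.tolist(), counts.tolist()))


@dataclass
class DomainPair:
    """A transfer task: labeled source, unlabeled target, compatible grids.

    ``sealed_target_labels`` exist only for synthetic / evaluation fixtures;
    training code must access targets through ``target_train``/``target_test``
    which carry no labels.
    """

    source_train: SpectralDataset
    source_test: SpectralDataset
    target_train: SpectralDataset
    target_test: SpectralDataset
    sealed_target_labels: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)

    def __post_init__(self):
        dims = {ds.n_features for ds in (self.source_train, self.source_test,
                                         self.target_train, self.target_test)}
        if len(dims) != 1:
            raise ValueError(f"all four datasets must share one feature grid, got dims {dims}")
        for name in ("target_train", "target_test"):
            ds = getattr(self, name)
            if ds.y is not None:
                raise ValueError(f"{name} must be unlabeled; sealed labels go in sealed_target_labels")

    @property
    def n_classes(self) -> int:
        return self.source_train.n_classes

    @property
    def input_len(self) -> int:
        return self.source_train.n_features

    def sealed_labels(self, split: str) -> np.ndarray:
        """Evaluation-only target labels ('train' or 'test')."""
        if split not in self.sealed_target_labels:
            raise KeyError(f"no sealed labels for split {split!r}")
        return self.sealed_target_labels[split]


# ---------------------------------------------------------------------------
# I/O: CSV (header row = wavenumbers, one sample/row, sidecar labels) and NPZ
# ---------------------------------------------------------------------------

def save_dataset(ds: SpectralDataset, path: str | Path) -> None:
    """Write a dataset as NPZ (.npz) or CSV + sidecar (.csv)."""
    path = Path(path)
    if path.suffix == ".npz":
        payload = {"X": ds.X, "domain": np.array(ds.domain)}
        if ds.y is not None:
            payload["y"] = ds.y
        if ds.wavenumbers is not None:
            payload["wavenumbers"] = ds.wavenumbers
        if ds.class_names:
            codes = sorted(ds.class_names)
            payload["class_codes"] = np.array(codes)
            payload["class_names"] = np.array([str(ds.class_names[c]) for c in codes])
        np.savez(path, **payload)
        return
    if path.suffix in (".csv", ".tsv"):
        sep = "\t" if path.suffix == ".tsv" else ","
        w = ds.wavenumbers if ds.wavenumbers is not None else np.arange(ds.n_features)
        pd.DataFrame(ds.X, columns=[f"{v:g}" for v in w]).to_csv(path, sep=sep, index=False)
        side = pd.DataFrame({
            "sample_id": ds.sample_ids,
            "label": ds.y if ds.y is not None else [""] * ds.n_samples,
            "domain": ds.domain,
        })
        side.to_csv(path.with_name(path.stem + "_labels" + path.suffix), sep=sep, index=False)
        return
    raise ValueError(f"unsupported extension {path.suffix!r}; use .npz/.csv/.tsv")


def load_dataset(path: str | Path, sidecar: str | Path | None = None) -> SpectralDataset:
    """Read a dataset written by :func:`save_dataset` (NPZ or CSV/TSV)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            names = {}
            if "class_codes" in z:
                names = {int(c): str(n) for c, n in zip(z["class_codes"], z["class_names"])}
            return SpectralDataset(
                X=z["X"],
                y=z["y"] if "y" in z else None,
                domain=str(z["domain"]),
                wavenumbers=z["wavenumbers"] if "wavenumbers" in z else None,
                class_names=names,
            )
    if path.suffix in (".csv", ".tsv"):
        sep = "\t" if path.suffix == ".tsv" else ","
        frame = pd.read_csv(path, sep=sep)
        wavenumbers = np.array([float(c) for c in frame.columns])
        if sidecar is None:
            sidecar = path.with_name(path.stem + "_labels" + path.suffix)
        y = domain = None
        sample_ids = None
        if Path(sidecar).exists():
            side = pd.read_csv(sidecar, sep=sep)
            sample_ids = side["sample_id"].to_numpy()
            labels = side["label"]
            if labels.notna().all() and (labels.astype(str) != "").all():
                y = labels.astype(int).to_numpy()
            domain = str(side["domain"].iloc[0])
        return SpectralDataset(
            X=frame.to_numpy(dtype=np.float64),
            y=y,
            domain=domain or "source",
            wavenumbers=wavenumbers,
            sample_ids=sample_ids,
        )
    raise ValueError(f"unsupported extension {path.suffix!r}; use .npz/.csv/.tsv")


def save_pair(pair: DomainPair, path: str | Path) -> None:
    """Write a whole transfer task (four datasets + sealed labels) to one NPZ."""
    import json

    payload = {}
    for name in ("source_train", "source_test", "target_train", "target_test"):
        ds = getattr(pair, name)
        payload[f"{name}_X"] = ds.X
        if ds.y is not None:
            payload[f"{name}_y"] = ds.y
        if ds.wavenumbers is not None:
            payload[f"{name}_w"] = ds.wavenumbers
    for split, labels in pair.sealed_target_labels.items():
        payload[f"sealed_{split}"] = labels
    payload["manifest"] = np.frombuffer(
        json.dumps(pair.manifest, default=str).encode(), dtype=np.uint8
    )
    np.savez(path, **payload)


def load_pair(path: str | Path) -> DomainPair:
    """Read a transfer task written by :func:`save_pair`."""
    import json

    with np.load(path, allow_pickle=False) as z:
        def ds(name, domain):
            return SpectralDataset(
                X=z[f"{name}_X"],
                y=z[f"{name}_y"] if f"{name}_y" in z else None,
                domain=domain,
                wavenumbers=z[f"{name}_w"] if f"{name}_w" in z else None,
            )

        sealed = {
            key.removeprefix("sealed_"): z[key]
            for key in z.files if key.startswith("sealed_")
        }
        manifest = json.loads(z["manifest"].tobytes().decode()) if "manifest" in z else {}
        return DomainPair(
            source_train=ds("source_train", "source"),
            source_test=ds("source_test", "source"),
            target_train=ds("target_train", "target"),
            target_test=ds("target_test", "target"),
            sealed_target_labels=sealed,
            manifest=manifest,
        )
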