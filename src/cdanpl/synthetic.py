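"""Synthetic two-domain Raman-like spectrum generator.

Emulates the study conditions this package is tested under: two spectrometer
setups producing systematically different spectra of the same underlying
chemistry (domain shift), binary disease-vs-control classes encoded as
amplitude differences at designated Raman peak positions, class imbalance and
small per-class sample counts.

Each synthetic spectrum is::

    gain * sum_p A_p(class) * Gaussian(center_p + offset + jitter, width_p * width_scale)
    + cubic_baseline(t) + N(0, noise_sd)

where ``A_p(class) = base_amplitude + class_effect * class_code`` (so the
disease class, code 1, gains ``class_effect`` of extra amplitude at
discriminative peaks).  The domain shift channels are the baseline
polynomial, a global gain, the noise level, per-sample peak-position jitter,
a systematic wavenumber calibration offset and a spectral-resolution (peak
width) ratio — the latter two emulate the residual differences between two
instruments that survive baseline correction and normalization.

Default discriminative peak centers follow the key characteristic peaks
reported for serum autoimmune-disease spectra (924, 929, 991, 1317, 1444,
1653 cm^-1); further non-discriminative serum bands are included so class
information is localized, not global.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import yaml

from .preprocess import SplitSpec, _split_7_3
from .spectra import DomainPair, SpectralDataset

__all__ = [
    "PeakSpec",
    "DomainShiftSpec",
    "TaskConfig",
    "default_grid",
    "default_peaks",
    "generate_domain",
    "generate_transfer_task",
    "load_preset",
    "PRESET_NAMES",
]

PRESET_NAMES = ("easy", "hard", "homologous-like", "nonhomologous-like")


@dataclass(frozen=True)
class PeakSpec:
    """One Gaussian peak: center/width in cm^-1, base amplitude, class delta."""

    center: float
    width: float
    base_amplitude: float
    class_effect: float = 0.0

    def __post_init__(self):
        if self.width <= 0:
            raise ValueError("peak width must be > 0")


@dataclass(frozen=True)
class DomainShiftSpec:
    """Acquisition-setup description for one domain.

    ``baseline_coeffs`` are cubic polynomial coefficients (c0..c3) evaluated
    on the grid normalized to [0, 1]; ``gain`` scales the peak sum;
    ``noise_sd`` is i.i.d. Gaussian noise; ``peak_jitter_sd`` jitters each
    peak center independently per sample; ``peak_shift`` is a systematic
    wavenumber calibration offset, ``peak_shift_sd`` the per-sample spread of
    that offset (calibration drift across measurement sessions — all peaks of
    one spectrum move together), and ``width_scale`` a spectral-resolution
    ratio.
    """

    baseline_coeffs: tuple = (0.0, 0.0, 0.0, 0.0)
    gain: float = 1.0
    noise_sd: float = 0.0
    peak_jitter_sd: float = 0.0
    seed: int = 0
    peak_shift: float = 0.0
    peak_shift_sd: float = 0.0
    width_scale: float = 1.0

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.width_scale <= 0:
            raise ValueError("width_scale must be > 0")


def default_grid(n_points: int = 600, lo: float = 500.0, hi: float = 2000.0) -> np.ndarray:
    """Desk-scale wavenumber grid over the serum fingerprint range."""
    return np.linspace(lo, hi, n_points)


def default_peaks(class_effect: float = 0.2) -> list[PeakSpec]:
    """Serum-like peak set: 6 discriminative bands + 6 class-neutral bands."""
    discriminative = [
        (924.02, 7.0, 0.75),
        (929.19, 7.0, 0.70),
        (990.84, 6.0, 0.90),
        (1316.85, 9.0, 0.80),
        (1444.16, 10.0, 0.85),
        (1653.46, 11.0, 0.95),
    ]
    neutral = [
        (631.18, 8.0, 0.55),
        (845.80, 8.0, 0.60),
        (980.62, 6.0, 0.50),
        (1051.74, 7.0, 0.65),
        (1249.49, 9.0, 0.70),
        (1254.33, 9.0, 0.60),
    ]
    peaks = [PeakSpec(c, w, a, class_effect) for c, w, a in discriminative]
    peaks += [PeakSpec(c, w, a, 0.0) for c, w, a in neutral]
    return peaks


def expected_spectrum(cls: int, peaks: list[PeakSpec], shift: DomainShiftSpec,
                      grid: np.ndarray) -> np.ndarray:
    """Closed-form noiseless, jitter-free expectation of one spectrum."""
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = sum(c * t**k for k, c in enumerate(shift.baseline_coeffs))
    total = np.zeros_like(grid)
    for p in peaks:
        amp = p.base_amplitude + p.class_effect * cls
        center = p.center + shift.peak_shift
        sigma = p.width * shift.width_scale
        total += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
    return shift.gain * total + baseline


def generate_domain(
    n_per_class: dict,
    peaks: list[PeakSpec],
    shift: DomainShiftSpec,
    grid: np.ndarray | None = None,
    domain: str = "source",
    class_names: dict | None = None,
) -> SpectralDataset:
    """Draw a labeled spectral dataset for one acquisition setup.

    Fully reproducible from ``shift.seed``; per-sample randomness is the peak
    jitter and the additive noise.
    """
    if not peaks:
        raise ValueError("peak list must not be empty")
    grid = default_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly increasing")
    for p in peaks:
        if not grid[0] <= p.center <= grid[-1]:
            raise ValueError(f"peak center {p.center} outside grid range")
    if any(n < 0 for n in n_per_class.values()):
        raise ValueError("n_per_class values must be >= 0")
    rng = np.random.default_rng(shift.seed)
    t = (grid - grid[0]) / (grid[-1] - grid[0])
    baseline = sum(c * t**k for k, c in enumerate(shift.baseline_coeffs))
    rows, labels = [], []
    for cls in sorted(n_per_class):
        for _ in range(n_per_class[cls]):
            total = np.zeros_like(grid)
            offset = shift.peak_shift
            if shift.peak_shift_sd:
                offset += rng.normal(0.0, shift.peak_shift_sd)
            for p in peaks:
                amp = p.base_amplitude + p.class_effect * cls
                jitter = rng.normal(0.0, shift.peak_jitter_sd) if shift.peak_jitter_sd else 0.0
                center = p.center + offset + jitter
                sigma = p.width * shift.width_scale
                total += amp * np.exp(-0.5 * ((grid - center) / sigma) ** 2)
            x = shift.gain * total + baseline
            if shift.noise_sd:
                x = x + rng.normal(0.0, shift.noise_sd, size=len(grid))
            rows.append(x)
            labels.append(cls)
    names = class_names or {0: "control", 1: "disease"}
    return SpectralDataset(
        X=np.vstack(rows) if rows else np.empty((0, len(grid))),
        y=np.asarray(labels, dtype=np.int64),
        domain=domain,
        wavenumbers=grid,
        class_names=names,
    )


@dataclass
class TaskConfig:
    """Full recipe of a synthetic transfer task."""

    name: str = "custom"
    grid_points: int = 600
    grid_lo: float = 500.0
    grid_hi: float = 2000.0
    target_grid_points: int | None = None  # differing resolution if set
    class_effect: float = 0.2
    n_source: dict = field(default_factory=lambda: {0: 34, 1: 72})
    n_target: dict = field(default_factory=lambda: {0: 68, 1: 72})
    source_shift: DomainShiftSpec = field(default_factory=DomainShiftSpec)
    target_shift: DomainShiftSpec = field(default_factory=DomainShiftSpec)
    train_test_ratio: float = 0.7
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_source"] = {int(k): int(v) for k, v in self.n_source.items()}
        d["n_target"] = {int(k): int(v) for k, v in self.n_target.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        for key in ("source_shift", "target_shift"):
            if key in d and isinstance(d[key], dict):
                spec = dict(d[key])
                if "baseline_coeffs" in spec:
                    spec["baseline_coeffs"] = tuple(spec["baseline_coeffs"])
                d[key] = DomainShiftSpec(**spec)
        for key in ("n_source", "n_target"):
            if key in d:
                d[key] = {int(k): int(v) for k, v in d[key].items()}
        return cls(**d)


def load_preset(name: str) -> TaskConfig:
    """Load one of the bundled task presets from its YAML file."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("cdanpl").joinpath(f"presets/{name.replace('-like', '')}.yaml").read_text()
    return TaskConfig.from_dict(yaml.safe_load(text))


def generate_transfer_task(config: TaskConfig | str | dict | None = None) -> DomainPair:
    """Build a DomainPair with sealed target labels from a task recipe.

    Accepts a :class:`TaskConfig`, a preset name, a config dict (e.g. parsed
    YAML), or ``None`` for the default configuration.  Deterministic in
    ``config.seed``.
    """
    if config is None:
        config = TaskConfig()
    elif isinstance(config, str):
        config = load_preset(config)
    elif isinstance(config, dict):
        config = TaskConfig.from_dict(config)
    grid_s = default_grid(config.grid_points, config.grid_lo, config.grid_hi)
    grid_t = default_grid(config.target_grid_points or config.grid_points,
                          config.grid_lo, config.grid_hi)
    peaks = default_peaks(config.class_effect)
    import dataclasses as _dc
    src_shift = _dc.replace(config.source_shift, seed=config.seed * 1000 + config.source_shift.seed)
    tgt_shift = _dc.replace(config.target_shift, seed=config.seed * 1000 + 500 + config.target_shift.seed)
    src = generate_domain(config.n_source, peaks, src_shift, grid_s, domain="source")
    tgt = generate_domain(config.n_target, peaks, tgt_shift, grid_t, domain="target")
    if len(grid_t) != len(grid_s):
        # differing instrument resolutions: align by linear interpolation so the
        # pair shares one grid; downstream PCA harmonization remains available
        from .preprocess import resample_to_grid

        tgt = resample_to_grid(tgt, grid_s)
    split = SplitSpec(train_test_ratio=config.train_test_ratio, seed=config.seed)
    s_tr, s_te = _split_7_3(src.X, src.y, split, seed=config.seed)
    t_tr, t_te = _split_7_3(tgt.X, tgt.y, split, seed=config.seed + 1)
    sealed = {"train": tgt.y[t_tr].copy(), "test": tgt.y[t_te].copy()}
    return DomainPair(
        source_train=src.subset(s_tr),
        source_test=src.subset(s_te),
        target_train=tgt.subset(t_tr).unlabeled(),
        target_test=tgt.subset(t_te).unlabeled(),
        sealed_target_labels=sealed,
        manifest={"task": config.to_dict()},
    )
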