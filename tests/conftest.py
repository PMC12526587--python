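import numpy as np
import pytest

from cdanpl.model import CDANPL, TrainConfig, prepare_pair
from cdanpl.networks import ExtractorConfig, build_bundle
from cdanpl.spectra import SpectralDataset
from cdanpl.synthetic import (
    DomainShiftSpec,
    PeakSpec,
    TaskConfig,
    default_grid,
    generate_transfer_task,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def grid():
    return default_grid(200, 500.0, 2000.0)


@pytest.fixture
def small_peaks():
    return [
        PeakSpec(800.0, 20.0, 1.0, 0.5),
        PeakSpec(1200.0, 25.0, 0.8, 0.0),
        PeakSpec(1600.0, 30.0, 0.6, 0.0),
    ]


def tiny_task_config(seed: int = 0) -> TaskConfig:
    """A fast, strongly separable two-domain task on a short grid."""
    return TaskConfig(
        name="tiny",
        grid_points=64,
        class_effect=0.6,
        n_source={0: 12, 1: 14},
        n_target={0: 12, 1: 14},
        source_shift=DomainShiftSpec(baseline_coeffs=(0.3, 0.2, -0.1, 0.05),
                                     noise_sd=0.01, peak_jitter_sd=0.5, seed=1),
        target_shift=DomainShiftSpec(baseline_coeffs=(0.6, -0.3, 0.4, -0.1),
                                     gain=1.2, noise_sd=0.02, peak_jitter_sd=1.0,
                                     peak_shift=8.0, width_scale=1.2, seed=2),
        seed=seed,
    )


def tiny_train_config(**kw) -> TrainConfig:
    base = dict(
        iterations=3,
        batch=8,
        lr=1e-4,
        seed=0,
        n_runs=1,
        feature_dim=16,
        extractor=ExtractorConfig(patch=8, d_model=16, depth=1, n_heads=2,
                                  conv_kernels=(3, 7), conv_channels=4,
                                  feature_dim=16),
    )
    base.update(kw)
    return TrainConfig(**base)


@pytest.fixture
def tiny_pair():
    pair = generate_transfer_task(tiny_task_config())
    return prepare_pair(pair, smote_target=16, smote_k=3, seed=0)


@pytest.fixture
def tiny_bundle():
    return build_bundle(
        64, n_classes=2, feature_dim=16,
        config=ExtractorConfig(patch=8, d_model=16, depth=1, n_heads=2,
                               conv_kernels=(3, 7), conv_channels=4, feature_dim=16),
        seed=7,
    )


@pytest.fixture
def labeled_dataset(rng):
    X = rng.normal(size=(30, 40))
    y = np.array([0] * 18 + [1] * 12)
    return SpectralDataset(X=X, y=y, domain="source",
                           wavenumbers=np.linspace(500, 2000, 40))
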