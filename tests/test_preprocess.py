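"""Preprocessing stack: baseline, smoothing, normalization, splits, SMOTE, PCA."""

import numpy as np
import pytest

from cdanpl.preprocess import (
    PreprocessParams,
    SplitSpec,
    correct_baseline,
    make_domain_split,
    minmax_normalize,
    pca_harmonize,
    preprocess_spectrum,
    resample_to_grid,
    smooth_mean,
    smote_balance,
)
from cdanpl.spectra import SpectralDataset, Spectrum


def cubic(w, coeffs=(2.0, -1.5, 0.8, 0.5)):
    t = (w - w[0]) / (w[-1] - w[0])
    return coeffs[0] + coeffs[1] * t + coeffs[2] * t**2 + coeffs[3] * t**3


class TestBaselineCorrection:
    def test_pure_cubic_is_removed_to_machine_precision(self, grid):
        signal = cubic(grid)
        out = correct_baseline(Spectrum(grid, signal))
        assert np.abs(out.intensities).max() < 1e-6 * np.ptp(signal)

    def test_all_zero_spectrum_stays_zero(self, grid):
        out = correct_baseline(Spectrum(grid, np.zeros_like(grid)))
        assert np.allclose(out.intensities, 0.0)

    def test_peaks_survive_baseline_removal(self, grid):
        # oracle: subtracting the generating cubic recovers the peak-only truth
        peaks = (1.0 * np.exp(-0.5 * ((grid - 800) / 15) ** 2)
                 + 0.7 * np.exp(-0.5 * ((grid - 1200) / 20) ** 2)
                 + 0.5 * np.exp(-0.5 * ((grid - 1650) / 25) ** 2))
        spec = Spectrum(grid, peaks + cubic(grid))
        corrected = correct_baseline(spec).intensities
        for center, height in ((800, 1.0), (1200, 0.7), (1650, 0.5)):
            i = np.argmin(np.abs(grid - center))
            assert abs(corrected[i] - height) < 0.05 * height

    def test_parameter_validation(self, grid):
        spec = Spectrum(grid, np.ones_like(grid) + grid / 1000)
        with pytest.raises(ValueError):
            correct_baseline(spec, degree=0)
        with pytest.raises(ValueError):
            correct_baseline(spec, max_iter=0)
        with pytest.raises(ValueError):
            correct_baseline(spec, loss_gradient=0.0)
        with pytest.raises(ValueError):
            correct_baseline(Spectrum(grid[:4], np.ones(4)), degree=3)


class TestSmoothing:
    def test_constant_vector_unchanged(self, grid):
        out = smooth_mean(Spectrum(grid, np.full_like(grid, 3.7)), window=9)
        assert np.allclose(out.intensities, 3.7)

    def test_unit_impulse_spreads_to_ninth(self, grid):
        x = np.zeros_like(grid)
        mid = len(grid) // 2
        x[mid] = 1.0
        out = smooth_mean(Spectrum(grid, x), window=9).intensities
        assert np.allclose(out[mid - 4: mid + 5], 1.0 / 9)
        assert np.allclose(out[: mid - 4], 0.0) and np.allclose(out[mid + 5:], 0.0)

    def test_matches_bruteforce_moving_average(self, grid, rng):
        x = rng.normal(size=len(grid))
        out = smooth_mean(Spectrum(grid, x), window=9).intensities
        half = 4
        brute = np.array([
            x[max(0, i - half): min(len(x), i + half + 1)].mean()
            for i in range(len(x))
        ])
        assert np.allclose(out, brute)

    def test_even_window_rejected(self, grid):
        with pytest.raises(ValueError):
            smooth_mean(Spectrum(grid, np.ones_like(grid)), window=8)


class TestNormalization:
    def test_affine_identity(self):
        out = minmax_normalize(Spectrum([1, 2, 3], [0.0, 5.0, 10.0]))
        assert np.allclose(out.intensities, [0.0, 0.5, 1.0])

    def test_unit_range_fixed_point(self, grid, rng):
        x = rng.random(len(grid))
        x[0], x[1] = 0.0, 1.0
        out = minmax_normalize(Spectrum(grid, x))
        assert np.allclose(out.intensities, x)

    def test_matches_elementwise_formula(self, grid, rng):
        x = rng.normal(size=len(grid))
        out = minmax_normalize(Spectrum(grid, x)).intensities
        assert np.allclose(out, (x - x.min()) / (x.max() - x.min()))

    def test_constant_spectrum_error_names_row(self, grid):
        with pytest.raises(ValueError, match="row 3"):
            minmax_normalize(Spectrum(grid, np.ones_like(grid)), row=3)


def test_pipeline_idempotent_up_to_normalization(rng):
    # at realistic resolution (2.5 cm^-1/point) a second pipeline pass changes
    # almost nothing: the baseline is already gone and the peaks, much wider
    # than the smoothing window, are barely touched again
    grid = np.linspace(500, 2000, 600)
    peaks = np.exp(-0.5 * ((grid - 900) / 25) ** 2) + cubic(grid)
    once = preprocess_spectrum(Spectrum(grid, peaks))
    twice = preprocess_spectrum(once)
    assert np.abs(once.intensities - twice.intensities).max() < 0.05


class TestDomainSplit:
    @staticmethod
    def _inputs(n_controls=68, n_dis=40, n_feat=30, seed=0):
        rng = np.random.default_rng(seed)
        w = np.linspace(500, 2000, n_feat)
        mk = lambda n, d: SpectralDataset(X=rng.normal(size=(n, n_feat)),
                                          domain=d, wavenumbers=w)
        return mk(n_controls, "source"), mk(n_dis, "source"), mk(n_dis, "target")

    def test_68_controls_split_one_to_one(self):
        controls, dis_s, dis_t = self._inputs()
        pair = make_domain_split(controls, dis_s, dis_t, SplitSpec(seed=3))
        n_ctrl_src = (pair.source_train.y == 0).sum() + (pair.source_test.y == 0).sum()
        sealed = np.concatenate([pair.sealed_labels("train"), pair.sealed_labels("test")])
        assert n_ctrl_src == 34 and (sealed == 0).sum() == 34

    def test_split_deterministic_under_seed(self):
        controls, dis_s, dis_t = self._inputs(n_controls=10, n_dis=8)
        a = make_domain_split(controls, dis_s, dis_t, SplitSpec(seed=9))
        b = make_domain_split(controls, dis_s, dis_t, SplitSpec(seed=9))
        assert np.array_equal(a.source_train.X, b.source_train.X)
        assert np.array_equal(a.target_test.X, b.target_test.X)

    def test_70_30_counts_disjoint_and_complete(self):
        controls, dis_s, dis_t = self._inputs(n_controls=60, n_dis=70)
        pair = make_domain_split(controls, dis_s, dis_t, SplitSpec(seed=1))
        n_src = pair.source_train.n_samples + pair.source_test.n_samples
        assert n_src == 100 and pair.source_train.n_samples == 70
        # completeness: every source-domain row appears exactly once
        all_rows = np.vstack([pair.source_train.X, pair.source_test.X])
        expected = np.vstack([controls.X, dis_s.X])
        matched = sum(
            any(np.array_equal(row, e) for e in expected) for row in all_rows
        )
        assert matched == 100
        assert len(np.unique(all_rows, axis=0)) == 100

    def test_mismatched_grids_rejected(self):
        controls, dis_s, dis_t = self._inputs()
        bad = SpectralDataset(X=np.random.default_rng(0).normal(size=(5, 31)),
                              domain="target")
        with pytest.raises(ValueError):
            make_domain_split(controls, dis_s, bad)


class TestSmote:
    def test_imbalanced_classes_reach_exact_target(self, rng):
        X = rng.normal(size=(106, 20))
        y = np.array([0] * 72 + [1] * 34)
        ds = SpectralDataset(X=X, y=y)
        out = smote_balance(ds, target_count=300, seed=5)
        assert out.class_counts() == {0: 300, 1: 300}
        # originals preserved
        assert np.array_equal(out.X[:106], X)

    def test_class_at_target_untouched(self, labeled_dataset):
        out = smote_balance(labeled_dataset, target_count=12, seed=0)
        assert out.n_samples == labeled_dataset.n_samples
        assert np.array_equal(out.X, labeled_dataset.X)

    def test_synthetic_rows_lie_on_same_class_segments(self, rng):
        X = rng.normal(size=(20, 8))
        y = np.array([0] * 12 + [1] * 8)
        ds = SpectralDataset(X=X, y=y)
        out = smote_balance(ds, target_count=40, k_neighbors=3, seed=2)
        for i in range(20, out.n_samples):
            row, cls = out.X[i], out.y[i]
            Xc = X[y == cls]
            dists = []
            for a in range(len(Xc)):
                for b in range(len(Xc)):
                    if a == b:
                        continue
                    seg = Xc[b] - Xc[a]
                    t = np.clip(np.dot(row - Xc[a], seg) / np.dot(seg, seg), 0, 1)
                    dists.append(np.linalg.norm(row - (Xc[a] + t * seg)))
            assert min(dists) < 1e-9

    def test_singleton_class_rejected(self, rng):
        ds = SpectralDataset(X=rng.normal(size=(4, 5)), y=np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError, match="SMOTE needs"):
            smote_balance(ds, target_count=10)


class TestPcaHarmonize:
    def test_projects_both_domains_to_n_components(self, rng):
        src = SpectralDataset(X=rng.normal(size=(60, 80)), domain="source")
        tgt = SpectralDataset(X=rng.normal(size=(40, 80)) + 0.5, domain="target")
        out_s, out_t, explained = pca_harmonize(src, tgt, n_components=50)
        assert out_s.n_features == 50 and out_t.n_features == 50
        assert 0 < explained <= 1.0

    def test_low_rank_data_fully_explained(self, rng):
        basis = rng.normal(size=(4, 30))
        src = SpectralDataset(X=rng.normal(size=(25, 4)) @ basis, domain="source")
        tgt = SpectralDataset(X=rng.normal(size=(25, 4)) @ basis, domain="target")
        *_, explained = pca_harmonize(src, tgt, n_components=6)
        assert explained == pytest.approx(1.0, abs=1e-9)

    def test_row_order_changes_only_signs(self, rng):
        X1 = rng.normal(size=(30, 12))
        X2 = rng.normal(size=(20, 12)) + 1.0
        a_s, a_t, _ = pca_harmonize(SpectralDataset(X=X1), SpectralDataset(X=X2, domain="target"), 5)
        perm = rng.permutation(30)
        b_s, b_t, _ = pca_harmonize(SpectralDataset(X=X1[perm]),
                                    SpectralDataset(X=X2, domain="target"), 5)
        # compare distances, which are sign- and order-free
        d_a = np.linalg.norm(a_t.X[:, None] - a_t.X[None], axis=-1)
        d_b = np.linalg.norm(b_t.X[:, None] - b_t.X[None], axis=-1)
        assert np.allclose(d_a, d_b, atol=1e-8)

    def test_excessive_rank_rejected(self, rng):
        src = SpectralDataset(X=rng.normal(size=(5, 8)))
        tgt = SpectralDataset(X=rng.normal(size=(4, 8)), domain="target")
        with pytest.raises(ValueError):
            pca_harmonize(src, tgt, n_components=20)

    def test_warns_below_99_percent(self, rng):
        src = SpectralDataset(X=rng.normal(size=(40, 30)))
        tgt = SpectralDataset(X=rng.normal(size=(40, 30)), domain="target")
        with pytest.warns(UserWarning, match="variance"):
            pca_harmonize(src, tgt, n_components=2)


def test_resample_preserves_linear_trends(grid):
    ds = SpectralDataset(X=np.vstack([grid * 0.001, 2 - grid * 0.0005]),
                         wavenumbers=grid)
    new = np.linspace(grid[0], grid[-1], 77)
    out = resample_to_grid(ds, new)
    assert out.n_features == 77
    assert np.allclose(out.X[0], new * 0.001)
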