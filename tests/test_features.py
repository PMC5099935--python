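import numpy as np
import pytest

from nirsbci.containers import ConfigurationError
from nirsbci.features import (
    extract,
    extract_all,
    normalize_apply,
    normalize_fit,
    window_anchors,
)
from conftest import build_epochs


class TestWindowGrid:
    def test_default_grid_has_31_anchors(self):
        grid = window_anchors((-5.0, 25.0), width=3.0, step=1.0)
        assert grid.n_windows == 31
        assert grid.anchors[0] == -5.0 and grid.anchors[-1] == 25.0

    def test_single_window(self):
        grid = window_anchors((3.0, 3.0), width=3.0, step=3.0)
        assert grid.anchors == (3.0,)

    def test_matches_brute_force_enumeration(self):
        grid = window_anchors((0.0, 10.0), width=3.0, step=2.0)
        brute = []
        a = 0.0
        while a <= 10.0 + 1e-9:
            brute.append(a)
            a += 2.0
        assert np.allclose(grid.anchors, brute)

    def test_pure_function(self):
        assert window_anchors((-5, 25), 3, 1) == window_anchors((-5, 25), 3, 1)


class TestExtract:
    def test_constant_signal(self):
        ep = build_epochs(ma_course=lambda t: np.full((4, t.size), 2.5), noise_sd=0.0)
        fm = extract(ep, anchor=10.0, chromophores=("hbo",))
        means = fm.X[:10, :4]        # MA trials, mean block first
        slopes = fm.X[:10, 4:8]
        assert np.allclose(means, 2.5)
        assert np.abs(slopes).max() < 1e-10

    def test_linear_ramp_slope_exact(self):
        ep = build_epochs(ma_course=lambda t: np.tile(2.0 * t, (4, 1)),
                          bl_course=lambda t: np.tile(2.0 * t, (4, 1)), noise_sd=0.0)
        for anchor in (-2.0, 5.0, 25.0):
            fm = extract(ep, anchor=anchor, chromophores=("hbr",))
            assert np.allclose(fm.X[:, 4:8], 2.0)

    def test_noisy_ramp_matches_normal_equations(self, rng):
        ep = build_epochs(noise_sd=1.0, seed=8)
        fm = extract(ep, anchor=10.0, chromophores=("hbo",))
        t = ep.times
        mask = (t >= 7.0 - 1e-9) & (t <= 10.0 + 1e-9)
        tw = t[mask]
        A = np.column_stack([tw, np.ones_like(tw)])
        for trial in range(3):
            for ch in range(4):
                y = ep.data["hbo"][trial, ch, mask]
                slope = np.linalg.lstsq(A, y, rcond=None)[0][0]
                assert fm.X[trial, 4 + ch] == pytest.approx(slope, abs=1e-10)

    def test_endpoint_slope_variant(self):
        ep = build_epochs(ma_course=lambda t: np.tile(3.0 * t, (4, 1)),
                          bl_course=lambda t: np.tile(3.0 * t, (4, 1)), noise_sd=0.0)
        fm = extract(ep, anchor=10.0, chromophores=("hbo",), slope_kind="endpoint")
        assert np.allclose(fm.X[:, 4:8], 3.0)

    def test_feature_counts_and_names(self):
        ep = build_epochs(n_channels=10, noise_sd=1.0)
        both = extract(ep, anchor=5.0)
        single = extract(ep, anchor=5.0, chromophores=("hbr",))
        assert both.n_features == 40 and single.n_features == 20
        assert "ch1_hbo_mean" in both.columns and "ch10_hbr_slope" in both.columns

    def test_31_matrices_for_default_grid(self):
        ep = build_epochs(noise_sd=1.0)
        fms = extract_all(ep)
        assert len(fms) == 31

    def test_slope_scales_inversely_with_time_unit(self):
        """Re-expressing time in minutes multiplies the slope by 60."""
        ep_s = build_epochs(ma_course=lambda t: np.tile(t, (4, 1)),
                            bl_course=lambda t: np.tile(t, (4, 1)), noise_sd=0.0)
        # same physical signal, time axis re-expressed in minutes: the value
        # at t minutes equals 60 t (the old seconds reading)
        ep_m = build_epochs(ma_course=lambda t: np.tile(60.0 * t, (4, 1)),
                            bl_course=lambda t: np.tile(60.0 * t, (4, 1)), noise_sd=0.0,
                            window=(-8 / 60, 25 / 60), fs=15.6 * 60)
        fs = extract(ep_s, anchor=10.0, chromophores=("hbo",))
        fm = extract(ep_m, anchor=10.0 / 60, width=3.0 / 60, chromophores=("hbo",))
        assert np.allclose(fm.X[:, 4:8], 60.0 * fs.X[:, 4:8], rtol=1e-6)

    def test_window_outside_epoch_rejected(self):
        ep = build_epochs(noise_sd=1.0)
        with pytest.raises(ConfigurationError):
            extract(ep, anchor=-6.0)             # window [-9, -6] outside [-8, 25]

    def test_empty_chromophores_rejected(self):
        ep = build_epochs(noise_sd=1.0)
        with pytest.raises(ConfigurationError):
            extract(ep, anchor=5.0, chromophores=())


class TestNormalization:
    def test_train_transform_is_standardized(self, rng):
        ep = build_epochs(noise_sd=1.0, seed=9)
        fm = extract(ep, anchor=5.0)
        norm = normalize_fit(fm)
        out = normalize_apply(norm, fm)
        assert np.abs(out.X.mean(axis=0)).max() < 1e-10
        assert np.abs(out.X.var(axis=0, ddof=1) - 1.0).max() < 1e-10

    def test_constant_column_flagged_and_centered(self):
        ep = build_epochs(noise_sd=1.0, seed=10)
        fm = extract(ep, anchor=5.0)
        fm.X[:, 0] = 7.0
        norm = normalize_fit(fm)
        assert norm.constant_columns[0]
        out = normalize_apply(norm, fm)
        assert np.allclose(out.X[:, 0], 0.0)

    def test_heldout_uses_train_statistics_only(self, rng):
        ep = build_epochs(noise_sd=1.0, seed=11)
        fm = extract(ep, anchor=5.0)
        from nirsbci.features import FeatureMatrix

        train = FeatureMatrix(X=fm.X[:12], labels=fm.labels[:12], anchor=5.0, columns=fm.columns)
        test = FeatureMatrix(X=fm.X[12:], labels=fm.labels[12:], anchor=5.0, columns=fm.columns)
        norm = normalize_fit(train)
        via_train = normalize_apply(norm, test)
        via_self = normalize_apply(normalize_fit(test), test)
        assert not np.allclose(via_train.X, via_self.X)

    def test_single_row_rejected(self):
        ep = build_epochs(n_ma=1, n_bl=0, noise_sd=1.0)
        fm = extract(ep, anchor=5.0)
        with pytest.raises(ConfigurationError):
            normalize_fit(fm)
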