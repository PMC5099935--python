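import numpy as np
import pytest
from scipy import signal

from nirsbci.containers import BL, MA, ConfigurationError, DataError, EventSchedule, HemoSeries
from nirsbci.preprocess import (
    FilterSpec,
    apply_zero_phase,
    bandpass_hemo,
    baseline_correct,
    concat_epochs,
    epoch,
)
from nirsbci.preprocess import design_bandpass

FS = 15.6


def _magnitude_db(sos, freqs):
    w, h = signal.sosfreqz(sos, worN=np.asarray(freqs, dtype=float), fs=FS)
    return 20 * np.log10(np.abs(h) + 1e-300)


class TestFilterDesign:
    def test_six_pole_realization(self):
        sos = design_bandpass(FilterSpec(), FS)
        assert sos.shape[0] == 3                 # 3 biquads = 6 poles

    def test_dc_heavily_attenuated(self):
        sos = design_bandpass(FilterSpec(), FS)
        assert _magnitude_db(sos, [1e-4])[0] <= -30.0

    def test_mayer_band_passes(self):
        sos = design_bandpass(FilterSpec(), FS)
        g = _magnitude_db(sos, [0.1])[0]
        assert -3.0 < g < 0.5

    def test_passband_and_stopband_contract(self):
        sos = design_bandpass(FilterSpec(), FS)
        pb = _magnitude_db(sos, np.linspace(0.02, 0.15, 50))
        assert pb.min() >= -3.0
        sb = _magnitude_db(sos, np.linspace(0.5, FS / 2 * 0.99, 50))
        assert sb.max() <= -40.0 + 1e-6          # design attenuation, float slack

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            design_bandpass(FilterSpec(band=(0.01, 8.0)), FS)


class TestZeroPhase:
    def test_constant_input_suppressed(self):
        sos = design_bandpass(FilterSpec(), FS)
        x = np.full(int(600 * FS), 5.0)
        y = apply_zero_phase(sos, x)
        interior = y[int(30 * FS):-int(30 * FS)]
        assert np.abs(interior).max() < 1e-3 * 5.0

    def test_mayer_probe_zero_lag_and_gain(self):
        sos = design_bandpass(FilterSpec(), FS)
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        y = apply_zero_phase(sos, x)
        sl = slice(int(60 * FS), -int(60 * FS))
        xc, yc = x[sl], y[sl]
        lags = signal.correlation_lags(yc.size, xc.size)
        lag = lags[np.argmax(signal.correlate(yc, xc))]
        assert lag == 0
        ratio = yc.std() / xc.std()
        assert 0.5 < ratio < 1.1

    def test_cardiac_attenuated_below_ten_percent(self):
        sos = design_bandpass(FilterSpec(), FS)
        t = np.arange(int(600 * FS)) / FS
        x = np.sin(2 * np.pi * 1.1 * t)
        y = apply_zero_phase(sos, x)
        sl = slice(int(60 * FS), -int(60 * FS))
        assert y[sl].std() < 0.1 * x[sl].std()

    def test_linearity_on_interior_samples(self, rng):
        sos = design_bandpass(FilterSpec(), FS)
        x = rng.standard_normal(int(400 * FS))
        y = rng.standard_normal(int(400 * FS))
        fa = apply_zero_phase(sos, 2.0 * x + 0.5 * y)
        fb = 2.0 * apply_zero_phase(sos, x) + 0.5 * apply_zero_phase(sos, y)
        assert np.abs(fa - fb).max() < 1e-9

    def test_too_short_series_rejected(self):
        sos = design_bandpass(FilterSpec(), FS)
        with pytest.raises(DataError):
            apply_zero_phase(sos, np.zeros(10))


def _hemo(n_sec=400, n_ch=2, fs=FS, seed=0):
    rng = np.random.default_rng(seed)
    n = int(n_sec * fs)
    return HemoSeries(
        hbo=rng.standard_normal((n_ch, n)), hbr=rng.standard_normal((n_ch, n)),
        fs=fs, channel_names=tuple(f"ch{i+1}" for i in range(n_ch)),
    )


def _schedule(onsets, labels, duration=15.0, run_length=400.0):
    return EventSchedule(
        onsets=np.asarray(onsets, dtype=float),
        labels=np.asarray(labels, dtype=object),
        duration=duration,
        run_length=run_length,
    )


class TestEpoching:
    def test_trial_count_and_labels_preserved(self):
        hemo = _hemo()
        onsets = np.arange(60.0, 360.0, 40.0)
        labels = [MA, BL] * 4
        ep = epoch(hemo, _schedule(onsets[:8], labels), window=(-8, 25))
        assert ep.n_trials == 8
        assert sorted(ep.labels) == sorted(labels)

    def test_sixty_trials_across_runs(self):
        """Three default runs concatenate to 30 MA + 30 BL epochs."""
        from nirsbci.simulate import ParadigmSpec, make_schedule

        spec = ParadigmSpec()
        parts = []
        for s in range(3):
            sched = make_schedule(spec, seed=s)
            hemo = _hemo(n_sec=sched.run_length + 1)
            parts.append(epoch(hemo, sched, window=(-8, 25)))
        ep = concat_epochs(parts)
        assert ep.n_trials == 60
        assert int(np.sum(ep.labels == MA)) == 30
        assert int(np.sum(ep.labels == BL)) == 30

    def test_empty_schedule_gives_empty_epochset(self):
        ep = epoch(_hemo(), _schedule([], []), window=(-8, 25))
        assert ep.n_trials == 0

    def test_onset_too_close_to_edge_dropped(self, caplog):
        ep = epoch(_hemo(), _schedule([1.0, 100.0], [MA, BL]), window=(-8, 25))
        assert ep.n_trials == 1
        assert list(ep.labels) == [BL]


class TestBaseline:
    def test_constant_trial_becomes_zero(self):
        ep = epoch(_hemo(), _schedule([100.0], [MA]), window=(-8, 25))
        for k in ep.data:
            ep.data[k][:] = 3.14
        out = baseline_correct(ep)
        assert np.allclose(out.data["hbo"], 0.0)

    def test_interval_means_vanish(self):
        ep = epoch(_hemo(seed=5), _schedule([60.0, 120.0, 180.0], [MA, BL, MA]), window=(-8, 25))
        out = baseline_correct(ep, interval=(-2.0, 0.0))
        t = out.times
        mask = (t >= -2.0) & (t <= 0.0)
        for arr in out.data.values():
            assert np.abs(arr[:, :, mask].mean(axis=2)).max() < 1e-12

    def test_idempotent(self):
        ep = epoch(_hemo(seed=6), _schedule([60.0, 120.0], [MA, BL]), window=(-8, 25))
        once = baseline_correct(ep)
        twice = baseline_correct(once)
        assert np.allclose(once.data["hbr"], twice.data["hbr"])

    def test_interval_outside_window_rejected(self):
        ep = epoch(_hemo(), _schedule([100.0], [MA]), window=(-8, 25))
        with pytest.raises(ConfigurationError):
            baseline_correct(ep, interval=(-10.0, 0.0))
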