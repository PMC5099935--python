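"""Seeded synthetic fNIRS recordings for the mental-arithmetic paradigm.

The generator reproduces the block design of the study it emulates: per
paradigm (eyes-open EO or eyes-closed EC) three runs, each with 20 task
repetitions split 10 mental-arithmetic (MA) / 10 baseline (BL) in seeded
pseudo-random order, 15 s tasks preceded by a 3 s instruction, variable
20-25 s rests, and lead-in / lead-out rest blocks.  Sampling rate 15.6 Hz.

Ground-truth hemodynamics are condition-specific double-gamma HRFs convolved
with the task boxcar, plus physiological noise (1/f drift, ~0.1 Hz Mayer
wave, respiration, cardiac pulsation) and white measurement noise in optical
density.  The clean + noisy truth is mapped to dual-wavelength raw
intensities through the forward Beer-Lambert model, so every downstream
stage -- including the MBLL inversion -- is exercised on simulated data.

One seed governs everything through a splittable ``numpy.random.SeedSequence``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .containers import BL, MA, ConfigurationError, EventSchedule, HemoSeries, RawRecording
from .optics import Montage, OpticalCoefficients, default_coefficients, default_montage, forward_model

__all__ = [
    "ParadigmSpec",
    "HRFParams",
    "EffectSpec",
    "NoiseSpec",
    "SimulatedRun",
    "SimulatedSubject",
    "make_schedule",
    "hrf",
    "generate_subject",
    "null_effect",
    "strong_effect",
]

FS_DEFAULT = 15.6


@dataclass
class ParadigmSpec:
    """Block-design trial schedule parameters for one paradigm."""

    n_runs_per_paradigm: int = 3
    reps_per_run: int = 20            # split evenly MA/BL
    task_duration: float = 15.0       # s
    rest_range: Tuple[float, float] = (20.0, 25.0)
    instruction_duration: float = 3.0
    lead_rest: float = 75.0           # 60 s rest + 15 s preparation
    trail_rest: float = 60.0
    paradigm: str = "EO"              # "EO" or "EC"
    fs: float = FS_DEFAULT

    def __post_init__(self) -> None:
        if self.reps_per_run % 2 != 0:
            raise ConfigurationError("reps_per_run must be even (equal MA/BL split)")
        if self.rest_range[0] > self.rest_range[1]:
            raise ConfigurationError("rest_range must be (lo, hi) with lo <= hi")
        for name in ("task_duration", "instruction_duration", "lead_rest", "trail_rest"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.paradigm not in ("EO", "EC"):
            raise ConfigurationError("paradigm must be 'EO' or 'EC'")


@dataclass
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_disp: float = 1.0
    undershoot_disp: float = 1.0
    ratio: float = 6.0                # peak / undershoot amplitude ratio

    def __post_init__(self) -> None:
        if min(self.peak_delay, self.undershoot_delay, self.peak_disp, self.undershoot_disp) <= 0:
            raise ConfigurationError("HRF delays and dispersions must be positive")
        if self.ratio <= 0:
            raise ConfigurationError("HRF ratio must be positive")


@dataclass
class EffectSpec:
    """Per-channel, per-condition response amplitudes (mmol/L).

    ``hbo_amp``/``hbr_amp`` map condition -> amplitude vector over channels.
    HbR is scaled independently of HbO (not a fixed negative mirror): the
    emulated pattern has Delta[HbR] *increasing* under MA at anterior
    channels.  ``trial_amplitude_jitter`` is the coefficient of variation of
    a per-trial multiplicative amplitude factor.
    """

    hbo_amp: Dict[str, np.ndarray]
    hbr_amp: Dict[str, np.ndarray]
    hrf_params: HRFParams = field(default_factory=HRFParams)
    trial_amplitude_jitter: float = 0.2

    def __post_init__(self) -> None:
        for d in (self.hbo_amp, self.hbr_amp):
            for cond in (MA, BL):
                if cond not in d:
                    raise ConfigurationError(f"effect amplitudes missing condition {cond}")
                d[cond] = np.asarray(d[cond], dtype=float)
                if not np.all(np.isfinite(d[cond])):
                    raise ConfigurationError("effect amplitudes must be finite")
        if self.trial_amplitude_jitter < 0:
            raise ConfigurationError("trial_amplitude_jitter must be >= 0")

    @property
    def n_channels(self) -> int:
        return self.hbo_amp[MA].size


def default_effect(n_channels: int = 10) -> EffectSpec:
    """Moderate, anatomically patterned effect emulating the EC grand average.

    MA drives an HbR increase strongest at the anterior channels 4 and 7
    (Fp1/Fp2), subtle at 5 and 6, and a larger biphasic HbO response; BL
    produces weak decreases of both chromophores.  Amplitudes are in mmol/L
    on the scale of the emulated grand-average figures (~1e-3).
    """
    hbr_ma = np.full(n_channels, 0.3e-3)
    hbo_ma = np.full(n_channels, 0.6e-3)
    for idx, strong in ((3, True), (6, True), (4, False), (5, False)):
        if idx < n_channels:
            hbr_ma[idx] = 2.0e-3 if strong else 1.0e-3
            hbo_ma[idx] = 3.0e-3 if strong else 1.8e-3
    return EffectSpec(
        hbo_amp={MA: hbo_ma, BL: np.full(n_channels, -0.8e-3)},
        hbr_amp={MA: hbr_ma, BL: np.full(n_channels, -0.3e-3)},
    )


def null_effect(n_channels: int = 10) -> EffectSpec:
    """Zero effect in every channel and condition (chance-level ground truth)."""
    z = np.zeros(n_channels)
    return EffectSpec(
        hbo_amp={MA: z.copy(), BL: z.copy()},
        hbr_amp={MA: z.copy(), BL: z.copy()},
        trial_amplitude_jitter=0.0,
    )


def strong_effect(n_channels: int = 10, channel: int = 3) -> EffectSpec:
    """Large single-channel HbR/HbO effect for signal-recovery checks.

    ``channel`` is a zero-based index; default 3 (= ch4, Fp1).
    """
    hbr = np.zeros(n_channels)
    hbo = np.zeros(n_channels)
    hbr[channel] = 8.0e-3
    hbo[channel] = 10.5e-3
    return EffectSpec(
        hbo_amp={MA: hbo, BL: np.zeros(n_channels)},
        hbr_amp={MA: hbr, BL: np.zeros(n_channels)},
        trial_amplitude_jitter=0.1,
    )


@dataclass
class NoiseSpec:
    """Physiological and instrumental noise levels.

    Amplitudes for drift/Mayer/respiration/cardiac are HbO-equivalent SDs in
    mmol/L; the same components are added to HbR scaled by
    ``hbr_noise_scale``.  ``white_sd`` is white measurement noise added in
    optical-density space.  Channel-wise amplitudes are scaled by a
    log-normal factor (sigma ``channel_scale_sigma``) so channels are not
    artificially identical.
    """

    drift_amp: float = 3.0e-3         # 1/f drift, SD
    mayer_freq: float = 0.1           # Hz
    mayer_amp: float = 2.4e-3
    mayer_phase_jitter: float = 0.1   # rad / sqrt(sample), random phase walk
    resp_freq: float = 0.25           # Hz
    resp_amp: float = 1.5e-3
    cardiac_freq: float = 1.1         # Hz
    cardiac_amp: float = 1.5e-3
    white_sd: float = 6.0e-3          # OD units
    hbr_noise_scale: float = 0.3
    channel_scale_sigma: float = 0.3

    def validate(self, fs: float) -> None:
        for name in ("drift_amp", "mayer_amp", "resp_amp", "cardiac_amp", "white_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("mayer_freq", "resp_freq", "cardiac_freq"):
            if getattr(self, name) >= fs / 2:
                raise ConfigurationError(f"{name} at or above Nyquist ({fs/2} Hz)")


def scaled_noise(scale: float) -> NoiseSpec:
    """Default noise with all amplitudes multiplied by ``scale``."""
    base = NoiseSpec()
    return NoiseSpec(
        drift_amp=base.drift_amp * scale,
        mayer_amp=base.mayer_amp * scale,
        resp_amp=base.resp_amp * scale,
        cardiac_amp=base.cardiac_amp * scale,
        white_sd=base.white_sd * scale,
    )


def make_schedule(spec: ParadigmSpec, seed: int) -> EventSchedule:
    """Seeded pseudo-random MA/BL schedule for one run.

    Exactly ``reps_per_run/2`` events per condition; each trial occupies
    instruction + task + a rest drawn uniformly from ``rest_range``.
    Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    half = spec.reps_per_run // 2
    labels = np.array([MA] * half + [BL] * half, dtype=object)
    rng.shuffle(labels)
    rests = rng.uniform(spec.rest_range[0], spec.rest_range[1], size=spec.reps_per_run)
    onsets = np.empty(spec.reps_per_run)
    t = spec.lead_rest
    for i in range(spec.reps_per_run):
        t += spec.instruction_duration
        onsets[i] = t
        t += spec.task_duration + rests[i]
    run_length = t + spec.trail_rest
    return EventSchedule(
        onsets=onsets, labels=labels, duration=spec.task_duration, run_length=run_length
    )


def hrf(t: np.ndarray, params: Optional[HRFParams] = None) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit peak amplitude.

    Zero at t <= 0, a single positive peak near ``peak_delay`` followed by an
    undershoot, decaying to zero for large t.
    """
    p = params or HRFParams()
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t > 0
    tp = t[pos]

    def gamma_pdf(x: np.ndarray, shape: float, scale: float) -> np.ndarray:
        from scipy.stats import gamma as gamma_dist

        return gamma_dist.pdf(x, a=shape, scale=scale)

    # shape = delay/disp + 1 puts the gamma mode exactly at the delay
    peak = gamma_pdf(tp, p.peak_delay / p.peak_disp + 1.0, p.peak_disp)
    under = gamma_pdf(tp, p.undershoot_delay / p.undershoot_disp + 1.0, p.undershoot_disp)
    h = peak - under / p.ratio
    out[pos] = h
    m = out.max()
    if m > 0:
        out = out / m
    return out


def _one_over_f(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-SD 1/f noise via spectral shaping of white Gaussian noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(freqs)
    shape[1:] = 1.0 / np.sqrt(freqs[1:])
    series = np.fft.irfft(spec * shape, n=n)
    sd = series.std()
    return series / sd if sd > 0 else series


def _oscillation(
    n: int, fs: float, freq: float, amp: float, phase_jitter: float, rng: np.random.Generator
) -> np.ndarray:
    phase0 = rng.uniform(0, 2 * np.pi)
    if phase_jitter > 0:
        walk = np.cumsum(rng.standard_normal(n)) * phase_jitter
    else:
        walk = 0.0
    t = np.arange(n) / fs
    return amp * np.sqrt(2.0) * np.sin(2 * np.pi * freq * t + phase0 + walk)


def _run_noise(
    n: int, fs: float, noise: NoiseSpec, n_channels: int, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """(hbo_noise, hbr_noise) arrays, (channels, samples), mmol/L."""
    hbo = np.zeros((n_channels, n))
    for c in range(n_channels):
        scale = float(np.exp(rng.normal(0.0, noise.channel_scale_sigma)))
        comp = noise.drift_amp * _one_over_f(n, rng)
        comp = comp + _oscillation(n, fs, noise.mayer_freq, noise.mayer_amp, noise.mayer_phase_jitter, rng)
        comp = comp + _oscillation(n, fs, noise.resp_freq, noise.resp_amp, 0.0, rng)
        comp = comp + _oscillation(n, fs, noise.cardiac_freq, noise.cardiac_amp, 0.0, rng)
        hbo[c] = scale * comp
    hbr = np.zeros_like(hbo)
    for c in range(n_channels):
        scale = float(np.exp(rng.normal(0.0, noise.channel_scale_sigma)))
        comp = noise.drift_amp * _one_over_f(n, rng)
        comp = comp + _oscillation(n, fs, noise.mayer_freq, noise.mayer_amp, noise.mayer_phase_jitter, rng)
        comp = comp + _oscillation(n, fs, noise.resp_freq, noise.resp_amp, 0.0, rng)
        comp = comp + _oscillation(n, fs, noise.cardiac_freq, noise.cardiac_amp, 0.0, rng)
        hbr[c] = noise.hbr_noise_scale * scale * comp
    return hbo, hbr


@dataclass
class SimulatedRun:
    raw: RawRecording
    schedule: EventSchedule
    truth: HemoSeries          # clean response + physiological noise
    clean: HemoSeries          # pre-noise condition responses only


@dataclass
class SimulatedSubject:
    runs: List[SimulatedRun]
    paradigm: str
    seed: int

    @property
    def montage(self) -> Montage:
        return self.runs[0].raw.montage


def _condition_response(
    schedule: EventSchedule,
    effect: EffectSpec,
    n: int,
    fs: float,
    trial_factors: np.ndarray,
    labels_amp: Dict[str, np.ndarray],
) -> np.ndarray:
    """(channels, samples) response: HRF-convolved per-trial boxcars."""
    kernel_t = np.arange(0, 40.0, 1.0 / fs)
    kernel = hrf(kernel_t, effect.hrf_params)
    n_ch = labels_amp[MA].size
    drive = np.zeros((n_ch, n))
    for i, (onset, label) in enumerate(zip(schedule.onsets, schedule.labels)):
        start = int(round(onset * fs))
        stop = min(int(round((onset + schedule.duration) * fs)), n)
        if start >= n:
            continue
        box = np.zeros(n)
        box[start:stop] = 1.0
        resp = np.convolve(box, kernel)[:n] / fs   # scale-invariant in fs
        drive += trial_factors[i] * np.outer(labels_amp[label], resp)
    # normalize so a unit amplitude yields a unit-peak single-trial response
    single = np.convolve(
        np.ones(int(round(schedule.duration * fs))), kernel
    )[: int(40 * fs)] / fs
    peak = single.max()
    if peak > 0:
        drive /= peak
    return drive


def generate_subject(
    paradigm: ParadigmSpec,
    effect: EffectSpec,
    noise: NoiseSpec,
    montage: Optional[Montage] = None,
    seed: int = 0,
    coeffs: Optional[OpticalCoefficients] = None,
) -> SimulatedSubject:
    """Generate all runs for one synthetic subject.

    Returns raw dual-wavelength intensities per run (via the forward optical
    model) together with the event schedules and the ground-truth
    concentration series, fully determined by ``seed``.
    """
    montage = montage or default_montage()
    coeffs = coeffs or default_coefficients()
    if montage.n_channels < 1:
        raise ConfigurationError("montage must have at least one channel")
    if effect.n_channels != montage.n_channels:
        raise ConfigurationError("effect amplitudes do not match montage channel count")
    noise.validate(paradigm.fs)

    root = np.random.SeedSequence(seed)
    runs: List[SimulatedRun] = []
    for run_ss in root.spawn(paradigm.n_runs_per_paradigm):
        sched_ss, jitter_ss, noise_ss, od_ss = run_ss.spawn(4)
        schedule = make_schedule(paradigm, seed=int(sched_ss.generate_state(1)[0] % 2**31))
        fs = paradigm.fs
        n = int(round(schedule.run_length * fs))

        jit_rng = np.random.default_rng(jitter_ss)
        cv = effect.trial_amplitude_jitter
        if cv > 0:
            # log-normal with unit mean and the requested coefficient of variation
            sigma = np.sqrt(np.log1p(cv**2))
            factors = jit_rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=schedule.n_events)
        else:
            factors = np.ones(schedule.n_events)

        hbo_clean = _condition_response(schedule, effect, n, fs, factors, effect.hbo_amp)
        hbr_clean = _condition_response(schedule, effect, n, fs, factors, effect.hbr_amp)
        clean = HemoSeries(hbo=hbo_clean, hbr=hbr_clean, fs=fs, channel_names=montage.channel_names)

        noise_rng = np.random.default_rng(noise_ss)
        hbo_noise, hbr_noise = _run_noise(n, fs, noise, montage.n_channels, noise_rng)
        truth = HemoSeries(
            hbo=hbo_clean + hbo_noise,
            hbr=hbr_clean + hbr_noise,
            fs=fs,
            channel_names=montage.channel_names,
        )

        od_rng = np.random.default_rng(od_ss)
        od_noise = (
            od_rng.standard_normal((montage.n_channels, 2, n)) * noise.white_sd
            if noise.white_sd > 0
            else None
        )
        raw = forward_model(truth, coeffs, I0=1.0, od_noise=od_noise, montage=montage)
        runs.append(SimulatedRun(raw=raw, schedule=schedule, truth=truth, clean=clean))
    return SimulatedSubject(runs=runs, paradigm=paradigm.paradigm, seed=seed)
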