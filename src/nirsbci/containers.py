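"""Shared in-memory containers for the analysis pipeline.

Conventions used throughout the package:

* intensity / optical-density arrays are shaped ``(n_channels, n_wavelengths,
  n_samples)`` with the wavelength axis ordered as in the montage coefficients;
* concentration arrays are shaped ``(n_channels, n_samples)`` per chromophore,
  in mmol/L;
* epochs are shaped ``(n_trials, n_channels, n_samples)`` per chromophore;
* class labels are the strings ``"MA"`` (mental arithmetic, the positive
  class everywhere) and ``"BL"`` (baseline task).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np

MA = "MA"
BL = "BL"
CHROMOPHORES = ("hbo", "hbr")


class DataError(ValueError):
    """Raised for malformed or physically impossible data."""


class ConfigurationError(ValueError):
    """Raised for invalid analysis settings."""


class ProtocolError(RuntimeError):
    """Raised when a cross-validation / fusion protocol contract is broken."""


@dataclass
class EventSchedule:
    """Task onsets and condition labels for one experimental run."""

    onsets: np.ndarray        # seconds, relative to run start
    labels: np.ndarray        # "MA" / "BL" per event
    duration: float           # task duration, seconds (same for all events)
    run_length: float         # total run length, seconds

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = np.asarray(self.labels, dtype=object)
        if self.onsets.shape != self.labels.shape:
            raise DataError("onsets and labels must have matching length")

    @property
    def n_events(self) -> int:
        return self.onsets.size

    def counts(self) -> Dict[str, int]:
        return {lab: int(np.sum(self.labels == lab)) for lab in (MA, BL)}


@dataclass
class RawRecording:
    """Dual-wavelength raw light intensities for one run."""

    intensity: np.ndarray             # (n_channels, n_wavelengths, n_samples)
    wavelengths: Tuple[float, float]  # nm
    fs: float                         # Hz
    channel_names: Tuple[str, ...]
    montage: Optional["object"] = None  # optics.Montage; optional for CSV data

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3:
            raise DataError("intensity must be (channels, wavelengths, samples)")
        if self.intensity.shape[1] != len(self.wavelengths):
            raise DataError("wavelength axis does not match wavelength list")
        if self.intensity.shape[0] != len(self.channel_names):
            raise DataError("channel axis does not match channel names")

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[2]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs


@dataclass
class OpticalDensity:
    """Optical-density change relative to a reference intensity."""

    od: np.ndarray                    # (n_channels, n_wavelengths, n_samples)
    wavelengths: Tuple[float, float]
    fs: float
    channel_names: Tuple[str, ...]


@dataclass
class HemoSeries:
    """Continuous Δ[HbO] / Δ[HbR] time series, mmol/L."""

    hbo: np.ndarray                   # (n_channels, n_samples)
    hbr: np.ndarray                   # (n_channels, n_samples)
    fs: float
    channel_names: Tuple[str, ...]
    units: str = "mmol/L"

    def __post_init__(self) -> None:
        self.hbo = np.atleast_2d(np.asarray(self.hbo, dtype=float))
        self.hbr = np.atleast_2d(np.asarray(self.hbr, dtype=float))
        if self.hbo.shape != self.hbr.shape:
            raise DataError("HbO and HbR must share shape (channels, samples)")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise DataError("non-finite concentration values")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def chromophore(self, name: str) -> np.ndarray:
        if name not in CHROMOPHORES:
            raise ConfigurationError(f"unknown chromophore {name!r}")
        return self.hbo if name == "hbo" else self.hbr

    def copy(self) -> "HemoSeries":
        return replace(self, hbo=self.hbo.copy(), hbr=self.hbr.copy())


@dataclass
class EpochSet:
    """Trials x channels x samples per chromophore, with class labels."""

    data: Dict[str, np.ndarray]       # "hbo"/"hbr" -> (trials, channels, samples)
    labels: np.ndarray                # "MA"/"BL" per trial
    window: Tuple[float, float]       # seconds relative to task onset
    fs: float
    channel_names: Tuple[str, ...]
    paradigm: str = "EO"              # "EO" or "EC"
    onsets: np.ndarray = field(default_factory=lambda: np.array([]))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        for name, arr in self.data.items():
            if arr.shape[0] != self.labels.size:
                raise DataError(f"{name}: trial axis does not match labels")

    @property
    def n_trials(self) -> int:
        return self.labels.size

    @property
    def n_samples(self) -> int:
        return next(iter(self.data.values())).shape[2]

    @property
    def times(self) -> np.ndarray:
        n = self.n_samples
        return self.window[0] + np.arange(n) / self.fs

    def chromophore(self, name: str) -> np.ndarray:
        return self.data[name]

    def class_masks(self) -> Tuple[np.ndarray, np.ndarray]:
        """Boolean masks for (MA, BL) trials."""
        return self.labels == MA, self.labels == BL
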