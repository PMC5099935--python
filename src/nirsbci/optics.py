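"""Continuous-wave NIRS optics: montage geometry and the modified
Beer-Lambert law (MBLL).

The MBLL relates optical-density change at wavelength lambda to chromophore
concentration changes::

    dOD(lambda) = sum_c eps(lambda, c) * dC_c * d * DPF(lambda)

with ``eps`` the molar extinction coefficient, ``d`` the source-detector
separation and ``DPF`` the differential pathlength factor.  With two
wavelengths and the two hemoglobin species this is a 2x2 linear solve per
channel and sample.  Concentrations are expressed in mmol/L throughout.

The forward model (concentrations -> intensities) is the exact inverse and
is what the synthetic-data generator uses, so the full pipeline exercises
the MBLL inversion on every simulated recording.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple, Union

import numpy as np

from .containers import (
    ConfigurationError,
    DataError,
    HemoSeries,
    OpticalDensity,
    RawRecording,
)

__all__ = [
    "Montage",
    "OpticalCoefficients",
    "default_montage",
    "default_coefficients",
    "intensity_to_od",
    "od_to_concentration",
    "forward_model",
]


@dataclass(frozen=True)
class Channel:
    name: str
    source: str
    detector: str
    landmark: Optional[str] = None    # e.g. "Fp1"


@dataclass
class Montage:
    """Source/detector geometry and the channel list derived from it."""

    sources: Dict[str, np.ndarray]
    detectors: Dict[str, np.ndarray]
    channels: Tuple[Channel, ...]
    separation: float = 30.0          # mm, nominal source-detector distance

    def __post_init__(self) -> None:
        for ch in self.channels:
            if ch.source not in self.sources:
                raise ConfigurationError(f"{ch.name}: unknown source {ch.source}")
            if ch.detector not in self.detectors:
                raise ConfigurationError(f"{ch.name}: unknown detector {ch.detector}")

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def channel_names(self) -> Tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)

    def channel_distance(self, ch: Channel) -> float:
        return float(
            np.linalg.norm(self.sources[ch.source] - self.detectors[ch.detector])
        )

    def channel_position(self, ch: Channel) -> np.ndarray:
        return 0.5 * (self.sources[ch.source] + self.detectors[ch.detector])


def default_montage() -> Montage:
    """Ten-channel prefrontal montage: 4 sources, 4 detectors, 30 mm pairs.

    Each hemisphere carries a 30 mm square of two sources and two detectors
    (four channels along its sides) and the two squares are joined by two
    midline-crossing pairs, giving 10 channels, five per hemisphere.
    Channels 4 and 7 sit on the Fp1/Fp2 positions of the 10-10 system.
    """
    s = 30.0
    sources = {
        "S1": np.array([-s - 15.0, 0.0]),
        "S2": np.array([-15.0, s]),
        "S3": np.array([15.0, 0.0]),
        "S4": np.array([s + 15.0, s]),
    }
    detectors = {
        "D1": np.array([-15.0, 0.0]),
        "D2": np.array([-s - 15.0, s]),
        "D3": np.array([s + 15.0, 0.0]),
        "D4": np.array([15.0, s]),
    }
    channels = (
        Channel("ch1", "S1", "D2"),
        Channel("ch2", "S1", "D1"),
        Channel("ch3", "S2", "D2"),
        Channel("ch4", "S2", "D1", landmark="Fp1"),
        Channel("ch5", "S3", "D1"),
        Channel("ch6", "S2", "D4"),
        Channel("ch7", "S3", "D4", landmark="Fp2"),
        Channel("ch8", "S3", "D3"),
        Channel("ch9", "S4", "D4"),
        Channel("ch10", "S4", "D3"),
    )
    return Montage(sources=sources, detectors=detectors, channels=channels, separation=s)


# Molar extinction coefficients (Gratzer/Cope compilation), converted from
# cm^-1 / (mol/L) to mm^-1 / (mmol/L): multiply by 1e-4.
_EXTINCTION_CM_M = {
    # wavelength nm: (HbO, HbR)
    760.0: (586.0, 1548.52),
    850.0: (1058.0, 691.32),
}


@dataclass
class OpticalCoefficients:
    """Wavelengths, extinction matrix, DPF and pathlength for the MBLL.

    ``extinction`` is 2x2 with rows = wavelengths, columns = (HbO, HbR), in
    mm^-1 per mmol/L so that concentrations come out in mmol/L for a
    pathlength given in mm.
    """

    wavelengths: Tuple[float, float] = (760.0, 850.0)
    extinction: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [v * 1e-4 for v in _EXTINCTION_CM_M[760.0]],
                [v * 1e-4 for v in _EXTINCTION_CM_M[850.0]],
            ]
        )
    )
    dpf: Tuple[float, float] = (7.25, 6.38)   # forehead-typical, per wavelength
    pathlength: float = 30.0                  # mm, channel separation

    def __post_init__(self) -> None:
        self.extinction = np.asarray(self.extinction, dtype=float)
        if self.extinction.shape != (2, 2):
            raise ConfigurationError("extinction must be 2x2 (wavelength x chromophore)")
        if not np.all(np.asarray(self.dpf) > 0):
            raise ConfigurationError("DPF must be positive")
        if np.linalg.cond(self.system_matrix()) > 1e12:
            raise ConfigurationError("extinction system is singular or near-singular")

    def system_matrix(self) -> np.ndarray:
        """The 2x2 matrix A with dOD = A @ (dHbO, dHbR)."""
        d = np.asarray(self.dpf) * self.pathlength
        return self.extinction * d[:, None]


def default_coefficients() -> OpticalCoefficients:
    return OpticalCoefficients()


def _reference(intensity: np.ndarray, reference: Union[str, np.ndarray]) -> np.ndarray:
    if isinstance(reference, np.ndarray):
        return reference[..., None]
    if reference == "mean":
        return intensity.mean(axis=-1, keepdims=True)
    if reference == "first-sample":
        return intensity[..., :1]
    raise ConfigurationError(f"unknown reference {reference!r}")


def intensity_to_od(
    raw: RawRecording, reference: Union[str, np.ndarray] = "mean"
) -> OpticalDensity:
    """Convert raw intensities to optical-density change.

    OD(lambda, t) = -log10(I(lambda, t) / I0(lambda)); ``reference`` selects
    I0: the temporal mean (default, the continuous-wave convention), the
    first sample, or an explicit (channels, wavelengths) array.
    """
    I = raw.intensity
    if np.any(I <= 0):
        ch, wl, t = np.argwhere(I <= 0)[0]
        raise DataError(
            f"nonpositive intensity at channel {raw.channel_names[ch]}, "
            f"wavelength index {wl}, sample {t}"
        )
    I0 = _reference(I, reference)
    od = -np.log10(I / I0)
    return OpticalDensity(
        od=od, wavelengths=raw.wavelengths, fs=raw.fs, channel_names=raw.channel_names
    )


def od_to_concentration(
    od: OpticalDensity, coeffs: OpticalCoefficients
) -> HemoSeries:
    """Solve the MBLL per channel and sample for (Δ[HbO], Δ[HbR]) in mmol/L."""
    if od.od.shape[1] != 2:
        raise ConfigurationError("MBLL inversion requires exactly two wavelengths")
    A = coeffs.system_matrix()
    if abs(np.linalg.det(A)) < 1e-300:
        raise ConfigurationError("singular extinction system")
    Ainv = np.linalg.inv(A)
    # (channels, 2, samples) -> concentrations (channels, 2, samples)
    conc = np.einsum("ij,cjt->cit", Ainv, od.od)
    return HemoSeries(
        hbo=conc[:, 0, :], hbr=conc[:, 1, :], fs=od.fs, channel_names=od.channel_names
    )


def forward_model(
    hemo: HemoSeries,
    coeffs: OpticalCoefficients,
    I0: float = 1.0,
    od_noise: Optional[np.ndarray] = None,
    montage: Optional[Montage] = None,
) -> RawRecording:
    """Map concentrations to dual-wavelength raw intensities (simulator side).

    The exact inverse of ``intensity_to_od`` + ``od_to_concentration`` when
    the inversion uses the same constant reference I0.  ``od_noise`` (same
    shape as the OD array) models measurement noise added in OD space.
    """
    A = coeffs.system_matrix()
    conc = np.stack([hemo.hbo, hemo.hbr], axis=1)          # (ch, 2, t)
    od = np.einsum("ij,cjt->cit", A, conc)
    if od_noise is not None:
        od = od + od_noise
    intensity = I0 * 10.0 ** (-od)
    return RawRecording(
        intensity=intensity,
        wavelengths=coeffs.wavelengths,
        fs=hemo.fs,
        channel_names=hemo.channel_names,
        montage=montage,
    )
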