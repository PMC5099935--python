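import numpy as np
import pytest

from nirsbci.containers import BL, MA, EpochSet, EventSchedule
from nirsbci.optics import default_coefficients, default_montage
from nirsbci.simulate import ParadigmSpec


@pytest.fixture(scope="session")
def montage():
    return default_montage()


@pytest.fixture(scope="session")
def coeffs():
    return default_coefficients()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def paradigm_ec():
    return ParadigmSpec(paradigm="EC")


def build_epochs(
    n_ma=10,
    n_bl=10,
    n_channels=4,
    window=(-8.0, 25.0),
    fs=15.6,
    ma_course=None,
    bl_course=None,
    noise_sd=0.0,
    seed=0,
    paradigm="EO",
):
    """Construct an EpochSet from explicit per-class time courses.

    ``ma_course``/``bl_course``: callables t -> (n_channels,) or (n_channels,
    n_samples) arrays added to every trial of that class.
    """
    rng = np.random.default_rng(seed)
    n_samp = int(round((window[1] - window[0]) * fs))
    t = window[0] + np.arange(n_samp) / fs
    labels = np.array([MA] * n_ma + [BL] * n_bl, dtype=object)
    data = {}
    for chromo in ("hbo", "hbr"):
        arr = noise_sd * rng.standard_normal((n_ma + n_bl, n_channels, n_samp))
        if ma_course is not None:
            arr[:n_ma] += ma_course(t)
        if bl_course is not None:
            arr[n_ma:] += bl_course(t)
        data[chromo] = arr
    return EpochSet(
        data=data,
        labels=labels,
        window=window,
        fs=fs,
        channel_names=tuple(f"ch{i + 1}" for i in range(n_channels)),
        paradigm=paradigm,
        onsets=np.arange(n_ma + n_bl, dtype=float) * 40.0 + 75.0,
    )


@pytest.fixture
def epochs_flat():
    """Featureless epochs: pure noise, no class effect."""
    return build_epochs(noise_sd=1.0, seed=3)
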