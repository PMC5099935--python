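"""File formats: the package CSV dialects and SNIRF containers.

CSV dialects (human-inspectable, full-precision, bit-exact round-trip):

* raw intensity: comment header (``# fs_hz=...``, ``# wavelengths_nm=...``),
  then ``time_s`` followed by one column per channel and wavelength named
  ``<ch>_<wavelength>nm``;
* events: ``onset_s, duration_s, label`` plus ``# run_length_s=...``;
* concentrations: ``time_s`` then ``<ch>_hbo`` and ``<ch>_hbr`` columns;
* epochs: a directory with ``manifest.csv`` (trial, label, onset_s,
  paradigm) and one long-format CSV per chromophore.

SNIRF (the community HDF5 container for fNIRS) is supported for raw
intensities with probe geometry and stimulus blocks, written and read with
h5py.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Optional, Tuple

import h5py
import numpy as np
import pandas as pd

from .containers import (
    BL,
    MA,
    DataError,
    EpochSet,
    EventSchedule,
    HemoSeries,
    RawRecording,
)
logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- CSV dialect

def write_recording_csv(raw: RawRecording, path: Path) -> None:
    path = Path(path)
    cols = {"time_s": raw.times}
    for c, ch in enumerate(raw.channel_names):
        for w, wl in enumerate(raw.wavelengths):
            cols[f"{ch}_{wl:g}nm"] = raw.intensity[c, w, :]
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        fh.write(f"# nirsbci raw intensity\n# fs_hz={float(raw.fs)!r}\n")
        fh.write(f"# wavelengths_nm={','.join(f'{w:g}' for w in raw.wavelengths)}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_recording_csv(path: Path) -> RawRecording:
    path = Path(path)
    meta = _read_comment_header(path)
    try:
        fs = float(meta["fs_hz"])
        wavelengths = tuple(float(w) for w in meta["wavelengths_nm"].split(","))
    except KeyError as exc:
        raise DataError(f"{path}: missing header key {exc}") from exc
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    channels = []
    for col in df.columns:
        if col == "time_s":
            continue
        ch = col.rsplit("_", 1)[0]
        if ch not in channels:
            channels.append(ch)
    intensity = np.empty((len(channels), len(wavelengths), len(df)))
    for c, ch in enumerate(channels):
        for w, wl in enumerate(wavelengths):
            col = f"{ch}_{wl:g}nm"
            if col not in df:
                raise DataError(f"{path}: missing column {col}")
            intensity[c, w, :] = df[col].to_numpy()
    return RawRecording(
        intensity=intensity, wavelengths=wavelengths, fs=fs,
        channel_names=tuple(channels),
    )


def write_events_csv(schedule: EventSchedule, path: Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "onset_s": schedule.onsets,
            "duration_s": np.full(schedule.n_events, schedule.duration),
            "label": schedule.labels,
        }
    )
    with path.open("w") as fh:
        fh.write(f"# run_length_s={float(schedule.run_length)!r}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_events_csv(path: Path) -> EventSchedule:
    path = Path(path)
    meta = _read_comment_header(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    duration = float(df["duration_s"].iloc[0]) if len(df) else 0.0
    return EventSchedule(
        onsets=df["onset_s"].to_numpy(dtype=float),
        labels=df["label"].to_numpy(dtype=object),
        duration=duration,
        run_length=float(meta.get("run_length_s", np.inf)),
    )


def write_hemo_csv(hemo: HemoSeries, path: Path) -> None:
    path = Path(path)
    cols = {"time_s": hemo.times}
    for c, ch in enumerate(hemo.channel_names):
        cols[f"{ch}_hbo"] = hemo.hbo[c]
        cols[f"{ch}_hbr"] = hemo.hbr[c]
    with path.open("w") as fh:
        fh.write(f"# nirsbci concentrations mmol/L\n# fs_hz={float(hemo.fs)!r}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format=_FLOAT_FMT)


def read_hemo_csv(path: Path) -> HemoSeries:
    path = Path(path)
    meta = _read_comment_header(path)
    fs = float(meta["fs_hz"])
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    channels = []
    for col in df.columns:
        if col.endswith("_hbo"):
            channels.append(col[:-4])
    hbo = np.stack([df[f"{ch}_hbo"].to_numpy() for ch in channels])
    hbr = np.stack([df[f"{ch}_hbr"].to_numpy() for ch in channels])
    return HemoSeries(hbo=hbo, hbr=hbr, fs=fs, channel_names=tuple(channels))


def _read_comment_header(path: Path) -> Dict[str, str]:
    meta: Dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    return meta


# ------------------------------------------------------------------- epochs

def write_epochs_dir(epochs: EpochSet, directory: Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = pd.DataFrame(
        {
            "trial": np.arange(epochs.n_trials),
            "label": epochs.labels,
            "onset_s": epochs.onsets if epochs.onsets.size else np.nan,
            "paradigm": epochs.paradigm,
        }
    )
    with (directory / "manifest.csv").open("w") as fh:
        fh.write(
            f"# window_s={float(epochs.window[0])!r},{float(epochs.window[1])!r}\n"
            f"# fs_hz={float(epochs.fs)!r}\n"
        )
        manifest.to_csv(fh, index=False, float_format=_FLOAT_FMT)
    t = epochs.times
    for chromo, arr in epochs.data.items():
        rows = {
            "trial": np.repeat(np.arange(epochs.n_trials), t.size),
            "time_s": np.tile(t, epochs.n_trials),
        }
        for c, ch in enumerate(epochs.channel_names):
            rows[ch] = arr[:, c, :].ravel()
        pd.DataFrame(rows).to_csv(
            directory / f"{chromo}.csv", index=False, float_format=_FLOAT_FMT
        )


def read_epochs_dir(directory: Path) -> EpochSet:
    directory = Path(directory)
    meta = _read_comment_header(directory / "manifest.csv")
    window = tuple(float(x) for x in meta["window_s"].split(","))
    fs = float(meta["fs_hz"])
    manifest = pd.read_csv(directory / "manifest.csv", comment="#", float_precision="round_trip")
    data = {}
    channel_names: Tuple[str, ...] = ()
    for chromo in ("hbo", "hbr"):
        df = pd.read_csv(directory / f"{chromo}.csv", float_precision="round_trip")
        channel_names = tuple(c for c in df.columns if c not in ("trial", "time_s"))
        n_trials = int(df["trial"].max()) + 1 if len(df) else 0
        n_samp = len(df) // max(n_trials, 1)
        arr = np.empty((n_trials, len(channel_names), n_samp))
        for c, ch in enumerate(channel_names):
            arr[:, c, :] = df[ch].to_numpy().reshape(n_trials, n_samp)
        data[chromo] = arr
    return EpochSet(
        data=data,
        labels=manifest["label"].to_numpy(dtype=object),
        window=(window[0], window[1]),
        fs=fs,
        channel_names=channel_names,
        paradigm=str(manifest["paradigm"].iloc[0]) if len(manifest) else "EO",
        onsets=manifest["onset_s"].to_numpy(dtype=float),
    )


# -------------------------------------------------------------------- SNIRF

def write_snirf(
    raw: RawRecording, path: Path, schedule: Optional[EventSchedule] = None
) -> None:
    """Write a raw-intensity SNIRF file (one data block, CW amplitude)."""
    path = Path(path)
    montage = raw.montage
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        meta = nirs.create_group("metaDataTags")
        for k, v in {
            "SubjectID": "synthetic",
            "MeasurementDate": "unknown",
            "MeasurementTime": "unknown",
            "LengthUnit": "mm",
            "TimeUnit": "s",
            "FrequencyUnit": "Hz",
        }.items():
            meta.create_dataset(k, data=v)
        data = nirs.create_group("data1")
        n_meas = raw.n_channels * len(raw.wavelengths)
        series = np.empty((raw.n_samples, n_meas))
        col = 0
        src_names = list(montage.sources) if montage else []
        det_names = list(montage.detectors) if montage else []
        for c in range(raw.n_channels):
            for w in range(len(raw.wavelengths)):
                series[:, col] = raw.intensity[c, w, :]
                ml = data.create_group(f"measurementList{col + 1}")
                if montage is not None:
                    ch = montage.channels[c]
                    ml.create_dataset("sourceIndex", data=src_names.index(ch.source) + 1)
                    ml.create_dataset("detectorIndex", data=det_names.index(ch.detector) + 1)
                else:
                    ml.create_dataset("sourceIndex", data=c + 1)
                    ml.create_dataset("detectorIndex", data=c + 1)
                ml.create_dataset("wavelengthIndex", data=w + 1)
                ml.create_dataset("dataType", data=1)       # CW amplitude
                ml.create_dataset("dataTypeIndex", data=1)
                col += 1
        data.create_dataset("dataTimeSeries", data=series)
        data.create_dataset("time", data=raw.times)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.asarray(raw.wavelengths, dtype=float))
        if montage is not None:
            probe.create_dataset(
                "sourcePos2D", data=np.stack([montage.sources[s] for s in src_names])
            )
            probe.create_dataset(
                "detectorPos2D", data=np.stack([montage.detectors[d] for d in det_names])
            )
            probe.create_dataset("sourceLabels", data=np.array(src_names, dtype="S"))
            probe.create_dataset("detectorLabels", data=np.array(det_names, dtype="S"))
        if schedule is not None:
            for i, label in enumerate((MA, BL)):
                mask = schedule.labels == label
                stim = nirs.create_group(f"stim{i + 1}")
                stim.create_dataset("name", data=label)
                block = np.column_stack(
                    [
                        schedule.onsets[mask],
                        np.full(mask.sum(), schedule.duration),
                        np.ones(mask.sum()),
                    ]
                )
                stim.create_dataset("data", data=block)


def read_snirf(path: Path) -> Tuple[RawRecording, Optional[EventSchedule]]:
    """Read a raw-intensity SNIRF file written by this package (or similar).

    A missing stimulus block yields ``schedule=None`` with a warning.
    """
    path = Path(path)
    with h5py.File(path, "r") as f:
        if "nirs" in f:
            nirs = f["nirs"]
        elif "nirs1" in f:
            nirs = f["nirs1"]
        else:
            raise DataError(f"{path}: no /nirs group")
        data = nirs["data1"]
        series = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        if time.size < 2:
            raise DataError(f"{path}: time vector too short")
        fs = float(1.0 / np.median(np.diff(time)))
        wavelengths = tuple(float(w) for w in np.asarray(nirs["probe"]["wavelengths"]))
        mls = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        pairs = []
        for k in mls:
            ml = data[k]
            pairs.append(
                (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]),
                 int(ml["wavelengthIndex"][()]))
            )
        chan_pairs = []
        for s, d, _ in pairs:
            if (s, d) not in chan_pairs:
                chan_pairs.append((s, d))
        n_ch = len(chan_pairs)
        intensity = np.empty((n_ch, len(wavelengths), series.shape[0]))
        for col, (s, d, w) in enumerate(pairs):
            intensity[chan_pairs.index((s, d)), w - 1, :] = series[:, col]
        channel_names = tuple(f"S{s}-D{d}" for s, d in chan_pairs)
        schedule = None
        stim_keys = [k for k in nirs.keys() if k.startswith("stim")]
        if stim_keys:
            onsets, labels, durations = [], [], []
            for k in stim_keys:
                stim = nirs[k]
                name = stim["name"][()]
                if isinstance(name, bytes):
                    name = name.decode()
                block = np.atleast_2d(np.asarray(stim["data"]))
                for row in block:
                    onsets.append(float(row[0]))
                    durations.append(float(row[1]))
                    labels.append(name)
            order = np.argsort(onsets)
            schedule = EventSchedule(
                onsets=np.asarray(onsets)[order],
                labels=np.asarray(labels, dtype=object)[order],
                duration=durations[0] if durations else 0.0,
                run_length=float(time[-1] + 1.0 / fs),
            )
        else:
            logger.warning("%s: no stimulus block; event markers empty", path)
    raw = RawRecording(
        intensity=intensity, wavelengths=wavelengths, fs=fs, channel_names=channel_names
    )
    return raw, schedule
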