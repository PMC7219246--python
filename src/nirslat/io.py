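"""Readers and writers: SNIRF (HDF5) containers and long-format text.

The SNIRF writer emits a minimal standards-shaped container:
``/formatVersion``, ``/nirs/data1`` with ``dataTimeSeries`` (T x M),
``time``, and one ``measurementListN`` group per column carrying
``sourceIndex``, ``dataTypeLabel`` ("HbO"/"HbR") and processed dataType
99999; events go to ``/nirs/stimN`` groups (name ``<hand>_<condition>``,
data rows ``[onset, duration, value]``); montage metadata lives under
``/nirs/metaDataTags``.

The text format is a long-format delimited table with columns
``time_s, channel, chromophore, value`` plus a ``<stem>.events.csv``
sidecar (``onset_s, hand, condition``).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .core import (
    CHROMOPHORES,
    ChromophoreSeries,
    Event,
    EventLog,
    Montage,
    Recording,
    default_montage,
)

__all__ = [
    "read_snirf",
    "write_snirf",
    "read_text",
    "write_text",
    "read_recording",
    "write_recording",
    "write_decisions",
    "read_decisions",
]

_SNIRF_EXT = {".snirf", ".h5", ".hdf5"}
_TEXT_EXT = {".csv", ".tsv", ".txt"}


def write_snirf(recording: Recording, path) -> None:
    path = Path(path)
    keys = sorted(recording.series)
    data = np.column_stack([recording.series[k].values for k in keys])
    time = np.arange(recording.n_samples) / recording.fs
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=time)
        for m, (ch, chrom) in enumerate(keys, start=1):
            ml = d1.create_group(f"measurementList{m}")
            ml.create_dataset("sourceIndex", data=ch)
            ml.create_dataset("detectorIndex", data=ch)
            ml.create_dataset("wavelengthIndex", data=1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=chrom)
        groups: dict[str, list[float]] = {}
        for ev in recording.events:
            groups.setdefault(f"{ev.hand}_{ev.condition}", []).append(ev.onset)
        for s, (name, onsets) in enumerate(sorted(groups.items()), start=1):
            stim = nirs.create_group(f"stim{s}")
            stim.create_dataset("name", data=name)
            rows = [[o, 15.0, 1.0] for o in onsets]
            stim.create_dataset("data", data=np.array(rows))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset(
            "montage",
            data=json.dumps(
                {
                    "channel_ids": list(recording.montage.channel_ids),
                    "hemisphere": {
                        str(k): v for k, v in recording.montage.hemisphere.items()
                    },
                    "pair_map": {
                        str(k): v for k, v in recording.montage.pair_map.items()
                    },
                }
            ),
        )
        meta.create_dataset("LengthUnit", data="s")


def _h5_str(ds) -> str:
    v = ds[()]
    return v.decode() if isinstance(v, bytes) else str(v)


def read_snirf(path) -> Recording:
    path = Path(path)
    with h5py.File(path, "r") as f:
        try:
            d1 = f["nirs/data1"]
            data = np.asarray(d1["dataTimeSeries"])
            time = np.asarray(d1["time"])
        except KeyError as exc:
            raise ValueError(f"malformed SNIRF container {path}: /nirs/data1 "
                             f"({exc})") from exc
        if len(time) < 2:
            raise ValueError(f"malformed SNIRF container {path}: time axis too short")
        fs = 1.0 / float(time[1] - time[0])
        keys = []
        for m in range(1, data.shape[1] + 1):
            try:
                ml = d1[f"measurementList{m}"]
                ch = int(np.asarray(ml["sourceIndex"]))
                chrom = _h5_str(ml["dataTypeLabel"])
            except KeyError as exc:
                raise ValueError(
                    f"malformed SNIRF container {path}: "
                    f"/nirs/data1/measurementList{m} ({exc})"
                ) from exc
            keys.append((ch, chrom))
        events = []
        s = 1
        while f"stim{s}" in f["nirs"]:
            stim = f[f"nirs/stim{s}"]
            name = _h5_str(stim["name"])
            hand, condition = name.split("_", 1)
            for row in np.atleast_2d(np.asarray(stim["data"])):
                events.append(Event(onset=float(row[0]), hand=hand, condition=condition))
            s += 1
        montage = default_montage()
        if "metaDataTags" in f["nirs"] and "montage" in f["nirs/metaDataTags"]:
            spec = json.loads(_h5_str(f["nirs/metaDataTags/montage"]))
            montage = Montage(
                channel_ids=tuple(spec["channel_ids"]),
                hemisphere={int(k): v for k, v in spec["hemisphere"].items()},
                pair_map={int(k): v for k, v in spec["pair_map"].items()},
            )
    series = {
        key: ChromophoreSeries(key[0], key[1], fs, data[:, i])
        for i, key in enumerate(keys)
        if key[1] in CHROMOPHORES  # ignore auxiliary columns (e.g. HbT)
    }
    _check_complete(series)
    events.sort(key=lambda e: e.onset)
    return Recording(montage=montage, series=series, events=EventLog(events))


def _check_complete(series: dict) -> None:
    channels = {ch for ch, _ in series}
    for ch in channels:
        for chrom in CHROMOPHORES:
            if (ch, chrom) not in series:
                raise ValueError(f"channel {ch} is missing its {chrom} series")


def write_text(recording: Recording, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    time = np.arange(recording.n_samples) / recording.fs
    frames = []
    for (ch, chrom), s in sorted(recording.series.items()):
        frames.append(
            pd.DataFrame(
                {"time_s": time, "channel": ch, "chromophore": chrom,
                 "value": s.values}
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep=sep, index=False)
    ev = pd.DataFrame(
        [
            {"onset_s": e.onset, "hand": e.hand, "condition": e.condition}
            for e in recording.events
        ],
        columns=["onset_s", "hand", "condition"],
    )
    ev.to_csv(_events_path(path), sep=sep, index=False)


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events" + path.suffix)


def read_text(path, montage: Montage | None = None) -> Recording:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    required = {"time_s", "channel", "chromophore", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    times = np.sort(df["time_s"].unique())
    fs = 1.0 / float(times[1] - times[0])
    series = {}
    for (ch, chrom), g in df.groupby(["channel", "chromophore"]):
        g = g.sort_values("time_s")
        series[(int(ch), str(chrom))] = ChromophoreSeries(
            int(ch), str(chrom), fs, g["value"].to_numpy()
        )
    _check_complete(series)
    events = []
    ev_path = _events_path(path)
    if ev_path.exists():
        ev = pd.read_csv(ev_path, sep=sep)
        events = [
            Event(onset=float(r.onset_s), hand=str(r.hand), condition=str(r.condition))
            for r in ev.itertuples()
        ]
    if montage is None:
        n = len({ch for ch, _ in series})
        montage = default_montage(n if n % 2 == 0 else n + 1)
        if set(montage.channel_ids) != {ch for ch, _ in series}:
            raise ValueError("cannot infer montage from channel ids; pass one")
    return Recording(montage=montage, series=series, events=EventLog(events))


def read_recording(path, montage: Montage | None = None) -> Recording:
    path = Path(path)
    if path.suffix in _SNIRF_EXT:
        return read_snirf(path)
    if path.suffix in _TEXT_EXT:
        return read_text(path, montage)
    raise ValueError(f"unrecognized recording format: {path.suffix!r}")


def write_recording(recording: Recording, path) -> None:
    path = Path(path)
    if path.suffix in _SNIRF_EXT:
        write_snirf(recording, path)
    elif path.suffix in _TEXT_EXT:
        write_text(recording, path)
    else:
        raise ValueError(f"unrecognized recording format: {path.suffix!r}")


def write_decisions(rows: list[dict], path) -> None:
    """Decisions table: trial_id, true_hand, condition, CR, CL, label."""
    cols = ["trial_id", "true_hand", "condition", "CR", "CL", "label"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_decisions(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"true_hand", "CR", "CL", "label"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df
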