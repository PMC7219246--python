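"""Domain types, montage model, and timing conventions.

Conventions used throughout the package:

* time windows are half-open ``[a, b)`` seconds; sample ``k`` covers
  ``[k/fs, (k+1)/fs)``, so the sample index of a time ``t`` is
  ``floor(t * fs)``;
* a trial lasts 35 s — 5 s preparation, 15 s task, 15 s rest — and its
  sample count is ``round(35 * fs)`` with round-half-even;
* trial time is relative to trial start, i.e. the command arrives at
  t = 5 s.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

__all__ = [
    "HBO",
    "HBR",
    "CHROMOPHORES",
    "DEFAULT_FS",
    "TRIAL_PRE_S",
    "TRIAL_TASK_S",
    "TRIAL_REST_S",
    "TRIAL_DURATION_S",
    "TASK_WINDOW",
    "Montage",
    "Event",
    "EventLog",
    "ChromophoreSeries",
    "Recording",
    "Trial",
    "default_montage",
    "sample_index",
    "window_slice",
    "trial_n_samples",
    "slice_trials",
]

HBO = "HbO"
HBR = "HbR"
CHROMOPHORES = (HBO, HBR)

DEFAULT_FS = 7.8125
TRIAL_PRE_S = 5.0
TRIAL_TASK_S = 15.0
TRIAL_REST_S = 15.0
TRIAL_DURATION_S = TRIAL_PRE_S + TRIAL_TASK_S + TRIAL_REST_S
#: default averaging window, relative to trial start (command at t=5 s)
TASK_WINDOW = (5.0, 20.0)

HANDS = ("left", "right")
CONDITIONS = ("execution", "imagery")


def sample_index(t: float, fs: float) -> int:
    """Sample index covering time ``t`` (floor convention)."""
    return int(np.floor(t * fs))


def window_slice(window: tuple[float, float], fs: float) -> slice:
    """Slice of sample indices covered by the half-open window ``[a, b)`` s."""
    a, b = window
    if b <= a:
        raise ValueError(f"empty window [{a}, {b})")
    return slice(sample_index(a, fs), sample_index(b, fs))


def trial_n_samples(fs: float, duration: float = TRIAL_DURATION_S) -> int:
    """Number of samples in a trial: round(duration * fs), round-half-even."""
    return int(np.round(duration * fs))


@dataclass(frozen=True)
class Montage:
    """Channel geometry: hemisphere labels and the symmetric-pair bijection.

    Parameters
    ----------
    channel_ids
        All channel identifiers (1-based).
    hemisphere
        Map channel id -> ``"L"`` or ``"R"``.
    pair_map
        Map from a left-hemisphere channel id to its symmetric
        right-hemisphere partner.  Must be a bijection.
    optodes
        Optional map channel id -> (source label, detector label,
        separation in cm).  Carried as metadata only.
    """

    channel_ids: tuple[int, ...]
    hemisphere: Mapping[int, str]
    pair_map: Mapping[int, int]
    optodes: Mapping[int, tuple[str, str, float]] | None = None

    def __post_init__(self) -> None:
        ids = set(self.channel_ids)
        if set(self.hemisphere) != ids:
            raise ValueError("every channel must appear in exactly one hemisphere")
        bad = {h for h in self.hemisphere.values() if h not in ("L", "R")}
        if bad:
            raise ValueError(f"unknown hemisphere labels: {bad}")
        rights = list(self.pair_map.values())
        if len(set(rights)) != len(rights):
            raise ValueError("pair_map must be a bijection")
        for lch, rch in self.pair_map.items():
            if self.hemisphere[lch] != "L" or self.hemisphere[rch] != "R":
                raise ValueError(f"pair ({lch}, {rch}) must map L -> R")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def left_channels(self) -> tuple[int, ...]:
        return tuple(c for c in self.channel_ids if self.hemisphere[c] == "L")

    @property
    def right_channels(self) -> tuple[int, ...]:
        return tuple(c for c in self.channel_ids if self.hemisphere[c] == "R")

    @property
    def pairs(self) -> tuple[tuple[int, int], ...]:
        """Symmetric (left, right) pairs sorted by left channel id."""
        return tuple(sorted(self.pair_map.items()))

    def partner(self, channel: int) -> int:
        """Symmetric partner of ``channel`` in the other hemisphere."""
        if channel in self.pair_map:
            return self.pair_map[channel]
        inv = {r: l for l, r in self.pair_map.items()}
        if channel in inv:
            return inv[channel]
        raise KeyError(f"channel {channel} has no symmetric partner")


def default_montage(n_channels: int = 20) -> Montage:
    """The default motor-cortex montage.

    Channels 1..n/2 lie on the left hemisphere, n/2+1..n on the right, and
    the symmetric-pair map is the offset-of-half bijection (so the default
    20-channel montage pairs (2,12), (3,13), (7,17), (8,18), ...).
    """
    if n_channels % 2:
        raise ValueError("default montage needs an even channel count")
    half = n_channels // 2
    ids = tuple(range(1, n_channels + 1))
    hemisphere = {c: ("L" if c <= half else "R") for c in ids}
    pair_map = {c: c + half for c in range(1, half + 1)}
    return Montage(channel_ids=ids, hemisphere=hemisphere, pair_map=pair_map)


@dataclass(frozen=True)
class Event:
    onset: float  # seconds from record start (command time)
    hand: str  # "left" | "right"
    condition: str  # "execution" | "imagery"

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )


@dataclass
class EventLog:
    """Ordered command markers for one recording."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")

    def __iter__(self):
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class ChromophoreSeries:
    """Concentration-change time series for one channel and chromophore."""

    channel_id: int
    chromophore: str
    fs: float
    values: np.ndarray
    units: str = "uM"

    def __post_init__(self) -> None:
        if self.chromophore not in CHROMOPHORES:
            raise ValueError(f"chromophore must be one of {CHROMOPHORES}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite samples")


@dataclass
class Recording:
    """A continuous multi-channel session: series for every (channel,
    chromophore), the montage, and the event log."""

    montage: Montage
    series: dict[tuple[int, str], ChromophoreSeries]
    events: EventLog

    def __post_init__(self) -> None:
        lengths = {len(s.values) for s in self.series.values()}
        rates = {s.fs for s in self.series.values()}
        if len(lengths) > 1 or len(rates) > 1:
            raise ValueError("all series must share fs and length")

    @property
    def fs(self) -> float:
        return next(iter(self.series.values())).fs

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.series.values())).values)

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def get(self, channel: int, chromophore: str) -> ChromophoreSeries:
        try:
            return self.series[(channel, chromophore)]
        except KeyError:
            raise KeyError(
                f"no series for channel {channel} / {chromophore}"
            ) from None

    def validate(self) -> None:
        """Check that every event leaves room for the full 35-s trial."""
        for ev in self.events:
            if ev.onset < TRIAL_PRE_S:
                raise ValueError(f"event at {ev.onset} s has no room for pre-window")
            if ev.onset + TRIAL_TASK_S + TRIAL_REST_S > self.duration:
                raise ValueError(f"event at {ev.onset} s extends past record end")


@dataclass
class Trial:
    """One labeled 35-s epoch, t=0 at 5 s before the command."""

    hand: str
    condition: str
    fs: float
    data: dict[tuple[int, str], np.ndarray]

    def __post_init__(self) -> None:
        n = trial_n_samples(self.fs)
        for key, arr in self.data.items():
            arr = np.asarray(arr, dtype=float)
            if len(arr) != n:
                raise ValueError(
                    f"series {key} has {len(arr)} samples, expected {n}"
                )
            self.data[key] = arr

    @property
    def n_samples(self) -> int:
        return trial_n_samples(self.fs)

    @property
    def channels(self) -> tuple[int, ...]:
        return tuple(sorted({ch for ch, _ in self.data}))

    @property
    def pre_slice(self) -> slice:
        return slice(0, sample_index(TRIAL_PRE_S, self.fs))

    @property
    def task_slice(self) -> slice:
        return slice(
            sample_index(TRIAL_PRE_S, self.fs),
            sample_index(TRIAL_PRE_S + TRIAL_TASK_S, self.fs),
        )

    @property
    def rest_slice(self) -> slice:
        return slice(
            sample_index(TRIAL_PRE_S + TRIAL_TASK_S, self.fs), self.n_samples
        )

    def get(self, channel: int, chromophore: str) -> np.ndarray:
        try:
            return self.data[(channel, chromophore)]
        except KeyError:
            raise KeyError(
                f"trial is missing channel {channel} / {chromophore}"
            ) from None


def slice_trials(recording: Recording) -> list[Trial]:
    """Cut the continuous recording into labeled 35-s trials.

    Trial t=0 corresponds to (event onset - 5 s).  Events whose trial would
    read outside the record are rejected with a warning and skipped.
    """
    fs = recording.fs
    n_trial = trial_n_samples(fs)
    n_total = recording.n_samples
    trials: list[Trial] = []
    for ev in recording.events:
        start = sample_index(ev.onset - TRIAL_PRE_S, fs)
        if start < 0 or start + n_trial > n_total:
            warnings.warn(
                f"event at {ev.onset:.2f} s too close to record edge; skipped",
                stacklevel=2,
            )
            continue
        data = {
            key: s.values[start : start + n_trial].copy()
            for key, s in recording.series.items()
        }
        trials.append(Trial(hand=ev.hand, condition=ev.condition, fs=fs, data=data))
    return trials
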