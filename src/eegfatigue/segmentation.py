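"""Event partitioning and fixed-window segmentation of recordings.

A recording holds one equal-length sample sequence per channel at 256 Hz.
Each session follows the ordered event schedule s1, m1, s2, m2, s3, m3
with fixed durations for every event except s3, which absorbs whatever
remains between the 600-s fixed prefix and the final 120-s m3 probe.
Within each event every channel is cut into consecutive, non-overlapping
2560-sample (10-s) windows; a trailing remainder shorter than one window
is discarded.

All sample indices are 0-based and ranges are half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from eegfatigue.constants import CHANNELS, EVENTS, SAMPLING_RATE, WINDOW_SAMPLES
from eegfatigue.errors import ParseError, PartitionError, ScheduleError

logger = logging.getLogger(__name__)

#: Fixed event durations in seconds; ``None`` marks the variable event.
DEFAULT_DURATIONS: dict[str, int | None] = {
    "s1": 180,
    "m1": 120,
    "s2": 180,
    "m2": 120,
    "s3": None,
    "m3": 120,
}


@dataclass(frozen=True)
class EventSchedule:
    """Ordered (event, duration_s) schedule of one session.

    ``durations["s3"]`` may be ``None``, in which case s3 is variable and
    runs from the end of m2 to the start of m3 (taken from the very end of
    the recording).
    """

    durations: dict[str, int | None] = field(
        default_factory=lambda: dict(DEFAULT_DURATIONS)
    )
    sampling_rate: int = SAMPLING_RATE

    def __post_init__(self) -> None:
        if tuple(self.durations) != EVENTS:
            raise ScheduleError(
                f"events must appear in order {EVENTS}, got {tuple(self.durations)}"
            )
        if self.sampling_rate <= 0:
            raise ScheduleError(f"sampling rate must be positive, got {self.sampling_rate}")
        for event, dur in self.durations.items():
            if dur is None:
                if event != "s3":
                    raise ScheduleError(f"only s3 may have a variable duration ({event})")
                continue
            if dur < 0 or (dur <= 0 and event != "s3"):
                raise ScheduleError(f"non-positive duration for {event}: {dur}")

    @property
    def fixed_prefix_s(self) -> int:
        """Seconds covered by the fixed events before s3 (s1+m1+s2+m2)."""
        return sum(self.durations[e] for e in ("s1", "m1", "s2", "m2"))

    @property
    def min_total_s(self) -> int:
        s3 = self.durations["s3"] or 0
        return self.fixed_prefix_s + s3 + self.durations["m3"]

    @property
    def total_s(self) -> int | None:
        """Total duration, or ``None`` when s3 is variable."""
        if self.durations["s3"] is None:
            return None
        return self.min_total_s

    def with_s3(self, s3_duration_s: int) -> "EventSchedule":
        if s3_duration_s < 0:
            raise ScheduleError(f"s3 duration must be >= 0, got {s3_duration_s}")
        durations = dict(self.durations)
        durations["s3"] = s3_duration_s
        return EventSchedule(durations=durations, sampling_rate=self.sampling_rate)


DEFAULT_SCHEDULE = EventSchedule()


@dataclass
class Recording:
    """One subject-session's per-channel sample sequences at 256 Hz."""

    subject_id: str
    session_index: int
    channels: dict[str, np.ndarray]
    sampling_rate: int = SAMPLING_RATE

    def __post_init__(self) -> None:
        if not self.channels:
            raise ParseError("recording has no channels")
        unknown = [c for c in self.channels if c not in CHANNELS]
        if unknown:
            raise ParseError(f"unknown channel(s) {unknown}; expected subset of {CHANNELS}")
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) != 1:
            raise ParseError(f"channels have unequal lengths: {lengths}")
        self.channels = {
            name: np.asarray(sig, dtype=float) for name, sig in self.channels.items()
        }

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values())))

    @property
    def total_duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)


@dataclass(frozen=True)
class EventRange:
    """Half-open, 0-based sample range of one event."""

    event: str
    start_sample: int
    end_sample: int

    @property
    def n_samples(self) -> int:
        return self.end_sample - self.start_sample


@dataclass(frozen=True)
class Segment:
    """One fixed-length window of one channel within one event."""

    subject_id: str
    session_index: int
    channel: str
    event: str
    window_index: int
    samples: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))


def partition_events(
    recording: Recording, schedule: EventSchedule = DEFAULT_SCHEDULE
) -> list[EventRange]:
    """Partition a recording into the six ordered event ranges.

    With the default schedule, s3 is variable: it covers everything between
    the 600-s fixed prefix and the final 120-s m3 window.  A recording
    shorter than prefix + m3 is rejected; an exactly-720-s recording yields
    an empty (but present) s3 range, which is logged.
    """
    fs = recording.sampling_rate
    if fs != schedule.sampling_rate:
        raise PartitionError(
            f"recording sampling rate {fs} != schedule rate {schedule.sampling_rate}"
        )
    n = recording.n_samples

    if schedule.durations["s3"] is None:
        min_samples = (schedule.fixed_prefix_s + schedule.durations["m3"]) * fs
        if n < min_samples:
            raise PartitionError(
                f"recording has {n} samples ({n / fs:.1f} s); needs at least "
                f"{min_samples} ({min_samples / fs:.0f} s) for the fixed events"
            )
        s3_samples = n - min_samples
    else:
        expected = schedule.min_total_s * fs
        if n != expected:
            raise PartitionError(
                f"recording has {n} samples but the fixed schedule implies {expected}"
            )
        s3_samples = schedule.durations["s3"] * fs

    ranges: list[EventRange] = []
    cursor = 0
    for event in EVENTS:
        length = s3_samples if event == "s3" else schedule.durations[event] * fs
        ranges.append(EventRange(event, cursor, cursor + length))
        cursor += length
    if s3_samples == 0:
        logger.warning(
            "recording %s/s%d: s3 range is empty (total duration equals the fixed events)",
            recording.subject_id,
            recording.session_index,
        )
    assert cursor == n
    return ranges


def segment_event(samples: np.ndarray, window: int = WINDOW_SAMPLES) -> list[np.ndarray]:
    """Cut consecutive non-overlapping windows; discard the remainder."""
    if window <= 0:
        raise ValueError(f"window must be positive, got {window}")
    samples = np.asarray(samples, dtype=float)
    n_windows = len(samples) // window
    return [samples[i * window : (i + 1) * window] for i in range(n_windows)]


def iter_segments(
    recording: Recording,
    schedule: EventSchedule = DEFAULT_SCHEDULE,
    window: int = WINDOW_SAMPLES,
    preprocess=None,
):
    """Yield every :class:`Segment` of a recording.

    ``preprocess`` is an optional per-channel hook ``f(samples) -> samples``
    applied before segmentation (off by default; the pipeline applies no
    filtering or artefact rejection).
    """
    ranges = partition_events(recording, schedule)
    for channel in recording.channel_names:
        signal = recording.channels[channel]
        if preprocess is not None:
            signal = np.asarray(preprocess(signal), dtype=float)
            if len(signal) != recording.n_samples:
                raise ParseError("preprocess hook changed the signal length")
        for rng in ranges:
            windows = segment_event(signal[rng.start_sample : rng.end_sample], window)
            for idx, samples in enumerate(windows):
                yield Segment(
                    subject_id=recording.subject_id,
                    session_index=recording.session_index,
                    channel=channel,
                    event=rng.event,
                    window_index=idx,
                    samples=samples,
                )


def segment_index(
    recording: Recording,
    schedule: EventSchedule = DEFAULT_SCHEDULE,
    window: int = WINDOW_SAMPLES,
) -> pd.DataFrame:
    """Tabular index of all window boundaries (no sample data)."""
    rows = []
    ranges = partition_events(recording, schedule)
    for channel in recording.channel_names:
        for rng in ranges:
            n_windows = rng.n_samples // window
            for idx in range(n_windows):
                start = rng.start_sample + idx * window
                rows.append(
                    {
                        "subject": recording.subject_id,
                        "session": recording.session_index,
                        "channel": channel,
                        "event": rng.event,
                        "window_index": idx,
                        "start_sample": start,
                        "end_sample": start + window,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def write_recording_csv(recording: Recording, path) -> Path:
    """Write ``timestamp_s`` plus one column per channel (256 rows/s)."""
    path = Path(path)
    t = np.arange(recording.n_samples) / recording.sampling_rate
    frame = pd.DataFrame({"timestamp_s": t})
    for channel in recording.channel_names:
        frame[channel] = recording.channels[channel]
    frame.to_csv(path, index=False, float_format="%.17g")
    return path


def read_recording(
    path,
    subject_id: str,
    session_index: int,
    required_channels=CHANNELS,
    sampling_rate: int = SAMPLING_RATE,
    interval_tol: float = 1e-6,
) -> Recording:
    """Read and validate a recording CSV written by :func:`write_recording_csv`."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"{path}: unreadable CSV ({exc})") from exc
    if "timestamp_s" not in frame.columns:
        raise ParseError(f"{path}: missing 'timestamp_s' column")
    missing = [c for c in required_channels if c not in frame.columns]
    if missing:
        raise ParseError(f"{path}: missing channel column(s) {missing}")

    t = frame["timestamp_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ParseError(f"{path}: fewer than two samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ParseError(f"{path}: non-monotone timestamps")
    if np.max(np.abs(dt - 1.0 / sampling_rate)) > interval_tol:
        raise ParseError(
            f"{path}: sampling interval deviates from 1/{sampling_rate} s "
            f"beyond tolerance {interval_tol}"
        )
    channels = {c: frame[c].to_numpy(dtype=float) for c in required_channels}
    return Recording(
        subject_id=subject_id,
        session_index=session_index,
        channels=channels,
        sampling_rate=sampling_rate,
    )
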