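"""Trim the initial walking period and cut overlapping rectangular windows.

Defaults: drop the first 20 s, then cut 10-s windows whose starts are
spaced by exactly one third of the window length, so consecutive windows
overlap by 2/3 of their length (6.66… s). A 280-s post-trim signal yields
82 windows per subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gaitrp.records import GaitRecord, ChannelSelector

#: tolerance absorbing d = 10/3 vs the printed 3.33-s spacing
_EPS = 1e-9


@dataclass(frozen=True)
class WindowingParams:
    """Windowing parameters: window length ``tw`` and start-to-start
    distance ``d`` in seconds, plus leading ``trim`` seconds to drop.

    ``d`` defaults to ``tw / 3`` exactly (not a decimal approximation):
    only the exact ratio reproduces 82 = (280 - 10)/(10/3) + 1 windows.
    """

    tw: float = 10.0
    d: float | None = None
    trim: float = 20.0

    def __post_init__(self) -> None:
        if self.d is None:
            object.__setattr__(self, "d", self.tw / 3.0)
        if self.tw <= 0:
            raise ValueError("tw must be positive")
        if not 0 < self.d <= self.tw + _EPS:
            raise ValueError(f"require 0 < d <= tw, got d={self.d}, tw={self.tw}")
        if self.trim < 0:
            raise ValueError("trim must be nonnegative")


@dataclass(frozen=True)
class ForceWindow:
    """One fixed-length single-channel segment with provenance."""

    subject_id: str
    label: str
    channel: str
    start: float  # seconds, relative to the (trimmed) signal start
    samples: np.ndarray

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class WindowSet:
    windows: list[ForceWindow] = field(default_factory=list)
    params: WindowingParams = field(default_factory=WindowingParams)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self):
        return iter(self.windows)


def expected_window_count(ell: float, tw: float, d: float, t: int = 1) -> int:
    """Number of windows: ((ell - tw) / d + 1) per subject, times ``t``
    subjects, with the per-subject count floored.

    A 1e-9 slack absorbs float error in the division so that exact
    multiples (e.g. 270 / (10/3) = 81) are not floored down spuriously.
    """
    if t < 1:
        raise ValueError("subject count t must be >= 1")
    if d <= 0:
        raise ValueError("d must be positive")
    if ell < tw - _EPS:
        raise ValueError(f"data length {ell} s shorter than window {tw} s")
    per_subject = math.floor((ell - tw) / d + _EPS) + 1
    return per_subject * t


def trim_initial(record: GaitRecord, trim: float) -> GaitRecord:
    """Drop the first ``round(trim * fs)`` samples from all channels."""
    if trim < 0:
        raise ValueError("trim must be nonnegative")
    if trim == 0:
        return record
    if trim >= record.duration:
        raise ValueError(
            f"trim {trim} s >= record duration {record.duration} s"
        )
    k = int(round(trim * record.fs))
    return GaitRecord(
        subject_id=record.subject_id,
        label=record.label,
        fs=record.fs,
        time=record.time[k:] - record.time[k],
        left=record.left[k:],
        right=record.right[k:],
        severity=record.severity,
        meta=dict(record.meta),
    )


def window_signal(
    x: np.ndarray,
    fs: float,
    params: WindowingParams,
    subject_id: str = "",
    label: str = "unknown",
    channel: str = "LF",
) -> WindowSet:
    """Cut one channel into overlapping rectangular windows.

    Window k starts at sample ``round(k * d * fs)`` (start times are
    quantized to whole samples) and copies ``round(tw * fs)`` samples
    verbatim — no taper.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    length = int(round(params.tw * fs))
    if n < length:
        raise ValueError(
            f"input of {n} samples shorter than window of {length} samples"
        )
    ell = n / fs
    k_total = expected_window_count(ell, params.tw, params.d, 1)
    windows = []
    for k in range(k_total):
        i0 = int(round(k * params.d * fs))
        i0 = min(i0, n - length)
        windows.append(
            ForceWindow(
                subject_id=subject_id,
                label=label,
                channel=channel,
                start=i0 / fs,
                samples=x[i0 : i0 + length].copy(),
            )
        )
    return WindowSet(windows=windows, params=params)


def window_record(
    record: GaitRecord,
    params: WindowingParams,
    channel: ChannelSelector | str = "LF",
    pre_trimmed: bool = False,
) -> WindowSet:
    """Trim a record and window the selected channel.

    ``pre_trimmed`` skips the trim for records already cut to the
    analysis span.
    """
    from gaitrp.records import select_channel

    rec = record if pre_trimmed else trim_initial(record, params.trim)
    ch = channel if isinstance(channel, str) else channel.channel
    x = select_channel(rec, ch)
    return window_signal(
        x, rec.fs, params,
        subject_id=rec.subject_id, label=rec.label, channel=ch,
    )


def full_length_params(record: GaitRecord, trim: float = 20.0) -> WindowingParams:
    """Params for the single-window mode: the window spans the whole
    post-trim record (the 5-min comparison arm)."""
    ell = record.duration - trim
    return WindowingParams(tw=ell, d=ell, trim=trim)


def cohort_window_counts(
    subject_counts: dict[str, int],
    ell: float = 280.0,
    params: WindowingParams | None = None,
    exclusions: dict[str, int] | None = None,
) -> dict[str, int]:
    """Per-class and total window bookkeeping for a cohort.

    ``subject_counts`` maps label -> number of subjects; ``exclusions``
    maps label -> number of excluded subjects (the auditable stand-in for
    per-subject exclusion lists at bookkeeping level).
    """
    params = params or WindowingParams()
    out: dict[str, int] = {}
    total = 0
    for label, count in subject_counts.items():
        count -= (exclusions or {}).get(label, 0)
        if count < 0:
            raise ValueError(f"more exclusions than subjects for {label}")
        n = expected_window_count(ell, params.tw, params.d, count) if count else 0
        out[label] = n
        total += n
    out["total"] = total
    return out
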