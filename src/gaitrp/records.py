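"""Core record types: a two-channel vGRF trace and channel selection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

LABELS = ("HC", "ALS", "PD", "HD")
VALID_LABELS = LABELS + ("unknown",)

CHANNELS = ("LF", "RF", "CF")


@dataclass
class GaitRecord:
    """One subject's two-channel vertical ground reaction force trace.

    Attributes
    ----------
    subject_id : str
        Unique subject identifier.
    label : str
        One of ``HC``, ``ALS``, ``PD``, ``HD`` or ``unknown``.
    fs : float
        Sampling rate in Hz.
    time : ndarray
        Sample times in seconds, strictly increasing and uniform.
    left, right : ndarray
        Left-foot and right-foot force samples (arbitrary force units).
    severity : float or None
        Optional clinical severity / duration metadata.
    """

    subject_id: str
    label: str
    fs: float
    time: np.ndarray
    left: np.ndarray
    right: np.ndarray
    severity: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        if self.label not in VALID_LABELS:
            raise ValueError(
                f"label must be one of {VALID_LABELS}, got {self.label!r}"
            )
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        n = len(self.time)
        if len(self.left) != n or len(self.right) != n:
            raise ValueError(
                "time, left and right must have equal length; got "
                f"{n}, {len(self.left)}, {len(self.right)}"
            )
        if n == 0:
            raise ValueError("empty record")
        if not (np.isfinite(self.left).all() and np.isfinite(self.right).all()):
            raise ValueError("forces must be finite")
        dt = np.diff(self.time)
        if n > 1:
            if not (dt > 0).all():
                raise ValueError("time must be strictly increasing")
            tol = 1e-6 / self.fs
            if np.abs(dt - 1.0 / self.fs).max() > tol:
                raise ValueError(
                    "time must be uniform at 1/fs within "
                    f"{tol:g} s (max deviation {np.abs(dt - 1.0 / self.fs).max():g})"
                )

    def __len__(self) -> int:
        return len(self.time)

    @property
    def duration(self) -> float:
        """Record duration in seconds (sample count / fs)."""
        return len(self.time) / self.fs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GaitRecord):
            return NotImplemented
        return (
            self.subject_id == other.subject_id
            and self.label == other.label
            and self.fs == other.fs
            and np.array_equal(self.time, other.time)
            and np.array_equal(self.left, other.left)
            and np.array_equal(self.right, other.right)
        )


@dataclass(frozen=True)
class ChannelSelector:
    """Selects the left-foot (LF), right-foot (RF) or compound-foot (CF)
    channel; CF is the elementwise sum LF + RF."""

    channel: str = "LF"

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}, got {self.channel!r}")


def select_channel(record: GaitRecord, selector: ChannelSelector | str) -> np.ndarray:
    """Return the selected force sequence of ``record``.

    ``LF`` maps to the left channel, ``RF`` to the right channel and
    ``CF`` to their elementwise sum.
    """
    if isinstance(selector, str):
        selector = ChannelSelector(selector)
    if selector.channel == "LF":
        return record.left
    if selector.channel == "RF":
        return record.right
    return record.left + record.right
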