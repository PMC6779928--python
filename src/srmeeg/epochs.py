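"""Event-locked EEG epoch container shared by every analysis stage.

The unit of data in this package is an :class:`EpochSet`: a
``(n_channels, n_samples, n_trials)`` tensor of event-locked EEG, in
microvolts, together with the sampling rate, the latency of the first
sample relative to stimulus onset, channel labels, and (optionally) the
experimental cell it belongs to (subject, group, task condition).

Timing conventions used throughout:

* ``t0`` is the time, in milliseconds, of the first sample relative to
  stimulus onset; the default study window is -300 to +800 ms, so
  ``t0 = -300`` and sample 150 (at 500 Hz) falls on stimulus onset.
* All time windows are half-open ``[start, end)`` in milliseconds; the
  100-300 ms window at 500 Hz covers exactly 100 samples.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

#: Task conditions of the self-referential memory encoding stage.
CONDITIONS = ("self", "other", "physical")

#: Participant groups.
GROUPS = ("control", "patient")

#: 59-channel analysis montage (10-20 / 10-10 names), ordered roughly
#: anterior to posterior so that the tail of the list is posterior scalp.
CHANNELS_59 = [
    "Fp1", "Fpz", "Fp2",
    "AF3", "AFz", "AF4",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

#: Mastoid labels used by the averaged-mastoid re-reference.
MASTOIDS = ("M1", "M2")


def default_labels(n_channels: int) -> list[str]:
    """Channel labels for an ``n_channels``-channel montage.

    For up to 59 channels the head of :data:`CHANNELS_59` is used (the
    full list for the replica configuration); beyond that, synthetic
    ``CHxx`` names are appended.
    """
    if n_channels <= len(CHANNELS_59):
        return list(CHANNELS_59[:n_channels])
    extra = [f"CH{i:02d}" for i in range(len(CHANNELS_59), n_channels)]
    return list(CHANNELS_59) + extra


def window_to_slice(window: tuple[float, float], t0: float, fs: float,
                    n_samples: int) -> slice:
    """Convert a half-open ``[start, end)`` ms window to a sample slice."""
    start, end = window
    if end <= start:
        raise ValueError(f"empty window {window}")
    i0 = int(round((start - t0) * fs / 1000.0))
    i1 = int(round((end - t0) * fs / 1000.0))
    i0 = max(i0, 0)
    i1 = min(i1, n_samples)
    if i1 <= i0:
        raise ValueError(f"window {window} lies outside the epoch")
    return slice(i0, i1)


@dataclass
class EpochSet:
    """Event-locked multi-channel, multi-trial EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples, n_trials)`` array, microvolts.
    fs
        Sampling rate in Hz.
    t0
        Time of the first sample relative to stimulus onset, ms
        (negative: prestimulus).
    channel_labels
        One label per channel.
    condition, subject_id, group
        Optional experimental-cell metadata.
    n_rejected
        Number of trials dropped during segmentation (bookkeeping only).
    """

    data: np.ndarray
    fs: float
    t0: float
    channel_labels: list[str] = field(default_factory=list)
    condition: str | None = None
    subject_id: str | None = None
    group: str | None = None
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_channels, n_samples, n_trials)")
        if not np.isfinite(self.data).all():
            raise ValueError("data contains NaN/Inf")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not self.channel_labels:
            self.channel_labels = default_labels(self.data.shape[0])
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length != n_channels")
        if self.condition is not None and self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.group is not None and self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        # stimulus onset must fall inside the epoch window
        if not (self.t0 <= 0.0 < self.t0 + self.duration_ms):
            raise ValueError("stimulus onset (t = 0) not inside the epoch")

    # -- shape helpers -------------------------------------------------
    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def n_trials(self) -> int:
        return self.data.shape[2]

    @property
    def duration_ms(self) -> float:
        return self.n_samples * 1000.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        return self.t0 + np.arange(self.n_samples) * 1000.0 / self.fs

    def sample_slice(self, window: tuple[float, float]) -> slice:
        """Sample slice for a half-open ms ``window``."""
        return window_to_slice(window, self.t0, self.fs, self.n_samples)

    def with_data(self, data: np.ndarray, **kw) -> "EpochSet":
        """Copy of this EpochSet with new data (metadata preserved)."""
        return replace(self, data=data, **kw)

    def channel_index(self, labels: Sequence[str]) -> np.ndarray:
        idx = []
        for lab in labels:
            try:
                idx.append(self.channel_labels.index(lab))
            except ValueError:
                raise KeyError(f"channel {lab!r} not present") from None
        return np.asarray(idx, dtype=int)
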