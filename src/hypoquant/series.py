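"""Core in-memory containers shared by every analysis stage.

An :class:`ImageSeries` is a time-ordered multi-channel stack with spatial
and temporal calibration.  A :class:`Trace` is any scalar-valued time course
(length percentage, median ratio, mean luminescence) that downstream
changepoint fitting consumes.  Both validate their invariants on
construction so that pipeline stages can assume well-formed inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["ImageSeries", "Trace"]


@dataclass
class ImageSeries:
    """Time-ordered multi-channel image stack.

    Parameters
    ----------
    data
        Array of shape ``(T, C, H, W)`` with finite, non-negative
        intensities (arbitrary units).
    channel_labels
        One label per channel, e.g. ``("RFP", "GFP")``.
    pixel_size_um
        Pixel edge length in micrometres (``None`` if uncalibrated).
    time_step_min
        Minutes between consecutive frames.
    t_start_min
        Acquisition time of frame 0, in minutes relative to treatment.
    ref_channel, sense_channel
        Labels designating the pH-insensitive reference channel and the
        pH-responsive sense channel, where applicable.
    valid
        Optional per-frame boolean mask ``(T, H, W)`` marking pixels with
        real data; vacated margins after drift correction are ``False`` and
        are excluded from downstream wall masks.
    """

    data: np.ndarray
    channel_labels: tuple[str, ...] = ("ch0",)
    pixel_size_um: float | None = None
    time_step_min: float = 1.0
    t_start_min: float = 0.0
    ref_channel: str | None = None
    sense_channel: str | None = None
    valid: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:  # (T, H, W) single channel
            self.data = self.data[:, None, :, :]
        if self.data.ndim != 4:
            raise ValueError(
                f"data must have shape (T, C, H, W); got {self.data.shape}"
            )
        t, c, _, _ = self.data.shape
        if t < 1:
            raise ValueError("series must contain at least one frame")
        if len(self.channel_labels) != c:
            raise ValueError(
                f"{c} channels but {len(self.channel_labels)} labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")
        if self.time_step_min <= 0:
            raise ValueError("time_step_min must be positive")
        for label in (self.ref_channel, self.sense_channel):
            if label is not None and label not in self.channel_labels:
                raise ValueError(f"unknown channel label {label!r}")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != (t,) + self.data.shape[2:]:
                raise ValueError("valid mask must have shape (T, H, W)")

    # -- geometry ---------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of every frame."""
        return self.data.shape[2:]

    @property
    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes since treatment."""
        return self.t_start_min + self.time_step_min * np.arange(self.n_frames)

    # -- channel access ---------------------------------------------------

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise ValueError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None

    def channel(self, label: str) -> np.ndarray:
        """View of one channel as a ``(T, H, W)`` array."""
        return self.data[:, self.channel_index(label)]

    @property
    def ref(self) -> np.ndarray:
        if self.ref_channel is None:
            raise ValueError("no reference channel designated")
        return self.channel(self.ref_channel)

    @property
    def sense(self) -> np.ndarray:
        if self.sense_channel is None:
            raise ValueError("no sense channel designated")
        return self.channel(self.sense_channel)

    def with_data(self, data: np.ndarray, valid: np.ndarray | None = None) -> "ImageSeries":
        """Copy of the series with new pixel data, same calibration."""
        return replace(self, data=data, valid=valid)


@dataclass
class Trace:
    """A scalar time course sampled at strictly increasing times."""

    time_min: np.ndarray
    value: np.ndarray
    value_kind: str = "value"

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time_min.ndim != 1 or self.time_min.shape != self.value.shape:
            raise ValueError("time_min and value must be equal-length 1-D arrays")
        if not np.all(np.diff(self.time_min) > 0):
            raise ValueError("time_min must be strictly increasing")
        if not np.all(np.isfinite(self.value)):
            raise ValueError("trace values must be finite")

    def __len__(self) -> int:
        return self.time_min.size
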