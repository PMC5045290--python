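"""Reading and writing the pipeline's file formats.

Image series travel as multi-page TIFF with channels interleaved per
timepoint (reference channel first), the layout declared in the file's
JSON description tag and re-declarable from config on read.  Tabular
outputs (summaries, traces, shift logs) are CSV; scalar results and
provenance are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .series import ImageSeries
from .ratiometric import AreaKymoImage

__all__ = [
    "write_series",
    "read_series",
    "write_kymo_tiff",
    "write_kymo_png",
    "write_json",
    "read_roi",
]


def write_series(path: str | Path, series: ImageSeries) -> None:
    """Write a series as multi-page TIFF (pages = frames x channels).

    Page order is frame-major with channels in label order per timepoint,
    so a two-channel series stores ref, sense, ref, sense, ...  The layout
    and calibration are recorded in the TIFF description as JSON.
    """
    t, c, h, w = series.data.shape
    meta = {
        "channel_labels": list(series.channel_labels),
        "ref_channel": series.ref_channel,
        "sense_channel": series.sense_channel,
        "n_frames": t,
        "n_channels": c,
        "page_order": "frame-major, channels interleaved (ref first)",
        "pixel_size_um": series.pixel_size_um,
        "time_step_min": series.time_step_min,
        "t_start_min": series.t_start_min,
    }
    tifffile.imwrite(
        str(path),
        series.data.reshape(t * c, h, w),  # float64: round trips exactly
        description=json.dumps(meta),
    )


def read_series(
    path: str | Path,
    n_channels: int | None = None,
    channel_labels: tuple[str, ...] | None = None,
    ref_channel: str | None = None,
    sense_channel: str | None = None,
    pixel_size_um: float | None = None,
    time_step_min: float | None = None,
    t_start_min: float | None = None,
) -> ImageSeries:
    """Read a multi-page TIFF stack back into an :class:`ImageSeries`.

    Layout and calibration default to the file's embedded metadata;
    explicit arguments override it.  The page count must be divisible by
    the channel count, and all pages must share one geometry.
    """
    path = Path(path)
    with tifffile.TiffFile(str(path)) as tf:
        shapes = [p.shape for p in tf.pages]
        for i, s in enumerate(shapes):
            if s != shapes[0]:
                raise ValueError(
                    f"page {i} geometry {s} differs from page 0 {shapes[0]}"
                )
        data = tf.asarray()
        meta = {}
        desc = tf.pages[0].description
        if desc:
            try:
                meta = json.loads(desc)
            except (json.JSONDecodeError, TypeError):
                meta = {}
    if data.ndim == 2:
        data = data[None]
    labels = channel_labels or tuple(meta.get("channel_labels") or ())
    if n_channels is None:
        n_channels = len(labels) or int(meta.get("n_channels") or 1)
    if data.shape[0] % n_channels:
        raise ValueError(
            f"{data.shape[0]} pages not divisible by {n_channels} channels"
        )
    t = data.shape[0] // n_channels
    data = data.reshape(t, n_channels, *data.shape[1:])
    if not labels:
        labels = tuple(f"ch{i}" for i in range(n_channels))
    return ImageSeries(
        data,
        channel_labels=labels,
        ref_channel=ref_channel or meta.get("ref_channel"),
        sense_channel=sense_channel or meta.get("sense_channel"),
        pixel_size_um=pixel_size_um
        if pixel_size_um is not None
        else meta.get("pixel_size_um"),
        time_step_min=time_step_min
        if time_step_min is not None
        else meta.get("time_step_min") or 1.0,
        t_start_min=t_start_min
        if t_start_min is not None
        else meta.get("t_start_min") or 0.0,
    )


def write_kymo_tiff(path: str | Path, kymo: AreaKymoImage) -> None:
    """Render the kymograph canvas to 16-bit TIFF using its LUT range.

    No-data cells map to 0; data spans 1..65535 so that "no data" stays
    distinguishable from the darkest ratio.  The LUT range is stored in
    the description tag.
    """
    lo, hi = kymo.lut_range
    span = hi - lo if hi > lo else 1.0
    scaled = 1 + np.round((np.clip(kymo.canvas, lo, hi) - lo) / span * 65534)
    scaled = np.where(np.isfinite(kymo.canvas), scaled, 0).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        scaled,
        description=json.dumps(
            {"lut_min": lo, "lut_max": hi, "no_data": 0,
             "rect_width_px": kymo.rect_width_px,
             "rows_per_block": kymo.rows_per_block,
             "fill_order": kymo.fill_order}
        ),
    )


def write_kymo_png(path: str | Path, kymo: AreaKymoImage, cmap: str = "viridis") -> None:
    """Rendered PNG of the kymograph for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    lo, hi = kymo.lut_range
    fig, ax = plt.subplots(figsize=(4, 6))
    im = ax.imshow(kymo.canvas, cmap=cmap, vmin=lo, vmax=hi,
                   interpolation="nearest", aspect="auto")
    ax.set_xlabel("packed wall pixels")
    ax.set_ylabel("time (blocks, top to bottom)")
    fig.colorbar(im, ax=ax, label="sense/ref ratio")
    fig.savefig(str(path), dpi=150)
    plt.close(fig)


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_roi(path: str | Path) -> np.ndarray:
    """Polygon ROI vertices from CSV (columns x, y) or JSON ([[x, y], ...]).

    Coordinates are 0-based pixel positions, x rightward, y downward.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        return np.asarray(json.loads(path.read_text()), dtype=float)
    df = pd.read_csv(path)
    return df[["x", "y"]].to_numpy(dtype=float)
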