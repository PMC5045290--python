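"""Ratiometric apoplastic-pH quantification: wall masks, per-pixel ratios,
area kymographs, per-frame summaries, z-projection and flank asymmetry.

The area-kymograph ("AreaKymo") algorithm selects cell-wall pixels on the
pH-insensitive reference channel with a user-chosen threshold, forms the
per-pixel sense/reference ratio at those pixels, and renders each
timepoint's ratio values as a fixed-width rectangle; rectangles stack
top-to-bottom in time order, giving a time-space plot of the wall pH proxy
without any cell segmentation.  The ratio is oriented sense/reference
(GFP/RFP), so a lower value means a more acidic apoplast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.draw import polygon2mask

from .series import ImageSeries

__all__ = [
    "WallMask",
    "RatioSample",
    "AreaKymoImage",
    "FlankResult",
    "wall_mask",
    "pixel_ratios",
    "area_kymograph",
    "frame_summary",
    "sum_project",
    "flank_ratio",
]

#: value marking unfilled cells of an area kymograph (distinct from any
#: finite ratio)
NO_DATA = np.nan


@dataclass
class WallMask:
    """Per-frame boolean wall selection on the reference channel."""

    masks: np.ndarray  # (T, H, W) bool
    threshold_value: float

    @property
    def n_pixels(self) -> np.ndarray:
        """Number of selected pixels in each frame."""
        return self.masks.sum(axis=(1, 2))


@dataclass
class RatioSample:
    """Per-pixel sense/reference ratios at wall pixels of one frame.

    ``ratios`` are ordered in raster order (row-major) of the mask
    coordinates, which is the documented packing order of the kymograph.
    """

    ratios: np.ndarray
    time_min: float


@dataclass
class AreaKymoImage:
    """Stacked fixed-width rectangles of ratio values, one per timepoint."""

    canvas: np.ndarray          # (T * rows_per_block, rect_width) float
    rect_width_px: int
    rows_per_block: int
    placed: np.ndarray          # per-timepoint count of placed ratios
    dropped: np.ndarray         # per-timepoint count of overflow ratios
    lut_range: tuple[float, float]
    fill_order: str = "raster order of mask coordinates; overflow dropped from the tail"

    @property
    def n_timepoints(self) -> int:
        return self.canvas.shape[0] // self.rows_per_block


def wall_mask(series: ImageSeries, threshold: float) -> WallMask:
    """Select cell-wall pixels: reference intensity strictly above threshold.

    The threshold is chosen by the user to isolate the bright wall lattice
    on the reference channel; pixels invalidated by drift correction are
    excluded.  An empty mask in some frame is reported with a warning, not
    an error — downstream summaries carry n = 0 for that frame.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    masks = series.ref > threshold
    if series.valid is not None:
        masks = masks & series.valid
    counts = masks.sum(axis=(1, 2))
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0)
        warnings.warn(
            f"wall mask is empty in frame(s) {empty.tolist()}", stacklevel=2
        )
    return WallMask(masks=masks, threshold_value=float(threshold))


def pixel_ratios(series: ImageSeries, mask: WallMask) -> list[RatioSample]:
    """Per-pixel sense/reference ratio at each wall pixel, per frame.

    Lower ratio = more acidic.  Reference intensities at mask pixels are
    strictly positive by construction of the mask (threshold > 0).
    """
    if mask.masks.shape != (series.n_frames,) + series.shape:
        raise ValueError("mask geometry does not match the series")
    sense = series.sense
    ref = series.ref
    samples: list[RatioSample] = []
    for t, time in enumerate(series.times_min):
        m = mask.masks[t]
        r = ref[t][m]
        assert np.all(r > 0), "mask includes non-positive reference pixels"
        samples.append(RatioSample(ratios=sense[t][m] / r, time_min=float(time)))
    return samples


def area_kymograph(
    samples: list[RatioSample],
    rect_width: int,
    rows_per_block: int,
    lut_range: tuple[float, float] | None = None,
) -> AreaKymoImage:
    """Pack each timepoint's ratios into a rect_width x rows_per_block block.

    Blocks are filled row-major (left to right, top to bottom) with the
    frame's ratios in raster order of the mask coordinates; values beyond
    the block capacity are dropped from the tail and the drop count is
    recorded.  Blocks are concatenated top-to-bottom in time order, so time
    progresses downward in the returned canvas.  Unfilled cells hold NaN.
    """
    if rect_width < 1:
        raise ValueError("rect_width must be >= 1")
    if rows_per_block < 1:
        raise ValueError("rows_per_block must be >= 1")
    capacity = rect_width * rows_per_block
    n_t = len(samples)
    canvas = np.full((n_t * rows_per_block, rect_width), NO_DATA)
    placed = np.zeros(n_t, dtype=int)
    dropped = np.zeros(n_t, dtype=int)
    for t, sample in enumerate(samples):
        vals = np.asarray(sample.ratios, dtype=float)
        n_place = min(vals.size, capacity)
        placed[t] = n_place
        dropped[t] = vals.size - n_place
        block = np.full(capacity, NO_DATA)
        block[:n_place] = vals[:n_place]
        canvas[t * rows_per_block:(t + 1) * rows_per_block] = block.reshape(
            rows_per_block, rect_width
        )
    if lut_range is None:
        finite = canvas[np.isfinite(canvas)]
        lut_range = (
            (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
        )
    return AreaKymoImage(
        canvas=canvas,
        rect_width_px=rect_width,
        rows_per_block=rows_per_block,
        placed=placed,
        dropped=dropped,
        lut_range=lut_range,
    )


def frame_summary(
    samples: list[RatioSample],
    series: ImageSeries | None = None,
    mask: WallMask | None = None,
) -> pd.DataFrame:
    """Boxplot statistics of the ratio distribution at every timepoint.

    Returns one row per frame with n, min, Q1, median, Q3, max and two
    mean variants.  Quantiles interpolate linearly between order
    statistics at positions p*n + 1/2 (the Hazen rule, which is also what
    MATLAB's boxplot uses), so the quartiles of {0.2, 0.4, 0.6, 0.8} are
    0.3 and 0.7.  The mean variants are: the mean of per-pixel
    ratios, and — when the source series and mask are given — the manual
    protocol's ratio of channel means, mean(sense)/mean(ref) over the mask.
    The two coincide exactly when the reference is uniform over the mask.
    Frames with an empty mask report NaN statistics at n = 0.
    """
    if not samples:
        raise ValueError("need at least one frame")
    rows = []
    for t, sample in enumerate(samples):
        vals = np.asarray(sample.ratios, dtype=float)
        row = {"time_min": sample.time_min, "n": vals.size}
        if vals.size:
            q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75], method="hazen")
            row.update(
                min=vals.min(), q1=q1, median=med, q3=q3, max=vals.max(),
                mean_of_ratios=vals.mean(),
            )
        else:
            row.update(min=np.nan, q1=np.nan, median=np.nan, q3=np.nan,
                       max=np.nan, mean_of_ratios=np.nan)
        if series is not None and mask is not None:
            m = mask.masks[t]
            if m.any():
                row["ratio_of_means"] = (
                    series.sense[t][m].mean() / series.ref[t][m].mean()
                )
            else:
                row["ratio_of_means"] = np.nan
        elif vals.size:
            # without channel data the harmonic pairing is unavailable;
            # fall back to the per-pixel mean so the column always exists
            row["ratio_of_means"] = np.nan
        else:
            row["ratio_of_means"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def sum_project(zstack: ImageSeries) -> ImageSeries:
    """SUM projection of a z-stack: per-pixel sum across slices, per channel.

    The stack axis of the input series is interpreted as z.  Returns a
    single-frame series with the same channels and calibration.
    """
    projected = zstack.data.sum(axis=0, keepdims=True)
    return zstack.with_data(projected)


@dataclass
class FlankResult:
    """Paired per-section flank ratios and their summary."""

    per_section: pd.DataFrame   # columns: section, upper, lower, difference
    mean_difference: float      # mean of (lower - upper)
    sign: int                   # sign of the mean difference
    n_skipped: int              # sections lacking mask pixels in an ROI


def _roi_mask(shape: tuple[int, int], polygon_xy: np.ndarray) -> np.ndarray:
    poly = np.asarray(polygon_xy, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
        raise ValueError("ROI polygon must be an (N >= 3, 2) array of (x, y)")
    return polygon2mask(shape, poly[:, ::-1])  # polygon2mask wants (row, col)


def flank_ratio(
    stack: ImageSeries,
    upper_roi: np.ndarray,
    lower_roi: np.ndarray,
    threshold: float,
) -> FlankResult:
    """Per-section GFP/RFP ratio on the two flanks of a bending organ.

    For every z-section the ratio of channel means, mean(sense)/mean(ref),
    is computed inside wall-mask ∩ ROI for the upper and the lower flank,
    and the paired difference (lower - upper) is reported.  A section whose
    mask misses either ROI is skipped and counted.  The two ROIs must be
    disjoint.
    """
    shape = stack.shape
    upper = _roi_mask(shape, upper_roi)
    lower = _roi_mask(shape, lower_roi)
    if not upper.any() or not lower.any():
        raise ValueError("each ROI must cover at least one pixel")
    if (upper & lower).any():
        raise ValueError("upper and lower ROIs must be disjoint")
    wm = wall_mask(stack, threshold)
    rows = []
    skipped = 0
    for z in range(stack.n_frames):
        m = wm.masks[z]
        mu, ml = m & upper, m & lower
        if not mu.any() or not ml.any():
            skipped += 1
            continue
        ru = stack.sense[z][mu].mean() / stack.ref[z][mu].mean()
        rl = stack.sense[z][ml].mean() / stack.ref[z][ml].mean()
        rows.append(
            {"section": z, "upper": ru, "lower": rl, "difference": rl - ru}
        )
    per_section = pd.DataFrame(
        rows, columns=["section", "upper", "lower", "difference"]
    )
    if len(per_section):
        mean_diff = float(per_section["difference"].mean())
    else:
        mean_diff = np.nan
    sign = 0 if not np.isfinite(mean_diff) or mean_diff == 0 else int(np.sign(mean_diff))
    return FlankResult(
        per_section=per_section,
        mean_difference=mean_diff,
        sign=sign,
        n_skipped=skipped,
    )
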