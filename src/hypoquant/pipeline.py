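"""End-to-end assay pipelines with provenance.

Each ``run_*`` function composes the stage modules into the complete
measurement for one assay type, optionally writing every stage output plus
a :class:`RunReport` (input checksums, configuration snapshot, per-stage
provenance) so a run can be audited and reproduced.  Given identical
inputs, configuration and seeds, outputs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import io as hio
from . import kinetics, morphometry, ratiometric, registration, synthdata
from .series import ImageSeries, Trace

__all__ = [
    "AssayConfig",
    "RunReport",
    "PhAssayResult",
    "ElongationResult",
    "GravitropismResult",
    "run_ph_assay",
    "run_elongation_assay",
    "run_gravitropism",
    "simulate",
]


@dataclass
class AssayConfig:
    """Per-run configuration shared by the assay pipelines.

    Only the fields relevant to the assay being run are consulted.  A YAML
    file with the same keys can be loaded with :meth:`from_yaml`; CLI
    flags override file values.
    """

    # channel layout
    channel_labels: tuple[str, ...] = ("RFP", "GFP")
    ref_channel: str = "RFP"
    sense_channel: str = "GFP"
    # ratiometric stage
    threshold: float = 100.0          # reference-channel wall cutoff
    rect_width: int = 100             # AreaKymo rectangle width (px)
    rows_per_block: int = 12          # AreaKymo rows per timepoint
    stabilize: bool = False           # run drift correction first
    # morphometry stage
    seg_threshold: float | str = "auto"   # "auto" = Otsu
    px_per_mm: float | None = None
    tip_window_px: float | None = None
    # calibration / kinetics
    time_step_min: float | None = None
    t_start_min: float | None = None
    direction: str | None = None      # override the assay default
    min_points_per_arm: int = 2
    # bookkeeping
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AssayConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "channel_labels" in raw:
            raw["channel_labels"] = tuple(raw["channel_labels"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["channel_labels"] = list(d["channel_labels"])
        return d


@dataclass
class RunReport:
    """Provenance of one pipeline run: enough to reproduce every output."""

    assay: str
    version: str = __version__
    inputs: dict = field(default_factory=dict)    # path -> sha256
    config: dict = field(default_factory=dict)
    stages: dict = field(default_factory=dict)    # stage -> provenance
    outputs: dict = field(default_factory=dict)   # path -> producing stage

    def add_input(self, path: str | Path) -> None:
        digest = hashlib.sha256(Path(path).read_bytes()).hexdigest()
        self.inputs[str(path)] = digest

    def add_output(self, path: str | Path, stage: str) -> None:
        self.outputs[str(path)] = stage

    def write(self, path: str | Path) -> None:
        hio.write_json(path, dataclasses.asdict(self))


def _load_series(source, config: AssayConfig, report: RunReport) -> ImageSeries:
    if isinstance(source, ImageSeries):
        return source
    report.add_input(source)
    return hio.read_series(
        source,
        channel_labels=config.channel_labels,
        ref_channel=config.ref_channel,
        sense_channel=config.sense_channel,
        time_step_min=config.time_step_min,
        t_start_min=config.t_start_min,
    )


def _maybe_stabilize(
    series: ImageSeries, config: AssayConfig, report: RunReport,
    outdir: Path | None,
) -> ImageSeries:
    if not config.stabilize:
        return series
    shifts = registration.estimate_translation(series)
    series = registration.apply_shifts(series, shifts)
    report.stages["registration"] = {
        "mode": "sequential",
        "max_abs_shift_px": float(np.abs(shifts.shifts).max()),
    }
    if outdir is not None:
        import pandas as pd

        p = outdir / "shifts.csv"
        pd.DataFrame(
            {"frame": np.arange(series.n_frames),
             "dx_px": shifts.shifts[:, 0], "dy_px": shifts.shifts[:, 1]}
        ).to_csv(p, index=False)
        report.add_output(p, "registration")
    return series


@dataclass
class PhAssayResult:
    kymo: ratiometric.AreaKymoImage
    summary: "object"          # per-frame boxplot statistics (DataFrame)
    onset: kinetics.OnsetEstimate
    report: RunReport


def run_ph_assay(
    source: ImageSeries | str | Path,
    config: AssayConfig | None = None,
    out_dir: str | Path | None = None,
) -> PhAssayResult:
    """Full ratiometric pH pipeline for one series.

    Wall-mask the reference channel, form per-pixel sense/ref ratios,
    render the area kymograph, summarize each frame, and estimate the
    acidification onset from the per-frame median ratio (direction:
    decrease).
    """
    config = config or AssayConfig()
    outdir = _prep_outdir(out_dir or config.out_dir)
    report = RunReport(assay="ph", config=config.to_dict())
    series = _load_series(source, config, report)
    series = _maybe_stabilize(series, config, report, outdir)
    mask = ratiometric.wall_mask(series, config.threshold)
    samples = ratiometric.pixel_ratios(series, mask)
    kymo = ratiometric.area_kymograph(
        samples, config.rect_width, config.rows_per_block
    )
    summary = ratiometric.frame_summary(samples, series, mask)
    summary["dropped"] = kymo.dropped
    report.stages["wall_mask"] = {
        "threshold": config.threshold,
        "n_pixels": mask.n_pixels.tolist(),
    }
    report.stages["area_kymograph"] = {
        "rect_width": config.rect_width,
        "rows_per_block": config.rows_per_block,
        "dropped": kymo.dropped.tolist(),
        "fill_order": kymo.fill_order,
    }
    median_trace = Trace(
        summary["time_min"].to_numpy(), summary["median"].to_numpy(),
        value_kind="median_ratio",
    )
    onset = kinetics.detect_onset(
        median_trace,
        direction=config.direction or "decrease",
        min_points_per_arm=config.min_points_per_arm,
    )
    report.stages["onset"] = onset.to_dict()
    if outdir is not None:
        p = outdir / "summary.csv"
        summary.to_csv(p, index=False)
        report.add_output(p, "frame_summary")
        p = outdir / "areakymo.tiff"
        hio.write_kymo_tiff(p, kymo)
        report.add_output(p, "area_kymograph")
        p = outdir / "areakymo.png"
        hio.write_kymo_png(p, kymo)
        report.add_output(p, "area_kymograph")
        p = outdir / "onset.json"
        hio.write_json(p, onset.to_dict())
        report.add_output(p, "onset")
        report.write(outdir / "run_report.json")
    return PhAssayResult(kymo=kymo, summary=summary, onset=onset, report=report)


@dataclass
class ElongationResult:
    trace: morphometry.GrowthTrace
    onset: kinetics.OnsetEstimate
    report: RunReport


def run_elongation_assay(
    source: ImageSeries | str | Path,
    config: AssayConfig | None = None,
    out_dir: str | Path | None = None,
) -> ElongationResult:
    """Segment -> Feret length -> %-growth trace -> onset estimate."""
    config = config or AssayConfig(channel_labels=("scan",))
    outdir = _prep_outdir(out_dir or config.out_dir)
    report = RunReport(assay="elongation", config=config.to_dict())
    if isinstance(source, ImageSeries):
        series = source
    else:
        report.add_input(source)
        series = hio.read_series(
            source,
            time_step_min=config.time_step_min,
            t_start_min=config.t_start_min,
        )
    masks = []
    for t in range(series.n_frames):
        try:
            masks.append(
                morphometry.segment_mask(series.data[t, 0], config.seg_threshold)
            )
        except ValueError as exc:
            raise ValueError(f"segmentation failed at frame {t}: {exc}") from exc
    trace = morphometry.growth_trace(series, masks, config.px_per_mm)
    report.stages["segmentation"] = {
        "threshold": [m.threshold_value for m in masks],
        "policy": masks[0].component_policy,
    }
    onset = kinetics.detect_onset(
        Trace(trace.time_min, trace.length_pct, value_kind="length_pct"),
        direction=config.direction or "increase",
        min_points_per_arm=config.min_points_per_arm,
    )
    report.stages["onset"] = onset.to_dict()
    if outdir is not None:
        p = outdir / "growth_trace.csv"
        trace.to_frame().to_csv(p, index=False)
        report.add_output(p, "growth_trace")
        p = outdir / "onset.json"
        hio.write_json(p, onset.to_dict())
        report.add_output(p, "onset")
        report.write(outdir / "run_report.json")
    return ElongationResult(trace=trace, onset=onset, report=report)


@dataclass
class GravitropismResult:
    angles: morphometry.BendAngleTrace | None
    flanks: ratiometric.FlankResult | None
    report: RunReport


def run_gravitropism(
    source: ImageSeries | str | Path,
    config: AssayConfig | None = None,
    out_dir: str | Path | None = None,
    upper_roi: np.ndarray | None = None,
    lower_roi: np.ndarray | None = None,
) -> GravitropismResult:
    """Tip-angle trajectory, or flank pH asymmetry when ROIs are given."""
    config = config or AssayConfig(channel_labels=("mask",))
    outdir = _prep_outdir(out_dir or config.out_dir)
    report = RunReport(assay="gravitropism", config=config.to_dict())
    if isinstance(source, ImageSeries):
        series = source
    else:
        report.add_input(source)
        series = hio.read_series(source, time_step_min=config.time_step_min,
                                 t_start_min=config.t_start_min)
    if upper_roi is not None or lower_roi is not None:
        if upper_roi is None or lower_roi is None:
            raise ValueError("flank analysis needs both ROIs")
        flanks = ratiometric.flank_ratio(
            series, upper_roi, lower_roi, config.threshold
        )
        report.stages["flank_ratio"] = {
            "mean_difference": flanks.mean_difference,
            "sign": flanks.sign,
            "n_skipped": flanks.n_skipped,
        }
        if outdir is not None:
            p = outdir / "flank_ratios.csv"
            flanks.per_section.to_csv(p, index=False)
            report.add_output(p, "flank_ratio")
            report.write(outdir / "run_report.json")
        return GravitropismResult(angles=None, flanks=flanks, report=report)
    angles = np.empty(series.n_frames)
    for t in range(series.n_frames):
        mask = morphometry.segment_mask(series.data[t, 0], 0.5
                                        if series.data[t, 0].max() <= 1 else "auto")
        angles[t] = morphometry.tip_angle(mask, config.tip_window_px)
    trace = morphometry.BendAngleTrace(
        time_min=series.times_min, angle_deg=angles,
        tip_window_px=config.tip_window_px,
    )
    report.stages["tip_angle"] = {"tip_window_px": config.tip_window_px}
    if outdir is not None:
        p = outdir / "bend_angles.csv"
        trace.to_frame().to_csv(p, index=False)
        report.add_output(p, "tip_angle")
        report.write(outdir / "run_report.json")
    return GravitropismResult(angles=trace, flanks=None, report=report)


def _prep_outdir(out_dir: str | Path | None) -> Path | None:
    if out_dir is None:
        return None
    outdir = Path(out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    return outdir


def simulate(
    kind: str,
    out_dir: str | Path,
    seed: int = 0,
    overrides: dict | None = None,
) -> dict:
    """Generate a synthetic dataset on disk with its ground-truth sidecar.

    ``kind`` is one of ``ph``, ``elongation``, ``luminescence``,
    ``bending``; ``overrides`` patch the generator's default parameters.
    Returns the written paths.
    """
    outdir = _prep_outdir(out_dir)
    overrides = dict(overrides or {})
    paths: dict[str, str] = {}

    def _write_truth(truth: synthdata.GroundTruth, extra: dict) -> None:
        payload = {"kind": kind, "seed": seed, **extra}
        if truth.true_onset_min is not None:
            payload["true_onset_min"] = truth.true_onset_min
        p = outdir / "ground_truth.json"
        hio.write_json(p, payload)
        paths["ground_truth"] = str(p)

    if kind == "ph":
        cfg = dataclasses.replace(
            synthdata.PHSeriesConfig(), seed=seed, **overrides
        )
        series, truth = synthdata.generate_ph_series(cfg)
        p = outdir / "ph_series.tiff"
        hio.write_series(p, series)
        paths["series"] = str(p)
        np.savetxt(outdir / "true_ph.csv",
                   np.column_stack([series.times_min, truth.ph_series]),
                   delimiter=",", header="time_min,ph", comments="")
        paths["true_ph"] = str(outdir / "true_ph.csv")
        _write_truth(truth, {"config": dataclasses.asdict(cfg)})
    elif kind == "elongation":
        cfg = dataclasses.replace(
            synthdata.GrowthSeriesConfig(), seed=seed, **overrides
        )
        series, truth = synthdata.generate_elongation_series(cfg)
        p = outdir / "elongation_series.tiff"
        hio.write_series(p, series)
        paths["series"] = str(p)
        np.savetxt(outdir / "true_length.csv",
                   np.column_stack([series.times_min, truth.true_length_series]),
                   delimiter=",", header="time_min,length_px", comments="")
        paths["true_length"] = str(outdir / "true_length.csv")
        _write_truth(truth, {"config": dataclasses.asdict(cfg)})
    elif kind == "luminescence":
        trace, truth = synthdata.generate_luminescence_trace(
            seed=seed, **overrides
        )
        p = outdir / "luminescence_trace.csv"
        np.savetxt(p, np.column_stack([trace.time_min, trace.value]),
                   delimiter=",", header="time_min,value", comments="")
        paths["trace"] = str(p)
        _write_truth(truth, {})
    elif kind == "bending":
        series, truth = synthdata.generate_bending_series(seed=seed, **overrides)
        p = outdir / "bending_series.tiff"
        hio.write_series(p, series)
        paths["series"] = str(p)
        np.savetxt(outdir / "true_angles.csv",
                   np.column_stack([series.times_min,
                                    truth.true_angle_series_deg]),
                   delimiter=",", header="time_min,angle_deg", comments="")
        paths["true_angles"] = str(outdir / "true_angles.csv")
        _write_truth(truth, {})
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    return paths
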