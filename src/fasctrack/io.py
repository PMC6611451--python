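"""Video, annotation, configuration and measurement-series input/output.

Formats
-------
* video: multi-page TIFF (lossless, preferred) or AVI/MP4 via imageio;
  frames are returned as 2-D grayscale arrays (colour is converted by
  luminance);
* annotation: JSON with the acquisition scale and one drawn segment per
  structure, in mm image coordinates::

      {"mm_per_px": 0.117, "frame_rate_hz": 60.0,
       "width_px": 512, "height_px": 512,
       "structures": [{"role": "fascicle",
                       "p0_mm": [x, y], "p1_mm": [x, y]}, ...]}

* measurement series: CSV with ``# key=value`` metadata header lines;
* run configuration: YAML, unknown keys rejected.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .geometry import FrameSpec, Segment2D, StructureRole
from .measurement import FascicleMeasurement, MeasurementSeries
from .tracking import TrackerConfig

__all__ = [
    "AnnotationError",
    "VideoReadError",
    "StatsConfig",
    "RunConfig",
    "read_video",
    "write_video",
    "read_annotation",
    "write_annotation",
    "read_measurement_csv",
    "write_measurement_csv",
    "read_run_config",
    "render_overlay",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


class VideoReadError(RuntimeError):
    """Raised when a video container cannot be read."""


class AnnotationError(ValueError):
    """Raised for malformed or out-of-bounds annotation files."""


def read_video(path: str | Path) -> np.ndarray:
    """Read a video as a (T, H, W) grayscale array.

    Multi-page TIFF is read via tifffile; other containers via imageio.
    Colour frames are collapsed to luminance.  Raises
    :class:`VideoReadError` naming the path on any failure.
    """
    path = Path(path)
    if not path.exists():
        raise VideoReadError(f"video file not found: {path}")
    try:
        if path.suffix.lower() in (".tif", ".tiff"):
            frames = tifffile.imread(str(path))
        else:
            import imageio.v3 as iio

            frames = iio.imread(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with the path
        raise VideoReadError(f"could not read video {path}: {exc}") from exc
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim == 4:  # (T, H, W, C) colour
        frames = (frames[..., :3].astype(np.float64) @ _LUMA).astype(frames.dtype)
    if frames.ndim != 3:
        raise VideoReadError(f"unsupported video layout {frames.shape} in {path}")
    return frames


def write_video(path: str | Path, frames: np.ndarray) -> None:
    """Write frames to a multi-page TIFF (or AVI/MP4 when imageio can)."""
    path = Path(path)
    frames = np.asarray(frames)
    if path.suffix.lower() in (".tif", ".tiff"):
        # grayscale pages; without this a 3-frame video is stored as RGB
        tifffile.imwrite(str(path), frames, photometric="minisblack")
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), frames)


def read_annotation(
    path: str | Path, frame_shape: tuple[int, int] | None = None
) -> tuple[FrameSpec, dict[StructureRole, Segment2D]]:
    """Read a first-frame annotation file.

    ``frame_shape`` (height, width in px) overrides the raster size stored
    in the file (e.g. taken from the video actually loaded).  Endpoints
    are validated against the field of view.
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"annotation file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"annotation {path} is not valid JSON: {exc}") from exc
    for key in ("mm_per_px", "frame_rate_hz", "structures"):
        if key not in payload:
            raise AnnotationError(f"annotation {path} missing key {key!r}")
    if frame_shape is not None:
        height_px, width_px = frame_shape
    else:
        try:
            width_px = int(payload["width_px"])
            height_px = int(payload["height_px"])
        except KeyError as exc:
            raise AnnotationError(
                f"annotation {path} lacks width_px/height_px and no frame shape given"
            ) from exc
    spec = FrameSpec(
        width_px=width_px,
        height_px=height_px,
        mm_per_px=float(payload["mm_per_px"]),
        frame_rate_hz=float(payload["frame_rate_hz"]),
    )
    segments: dict[StructureRole, Segment2D] = {}
    for entry in payload["structures"]:
        try:
            role = StructureRole(entry["role"])
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"bad structure role in {path}: {exc}") from exc
        if role in segments:
            raise AnnotationError(f"duplicate role {role.value!r} in {path}")
        seg = Segment2D(p0=tuple(entry["p0_mm"]), p1=tuple(entry["p1_mm"]))
        for p in seg.endpoints:
            if not spec.contains_mm(p)[0]:
                raise AnnotationError(
                    f"{role.value} endpoint {tuple(np.round(p, 2))} mm outside "
                    f"the {spec.width_mm:.1f} x {spec.height_mm:.1f} mm field of view"
                )
        segments[role] = seg
    missing = [r.value for r in StructureRole if r not in segments]
    if missing:
        raise AnnotationError(f"annotation {path} missing roles: {missing}")
    return spec, segments


def write_annotation(
    path: str | Path, spec: FrameSpec, segments: dict[StructureRole, Segment2D]
) -> None:
    payload = {
        "mm_per_px": spec.mm_per_px,
        "frame_rate_hz": spec.frame_rate_hz,
        "width_px": spec.width_px,
        "height_px": spec.height_px,
        "structures": [
            {
                "role": role.value,
                "p0_mm": list(map(float, seg.p0)),
                "p1_mm": list(map(float, seg.p1)),
            }
            for role, seg in segments.items()
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


_CSV_COLUMNS = [
    "frame_index",
    "time_s",
    "length_mm",
    "pennation_deg",
    "superficial_extrapolated",
    "deep_extrapolated",
    "n_valid_sup",
    "n_valid_deep",
    "n_valid_fas",
]


def write_measurement_csv(path: str | Path, series: MeasurementSeries) -> None:
    """Write a measurement series with ``# key=value`` metadata lines.

    Floats use repr precision so a write/read round trip is lossless.
    """
    lines = [f"# {k}={v}" for k, v in sorted(series.metadata.items())]
    lines.append(",".join(_CSV_COLUMNS))
    for m in series.measurements:
        lines.append(
            f"{m.frame_index},{m.time_s!r},{m.length_mm!r},{m.pennation_deg!r},"
            f"{m.superficial_extrapolated},{m.deep_extrapolated},"
            f"{m.n_valid_sup},{m.n_valid_deep},{m.n_valid_fas}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_measurement_csv(path: str | Path) -> MeasurementSeries:
    path = Path(path)
    metadata: dict[str, str] = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].strip().partition("=")
                metadata[key.strip()] = value.strip()
            else:
                rows.append(line)
    if not rows:
        raise ValueError(f"no measurement rows in {path}")
    header = rows[0].split(",")
    if header != _CSV_COLUMNS:
        raise ValueError(f"unexpected columns in {path}: {header}")
    measurements = []
    for row in rows[1:]:
        vals = row.split(",")
        measurements.append(
            FascicleMeasurement(
                frame_index=int(vals[0]),
                time_s=float(vals[1]),
                length_mm=float(vals[2]),
                pennation_deg=float(vals[3]),
                superficial_extrapolated=vals[4] == "True",
                deep_extrapolated=vals[5] == "True",
                n_valid_sup=int(vals[6]),
                n_valid_deep=int(vals[7]),
                n_valid_fas=int(vals[8]),
            )
        )
    return MeasurementSeries(measurements, metadata=metadata)


@dataclass(frozen=True)
class StatsConfig:
    """Thresholds used by the statistics harness."""

    cv_threshold_percent: float = 10.0
    outlier_threshold_mm: float = 40.0
    class_boundaries: tuple[float, float, float] = (0.36, 0.67, 0.90)


@dataclass(frozen=True)
class RunConfig:
    """Full pipeline configuration (tracker + statistics + seed)."""

    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    verbosity: str = "info"


def _strict_dataclass(cls, data: dict, context: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


def read_run_config(path: str | Path | None) -> RunConfig:
    """Load a YAML run configuration; ``None`` gives all defaults.

    Unknown keys raise, so typos cannot silently fall back to defaults.
    """
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be a mapping")
    unknown = set(raw) - {"tracker", "stats", "seed", "verbosity"}
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    tracker = _strict_dataclass(TrackerConfig, raw.get("tracker", {}) or {}, "tracker")
    stats_raw = dict(raw.get("stats", {}) or {})
    if "class_boundaries" in stats_raw:
        stats_raw["class_boundaries"] = tuple(stats_raw["class_boundaries"])
    stats = _strict_dataclass(StatsConfig, stats_raw, "stats")
    return RunConfig(
        tracker=tracker,
        stats=stats,
        seed=int(raw.get("seed", 0)),
        verbosity=str(raw.get("verbosity", "info")),
    )


def run_config_to_yaml(config: RunConfig) -> str:
    return yaml.safe_dump(
        {
            "tracker": asdict(config.tracker),
            "stats": {
                "cv_threshold_percent": config.stats.cv_threshold_percent,
                "outlier_threshold_mm": config.stats.outlier_threshold_mm,
                "class_boundaries": list(config.stats.class_boundaries),
            },
            "seed": config.seed,
            "verbosity": config.verbosity,
        },
        sort_keys=True,
    )


def render_overlay(result, frames: np.ndarray) -> np.ndarray:
    """Burn tracked point clouds and fitted lines into the frames.

    Returns a copy of ``frames`` (uint8) with fitted lines drawn at the
    dtype maximum and valid points as 3 px crosses, one output frame per
    input frame.
    """
    from skimage.draw import line as draw_line

    spec = result.frame_spec
    out = np.asarray(frames).copy()
    if out.dtype != np.uint8:
        out = np.clip(out, 0, 255).astype(np.uint8)
    h, w = spec.height_px, spec.width_px
    for t in range(out.shape[0]):
        img = out[t]
        for role, ln in result.lines[t].items():
            # clip the infinite line to the raster by sampling far endpoints
            p0 = ln.point_at(-2 * spec.width_mm) / spec.mm_per_px
            p1 = ln.point_at(2 * spec.width_mm) / spec.mm_per_px
            rr, cc = draw_line(
                int(round(p0[1])), int(round(p0[0])),
                int(round(p1[1])), int(round(p1[0])),
            )
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            img[rr[keep], cc[keep]] = 255
        for role, cloud in result.clouds[t].items():
            pts = np.round(cloud.valid_positions / spec.mm_per_px).astype(int)
            for x, y in pts:
                for dx, dy in ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1)):
                    xx, yy = x + dx, y + dy
                    if 0 <= xx < w and 0 <= yy < h:
                        img[yy, xx] = 255
    return out
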