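"""Per-structure point tracking through an ultrasound video.

For each of the three structures (two aponeuroses, one fascicle) drawn
in the first frame:

1. a rectangular oriented ROI is built along the structure's long axis
   (the fascicle ROI keeps only the middle 90% to avoid seeding either
   aponeurosis);
2. the deep-aponeurosis ROI has its gray scale rebalanced (percentile
   contrast stretch), which improves tracking of that low-contrast band;
3. up to ``n_seed_points`` points are seeded: strongest minimum-eigenvalue
   corner responses first, padded with an even grid over the ROI;
4. points are propagated frame-to-frame by pyramidal Lucas-Kanade optical
   flow (3 mm block, 4 levels, <= 30 iterations by default);
5. a point is invalidated if the tracker fails, if it leaves the frame,
   or if its forward-backward re-track lands more than 2 mm from where it
   started; if more than 10% of the prior frame's points are lost the
   structure is reseeded with fresh points in the current frame, and if
   100% are lost tracking aborts with a fatal error;
6. the surviving point cloud is refit with a straight line, from which
   fascicle length and pennation angle are measured every frame.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from skimage.feature import corner_shi_tomasi, peak_local_max

from ._lk import ImagePyramid, track_points
from .geometry import (
    DegenerateGeometryError,
    FrameSpec,
    Line2D,
    Segment2D,
    StructureRole,
    fascicle_length,
    fit_line,
    pennation_angle,
)
from .measurement import FascicleMeasurement, MeasurementSeries

__all__ = [
    "TrackerConfig",
    "OrientedROI",
    "PointCloud",
    "TrackState",
    "TrackingResult",
    "TrackingLostError",
    "build_roi",
    "rebalance_intensity",
    "seed_points",
    "track_step",
    "update_structure",
    "track_video",
]

logger = logging.getLogger(__name__)


class TrackingLostError(RuntimeError):
    """Raised when 100% of a structure's points are invalidated."""

    def __init__(self, role: StructureRole, frame_index: int):
        self.role = role
        self.frame_index = frame_index
        super().__init__(
            f"tracking lost: 100% of points for {role.value} "
            f"were invalid at frame {frame_index}"
        )


@dataclass(frozen=True)
class TrackerConfig:
    """Tracker parameters.  Defaults follow the validated configuration:
    100 seed points per structure, 3 mm block, 4 pyramid levels, 2 mm
    bidirectional error, 30 iterations, reseed above 10% attrition,
    fascicle ROI covering the middle 90% of the drawn segment."""

    n_seed_points: int = 100
    block_size_mm: float = 3.0
    pyramid_levels: int = 4
    fb_error_mm: float = 2.0
    max_iterations: int = 30
    reseed_fraction: float = 0.10
    roi_axial_fraction_fascicle: float = 0.90
    roi_axial_fraction_aponeurosis: float = 1.0
    roi_half_width_mm: float = 2.5
    min_points_for_fit: int = 5
    fit: str = "orthogonal"
    seeding: str = "grid"
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_seed_points < 1:
            raise ValueError("n_seed_points must be >= 1")
        if self.block_size_mm <= 0 or self.fb_error_mm <= 0:
            raise ValueError("block size and bidirectional error must be positive")
        if self.pyramid_levels < 1 or self.max_iterations < 1:
            raise ValueError("pyramid_levels and max_iterations must be >= 1")
        if not 0 < self.reseed_fraction <= 1:
            raise ValueError("reseed_fraction must be in (0, 1]")
        for f in (self.roi_axial_fraction_fascicle, self.roi_axial_fraction_aponeurosis):
            if not 0 < f <= 1:
                raise ValueError("ROI axial fractions must be in (0, 1]")
        if self.roi_half_width_mm <= 0:
            raise ValueError("roi_half_width_mm must be positive")
        if self.min_points_for_fit < 2:
            raise ValueError("min_points_for_fit must be >= 2")
        if self.fit not in ("orthogonal", "ols_yx"):
            raise ValueError("fit must be 'orthogonal' or 'ols_yx'")
        if self.seeding not in ("grid", "corners"):
            raise ValueError("seeding must be 'grid' or 'corners'")

    def axial_fraction(self, role: StructureRole) -> float:
        if role is StructureRole.FASCICLE:
            return self.roi_axial_fraction_fascicle
        return self.roi_axial_fraction_aponeurosis

    def window_px(self, spec: FrameSpec) -> int:
        """Block size converted to the nearest odd pixel count >= 3."""
        x = self.block_size_mm / spec.mm_per_px
        w = int(round(x))
        if w % 2 == 0:
            w = w - 1 if (x - (w - 1)) <= ((w + 1) - x) else w + 1
        return max(3, w)


@dataclass(frozen=True)
class OrientedROI:
    """Rectangle aligned with a structure's long axis, mm coordinates."""

    center: tuple[float, float]
    axis: tuple[float, float]
    half_length_mm: float
    half_width_mm: float

    def __post_init__(self) -> None:
        a = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(a)
        if n == 0 or not np.isfinite(n):
            raise ValueError("ROI axis must be a nonzero vector")
        object.__setattr__(self, "axis", tuple(a / n))
        if self.half_length_mm <= 0 or self.half_width_mm <= 0:
            raise ValueError("ROI half extents must be positive")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def axis_arr(self) -> np.ndarray:
        return np.asarray(self.axis, dtype=float)

    @property
    def normal_arr(self) -> np.ndarray:
        ax, ay = self.axis
        return np.array([-ay, ax])

    def corners(self) -> np.ndarray:
        """The four rectangle corners (mm), counter-clockwise."""
        c, a, n = self.center_arr, self.axis_arr, self.normal_arr
        hl, hw = self.half_length_mm, self.half_width_mm
        return np.array(
            [c + hl * a + hw * n, c - hl * a + hw * n,
             c - hl * a - hw * n, c + hl * a - hw * n]
        )

    def local_coords(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float)) - self.center_arr
        return np.column_stack([p @ self.axis_arr, p @ self.normal_arr])

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Exact rotated-rectangle membership test, mm coordinates."""
        uv = self.local_coords(points)
        return (np.abs(uv[:, 0]) <= self.half_length_mm + 1e-12) & (
            np.abs(uv[:, 1]) <= self.half_width_mm + 1e-12
        )

    def pixel_mask(self, spec: FrameSpec) -> np.ndarray:
        """Boolean raster mask of pixels whose centres lie inside the ROI."""
        xs = np.arange(spec.width_px) * spec.mm_per_px
        ys = np.arange(spec.height_px) * spec.mm_per_px
        gx, gy = np.meshgrid(xs, ys)
        pts = np.column_stack([gx.ravel(), gy.ravel()])
        return self.contains(pts).reshape(spec.height_px, spec.width_px)


@dataclass
class PointCloud:
    """Tracked feature points of one structure at one frame (mm)."""

    positions: np.ndarray  # (N, 2)
    valid: np.ndarray  # (N,) bool
    frame_index: int
    structure: StructureRole

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.positions.shape[0] != self.valid.shape[0]:
            raise ValueError("positions and validity flags disagree in length")

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_positions(self) -> np.ndarray:
        return self.positions[self.valid]


@dataclass
class TrackState:
    """Per-structure tracker state after processing a frame."""

    role: StructureRole
    cloud: PointCloud
    line: Line2D
    roi: OrientedROI
    prior_count: int
    reseed_count: int = 0


@dataclass
class TrackingResult:
    """Full-video tracking output."""

    frame_spec: FrameSpec
    lines: list[dict[StructureRole, Line2D]]
    clouds: list[dict[StructureRole, PointCloud]]
    series: MeasurementSeries
    reseed_events: list[tuple[int, StructureRole]] = field(default_factory=list)


def build_roi(segment: Segment2D, axial_fraction: float, half_width_mm: float) -> OrientedROI:
    """Oriented ROI along a drawn segment: centred at the segment midpoint,
    axial extent ``axial_fraction`` of the segment length."""
    if not 0 < axial_fraction <= 1:
        raise ValueError("axial_fraction must be in (0, 1]")
    return OrientedROI(
        center=tuple(segment.midpoint),
        axis=tuple(segment.direction),
        half_length_mm=axial_fraction * segment.length / 2.0,
        half_width_mm=half_width_mm,
    )


def rebalance_intensity(image: np.ndarray, roi: OrientedROI, spec: FrameSpec) -> np.ndarray:
    """Contrast-stretch the pixels inside the ROI; leave the rest untouched.

    The ROI's 1st/99th intensity percentiles are mapped linearly onto the
    dtype's representable range (0..255 for uint8, 0..1 for floats), with
    clipping.  A zero-dynamic-range ROI is returned unchanged.
    """
    mask = roi.pixel_mask(spec)
    if not mask.any():
        raise ValueError("ROI lies entirely outside the image")
    out = image.copy()
    vals = image[mask].astype(np.float64)
    lo, hi = np.percentile(vals, [1.0, 99.0])
    if hi <= lo:
        return out
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        vmin, vmax = float(info.min), float(info.max)
    else:
        vmin, vmax = 0.0, 1.0
    stretched = (vals - lo) / (hi - lo) * (vmax - vmin) + vmin
    stretched = np.clip(stretched, vmin, vmax)
    if np.issubdtype(image.dtype, np.integer):
        stretched = np.round(stretched)
    out[mask] = stretched.astype(image.dtype)
    return out


def _grid_points(roi: OrientedROI, m: int) -> np.ndarray:
    """``m`` points evenly spaced in the ROI's axis/width coordinates.

    The set is exactly symmetric about the ROI axis for any ``m``: a full
    na x nw cell-centre grid, with the remainder placed on the axis
    itself at symmetric positions.  The orthogonal line fit of such a
    cloud therefore reproduces the ROI axis exactly.
    """
    ratio = roi.half_length_mm / roi.half_width_mm
    nw = max(1, int(round(np.sqrt(m / ratio))))
    na = max(1, m // nw)
    if na * nw > m:
        na = m // nw
    r = m - na * nw
    u = (np.arange(na) + 0.5) / na * 2 * roi.half_length_mm - roi.half_length_mm
    v = (np.arange(nw) + 0.5) / nw * 2 * roi.half_width_mm - roi.half_width_mm
    uu, vv = np.meshgrid(u, v)
    local = np.column_stack([uu.ravel(), vv.ravel()])
    if r > 0:
        u_extra = (np.arange(r) + 0.5) / r * 2 * roi.half_length_mm - roi.half_length_mm
        local = np.vstack([local, np.column_stack([u_extra, np.zeros(r)])])
    return roi.center_arr + np.outer(local[:, 0], roi.axis_arr) + np.outer(
        local[:, 1], roi.normal_arr
    )


def seed_points(
    image: np.ndarray,
    roi: OrientedROI,
    n: int,
    spec: FrameSpec,
    config: TrackerConfig | None = None,
    structure: StructureRole = StructureRole.FASCICLE,
    frame_index: int = 0,
) -> PointCloud:
    """Seed up to ``n`` tracking points inside the ROI.

    ``config.seeding`` selects between two readings of "evenly
    distributed, automatically identified ideal points":

    * ``grid`` (default): an even grid over the ROI's axis/width
      coordinates.  The grid is symmetric about the ROI axis, so the
      line refit of a freshly seeded cloud reproduces the drawn line
      exactly; unreliable grid points are weeded out by forward-backward
      validation as tracking proceeds.
    * ``corners``: strongest minimum-eigenvalue responses first (minimum
      mutual spacing of a quarter block size), padded to ``n`` with the
      even grid when fewer corners qualify.  The ordering is
      gain-invariant (relative response threshold).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    config = config or TrackerConfig()
    mask = roi.pixel_mask(spec)
    if not mask.any():
        raise ValueError("ROI has no pixels inside the image")

    if config.seeding == "grid":
        pts = _grid_points(roi, n)
        return PointCloud(
            positions=pts,
            valid=np.ones(pts.shape[0], dtype=bool),
            frame_index=frame_index,
            structure=structure,
        )

    # small integration scale (~5 px filter) so corners on the bright,
    # thin structure bands qualify; a block-sized scale would reject the
    # quasi-1-D bands and scatter seeds over off-structure tissue, whose
    # material shear then biases the fitted line orientation
    response = corner_shi_tomasi(image.astype(np.float64), sigma=1.5)
    min_dist = max(1, config.window_px(spec) // 4)
    resp_max = float(response[mask].max(initial=0.0))
    corner_mm = np.empty((0, 2))
    if resp_max > 0:
        peaks = peak_local_max(
            np.where(mask, response, 0.0),
            min_distance=min_dist,
            threshold_abs=1e-6 * resp_max,
            num_peaks=n,
        )  # (k, 2) array of (row, col), strongest first
        if peaks.size:
            pk_mm = peaks[:, ::-1].astype(float) * spec.mm_per_px
            inside = roi.contains(pk_mm)
            corner_mm = pk_mm[inside][:n]
    if corner_mm.shape[0] < n:
        pad = _grid_points(roi, n - corner_mm.shape[0])
        pts = np.vstack([corner_mm, pad]) if corner_mm.size else pad
    else:
        pts = corner_mm
    return PointCloud(
        positions=pts,
        valid=np.ones(pts.shape[0], dtype=bool),
        frame_index=frame_index,
        structure=structure,
    )


def _as_pyramid(image_or_pyr, levels: int) -> ImagePyramid:
    if isinstance(image_or_pyr, ImagePyramid):
        return image_or_pyr
    return ImagePyramid(np.asarray(image_or_pyr), levels)


def track_step(
    prev_image,
    next_image,
    points: PointCloud,
    config: TrackerConfig,
    spec: FrameSpec,
) -> PointCloud:
    """Propagate a point cloud one frame forward.

    Each valid input point is tracked by pyramidal Lucas-Kanade flow and
    then re-tracked backward; the point is invalidated if the tracker
    fails, the point leaves the frame, or the backward re-track lands
    more than ``fb_error_mm`` from the starting position.  Total
    function: failures are carried in the validity flags.
    """
    prev_pyr = _as_pyramid(prev_image, config.pyramid_levels)
    next_pyr = _as_pyramid(next_image, config.pyramid_levels)
    window = config.window_px(spec)

    new_positions = points.positions.copy()
    new_valid = points.valid.copy()
    idx = np.flatnonzero(points.valid)
    if idx.size:
        pts_px = points.positions[idx] / spec.mm_per_px
        fwd_px, ok_f = track_points(prev_pyr, next_pyr, pts_px, window, config.max_iterations)
        back_px, ok_b = track_points(next_pyr, prev_pyr, fwd_px, window, config.max_iterations)
        fb_mm = np.linalg.norm(back_px - pts_px, axis=1) * spec.mm_per_px
        fwd_mm = fwd_px * spec.mm_per_px
        in_frame = spec.contains_mm(fwd_mm)
        ok = ok_f & ok_b & in_frame & (fb_mm <= config.fb_error_mm)
        new_positions[idx] = fwd_mm
        new_valid[idx] = ok
    return PointCloud(
        positions=new_positions,
        valid=new_valid,
        frame_index=points.frame_index + 1,
        structure=points.structure,
    )


def update_structure(
    state: TrackState,
    new_cloud: PointCloud,
    image: np.ndarray,
    config: TrackerConfig,
    spec: FrameSpec,
) -> TrackState:
    """Discard invalid points, refit the structure line, and reseed when
    attrition exceeds the 10% rule.

    Reseeding rebuilds the ROI around the refitted line (keeping the prior
    ROI's axial extent) and seeds ``n_seed_points`` fresh points in the
    current frame.  Losing every point is fatal.
    """
    survivors = new_cloud.valid_positions
    n_prior = state.prior_count
    n_lost = n_prior - survivors.shape[0]
    if survivors.shape[0] == 0:
        raise TrackingLostError(state.role, new_cloud.frame_index)

    line = state.line
    if survivors.shape[0] >= 2:
        try:
            line = fit_line(survivors, method=config.fit)
        except DegenerateGeometryError:
            pass  # keep the prior line

    need_reseed = (n_lost > config.reseed_fraction * n_prior) or (
        survivors.shape[0] < config.min_points_for_fit
    )
    roi = state.roi
    cloud = PointCloud(
        positions=survivors,
        valid=np.ones(survivors.shape[0], dtype=bool),
        frame_index=new_cloud.frame_index,
        structure=state.role,
    )
    reseeds = state.reseed_count
    if need_reseed:
        # re-anchor the ROI on the refitted line, same axial extent
        foot = line.anchor_arr + (
            (state.roi.center_arr - line.anchor_arr) @ line.direction_arr
        ) * line.direction_arr
        axis = line.direction_arr
        if axis @ state.roi.axis_arr < 0:
            axis = -axis
        roi = OrientedROI(
            center=tuple(foot),
            axis=tuple(axis),
            half_length_mm=state.roi.half_length_mm,
            half_width_mm=state.roi.half_width_mm,
        )
        img = image
        if state.role is StructureRole.DEEP_APONEUROSIS:
            img = rebalance_intensity(image, roi, spec)
        cloud = seed_points(
            img, roi, config.n_seed_points, spec, config,
            structure=state.role, frame_index=new_cloud.frame_index,
        )
        reseeds += 1
        logger.info(
            "reseeded %s at frame %d (%d of %d points lost)",
            state.role.value, new_cloud.frame_index, n_lost, n_prior,
        )
    return TrackState(
        role=state.role,
        cloud=cloud,
        line=line,
        roi=roi,
        prior_count=cloud.positions.shape[0],
        reseed_count=reseeds,
    )


def _measure_frame(
    lines: dict[StructureRole, Line2D],
    counts: dict[StructureRole, int],
    frame_index: int,
    spec: FrameSpec,
) -> FascicleMeasurement:
    from .geometry import intersect  # local import keeps module surface tidy

    fas = lines[StructureRole.FASCICLE]
    sup = lines[StructureRole.SUPERFICIAL_APONEUROSIS]
    deep = lines[StructureRole.DEEP_APONEUROSIS]
    p_sup = intersect(fas, sup, names=("fascicle", "superficial aponeurosis"))
    p_deep = intersect(fas, deep, names=("fascicle", "deep aponeurosis"))
    return FascicleMeasurement(
        frame_index=frame_index,
        time_s=frame_index / spec.frame_rate_hz,
        length_mm=float(np.linalg.norm(p_sup - p_deep)),
        pennation_deg=pennation_angle(fas, deep),
        superficial_extrapolated=not bool(spec.contains_mm(p_sup)[0]),
        deep_extrapolated=not bool(spec.contains_mm(p_deep)[0]),
        n_valid_sup=counts[StructureRole.SUPERFICIAL_APONEUROSIS],
        n_valid_deep=counts[StructureRole.DEEP_APONEUROSIS],
        n_valid_fas=counts[StructureRole.FASCICLE],
    )


def track_video(
    frames,
    annotations: dict[StructureRole, Segment2D],
    config: TrackerConfig,
    spec: FrameSpec,
    metadata: dict[str, str] | None = None,
) -> TrackingResult:
    """Track all three structures through a video and measure every frame.

    Frame 0 geometry comes directly from the drawn annotations; every
    subsequent frame runs the optical-flow step and the attrition logic
    per structure.  Deterministic for fixed inputs and configuration.
    """
    frames = [np.asarray(f) for f in frames]
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    shape = frames[0].shape
    for i, f in enumerate(frames):
        if f.ndim != 2:
            raise ValueError(f"frame {i} is not grayscale")
        if f.shape != shape:
            raise ValueError(f"frame {i} shape {f.shape} != frame 0 shape {shape}")
    if shape != (spec.height_px, spec.width_px):
        raise ValueError("frame shape disagrees with FrameSpec")
    missing = [r for r in StructureRole if r not in annotations]
    if missing:
        raise ValueError(f"missing annotation for roles: {[r.value for r in missing]}")

    # --- frame 0: lines from the drawn segments, seed point clouds
    states: dict[StructureRole, TrackState] = {}
    for role, seg in annotations.items():
        line = fit_line(seg.endpoints, method=config.fit)
        roi = build_roi(seg, config.axial_fraction(role), config.roi_half_width_mm)
        img0 = frames[0]
        if role is StructureRole.DEEP_APONEUROSIS:
            img0 = rebalance_intensity(frames[0], roi, spec)
        cloud = seed_points(
            img0, roi, config.n_seed_points, spec, config,
            structure=role, frame_index=0,
        )
        states[role] = TrackState(
            role=role, cloud=cloud, line=line, roi=roi,
            prior_count=cloud.positions.shape[0],
        )

    all_lines = [{r: s.line for r, s in states.items()}]
    all_clouds = [{r: s.cloud for r, s in states.items()}]
    measurements = [
        _measure_frame(
            all_lines[0], {r: s.cloud.n_valid for r, s in states.items()}, 0, spec
        )
    ]
    reseed_events: list[tuple[int, StructureRole]] = []

    prev_raw = ImagePyramid(frames[0], config.pyramid_levels)
    for t in range(1, len(frames)):
        next_raw = ImagePyramid(frames[t], config.pyramid_levels)
        for role in StructureRole:
            st = states[role]
            if role is StructureRole.DEEP_APONEUROSIS:
                prev_img = rebalance_intensity(frames[t - 1], st.roi, spec)
                next_img = rebalance_intensity(frames[t], st.roi, spec)
                prev_pyr = ImagePyramid(prev_img, config.pyramid_levels)
                next_pyr = ImagePyramid(next_img, config.pyramid_levels)
            else:
                prev_pyr, next_pyr = prev_raw, next_raw
            stepped = track_step(prev_pyr, next_pyr, st.cloud, config, spec)
            before = st.reseed_count
            states[role] = update_structure(st, stepped, frames[t], config, spec)
            if states[role].reseed_count > before:
                reseed_events.append((t, role))
        all_lines.append({r: s.line for r, s in states.items()})
        all_clouds.append({r: s.cloud for r, s in states.items()})
        measurements.append(
            _measure_frame(
                all_lines[-1], {r: s.cloud.n_valid for r, s in states.items()}, t, spec
            )
        )
        prev_raw = next_raw

    meta = dict(metadata or {})
    meta.setdefault("method", "automatic")
    return TrackingResult(
        frame_spec=spec,
        lines=all_lines,
        clouds=all_clouds,
        series=MeasurementSeries(measurements, metadata=meta),
        reseed_events=reseed_events,
    )
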