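"""Synthetic speckle phantom: ultrasound-like video with exact ground truth.

Renders a pennate-muscle scene — two bright near-horizontal aponeurosis
bands and a family of oblique bright fascicle bands between them — with
prescribed fascicle-length L(t) and pennation theta(t) trajectories.
The superficial aponeurosis depth is derived from the deep aponeurosis,
L and theta so that the perpendicular separation d(t) = L(t) sin theta(t)
holds exactly; the emitted ground-truth lines therefore reproduce L and
theta identically through the measurement geometry.

Two oblique streak families (sparse prominent fascicles over fine
perimysial texture) are anchored at fixed attachment points on the deep
aponeurosis and rotate about them as theta changes, so band texture is
advected consistently with the shortening tissue.  Rendering adds a
Gaussian blur, mean-one multiplicative lognormal speckle and additive
Gaussian noise — enough texture and noise to exercise a gradient-based
tracker, not a physical acoustics simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .geometry import FrameSpec, Line2D, Segment2D, StructureRole

__all__ = [
    "SpeckleConfig",
    "KinematicProfile",
    "PhantomConfig",
    "GroundTruthSeries",
    "PhantomVideo",
    "kinematics",
    "render_frame",
    "generate",
]

#: physiological bounds enforced on the pennation trajectory (degrees)
THETA_BOUNDS = (5.0, 80.0)

_DEFAULT_SPEC = FrameSpec(
    width_px=512, height_px=512, mm_per_px=60.0 / 512, frame_rate_hz=60.0
)


@dataclass(frozen=True)
class SpeckleConfig:
    """Rendering noise model (intensities in [0, 1]).

    The default model is bright structural bands under a blur, a
    per-frame mean-one multiplicative lognormal speckle factor and
    additive Gaussian electronic noise.  ``coherent_amplitude``
    optionally adds a tissue-attached speckle texture advected with the
    material motion (off by default), for experiments where a coherent
    background matters.
    """

    gaussian_blur_sigma_px: float = 1.0
    coherent_amplitude: float = 0.0
    multiplicative_noise_sd: float = 0.15
    additive_noise_sd: float = 0.02


@dataclass(frozen=True)
class KinematicProfile:
    """Scalar trajectory over the video.

    kind:
      * ``linear_ramp`` — start -> end linearly over all frames;
      * ``ramp_hold`` — ramp over the first half, hold at ``end`` after
        (isometric-like);
      * ``tabulated`` — explicit per-frame values.
    """

    kind: str = "linear_ramp"
    start: float = 0.0
    end: float = 0.0
    values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("linear_ramp", "ramp_hold", "tabulated"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.kind == "tabulated" and not self.values:
            raise ValueError("tabulated profile requires values")

    def at(self, t: int, n_frames: int) -> float:
        if self.kind == "tabulated":
            return float(self.values[t])
        f = 0.0 if n_frames <= 1 else t / (n_frames - 1)
        if self.kind == "ramp_hold":
            f = min(2.0 * f, 1.0)
        return self.start + (self.end - self.start) * f


@dataclass(frozen=True)
class PhantomConfig:
    """Phantom scene and kinematics.

    Defaults emulate a 6 cm linear-array field of view imaged at
    60 frames/s over the mid-belly of a pennate calf muscle: deep
    aponeurosis at 45 mm depth, prominent fascicle streaks attached every
    12 mm along it over fine perimysial streaks every 2 mm, and the
    candidate fascicle attached at x = 58 mm so its superficial end stays
    in view for lengths up to ~60 mm.
    """

    frame_spec: FrameSpec = _DEFAULT_SPEC
    n_frames: int = 120
    deep_depth_mm: float = 45.0
    deep_slope_deg: float = 0.0
    fascicle_x_mm: float = 58.0
    fascicle_spacing_mm: float = 12.0
    fine_spacing_mm: float = 2.0
    band_width_mm: float = 1.2
    length_profile: KinematicProfile = field(
        default_factory=lambda: KinematicProfile("linear_ramp", 60.0, 40.0)
    )
    pennation_profile: KinematicProfile = field(
        default_factory=lambda: KinematicProfile("linear_ramp", 20.0, 35.0)
    )
    speckle: SpeckleConfig = field(default_factory=SpeckleConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.fascicle_spacing_mm <= 0 or self.band_width_mm <= 0:
            raise ValueError("band geometry must be positive")
        for t in range(self.n_frames):
            theta = self.pennation_profile.at(t, self.n_frames)
            length = self.length_profile.at(t, self.n_frames)
            if not THETA_BOUNDS[0] < theta < THETA_BOUNDS[1]:
                raise ValueError(
                    f"pennation {theta:.2f} deg at frame {t} outside "
                    f"({THETA_BOUNDS[0]}, {THETA_BOUNDS[1]})"
                )
            if length <= 0:
                raise ValueError(f"non-positive fascicle length at frame {t}")


@dataclass
class GroundTruthSeries:
    """Analytically exact per-frame kinematics (no rendering noise)."""

    length_mm: np.ndarray
    pennation_deg: np.ndarray
    deep_lines: list[Line2D]
    sup_lines: list[Line2D]
    fascicle_lines: list[Line2D]

    def __len__(self) -> int:
        return len(self.length_mm)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": np.arange(len(self.length_mm)),
                "L_true_mm": self.length_mm,
                "theta_true_deg": self.pennation_deg,
            }
        )


@dataclass
class PhantomVideo:
    """Rendered frames plus exact truth and a first-frame annotation."""

    frames: np.ndarray  # (T, H, W) uint8
    truth: GroundTruthSeries
    annotation: dict[StructureRole, Segment2D]
    frame_spec: FrameSpec


def _deep_frame_vectors(config: PhantomConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deep-aponeurosis anchor, unit direction, and unit normal (into depth)."""
    phi = np.radians(config.deep_slope_deg)
    anchor = np.array([0.0, config.deep_depth_mm])
    direction = np.array([np.cos(phi), np.sin(phi)])
    normal = np.array([-np.sin(phi), np.cos(phi)])  # points deeper
    return anchor, direction, normal


def kinematics(config: PhantomConfig, t: int) -> tuple[float, float, Line2D, Line2D]:
    """True (L, theta, deep line, superficial line) at frame ``t``.

    The superficial aponeurosis is the deep line shifted toward the probe
    by d(t) = L(t) sin theta(t), so length and pennation recomputed from
    the emitted lines reproduce the profiles exactly.
    """
    if not 0 <= t < config.n_frames:
        raise IndexError(f"frame {t} outside [0, {config.n_frames})")
    length = config.length_profile.at(t, config.n_frames)
    theta = config.pennation_profile.at(t, config.n_frames)
    anchor, direction, normal = _deep_frame_vectors(config)
    d = length * np.sin(np.radians(theta))
    deep = Line2D(anchor=tuple(anchor), direction=tuple(direction))
    sup = Line2D(anchor=tuple(anchor - d * normal), direction=tuple(direction))
    return float(length), float(theta), deep, sup


def _fascicle_line(config: PhantomConfig, t: int) -> Line2D:
    length, theta, deep, _ = kinematics(config, t)
    anchor, direction, normal = _deep_frame_vectors(config)
    p_deep = anchor + config.fascicle_x_mm * direction
    th = np.radians(theta)
    fas_dir = -np.cos(th) * direction - np.sin(th) * normal  # toward probe
    return Line2D(anchor=tuple(p_deep), direction=tuple(fas_dir))


_SPECKLE_TEX_PX = 1024
_SPECKLE_PX_PER_MM = 4.0


def _speckle_texture(seed: int) -> np.ndarray:
    """Static random texture (zero mean, unit sd) sampled in material
    coordinates to render tissue-attached speckle."""
    rng = np.random.default_rng((seed * 7_368_787 + 3) % 2**31)
    tex = gaussian_filter(
        rng.standard_normal((_SPECKLE_TEX_PX, _SPECKLE_TEX_PX)), 2.0, mode="wrap"
    )
    return tex / tex.std()


def _sample_wrap(tex: np.ndarray, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Bilinear sampling of a periodically tiled texture; u, v in texture px."""
    n = tex.shape[0]
    u0 = np.floor(u).astype(np.int64)
    v0 = np.floor(v).astype(np.int64)
    fu, fv = u - u0, v - v0
    u0 %= n
    v0 %= n
    u1 = (u0 + 1) % n
    v1 = (v0 + 1) % n
    t00 = tex[v0, u0]
    t01 = tex[v0, u1]
    t10 = tex[v1, u0]
    t11 = tex[v1, u1]
    return (t00 * (1 - fu) + t01 * fu) * (1 - fv) + (t10 * (1 - fu) + t11 * fu) * fv


def _texture(rng: np.random.Generator, n_components: int = 6) -> callable:
    """Smooth 1-D multiplicative texture: fixed random Fourier series."""
    amps = rng.uniform(0.05, 0.12, n_components)
    wavelengths = rng.uniform(2.0, 12.0, n_components)  # mm
    phases = rng.uniform(0, 2 * np.pi, n_components)

    def tex(s: np.ndarray) -> np.ndarray:
        out = np.ones_like(s)
        for a, lam, ph in zip(amps, wavelengths, phases):
            out = out + a * np.cos(2 * np.pi * s / lam + ph)
        return out

    return tex


def render_frame(config: PhantomConfig, t: int) -> np.ndarray:
    """Render frame ``t`` as an 8-bit grayscale image.

    Deterministic given ``config.seed`` and ``t``; the structural texture
    is drawn once from the seed (shared by all frames) while the noise
    realisation is per-frame.
    """
    spec = config.frame_spec
    length, theta, _, _ = kinematics(config, t)
    anchor, direction, normal = _deep_frame_vectors(config)
    d = length * np.sin(np.radians(theta))

    xs = np.arange(spec.width_px) * spec.mm_per_px
    ys = np.arange(spec.height_px) * spec.mm_per_px
    gx, gy = np.meshgrid(xs, ys)
    px = np.stack([gx - anchor[0], gy - anchor[1]], axis=-1)
    xi = px @ direction  # along the deep aponeurosis
    eta = px @ normal  # signed depth relative to it (negative toward probe)

    tex_rng = np.random.default_rng((config.seed * 2_000_003 + 17) % 2**31)
    tex_deep = _texture(tex_rng)
    tex_sup = _texture(tex_rng)

    # region base echogenicity: subcutaneous tissue above the superficial
    # aponeurosis is bright, muscle tissue between the aponeuroses is dark
    # (fascicle streaks carry the echoes), tissue below the deep
    # aponeurosis is intermediate
    tau = 0.6
    w_deep_region = np.clip(eta / tau + 0.5, 0, 1)
    w_skin_region = np.clip((-eta - d) / tau + 0.5, 0, 1)
    w_muscle_region = np.clip(1.0 - w_deep_region - w_skin_region, 0, 1)
    sigma_apo = config.band_width_mm / 2.0
    img = 0.30 * w_skin_region + 0.10 * w_muscle_region + 0.15 * w_deep_region
    img += 0.85 * np.exp(-(eta**2) / (2 * sigma_apo**2)) * tex_deep(xi)
    img += 0.85 * np.exp(-((eta + d) ** 2) / (2 * sigma_apo**2)) * tex_sup(xi)

    # two oblique streak families between the aponeuroses, attachments
    # fixed on the deep aponeurosis so the bands rotate about them as
    # theta changes: sparse prominent fascicle streaks (the examiner
    # annotates one of these; the candidate passes through fascicle_x_mm)
    # over a dense family of fine perimysial streaks
    th = np.radians(theta)
    attach = xi - eta / np.tan(th)

    def band_family(spacing: float, width_sigma: float, x0: float) -> np.ndarray:
        pos = (attach - x0) / spacing
        frac = pos - np.round(pos)
        dist_perp = frac * spacing * np.sin(th)
        return np.exp(-(dist_perp**2) / (2 * width_sigma**2))

    sigma_fas = config.band_width_mm / 2.0
    fas = 0.5 * band_family(config.fascicle_spacing_mm, sigma_fas, config.fascicle_x_mm)
    fas += 0.22 * band_family(
        config.fine_spacing_mm, sigma_fas / 2.0,
        config.fascicle_x_mm + config.fine_spacing_mm / 2.0,
    )
    margin, taper = 0.8, 0.8
    between = np.clip((-eta - margin) / taper, 0, 1) * np.clip(
        (eta + d - margin) / taper, 0, 1
    )
    img += fas * between

    # tissue-attached coherent speckle, advected with the material motion:
    # the muscle region follows the fascicle material coordinates
    # (attachment, fractional position along the fascicle), the layer
    # superficial to the upper aponeurosis rides on that aponeurosis, and
    # the region below the deep aponeurosis is stationary
    amp_c = config.speckle.coherent_amplitude
    if amp_c > 0:
        tex = _speckle_texture(config.seed)
        k = _SPECKLE_PX_PER_MM
        mu = -eta / (length * np.sin(th))
        s_muscle = _sample_wrap(tex, attach * k, mu * 50.0 * k)
        s_skin = _sample_wrap(tex, xi * k + 300.0, (eta + d) * k + 300.0)
        s_deep = _sample_wrap(tex, xi * k + 700.0, eta * k + 700.0)
        # speckle in the contracting muscle decorrelates through-plane
        # (fibres cross the imaging plane), so only the stationary
        # subcutaneous and deep layers keep a coherent component; the
        # muscle's trackable echoes are the material fascicle bands
        s = w_deep_region * s_deep + w_skin_region * s_skin
        img = img * np.clip(1.0 + amp_c * s, 0.0, None)

    if config.speckle.gaussian_blur_sigma_px > 0:
        img = gaussian_filter(img, config.speckle.gaussian_blur_sigma_px, mode="nearest")
    rng = np.random.default_rng((config.seed * 1_000_003 + t) % 2**31)
    sd_m = config.speckle.multiplicative_noise_sd
    if sd_m > 0:
        img = img * rng.lognormal(mean=-(sd_m**2) / 2, sigma=sd_m, size=img.shape)
    if config.speckle.additive_noise_sd > 0:
        img = img + rng.normal(0.0, config.speckle.additive_noise_sd, size=img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def _annotation(
    config: PhantomConfig,
    jitter_mm: float = 0.0,
    jitter_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[StructureRole, Segment2D]:
    """First-frame segments lying exactly on the true structures, optionally
    jittered (translation sd in mm, rotation sd in degrees about the
    midpoint) to simulate examiner variability."""
    spec = config.frame_spec
    length, theta, deep, sup = kinematics(config, 0)
    anchor, direction, normal = _deep_frame_vectors(config)
    s0, s1 = 0.1 * spec.width_mm, 0.9 * spec.width_mm
    p_deep_attach = anchor + config.fascicle_x_mm * direction
    fas_dir = _fascicle_line(config, 0).direction_arr
    if fas_dir[1] > 0:
        fas_dir = -fas_dir  # point toward the probe
    segments = {
        StructureRole.DEEP_APONEUROSIS: (deep.point_at(s0), deep.point_at(s1)),
        StructureRole.SUPERFICIAL_APONEUROSIS: (sup.point_at(s0), sup.point_at(s1)),
        StructureRole.FASCICLE: (p_deep_attach, p_deep_attach + length * fas_dir),
    }
    out: dict[StructureRole, Segment2D] = {}
    for role, (p0, p1) in segments.items():
        p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
        if rng is not None and (jitter_mm > 0 or jitter_deg > 0):
            shift = rng.normal(0.0, jitter_mm, 2) if jitter_mm > 0 else np.zeros(2)
            ang = np.radians(rng.normal(0.0, jitter_deg)) if jitter_deg > 0 else 0.0
            mid = (p0 + p1) / 2
            c, s = np.cos(ang), np.sin(ang)
            rot = np.array([[c, -s], [s, c]])
            p0 = mid + rot @ (p0 - mid) + shift
            p1 = mid + rot @ (p1 - mid) + shift
        out[role] = Segment2D(p0=tuple(p0), p1=tuple(p1))
    return out


def make_annotation(
    config: PhantomConfig,
    jitter_mm: float = 0.0,
    jitter_deg: float = 0.0,
    rng: np.random.Generator | None = None,
) -> dict[StructureRole, Segment2D]:
    """First-frame annotation on the true structures, optionally jittered
    (translation sd mm, rotation sd degrees) to emulate a different
    examiner's drawing of the same structures."""
    return _annotation(config, jitter_mm, jitter_deg, rng)


def generate(
    config: PhantomConfig,
    annotation_jitter_mm: float = 0.0,
    annotation_jitter_deg: float = 0.0,
) -> PhantomVideo:
    """Render the full phantom video with its ground truth and a
    first-frame annotation (jitter sd 0 gives a perfect examiner)."""
    frames = np.stack([render_frame(config, t) for t in range(config.n_frames)])
    lengths, thetas = [], []
    deep_lines, sup_lines, fas_lines = [], [], []
    for t in range(config.n_frames):
        length, theta, deep, sup = kinematics(config, t)
        lengths.append(length)
        thetas.append(theta)
        deep_lines.append(deep)
        sup_lines.append(sup)
        fas_lines.append(_fascicle_line(config, t))
    rng = np.random.default_rng((config.seed * 3_000_017 + 5) % 2**31)
    annotation = _annotation(config, annotation_jitter_mm, annotation_jitter_deg, rng)
    truth = GroundTruthSeries(
        length_mm=np.array(lengths),
        pennation_deg=np.array(thetas),
        deep_lines=deep_lines,
        sup_lines=sup_lines,
        fascicle_lines=fas_lines,
    )
    return PhantomVideo(
        frames=frames, truth=truth, annotation=annotation, frame_spec=config.frame_spec
    )
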