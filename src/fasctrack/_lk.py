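"""Pyramidal Kanade–Lucas–Tomasi sparse point tracking.

Implements the classic coarse-to-fine iterative Lucas–Kanade scheme
(Bouguet-style): spatial gradients are evaluated once per pyramid level
on the template (previous) image window; the displacement is refined by
Gauss–Newton iterations against the target (next) image, then propagated
to the next finer level with doubled magnitude.  All point windows at a
level are processed in one vectorised batch.

Pixel coordinates throughout; callers convert mm <-> px.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["ImagePyramid", "track_points"]

#: convergence threshold on the per-iteration update, pixels at the
#: current pyramid level
_EPS_PX = 0.03

#: Tikhonov floor added to the structure tensor so flat (aperture-limited)
#: windows yield a near-zero update instead of a numerical blow-up
_REG_FRACTION = 1e-8


class ImagePyramid:
    """Gaussian pyramid of one frame plus per-level spatial gradients.

    Built once per frame and reused for every structure and for both the
    forward and backward tracking passes of a frame pair.
    """

    def __init__(self, image: np.ndarray, levels: int):
        img = np.ascontiguousarray(image, dtype=np.float64)
        if img.ndim != 2:
            raise ValueError("expected a 2-D grayscale image")
        # prefilter before differentiation: uncorrelated pixel noise in the
        # gradients otherwise shrinks every flow update (errors-in-variables
        # attenuation), which accumulates into systematic tracking lag
        img = gaussian_filter(img, sigma=1.0, mode="nearest")
        self.levels: list[np.ndarray] = [img]
        for _ in range(levels - 1):
            prev = self.levels[-1]
            if min(prev.shape) < 8:
                break  # stop rather than degenerate to a few pixels
            smoothed = gaussian_filter(prev, sigma=1.0, mode="nearest")
            self.levels.append(np.ascontiguousarray(smoothed[::2, ::2]))
        self.grads: list[tuple[np.ndarray, np.ndarray]] = []
        for lv in self.levels:
            gy, gx = np.gradient(lv)
            self.grads.append((gx, gy))

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels[0].shape


def _sample(img: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
    """Bilinear sampling with edge clamping (vectorised gather)."""
    h, w = img.shape
    x = np.clip(xs, 0.0, w - 1.0)
    y = np.clip(ys, 0.0, h - 1.0)
    x0 = np.minimum(x.astype(np.int64), w - 2)
    y0 = np.minimum(y.astype(np.int64), h - 2)
    fx = x - x0
    fy = y - y0
    flat = img.ravel()
    base = y0 * w + x0
    v00 = flat[base]
    v01 = flat[base + 1]
    v10 = flat[base + w]
    v11 = flat[base + w + 1]
    top = v00 + fx * (v01 - v00)
    bot = v10 + fx * (v11 - v10)
    return top + fy * (bot - top)


def track_points(
    prev: ImagePyramid,
    nxt: ImagePyramid,
    points_px: np.ndarray,
    window_px: int,
    max_iterations: int = 30,
) -> tuple[np.ndarray, np.ndarray]:
    """Track points from ``prev`` to ``nxt``.

    Parameters
    ----------
    prev, nxt : ImagePyramid
        Pyramids of the two frames (same raster shape).
    points_px : (N, 2) float array
        Point positions (x, y) in pixels of the full-resolution frame.
    window_px : int
        Odd side length of the square integration window, full-resolution
        pixels; the same window is used at every level.
    max_iterations : int
        Cap on Gauss-Newton iterations per pyramid level.

    Returns
    -------
    new_points : (N, 2) float array
        Tracked positions (x, y), full-resolution pixels.
    ok : (N,) bool array
        False where the track failed outright (non-finite result or the
        point landed outside the raster).  Forward-backward validation is
        the caller's responsibility.
    """
    pts = np.atleast_2d(np.asarray(points_px, dtype=np.float64))
    n = pts.shape[0]
    if n == 0:
        return pts.copy(), np.zeros(0, dtype=bool)
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    n_levels = min(prev.n_levels, nxt.n_levels)

    half = window_px // 2
    dy, dx = np.mgrid[-half : half + 1, -half : half + 1]
    off_x = dx.ravel()[None, :]  # (1, w*w)
    off_y = dy.ravel()[None, :]

    g = np.zeros((n, 2))  # displacement guess carried across levels
    for level in range(n_levels - 1, -1, -1):
        scale = 2.0**level
        p_l = pts / scale
        img_prev = prev.levels[level]
        gx_img, gy_img = prev.grads[level]
        img_next = nxt.levels[level]

        tx = p_l[:, 0:1] + off_x  # template sampling grid, (N, w*w)
        ty = p_l[:, 1:2] + off_y
        patch = _sample(img_prev, ty, tx)
        ix = _sample(gx_img, ty, tx)
        iy = _sample(gy_img, ty, tx)

        g11 = np.einsum("ij,ij->i", ix, ix)
        g12 = np.einsum("ij,ij->i", ix, iy)
        g22 = np.einsum("ij,ij->i", iy, iy)
        reg = _REG_FRACTION * (g11 + g22) + 1e-30
        g11 = g11 + reg
        g22 = g22 + reg
        det = g11 * g22 - g12 * g12

        d = np.zeros((n, 2))
        active = np.ones(n, dtype=bool)
        for _ in range(max_iterations):
            idx = np.flatnonzero(active)
            if idx.size == 0:
                break
            qx = tx[idx] + (g[idx, 0:1] + d[idx, 0:1])
            qy = ty[idx] + (g[idx, 1:2] + d[idx, 1:2])
            target = _sample(img_next, qy, qx)
            r = patch[idx] - target
            b1 = np.einsum("ij,ij->i", ix[idx], r)
            b2 = np.einsum("ij,ij->i", iy[idx], r)
            nu_x = (g22[idx] * b1 - g12[idx] * b2) / det[idx]
            nu_y = (g11[idx] * b2 - g12[idx] * b1) / det[idx]
            d[idx, 0] += nu_x
            d[idx, 1] += nu_y
            still = np.hypot(nu_x, nu_y) > _EPS_PX
            active[idx] = still
        g = 2.0 * (g + d) if level > 0 else (g + d)

    new_pts = pts + g
    h, w = prev.shape
    ok = (
        np.all(np.isfinite(new_pts), axis=1)
        & (new_pts[:, 0] >= 0)
        & (new_pts[:, 0] <= w - 1)
        & (new_pts[:, 1] >= 0)
        & (new_pts[:, 1] <= h - 1)
    )
    return new_pts, ok
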