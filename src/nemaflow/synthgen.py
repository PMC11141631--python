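"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage (orientation extraction, order statistics, PIV,
tracking, defect detection) is testable against these generators without
external microscopy data.  They emulate, at the level of statistics rather
than photorealism:

* director fields of controllable nematic order and correlation length,
* analytic fields containing planted +-1/2 topological defects,
* filament-textured images (actin-like) following a director field,
* image pairs displaced by a known flow (PIV ground truth),
* nuclei time-lapse movies from a biased persistent random walk with
  logistic density growth and density-dependent slowdown.

All randomness flows through explicit seeds; identical parameters produce
bit-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from ._angles import wrap_nematic, wrap_directional
from .fields import OrientationField

__all__ = [
    "SyntheticSpec",
    "gen_uniform_field",
    "gen_correlated_field",
    "gen_defect_field",
    "gen_filament_image",
    "gen_displaced_pair",
    "gen_growth_tracks",
]


@dataclass
class SyntheticSpec:
    """Parameter bundle for the nuclei-movie generator.

    Units: image_shape in pixels, pixel_size in um/px, frame_interval in
    hours, carrying_capacity in cells/mm^2, growth_rate in 1/h, speed in
    um/h.  ``bias`` >= 0 pulls step directions toward the 0 deg director
    (np.inf = deterministic steps along the director); ``persistence`` in
    [0, 1) weights the previous heading.
    """

    image_shape: Tuple[int, int] = (256, 256)
    pixel_size: float = 1.3
    seed: int = 0
    n_frames: int = 48
    frame_interval: float = 1.0
    initial_cells: int = 60
    carrying_capacity: float = 4000.0
    growth_rate: float = 0.12
    speed: float = 15.0
    persistence: float = 0.5
    bias: float = 0.0
    nucleus_sigma_um: float = 4.0
    speed_density_slowdown: float = 0.6
    min_separation_um: float = 15.0   # excluded volume at seeding/birth
    seed_margin_um: float = 0.0       # keep initial cells away from the border

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.image_shape[0] < 64 or self.image_shape[1] < 64:
            raise ValueError("image_shape must be at least 64x64")
        for name in ("frame_interval", "carrying_capacity", "growth_rate", "speed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.bias < 0 or self.persistence < 0 or self.persistence >= 1:
            raise ValueError("bias >= 0 and persistence in [0, 1) required")

    def to_json(self, path):
        d = asdict(self)
        d["image_shape"] = list(self.image_shape)
        d["bias"] = "inf" if np.isinf(self.bias) else self.bias
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticSpec":
        with open(path) as fh:
            d = json.load(fh)
        d["image_shape"] = tuple(d["image_shape"])
        if d.get("bias") == "inf":
            d["bias"] = np.inf
        return cls(**d)


# ---------------------------------------------------------------------------
# director fields
# ---------------------------------------------------------------------------

def gen_uniform_field(shape, theta0, grid_size=1.0, pixel_size=1.0) -> OrientationField:
    """Perfectly ordered field: every angle equals ``theta0`` (degrees)."""
    if not (-90.0 < theta0 <= 90.0):
        raise ValueError("theta0 must lie in the nematic range (-90, 90]")
    theta = np.full(shape, float(theta0))
    return OrientationField(theta, np.ones(shape), np.ones(shape, bool),
                            grid_size, pixel_size)


def gen_correlated_field(shape, smoothing_scale, seed, grid_size=1.0,
                         pixel_size=1.0) -> OrientationField:
    """Random nematic field with tunable correlation length.

    Two independent unit-variance Gaussian noise fields are interpreted as
    the components (cos 2theta, sin 2theta) of the doubled-angle order
    tensor, smoothed with an isotropic Gaussian of scale ``smoothing_scale``
    (grid units, periodic boundary so the field is stationary), and the
    angle recovered as half the argument.  This guarantees valid nematic
    angles at every point; the correlation length grows monotonically with
    the smoothing scale but the map between the two is empirical, not
    analytic.
    """
    if smoothing_scale < 0:
        raise ValueError("smoothing_scale must be >= 0")
    rng = np.random.default_rng(seed)
    c = rng.standard_normal(shape)
    s = rng.standard_normal(shape)
    if smoothing_scale > 0:
        c = ndimage.gaussian_filter(c, smoothing_scale, mode="wrap")
        s = ndimage.gaussian_filter(s, smoothing_scale, mode="wrap")
    theta = 0.5 * np.degrees(np.arctan2(s, c))
    theta = wrap_nematic(theta)
    return OrientationField(theta, np.ones(shape), np.ones(shape, bool),
                            grid_size, pixel_size)


def gen_defect_field(shape, defect_list, theta0=0.0, grid_size=1.0,
                     pixel_size=1.0) -> OrientationField:
    """Analytic director field containing +-1/2 defects at given positions.

    theta(r) = sum_i k_i * atan2(y - y_i, x - x_i) + theta0, reduced to the
    nematic range.  Positions are (x, y) in grid units with y measured
    upward (array row axis points along -y).
    """
    h, w = shape
    defect_list = list(defect_list)
    for (x, y, k) in defect_list:
        if k not in (0.5, -0.5):
            raise ValueError("defect charge must be +1/2 or -1/2")
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError("defect core must lie inside the domain")
    for i in range(len(defect_list)):
        for j in range(i + 1, len(defect_list)):
            if (defect_list[i][0] == defect_list[j][0]
                    and defect_list[i][1] == defect_list[j][1]):
                raise ValueError("coincident defect cores are not allowed")
    rows, cols = np.indices(shape, dtype=float)
    theta = np.full(shape, float(theta0))
    for (x, y, k) in defect_list:
        # y-up: the y coordinate of array row r is -r (up to origin choice)
        theta = theta + k * np.degrees(np.arctan2(-(rows - y), cols - x))
    theta = wrap_nematic(theta)
    return OrientationField(theta, np.ones(shape), np.ones(shape, bool),
                            grid_size, pixel_size)


# ---------------------------------------------------------------------------
# textured images
# ---------------------------------------------------------------------------

def gen_filament_image(field: OrientationField, filament_length=15.0,
                       filament_density=0.02, seed=0, image_shape=None,
                       jitter_deg=3.0) -> np.ndarray:
    """Render a filament texture whose local orientation follows ``field``.

    Anti-aliased line segments of the given length (pixels) are placed at
    uniformly random positions at a mean count of ``filament_density``
    segments per pixel; each takes the orientation of the nearest grid
    point plus Gaussian jitter (sigma 3 deg by default, below the
    structure-tensor recovery tolerance).  Returns a float image in [0, 1].
    """
    from skimage.draw import line_aa

    h_g, w_g = field.shape
    if image_shape is None:
        image_shape = (int(round(h_g * field.grid_size)),
                       int(round(w_g * field.grid_size)))
    h, w = image_shape
    rng = np.random.default_rng(seed)
    n = rng.poisson(filament_density * h * w)
    img = np.zeros((h, w), dtype=float)
    if n == 0:
        return img
    rows = rng.uniform(0, h, size=n)
    cols = rng.uniform(0, w, size=n)
    gr = np.clip(np.round((rows - field.origin[1]) / field.grid_size), 0, h_g - 1).astype(int)
    gc = np.clip(np.round((cols - field.origin[0]) / field.grid_size), 0, w_g - 1).astype(int)
    ang = field.theta[gr, gc] + rng.normal(0.0, jitter_deg, size=n)
    t = np.deg2rad(ang)
    half = filament_length / 2.0
    # y-up: direction (cos t, sin t) -> array step (-sin t, cos t)
    dr = -np.sin(t) * half
    dc = np.cos(t) * half
    for i in range(n):
        r0 = int(round(rows[i] - dr[i])); c0 = int(round(cols[i] - dc[i]))
        r1 = int(round(rows[i] + dr[i])); c1 = int(round(cols[i] + dc[i]))
        r0 = min(max(r0, 0), h - 1); r1 = min(max(r1, 0), h - 1)
        c0 = min(max(c0, 0), w - 1); c1 = min(max(c1, 0), w - 1)
        rr, cc, val = line_aa(r0, c0, r1, c1)
        img[rr, cc] += val
    return np.clip(img, 0.0, 1.0)


def gen_displaced_pair(image, flow):
    """Image pair related by a known flow (PIV ground truth).

    ``flow`` is either a constant displacement ``(u, v)`` in pixels
    (u along +x/columns, v along +y/up) or a pair of arrays ``(U, V)`` of
    image shape giving the per-pixel displacement.  The second image is the
    first resampled backward along the flow: constant flows use an exact
    Fourier shift (periodic), varying flows cubic-spline interpolation.
    """
    image = np.asarray(image, dtype=float)
    u, v = flow
    if np.isscalar(u) and np.isscalar(v):
        # content moves by +u columns and -v rows (y-up)
        shifted = np.fft.ifft2(ndimage.fourier_shift(np.fft.fft2(image), (-v, u))).real
        return image, shifted
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != image.shape or v.shape != image.shape:
        raise ValueError("flow component arrays must match the image shape")
    rows, cols = np.indices(image.shape, dtype=float)
    sample = np.stack([rows + v, cols - u])  # backward warp, y-up
    warped = ndimage.map_coordinates(image, sample, order=3, mode="reflect")
    return image, warped


# ---------------------------------------------------------------------------
# nuclei movies / tracks
# ---------------------------------------------------------------------------

def _logistic_counts(n0, k_count, rate, times):
    if n0 >= k_count:
        return np.full(len(times), int(round(n0)))
    a = (k_count - n0) / n0
    n = k_count / (1.0 + a * np.exp(-rate * times))
    return np.round(n).astype(int)


def _blue_noise(rng, n, w_um, h_um, min_sep):
    """Uniform placement with a minimum pairwise separation (dart throwing).

    Emulates nuclear excluded volume; falls back to plain uniform points
    once the rejection budget is exhausted (very dense requests).
    """
    from scipy.spatial import cKDTree

    xs: list = []
    ys: list = []
    attempts = 0
    budget = 200 * max(n, 1)
    while len(xs) < n and attempts < budget:
        attempts += 1
        px, py = rng.uniform(0, w_um), rng.uniform(0, h_um)
        if xs and min_sep > 0:
            tree = cKDTree(np.column_stack([xs, ys]))
            if tree.query([px, py])[0] < min_sep:
                continue
        xs.append(px)
        ys.append(py)
    while len(xs) < n:
        xs.append(rng.uniform(0, w_um))
        ys.append(rng.uniform(0, h_um))
    return np.asarray(xs), np.asarray(ys)


def _sample_heading(rng, prev_heading_deg, persistence, bias):
    """Next step direction for one frame of walkers (vectorised, degrees)."""
    if np.isinf(bias):
        return np.zeros_like(prev_heading_deg)
    prev = np.deg2rad(prev_heading_deg)
    rx = persistence * np.cos(prev) + bias
    ry = persistence * np.sin(prev)
    kappa = np.hypot(rx, ry)
    mu = np.arctan2(ry, rx)
    out = np.empty_like(mu)
    weak = kappa < 1e-9
    out[weak] = rng.uniform(-np.pi, np.pi, size=int(weak.sum()))
    strong = ~weak
    if np.any(strong):
        out[strong] = rng.vonmises(mu[strong], kappa[strong])
    return np.degrees(out)


def _render_spots(shape, xs_px, ys_px, sigma_px):
    """Sum of Gaussian spots; positions in pixel units, y-up origin at row 0."""
    img = np.zeros(shape, dtype=float)
    r = int(np.ceil(3 * sigma_px))
    ax = np.arange(-r, r + 1)
    for x, y in zip(xs_px, ys_px):
        ci, ri = int(round(x)), int(round(y))
        if not (0 <= ri < shape[0] and 0 <= ci < shape[1]):
            continue
        rr = np.clip(ri + ax, 0, shape[0] - 1)
        cc = np.clip(ci + ax, 0, shape[1] - 1)
        gy = np.exp(-((ri + ax - y) ** 2) / (2 * sigma_px ** 2))
        gx = np.exp(-((ci + ax - x) ** 2) / (2 * sigma_px ** 2))
        patch = np.outer(gy, gx)
        img[rr[:, None], cc[None, :]] += patch
    return img


def gen_growth_tracks(spec: SyntheticSpec, render_images: bool = True):
    """Simulate a proliferating, migrating nuclei culture.

    The population follows deterministic logistic growth toward the
    carrying capacity; each cell performs a persistent random walk whose
    step directions are biased toward the 0 deg director, and per-step
    speed decays linearly with density (down to a floor at capacity).
    New cells appear adjacent to randomly chosen existing cells.

    Returns ``(tracks, stack)``: a tidy track table (track_id, frame, t_h,
    x_um, y_um) and, if requested, a (n_frames, H, W) float image stack of
    Gaussian nuclei spots.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    w_um = w * spec.pixel_size
    h_um = h * spec.pixel_size
    area_mm2 = (w_um * h_um) / 1.0e6
    times = np.arange(spec.n_frames) * spec.frame_interval
    k_count = spec.carrying_capacity * area_mm2
    counts = _logistic_counts(spec.initial_cells, k_count, spec.growth_rate, times)

    m = spec.seed_margin_um
    x, y = _blue_noise(rng, counts[0], w_um - 2 * m, h_um - 2 * m,
                       spec.min_separation_um)
    x = x + m
    y = y + m
    heading = rng.uniform(-180.0, 180.0, size=counts[0])
    ids = np.arange(counts[0])
    next_id = counts[0]

    rows = []
    frames = []
    sigma_px = spec.nucleus_sigma_um / spec.pixel_size
    for f in range(spec.n_frames):
        if f > 0:
            density = len(x) / area_mm2
            slow = 1.0 - spec.speed_density_slowdown * min(
                1.0, density / spec.carrying_capacity)
            step = spec.speed * slow * spec.frame_interval
            heading = _sample_heading(rng, heading, spec.persistence, spec.bias)
            t = np.deg2rad(heading)
            x = x + step * np.cos(t)
            y = y + step * np.sin(t)
            # reflective boundaries
            x = np.abs(x); x = np.where(x > w_um, 2 * w_um - x, x)
            y = np.abs(y); y = np.where(y > h_um, 2 * h_um - y, y)
            n_new = counts[f] - len(x)
            if n_new > 0:
                parents = rng.integers(0, len(x), size=n_new)
                # daughters placed one exclusion radius from the parent
                phi = rng.uniform(-np.pi, np.pi, size=n_new)
                off = spec.min_separation_um
                x = np.concatenate([x, np.clip(x[parents] + off * np.cos(phi), 0, w_um)])
                y = np.concatenate([y, np.clip(y[parents] + off * np.sin(phi), 0, h_um)])
                heading = np.concatenate(
                    [heading, rng.uniform(-180.0, 180.0, size=n_new)])
                ids = np.concatenate([ids, np.arange(next_id, next_id + n_new)])
                next_id += n_new
        rows.append(pd.DataFrame({
            "track_id": ids, "frame": f, "t_h": times[f],
            "x_um": x.copy(), "y_um": y.copy(),
        }))
        if render_images:
            frames.append(_render_spots(
                (h, w), x / spec.pixel_size, y / spec.pixel_size, sigma_px))

    tracks = pd.concat(rows, ignore_index=True)
    tracks.attrs["frame_interval"] = spec.frame_interval
    tracks.attrs["field_area_mm2"] = area_mm2
    stack = np.stack(frames) if render_images else None
    return tracks, stack
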