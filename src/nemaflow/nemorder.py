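"""Nematic order statistics: order parameter, spatial disorder,
autocorrelation and correlation length.

The 2D orientation-order parameter of an axial angle ensemble is

    S = | < 2 cos^2(theta - theta_bar) - 1 > |,

with theta_bar the doubled-angle circular mean; this equals the resultant
length of the doubled angles, ranging from 0 (isotropic) to 1 (perfect
order).  Local order uses the same statistic on sliding 4x4 windows of
grid vectors, and spatial disorder is the percentage of windows with
S < 0.5.

The spatial autocorrelation of the director field is

    C(d) = 2 < cos^2[ theta(r) - theta(r + d) ] > - 1,

averaged over all grid-point pairs with the same separation distance d.
On a square lattice the exact distance classes are the square roots of the
integer squared offsets (0, 1, sqrt(2), 2, sqrt(5), ...), so classes are
grouped exactly by integer squared distance.  The correlation length xi is
the x-intercept of an ordinary least-squares line through the first
``n_fit`` (default 10) points of C(d), converted to micrometers with the
pixel calibration.
"""

from __future__ import annotations

import numpy as np

from .fields import CorrelationCurve, OrderMap, OrientationField

__all__ = [
    "global_order",
    "local_order_map",
    "spatial_disorder",
    "nematic_autocorrelation",
    "correlation_length",
    "order_parameter",
    "local_order_to_grayscale",
]


def order_parameter(angles_deg) -> float:
    """S for a bare set of axial angles (degrees)."""
    ang = np.asarray(angles_deg, dtype=float)
    ang = ang[np.isfinite(ang)]
    if ang.size < 2:
        raise ValueError("need at least 2 angles")
    # reference to the first angle: |mean| is unchanged, but a perfectly
    # uniform sample then averages exp(0) = 1 exactly
    z = np.exp(2j * np.deg2rad(ang - ang[0])).mean()
    return min(float(np.abs(z)), 1.0)


def global_order(field: OrientationField) -> float:
    """Global 2D orientation-order parameter of a lattice field.

    Equals |<exp(2 i theta)>| over unmasked vectors, identical to
    averaging 2 cos^2(theta - theta_bar) - 1 about the doubled-angle mean.
    """
    if field.n_valid < 2:
        raise ValueError("global_order requires at least 2 unmasked vectors")
    return order_parameter(field.valid_angles())


def local_order_map(field: OrientationField, window: int = 4) -> OrderMap:
    """S on sliding ``window`` x ``window`` blocks of grid vectors.

    Windows slide with stride one grid point and must lie fully inside the
    lattice (border-incomplete windows are dropped, not padded).  Each
    window uses its own doubled-angle mean.  Windows with fewer than two
    unmasked vectors are NaN.
    """
    h, w = field.shape
    if h < window or w < window:
        raise ValueError(f"field must be at least {window}x{window}")
    t = 2.0 * np.deg2rad(np.where(field.mask, field.theta, 0.0))
    c = np.where(field.mask, np.cos(t), 0.0)
    s = np.where(field.mask, np.sin(t), 0.0)
    n = field.mask.astype(float)

    def win_sum(a):
        cs = np.cumsum(np.cumsum(a, axis=0), axis=1)
        cs = np.pad(cs, ((1, 0), (1, 0)))
        return (cs[window:, window:] - cs[:-window, window:]
                - cs[window:, :-window] + cs[:-window, :-window])

    cs_, ss_, ns_ = win_sum(c), win_sum(s), win_sum(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        local_s = np.hypot(cs_, ss_) / ns_
    local_s = np.where(ns_ >= 2, local_s, np.nan)
    s_global = global_order(field)
    return OrderMap(local_s, window, s_global)


def spatial_disorder(order_map: OrderMap, threshold: float = 0.5) -> float:
    """Percentage of local windows with S below ``threshold``."""
    vals = order_map.local_S[order_map.valid]
    if vals.size == 0:
        raise ValueError("order map has no valid windows")
    pct = 100.0 * np.count_nonzero(vals < threshold) / vals.size
    order_map.spatial_disorder = pct
    order_map.disorder_threshold = threshold
    return pct


def nematic_autocorrelation(field: OrientationField,
                            max_pairs_chunk: int = 4_000_000) -> CorrelationCurve:
    """Spatial autocorrelation C(d) over exact distance classes.

    Pairs are grouped by their exact Euclidean separation (equivalently,
    by integer squared lattice offset); masked vectors are excluded
    pairwise.  C(0) = 1 exactly (self pairs).
    """
    if field.n_valid < 2:
        raise ValueError("need at least 2 unmasked vectors")
    rr, cc = np.nonzero(field.mask)
    t2 = 2.0 * np.deg2rad(field.theta[rr, cc])
    n = len(rr)
    h, w = field.shape
    max_k = (h - 1) ** 2 + (w - 1) ** 2      # squared-distance classes
    sums = np.zeros(max_k + 1)
    counts = np.zeros(max_k + 1)
    # self pairs: distance class 0, cos(0) = 1
    sums[0] += n
    counts[0] += n

    rows_i = rr.astype(np.int64)
    cols_i = cc.astype(np.int64)
    chunk = max(1, int(max_pairs_chunk // max(n, 1)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dr = rows_i[start:stop, None] - rows_i[None, :]
        dc = cols_i[start:stop, None] - cols_i[None, :]
        k = dr * dr + dc * dc
        cosd = np.cos(t2[start:stop, None] - t2[None, :])
        # keep each unordered pair once: global index j > i
        jj = np.arange(n)[None, :]
        ii = np.arange(start, stop)[:, None]
        sel = jj > ii
        ksel = k[sel]
        sums += np.bincount(ksel, weights=cosd[sel], minlength=max_k + 1)
        counts += np.bincount(ksel, minlength=max_k + 1)
    present = counts > 0
    d_grid = np.sqrt(np.nonzero(present)[0].astype(float))
    c_vals = sums[present] / counts[present]
    return CorrelationCurve(
        distance_grid=d_grid,
        distance_px=d_grid * field.grid_size,
        distance_um=d_grid * field.grid_size * field.pixel_size,
        C=c_vals,
        n_pairs=counts[present],
        grid_size=field.grid_size,
        pixel_size=field.pixel_size,
    )


def correlation_length(curve: CorrelationCurve, n_fit: int = 10) -> float:
    """Correlation length xi (um) from the x-intercept of a line fit.

    Ordinary least squares through the first ``n_fit`` points of C(d);
    xi = -intercept / slope.  Degenerate cases are clamped to the maximum
    sampled distance with the flag set: a non-negative slope, a
    non-positive intercept, or an intercept beyond the sampled range when
    the fit used only a truncation of a longer curve (a curve fitted in
    full carries no information about larger distances, so its intercept
    is accepted as an extrapolation).  The curve's xi fields are populated
    in place; the return value is xi in um.
    """
    if len(curve.distance_grid) < 2:
        raise ValueError("need at least 2 distance classes to fit")
    k = min(n_fit, len(curve.distance_grid))
    d = curve.distance_grid[:k]
    c = curve.C[:k]
    slope, intercept = np.polyfit(d, c, 1)
    d_max = float(curve.distance_grid[-1])
    truncated = k < len(curve.distance_grid)
    degenerate = False
    if slope >= 0:
        xi_grid = d_max
        degenerate = True
    else:
        xi_grid = -intercept / slope
        if xi_grid <= 0 or (truncated and xi_grid > d_max):
            xi_grid = d_max
            degenerate = True
    curve.xi_grid = float(xi_grid)
    curve.xi_px = float(xi_grid * curve.grid_size)
    curve.xi_um = float(curve.xi_px * curve.pixel_size)
    curve.fit_points = k
    curve.degenerate = degenerate
    return curve.xi_um


def local_order_to_grayscale(order_map: OrderMap) -> np.ndarray:
    """Local S scaled to 8-bit grayscale (0-255); NaN windows -> 0."""
    s = np.nan_to_num(order_map.local_S, nan=0.0)
    return np.clip(np.round(s * 255.0), 0, 255).astype(np.uint8)
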