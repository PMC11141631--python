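"""Core data containers shared across the analysis pipeline.

These are light dataclasses around numpy arrays: an orientation field on a
regular grid, the per-pixel structure-tensor output, angular frequency
distributions, spatial autocorrelation curves, local-order maps and PIV
velocity fields.  CSV round-trips use plain pandas tables so results are
interoperable with external tools (OrientationJ / PIVlab style exports).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._angles import wrap_nematic

__all__ = [
    "OrientationField",
    "PixelOrientationMap",
    "FrequencyDistribution",
    "CorrelationCurve",
    "OrderMap",
    "VelocityField",
]


@dataclass
class OrientationField:
    """Nematic angles on a regular lattice.

    Parameters
    ----------
    theta : (H, W) array
        Angles in degrees, nematic range (-90, 90].  Entries at masked
        points are ignored (may be NaN).
    coherency : (H, W) array
        Orientation confidence in [0, 1].
    mask : (H, W) bool array
        True where the grid point carries a valid orientation.
    grid_size : float
        Lattice spacing in pixels.
    pixel_size : float
        Physical calibration in micrometers per pixel.
    origin : (float, float)
        Pixel coordinates (x, y) of grid point [0, 0].
    """

    theta: np.ndarray
    coherency: np.ndarray
    mask: np.ndarray
    grid_size: float = 1.0
    pixel_size: float = 1.0
    origin: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        if self.theta.ndim != 2:
            raise ValueError("theta must be a 2D lattice")
        if self.coherency is None:
            self.coherency = np.ones_like(self.theta)
        self.coherency = np.asarray(self.coherency, dtype=float)
        if self.mask is None:
            self.mask = np.ones(self.theta.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.coherency.shape != self.theta.shape or self.mask.shape != self.theta.shape:
            raise ValueError("theta, coherency and mask shapes must match")
        if self.grid_size <= 0 or self.pixel_size <= 0:
            raise ValueError("grid_size and pixel_size must be positive")
        valid = self.mask
        if np.any(valid):
            self.theta = np.where(valid, wrap_nematic(self.theta), self.theta)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.theta.shape

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def valid_angles(self) -> np.ndarray:
        return self.theta[self.mask]

    def grid_positions_px(self):
        """(x, y) pixel coordinates of every grid point, each (H, W)."""
        h, w = self.theta.shape
        x = self.origin[0] + self.grid_size * np.arange(w)
        y = self.origin[1] + self.grid_size * np.arange(h)
        return np.meshgrid(x, y)

    def rotated(self, alpha_deg: float) -> "OrientationField":
        """Rotate every angle by ``alpha_deg`` (closed under mod 180)."""
        theta = np.where(self.mask, wrap_nematic(self.theta + alpha_deg), self.theta)
        return OrientationField(theta, self.coherency.copy(), self.mask.copy(),
                                self.grid_size, self.pixel_size, self.origin)

    def to_frame(self) -> pd.DataFrame:
        xx, yy = self.grid_positions_px()
        return pd.DataFrame({
            "x_px": xx.ravel(),
            "y_px": yy.ravel(),
            "theta_deg": self.theta.ravel(),
            "coherency": self.coherency.ravel(),
            "mask": self.mask.ravel().astype(int),
        })

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid_size=None, pixel_size=1.0) -> "OrientationField":
        df = pd.read_csv(path)
        xs = np.unique(df["x_px"].to_numpy())
        ys = np.unique(df["y_px"].to_numpy())
        if grid_size is None:
            grid_size = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0
        h, w = len(ys), len(xs)
        order = np.lexsort((df["x_px"].to_numpy(), df["y_px"].to_numpy()))
        theta = df["theta_deg"].to_numpy()[order].reshape(h, w)
        coh = df["coherency"].to_numpy()[order].reshape(h, w)
        mask = df["mask"].to_numpy()[order].reshape(h, w).astype(bool)
        return cls(theta, coh, mask, grid_size, pixel_size, (float(xs[0]), float(ys[0])))


@dataclass
class PixelOrientationMap:
    """Per-pixel structure-tensor orientation output."""

    theta: np.ndarray      # degrees, (-90, 90]; undefined where energy == 0
    coherency: np.ndarray  # [0, 1]
    energy: np.ndarray     # tensor trace (gradient energy), >= 0
    sigma: float           # Gaussian window scale used (pixels)

    def __post_init__(self):
        for name in ("theta", "coherency", "energy"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.theta.shape != self.coherency.shape or self.theta.shape != self.energy.shape:
            raise ValueError("component shapes must match")

    @property
    def mask(self) -> np.ndarray:
        return self.energy > 0

    @property
    def shape(self):
        return self.theta.shape


@dataclass
class FrequencyDistribution:
    """Angular histogram normalised to frequencies (sums to one)."""

    bin_edges: np.ndarray   # degrees, length n_bins + 1
    frequency: np.ndarray   # length n_bins, sums to 1
    axis_label: str = "Angle (°)"

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.frequency = np.asarray(self.frequency, dtype=float)
        if len(self.bin_edges) != len(self.frequency) + 1:
            raise ValueError("bin_edges must have one more entry than frequency")
        total = self.frequency.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"frequencies must sum to 1, got {total}")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def mode_angle(self) -> float:
        """Center of the highest-frequency bin (ties -> lowest angle)."""
        return float(self.bin_centers[int(np.argmax(self.frequency))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_low_deg": self.bin_edges[:-1],
            "bin_high_deg": self.bin_edges[1:],
            "frequency": self.frequency,
        })


@dataclass
class CorrelationCurve:
    """Spatial autocorrelation C(d) with its fitted correlation length.

    Distances are carried in grid units, pixels and micrometers; ``xi``
    fields are populated by :func:`nemaflow.nemorder.correlation_length`.
    """

    distance_grid: np.ndarray
    distance_px: np.ndarray
    distance_um: np.ndarray
    C: np.ndarray
    n_pairs: np.ndarray
    grid_size: float = 1.0
    pixel_size: float = 1.0
    xi_grid: Optional[float] = None
    xi_px: Optional[float] = None
    xi_um: Optional[float] = None
    fit_points: int = 10
    degenerate: bool = False

    def __post_init__(self):
        for name in ("distance_grid", "distance_px", "distance_um", "C", "n_pairs"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "d_grid": self.distance_grid,
            "d_px": self.distance_px,
            "d_um": self.distance_um,
            "C": self.C,
            "n_pairs": self.n_pairs,
        })


@dataclass
class OrderMap:
    """Local nematic order on sliding windows plus the global statistic."""

    local_S: np.ndarray          # (H - w + 1, W - w + 1), NaN where masked
    window: int
    S_global: float
    disorder_threshold: float = 0.5
    spatial_disorder: Optional[float] = None   # percent, filled on demand

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.local_S)


@dataclass
class VelocityField:
    """PIV displacement field on a regular window lattice.

    ``u`` points along +x (columns), ``v`` along +y (up, i.e. -rows), in
    micrometers per hour once calibrated.  The invalid outer ring mirrors
    the rejection of boundary vectors as frame-edge artifacts.
    """

    x: np.ndarray              # 1D, window-center x positions (px)
    y: np.ndarray              # 1D, window-center y positions (px, row coords)
    u: np.ndarray              # (ny, nx) um/h (or px/frame if uncalibrated)
    v: np.ndarray
    valid: np.ndarray
    frame_interval: float = 1.0    # hours
    pixel_size: float = 1.0        # um/px
    pass_settings: Sequence[Tuple[int, int]] = dc_field(default_factory=list)

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.u.shape != (len(self.y), len(self.x)):
            raise ValueError("u shape must be (len(y), len(x))")
        if self.v.shape != self.u.shape or self.valid.shape != self.u.shape:
            raise ValueError("u, v and valid shapes must match")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.u, self.v)

    @property
    def angle_deg(self) -> np.ndarray:
        """Directional flow angle in (-180, 180], y-up convention."""
        return np.degrees(np.arctan2(self.v, self.u))

    def to_frame(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.x, self.y)
        return pd.DataFrame({
            "x_px": xx.ravel(), "y_px": yy.ravel(),
            "u": self.u.ravel(), "v": self.v.ravel(),
            "valid": self.valid.ravel().astype(int),
        })
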