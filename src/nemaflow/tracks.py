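"""Nuclei detection, linking, density, time alignment and migration stats.

Nuclei are detected classically (Laplacian-of-Gaussian blobs with an
equivalent-diameter gate of 6-30 um, then intensity-weighted centroid
refinement) and linked frame-to-frame by greedy mutual nearest neighbours
under a displacement gate — no gap closing, merging or splitting.  All
track-level statistics also accept externally produced track tables
(TrackMate-style exports mapped onto the track_id/frame/t_h/x_um/y_um
schema), so the classical detector is interchangeable with a trained one.

Replicate time axes are registered by shifting each density series so its
(smoothed) maximum sits at an aligned time t_a = 36 h, which places
confluence near t_a = 0 h; the same offset applies to companion series
(order, disorder, speed, velocity correlation length).

Migration is quantified per step (displacement / frame interval; direction
by atan2) and summarised as the normalized migration within +-10 deg of
the director: step directions are folded onto the nematic range, binned in
10 deg increments (18 bins across 180 deg), and the summed frequency of
the two bins flanking the director is divided by the isotropic expectation
of 2/18 = 11.111%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from ._angles import wrap_directional, wrap_nematic
from .fields import FrequencyDistribution

logger = logging.getLogger(__name__)

__all__ = [
    "detect_nuclei",
    "link_tracks",
    "cell_density",
    "align_time_series",
    "migration_stats",
    "normalized_directional_migration",
    "directional_migration_series",
    "division_axis",
    "profile_vs_density",
    "DensitySeries",
    "read_track_csv",
    "ISOTROPIC_MIGRATION_FRACTION",
]

#: isotropic expectation for the +-10 deg window: 2 bins out of 18
ISOTROPIC_MIGRATION_FRACTION = 2.0 / 18.0

TRACK_COLUMNS = ["track_id", "frame", "t_h", "x_um", "y_um"]


@dataclass
class DensitySeries:
    """Cell density vs time, with optional alignment offset.

    t_a = t_raw + offset; the offset registers the density maximum at the
    target aligned time.
    """

    t_raw: np.ndarray          # hours
    density: np.ndarray        # cells/mm^2
    offset: float = 0.0
    flagged: bool = False      # degenerate alignment (flat / monotone series)

    def __post_init__(self):
        self.t_raw = np.asarray(self.t_raw, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if np.any(self.density < 0):
            raise ValueError("density must be non-negative")
        if len(self.t_raw) != len(self.density):
            raise ValueError("t_raw and density lengths differ")

    @property
    def t_a(self) -> np.ndarray:
        return self.t_raw + self.offset

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_raw_h": self.t_raw, "t_a_h": self.t_a,
                             "density_per_mm2": self.density})


def detect_nuclei(image, pixel_size: float, diameter_range_um=(6.0, 30.0),
                  threshold: float = 0.05) -> np.ndarray:
    """LoG blob detection with a physical diameter gate.

    Returns an (n, 2) array of (x, y) centroids in micrometers (y along
    image rows).  Blobs whose equivalent diameter falls outside the open
    interval ``diameter_range_um`` are excluded; positions are refined by
    an intensity-weighted centroid within each blob's radius.
    """
    from skimage.feature import blob_log

    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D grayscale frame")
    if img.max() > img.min():
        img = (img - img.min()) / (img.max() - img.min())
    else:
        return np.empty((0, 2))
    d_lo, d_hi = diameter_range_um
    s_lo = d_lo / pixel_size / (2.0 * np.sqrt(2.0))
    s_hi = d_hi / pixel_size / (2.0 * np.sqrt(2.0))
    blobs = blob_log(img, min_sigma=max(s_lo * 0.75, 1.0), max_sigma=s_hi * 1.25,
                     num_sigma=10, threshold=threshold, overlap=1.0)
    pts = []
    h, w = img.shape
    for r, c, sig in blobs:
        diam_um = 2.0 * np.sqrt(2.0) * sig * pixel_size
        if not (d_lo < diam_um < d_hi):
            continue
        rad = max(int(round(2 * sig)), 2)
        r0, r1 = int(max(r - rad, 0)), int(min(r + rad + 1, h))
        c0, c1 = int(max(c - rad, 0)), int(min(c + rad + 1, w))
        patch = img[r0:r1, c0:c1]
        tot = patch.sum()
        if tot > 0:
            rr, cc = np.mgrid[r0:r1, c0:c1]
            r_ref = (patch * rr).sum() / tot
            c_ref = (patch * cc).sum() / tot
        else:
            r_ref, c_ref = r, c
        pts.append((c_ref * pixel_size, r_ref * pixel_size))
    return np.asarray(pts).reshape(-1, 2)


def link_tracks(points_per_frame: Sequence[np.ndarray], max_disp: float,
                frame_interval: float = 1.0,
                field_area_mm2: Optional[float] = None) -> pd.DataFrame:
    """Greedy mutual-nearest-neighbour frame-to-frame linking.

    A point in frame f links to a point in frame f+1 iff each is the
    other's nearest neighbour and their distance is at most ``max_disp``
    (um).  Unmatched points start new tracks; there is no gap closing.
    Ties are broken by smallest distance then lowest index.
    """
    pts = [np.asarray(p, dtype=float).reshape(-1, 2) for p in points_per_frame]
    if len(pts) < 1:
        raise ValueError("need at least one frame")
    next_id = 0
    cur_ids = np.arange(len(pts[0])); next_id = len(pts[0])
    rows = [pd.DataFrame({"track_id": cur_ids, "frame": 0, "t_h": 0.0,
                          "x_um": pts[0][:, 0], "y_um": pts[0][:, 1]})]
    for f in range(1, len(pts)):
        prev, cur = pts[f - 1], pts[f]
        new_ids = np.full(len(cur), -1, dtype=int)
        if len(prev) and len(cur):
            tree_prev = cKDTree(prev)
            tree_cur = cKDTree(cur)
            d_pc, nn_pc = tree_cur.query(prev)   # prev -> nearest cur
            d_cp, nn_cp = tree_prev.query(cur)   # cur -> nearest prev
            cand = [(d_pc[i], i, nn_pc[i]) for i in range(len(prev))
                    if d_pc[i] <= max_disp and nn_cp[nn_pc[i]] == i]
            used_prev, used_cur = set(), set()
            for d, i, j in sorted(cand):
                if i in used_prev or j in used_cur:
                    continue
                new_ids[j] = cur_ids[i]
                used_prev.add(i); used_cur.add(j)
        for j in range(len(cur)):
            if new_ids[j] < 0:
                new_ids[j] = next_id
                next_id += 1
        cur_ids = new_ids
        rows.append(pd.DataFrame({"track_id": cur_ids, "frame": f,
                                  "t_h": f * frame_interval,
                                  "x_um": cur[:, 0], "y_um": cur[:, 1]}))
    out = pd.concat(rows, ignore_index=True)
    out.attrs["frame_interval"] = frame_interval
    if field_area_mm2 is not None:
        out.attrs["field_area_mm2"] = field_area_mm2
    return out


def read_track_csv(path, frame_interval: Optional[float] = None) -> pd.DataFrame:
    """Read a track table; accepts the native schema or TrackMate-style
    spot exports (TRACK_ID/FRAME/POSITION_X/POSITION_Y[/POSITION_T])."""
    df = pd.read_csv(path)
    if set(TRACK_COLUMNS) <= set(df.columns):
        return df[TRACK_COLUMNS].copy()
    mapping = {"TRACK_ID": "track_id", "FRAME": "frame",
               "POSITION_X": "x_um", "POSITION_Y": "y_um", "POSITION_T": "t_h"}
    if set(mapping) - {"POSITION_T"} <= set(df.columns):
        out = df.rename(columns=mapping)
        if "t_h" not in out.columns:
            if frame_interval is None:
                raise ValueError("frame_interval required when POSITION_T absent")
            out["t_h"] = out["frame"] * frame_interval
        return out[TRACK_COLUMNS].copy()
    raise ValueError("unrecognised track table schema")


def cell_density(points_per_frame: Sequence[np.ndarray], field_area_mm2: float,
                 frame_interval: float = 1.0) -> DensitySeries:
    """Cell count per frame divided by the field area (cells/mm^2)."""
    if field_area_mm2 <= 0:
        raise ValueError("field area must be positive")
    counts = np.array([len(np.asarray(p).reshape(-1, 2)) for p in points_per_frame],
                      dtype=float)
    t = np.arange(len(counts)) * frame_interval
    return DensitySeries(t, counts / field_area_mm2)


def align_time_series(series: DensitySeries, target_peak: float = 36.0,
                      smooth_window: int = 3) -> DensitySeries:
    """Shift the time axis so the smoothed density maximum sits at t_a.

    Density is smoothed with a centered moving average (window 3) before
    locating the peak.  A flat series is flagged with zero offset; a
    monotonically increasing series uses the last point as the peak and is
    flagged as well.  Apply the resulting ``offset`` to companion series.
    """
    if len(series.density) < 3:
        raise ValueError("need at least 3 time points")
    d = series.density
    kernel = np.ones(smooth_window)
    smoothed = np.convolve(d, kernel, mode="same") / \
        np.convolve(np.ones_like(d), kernel, mode="same")
    flagged = False
    if np.ptp(smoothed) == 0:
        logger.warning("flat density series: alignment offset set to 0")
        return DensitySeries(series.t_raw.copy(), d.copy(), 0.0, True)
    peak_idx = int(np.argmax(smoothed))
    if peak_idx == len(d) - 1 and np.all(np.diff(smoothed) >= 0):
        logger.warning("monotonically increasing density: peak taken at last point")
        flagged = True
    offset = float(target_peak - series.t_raw[peak_idx])
    return DensitySeries(series.t_raw.copy(), d.copy(), offset, flagged)


def migration_stats(tracks: pd.DataFrame,
                    frame_interval: Optional[float] = None) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Per-step speed/angle and per-cell means from a track table.

    Steps are consecutive positions within a track: speed = displacement /
    dt (um/h), direction = atan2(dy, dx) in (-180, 180].  Zero-length
    steps contribute speed 0 and no angle (NaN).  Per-cell means use the
    arithmetic mean speed and the circular mean direction.
    """
    df = tracks.sort_values(["track_id", "frame"])
    g = df.groupby("track_id", sort=False)
    dx = g["x_um"].diff()
    dy = g["y_um"].diff()
    dt = g["t_h"].diff()
    ok = dx.notna() & (dt > 0)
    disp = np.hypot(dx[ok], dy[ok])
    speed = disp / dt[ok]
    ang = np.where(disp > 0,
                   np.degrees(np.arctan2(dy[ok], dx[ok])), np.nan)
    steps = pd.DataFrame({
        "track_id": df.loc[ok.index[ok], "track_id"].to_numpy(),
        "frame": df.loc[ok.index[ok], "frame"].to_numpy(),
        "t_h": df.loc[ok.index[ok], "t_h"].to_numpy(),
        "speed_um_h": speed.to_numpy(),
        "angle_deg": wrap_directional(ang),
    })
    def _cell_summary(sub):
        a = sub["angle_deg"].dropna().to_numpy()
        if len(a):
            z = np.exp(1j * np.deg2rad(a)).mean()
            mean_ang = float(wrap_directional(np.degrees(np.angle(z))))
        else:
            mean_ang = np.nan
        return pd.Series({"mean_speed_um_h": sub["speed_um_h"].mean(),
                          "mean_angle_deg": mean_ang,
                          "n_steps": len(sub)})
    cells = steps.groupby("track_id").apply(_cell_summary, include_groups=False) \
        .reset_index()
    return steps, cells


def normalized_directional_migration(angles_deg, director: float = 0.0,
                                     bin_width: float = 10.0) -> float:
    """Normalized migration within +-10 deg of the director.

    Step directions are taken relative to the director and folded onto the
    nematic range (migration toward either end of the director axis
    counts), then histogrammed in ``bin_width`` increments (18 bins across
    180 deg by default).  The summed frequency of the two bins adjacent to
    0 deg, (-10, 0] and (0, 10], is divided by the isotropic expectation
    2/18 = 11.111%, so 1 means unbiased migration and 9 is the maximum.
    """
    ang = np.asarray(angles_deg, dtype=float)
    ang = ang[np.isfinite(ang)]
    if ang.size == 0:
        return np.nan
    n_bins = 180.0 / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide 180")
    rel = wrap_nematic(ang - director)
    frac = np.count_nonzero((rel > -bin_width) & (rel <= bin_width)) / ang.size
    return float(frac / (2.0 * bin_width / 180.0))


def directional_migration_series(steps: pd.DataFrame, director: float = 0.0,
                                 bin_width: float = 10.0) -> pd.DataFrame:
    """Normalized directional migration per time point.

    Time points with no finite-angle steps get NaN.
    """
    rows = []
    for t, sub in steps.groupby("t_h"):
        rows.append({"t_h": t, "normalized_migration": normalized_directional_migration(
            sub["angle_deg"].to_numpy(), director, bin_width)})
    return pd.DataFrame(rows)


def division_axis(pairs, bin_width: float = 20.0) -> FrequencyDistribution:
    """Division-axis distribution from nucleus-pair coordinates.

    ``pairs`` is an (n, 4) array-like of (x1, y1, x2, y2); the axis angle
    is folded to the nematic range and binned (20 deg increments).
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 4)
    dx = arr[:, 2] - arr[:, 0]
    dy = arr[:, 3] - arr[:, 1]
    if np.any((dx == 0) & (dy == 0)):
        raise ValueError("coincident nucleus pairs are not allowed")
    ang = wrap_nematic(np.degrees(np.arctan2(dy, dx)))
    n_bins = int(round(180.0 / bin_width))
    if abs(180.0 / bin_width - n_bins) > 1e-9:
        raise ValueError("bin_width must divide 180")
    idx = np.clip(np.ceil((ang + 90.0) / bin_width).astype(int) - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    edges = -90.0 + bin_width * np.arange(n_bins + 1)
    return FrequencyDistribution(edges, counts / counts.sum())


def profile_vs_density(replicates: Sequence[Tuple[np.ndarray, np.ndarray]],
                       increment: float = 10.0) -> pd.DataFrame:
    """Average per-replicate linear interpolations onto a density lattice.

    Each replicate is a (density, value) pair of same-length arrays (e.g.
    per-frame density and mean speed).  Every replicate is linearly
    interpolated onto a common lattice with ``increment`` cells/mm^2
    spacing, restricted to its own density range; lattice points covered by
    at least one replicate are averaged with equal replicate weight.
    """
    reps = [(np.asarray(d, float), np.asarray(v, float)) for d, v in replicates]
    if not reps:
        raise ValueError("need at least one replicate")
    lo = min(d.min() for d, _ in reps)
    hi = max(d.max() for d, _ in reps)
    lattice = np.arange(np.ceil(lo / increment) * increment,
                        hi + 0.5 * increment, increment)
    acc = np.zeros(len(lattice))
    cnt = np.zeros(len(lattice))
    for d, v in reps:
        order = np.argsort(d)
        ds, vs = d[order], v[order]
        inside = (lattice >= ds[0]) & (lattice <= ds[-1])
        if inside.any():
            acc[inside] += np.interp(lattice[inside], ds, vs)
            cnt[inside] += 1
    keep = cnt > 0
    return pd.DataFrame({"density_per_mm2": lattice[keep],
                         "value": acc[keep] / cnt[keep],
                         "n_replicates": cnt[keep].astype(int)})
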