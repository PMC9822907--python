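"""Epidermis and epidermal-dermal junction (EDJ) morphometry.

Covers the four epidermal read-outs: viable-epidermis thickness probed at
regularly spaced locations, the Ki67-positive fraction in windows along the
epidermis, the arc-chord interdigitation ratio of the EDJ, and basement-
membrane width/peak from COLIV intensity profiles normal to the EDJ.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters

from .segmentation import PointSet

__all__ = [
    "BoundaryCurve",
    "IntensityProfile",
    "EpidermisMetrics",
    "epidermal_thickness",
    "ki67_fraction",
    "arc_chord_ratio",
    "edj_profiles",
    "profile_width_peak",
]


@dataclass
class BoundaryCurve:
    """Ordered open polyline in µm tracing a tissue boundary (e.g. the EDJ)."""

    vertices: np.ndarray   # (n, 2) as (x, y) µm

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("BoundaryCurve needs >= 2 (x, y) vertices")
        steps = np.linalg.norm(np.diff(self.vertices, axis=0), axis=1)
        if np.any(steps == 0):
            raise ValueError("consecutive vertices must be distinct")
        self._cum = np.concatenate([[0.0], np.cumsum(steps)])

    @property
    def arc_length(self) -> float:
        return float(self._cum[-1])

    def point_at(self, s) -> np.ndarray:
        """Point(s) at arc-length position(s) s (µm) by linear interpolation."""
        s = np.atleast_1d(np.asarray(s, float))
        x = np.interp(s, self._cum, self.vertices[:, 0])
        y = np.interp(s, self._cum, self.vertices[:, 1])
        return np.column_stack([x, y])

    def y_at(self, x) -> np.ndarray:
        """Depth of the curve at horizontal position(s) x (requires x-monotone curve)."""
        xs = self.vertices[:, 0]
        if not (np.all(np.diff(xs) > 0) or np.all(np.diff(xs) < 0)):
            raise ValueError("curve is not x-monotone; vertical probing undefined")
        if np.all(np.diff(xs) < 0):
            return np.interp(x, xs[::-1], self.vertices[::-1, 1])
        return np.interp(x, xs, self.vertices[:, 1])

    def to_csv(self, path) -> None:
        pd.DataFrame(self.vertices, columns=["x_um", "y_um"]).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BoundaryCurve":
        df = pd.read_csv(path)
        return cls(df[["x_um", "y_um"]].to_numpy())

    @classmethod
    def from_function(cls, fn, x0, x1, step_um=0.5) -> "BoundaryCurve":
        x = np.arange(x0, x1 + step_um / 2, step_um)
        return cls(np.column_stack([x, fn(x)]))


@dataclass
class IntensityProfile:
    """Intensity sampled along a short trajectory crossing the EDJ.

    ``positions_um`` are signed distances along the trajectory with 0 at the
    EDJ crossing; the total span is the trajectory length (25 µm default).
    """

    positions_um: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.positions_um) <= 0):
            raise ValueError("profile positions must be strictly increasing")


@dataclass
class EpidermisMetrics:
    thickness_um: float
    ki67_fraction: float
    arc_chord_ratio: float
    bm_width_um: float
    bm_peak: float


# --------------------------------------------------------------------------

def epidermal_thickness(top: BoundaryCurve, edj: BoundaryCurve,
                        n_probes: int = 10, spacing_um: float = 150.0,
                        x_start: float | None = None):
    """Viable-epidermis thickness probed by vertical rays at ``n_probes``
    locations ``spacing_um`` apart; returns ``(mean_um, per-probe array)``.
    """
    span = (n_probes - 1) * spacing_um
    x_lo = max(top.vertices[:, 0].min(), edj.vertices[:, 0].min())
    x_hi = min(top.vertices[:, 0].max(), edj.vertices[:, 0].max())
    if x_hi - x_lo < span:
        raise ValueError(
            f"boundaries span {x_hi - x_lo:.0f} µm horizontally; "
            f"{span:.0f} µm required for {n_probes} probes {spacing_um:.0f} µm apart")
    if x_start is None:
        x_start = x_lo + (x_hi - x_lo - span) / 2.0
    xs = x_start + spacing_um * np.arange(n_probes)
    per_probe = edj.y_at(xs) - top.y_at(xs)
    return float(np.mean(per_probe)), per_probe


def ki67_fraction(nuclei: PointSet, ki67: np.ndarray, pixel_size_um: float,
                  region: np.ndarray, window_um: float = 250.0,
                  positivity_threshold="otsu", disk_radius_um: float = 2.5):
    """Fraction of Ki67-positive nuclei among nuclei in an epidermal region.

    A nucleus is positive when its mean Ki67 intensity over a disk at its
    centre exceeds the positivity threshold (Otsu over the per-nucleus means
    by default, or a fixed value).  Returns ``(pooled_fraction,
    per-window DataFrame)`` with one row per ``window_um`` bin along x; the
    pooled fraction is NaN (missing) when no nucleus lies in the region.
    """
    region = np.asarray(region, bool)
    ny, nx = region.shape
    in_region = []
    for (x, y) in np.atleast_2d(nuclei.centres_um) if len(nuclei) else []:
        r, c = int(y / pixel_size_um), int(x / pixel_size_um)
        in_region.append(0 <= r < ny and 0 <= c < nx and region[r, c])
    in_region = np.array(in_region, bool) if len(nuclei) else np.empty(0, bool)
    centres = nuclei.centres_um[in_region] if len(nuclei) else np.empty((0, 2))
    if len(centres) == 0:
        return float("nan"), pd.DataFrame(columns=["window_x0_um", "n", "n_positive", "fraction"])

    r_px = disk_radius_um / pixel_size_um
    means = np.empty(len(centres))
    for i, (x, y) in enumerate(centres):
        cx, cy = x / pixel_size_um, y / pixel_size_um
        r0, r1 = max(int(cy - r_px), 0), min(int(cy + r_px) + 2, ny)
        c0, c1 = max(int(cx - r_px), 0), min(int(cx + r_px) + 2, nx)
        cols, rows = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        disk = np.hypot(cols + 0.5 - cx, rows + 0.5 - cy) < r_px
        means[i] = ki67[r0:r1, c0:c1][disk].mean() if disk.any() else 0.0

    if positivity_threshold == "otsu":
        thr = float(filters.threshold_otsu(means)) if means.max() > means.min() else np.inf
    else:
        thr = float(positivity_threshold)
    positive = means > thr

    bins = np.floor(centres[:, 0] / window_um).astype(int)
    rows_out = []
    for b in np.unique(bins):
        sel = bins == b
        rows_out.append({"window_x0_um": b * window_um, "n": int(sel.sum()),
                         "n_positive": int(positive[sel].sum()),
                         "fraction": float(positive[sel].mean())})
    pooled = float(positive.mean())
    return pooled, pd.DataFrame(rows_out)


def arc_chord_ratio(edj: BoundaryCurve, section_length_um: float):
    """Interdigitation of a boundary: split into consecutive sections of
    equal arc length and divide each section's arc length by its end-to-end
    distance.  Returns ``(mean_ratio, per-section array, whole_curve_ratio)``;
    the trailing remainder shorter than one section is discarded.
    """
    if section_length_um <= 0:
        raise ValueError("section_length_um must be > 0")
    total = edj.arc_length
    if total < section_length_um:
        raise ValueError("curve arc length is shorter than one section")
    n = int(total // section_length_um)
    ticks = edj.point_at(section_length_um * np.arange(n + 1))
    chords = np.linalg.norm(np.diff(ticks, axis=0), axis=1)
    per_section = section_length_um / chords
    whole = total / float(np.linalg.norm(edj.vertices[-1] - edj.vertices[0]))
    return float(np.mean(per_section)), per_section, whole


def edj_profiles(coliv: np.ndarray, pixel_size_um: float, edj: BoundaryCurve,
                 trajectory_length_um: float = 25.0, n_trajectories: int = 20,
                 logger=None):
    """Sample COLIV intensity along trajectories normal to the EDJ.

    Trajectories are centred on the EDJ, oriented along the local normal,
    sampled at pixel resolution.  Trajectories that exit the image are
    skipped (and logged).  Returns a list of :class:`IntensityProfile`.
    """
    ny, nx = coliv.shape
    total = edj.arc_length
    margin = trajectory_length_um / 2.0
    s = np.linspace(margin, total - margin, n_trajectories)
    pts = edj.point_at(s)
    # local tangent by central difference in arc length
    ds = max(2 * pixel_size_um, total / 500.0)
    ahead = edj.point_at(np.clip(s + ds, 0, total))
    behind = edj.point_at(np.clip(s - ds, 0, total))
    tang = ahead - behind
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    normal = np.column_stack([-tang[:, 1], tang[:, 0]])

    half = trajectory_length_um / 2.0
    t = np.arange(-half, half + pixel_size_um / 2, pixel_size_um)
    profiles = []
    for p, nvec in zip(pts, normal):
        xy = p[None, :] + t[:, None] * nvec[None, :]
        cols = xy[:, 0] / pixel_size_um - 0.5
        rows = xy[:, 1] / pixel_size_um - 0.5
        if (rows.min() < 0 or cols.min() < 0
                or rows.max() > ny - 1 or cols.max() > nx - 1):
            if logger is not None:
                logger.warning("skipping trajectory at (%.1f, %.1f) µm: exits image",
                               p[0], p[1])
            continue
        vals = ndimage.map_coordinates(coliv, [rows, cols], order=1)
        profiles.append(IntensityProfile(positions_um=t.copy(), values=vals))
    return profiles


def profile_width_peak(profile: IntensityProfile):
    """Basement-membrane width and peak from one intensity profile.

    Baseline is the mean of the outer 20% of samples at each end; peak is
    max − baseline; width is the full width at half the peak, linearly
    interpolated between samples.  Returns ``(width_um, peak)``; width is
    NaN (missing) when the peak is not positive.
    """
    v = np.asarray(profile.values, float)
    pos = np.asarray(profile.positions_um, float)
    if len(v) < 5:
        raise ValueError("profile needs >= 5 samples")
    k = max(int(round(0.2 * len(v))), 1)
    baseline = float(np.mean(np.concatenate([v[:k], v[-k:]])))
    peak = float(v.max() - baseline)
    if peak <= 0:
        return float("nan"), peak
    half = baseline + peak / 2.0
    imax = int(np.argmax(v))
    # walk outward from the maximum to the half-crossings
    left = pos[0]
    for i in range(imax, 0, -1):
        if v[i - 1] < half <= v[i]:
            frac = (half - v[i - 1]) / (v[i] - v[i - 1])
            left = pos[i - 1] + frac * (pos[i] - pos[i - 1])
            break
    right = pos[-1]
    for i in range(imax, len(v) - 1):
        if v[i + 1] < half <= v[i]:
            frac = (v[i] - half) / (v[i] - v[i + 1])
            right = pos[i] + frac * (pos[i + 1] - pos[i])
            break
    return float(right - left), peak
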