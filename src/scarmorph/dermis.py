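"""Dermal morphometry: cell and vessel density, collagen architecture,
fibre orientation and alignment, and normalized SHG intensity.

The alignment coefficient is the circular-statistics mean resultant length
of doubled orientation angles: R = |Σ w·exp(2iθ)| / Σ w.  Doubling removes
the 180° ambiguity of undirected fibres; R = 1 means perfectly aligned
fibres and values near 0 an isotropic field.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.feature import structure_tensor

from .segmentation import FibreClassMask, PointSet, THIN, THICK

__all__ = [
    "DermisMetrics",
    "OrientationField",
    "cell_density",
    "vessel_density",
    "collagen_fractions",
    "orientation_field",
    "alignment_coefficient",
    "normalized_shg_intensity",
    "orientation_histogram",
]


@dataclass
class DermisMetrics:
    cell_density_per_mm2: float
    vessel_density_pct: float
    collagen_fraction: float
    thick_proportion: float
    mean_thickness_um: float
    alignment_coefficient: float
    normalized_shg_intensity: float


@dataclass
class OrientationField:
    """Per-pixel fibre orientation (deg, [0, 180)) and anisotropy coherence
    ([0, 1]); both defined only on fibre pixels (NaN elsewhere)."""

    angle_deg: np.ndarray
    coherence: np.ndarray
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)

    def angles(self):
        """Valid angles (deg) on fibre pixels, flattened."""
        return self.angle_deg[self.mask]


# --------------------------------------------------------------------------

def cell_density(nuclei: PointSet, roi_um) -> float:
    """Nuclei per mm² inside a rectangular ROI ``(x0, y0, x1, y1)`` in µm."""
    x0, y0, x1, y1 = roi_um
    area_mm2 = (x1 - x0) * (y1 - y0) / 1e6
    if area_mm2 <= 0:
        raise ValueError("ROI area must be > 0")
    if len(nuclei) == 0:
        return 0.0
    c = nuclei.centres_um
    inside = (c[:, 0] >= x0) & (c[:, 0] < x1) & (c[:, 1] >= y0) & (c[:, 1] < y1)
    return float(inside.sum() / area_mm2)


def vessel_density(mask: np.ndarray, roi: np.ndarray) -> float:
    """Percentage of ROI pixels covered by the vessel mask."""
    roi = np.asarray(roi, bool)
    n = roi.sum()
    if n == 0:
        raise ValueError("ROI is empty")
    return float(100.0 * (np.asarray(mask, bool) & roi).sum() / n)


def collagen_fractions(mask: FibreClassMask, roi: np.ndarray | None = None):
    """Collagen architecture summary from a fibre-class mask.

    Returns ``(collagen_fraction, thick_proportion, mean_thickness_um)``
    over the ROI (boolean raster; whole image when None).  ``thick_proportion``
    and ``mean_thickness_um`` are NaN when the ROI contains no fibre pixels;
    mean thickness is the area-weighted mean local fibre width.
    """
    labels = mask.labels
    roi = np.ones(labels.shape, bool) if roi is None else np.asarray(roi, bool)
    total = roi.sum()
    thin_px = int(((labels == THIN) & roi).sum())
    thick_px = int(((labels == THICK) & roi).sum())
    fibre_px = thin_px + thick_px
    frac = fibre_px / total if total else float("nan")
    if fibre_px == 0:
        return float(frac), float("nan"), float("nan")
    thick_prop = thick_px / fibre_px
    mean_um = float(np.nanmean(mask.thickness_um[(labels > 0) & roi]))
    return float(frac), float(thick_prop), mean_um


def orientation_field(shg: np.ndarray, fibre_mask: np.ndarray,
                      pixel_size_um: float,
                      smoothing_scale_um: float = 4.0) -> OrientationField:
    """Per-pixel dominant orientation from the local structure tensor.

    The fibre direction at a pixel is the eigenvector of the smaller
    eigenvalue of the smoothed structure tensor; coherence is
    (λ₁ − λ₂)/(λ₁ + λ₂).  Angles follow the image convention (x rightward,
    y downward, 0° parallel to the epidermis, range [0°, 180°)).
    """
    fibre_mask = np.asarray(fibre_mask, bool)
    if not fibre_mask.any():
        raise ValueError("no fibre pixels to orient")
    sigma = smoothing_scale_um / pixel_size_um
    Arr, Arc, Acc = structure_tensor(np.asarray(shg, float), sigma=sigma, order="rc")
    # gradient-dominant direction angle (in row/col = y/x chart); fibres run
    # perpendicular to the dominant gradient
    grad_angle = 0.5 * np.arctan2(2 * Arc, Acc - Arr)
    fibre_angle = np.rad2deg(grad_angle) + 90.0
    angle = np.where(fibre_mask, fibre_angle % 180.0, np.nan)
    tr = Arr + Acc
    det_disc = np.sqrt(np.maximum((Arr - Acc) ** 2 + 4 * Arc**2, 0.0))
    coh = np.where(tr > 1e-12, det_disc / np.maximum(tr, 1e-12), 0.0)
    coherence = np.where(fibre_mask, np.clip(coh, 0.0, 1.0), np.nan)
    return OrientationField(angle, coherence, fibre_mask,
                            provenance={"smoothing_scale_um": smoothing_scale_um})


def alignment_coefficient(angles_deg, weights=None) -> float:
    """Mean resultant length of doubled angles; 1 = perfectly aligned.

    Accepts an :class:`OrientationField` (votes weighted by local coherence
    by default, which discounts fibre-interior pixels whose gradient carries
    no orientation signal; pass ``weights="uniform"`` for one vote per fibre
    pixel) or an array of angles in degrees, optionally weighted.
    """
    if isinstance(angles_deg, OrientationField):
        field = angles_deg
        angles_deg = field.angles()
        if weights is None or weights == "coherence":
            weights = field.coherence[field.mask]
        elif weights == "uniform":
            weights = None
        elif isinstance(weights, str):
            raise ValueError(f"unknown weighting {weights!r}")
    a = np.asarray(angles_deg, float).ravel()
    a = a[np.isfinite(a)]
    if a.size == 0:
        raise ValueError("alignment coefficient of an empty angle set is undefined")
    w = np.ones_like(a) if weights is None else np.asarray(weights, float).ravel()
    z = np.sum(w * np.exp(2j * np.deg2rad(a)))
    return float(np.abs(z) / np.sum(w))


def normalized_shg_intensity(shg: np.ndarray, fibre_mask: np.ndarray,
                             background: np.ndarray) -> float:
    """Mean SHG intensity over fibre pixels divided by the background mean."""
    shg = np.asarray(shg, float)
    fibre_mask = np.asarray(fibre_mask, bool)
    background = np.asarray(background, bool)
    if not fibre_mask.any() or not background.any():
        raise ValueError("fibre and background regions must both be non-empty")
    bg = shg[background].mean()
    if bg == 0:
        raise ValueError("background mean intensity is zero; ratio undefined")
    return float(shg[fibre_mask].mean() / bg)


def orientation_histogram(field: OrientationField, bin_deg: float = 1.0) -> pd.DataFrame:
    """Histogram of fibre-pixel orientations in ``bin_deg``-degree bins."""
    edges = np.arange(0.0, 180.0 + bin_deg / 2, bin_deg)
    counts, _ = np.histogram(field.angles(), bins=edges)
    return pd.DataFrame({"angle_deg": edges[:-1], "count": counts})
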