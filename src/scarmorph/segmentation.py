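"""Channel-to-mask stage: collagen fibre classification, nuclei, vessels.

The three-class fibre segmentation follows an operational definition of
fibre calibre: foreground by intensity threshold, per-pixel local thickness
(largest inscribed disk), skeleton-based splitting into non-branching fibre
segments, and a thin/thick split at a mean width along the skeleton of
10 µm (inclusive for thin).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import filters, morphology
from skimage.feature import blob_log

__all__ = [
    "SectionImage",
    "FibreClassMask",
    "PointSet",
    "BACKGROUND", "THIN", "THICK",
    "THIN_THICK_SPLIT_UM",
    "segment_fibres",
    "local_thickness_map",
    "detect_nuclei",
    "vessel_mask",
]

BACKGROUND, THIN, THICK = 0, 1, 2
THIN_THICK_SPLIT_UM = 10.0   # mean width along the fibre <= 10 um -> thin


@dataclass
class SectionImage:
    """Multi-channel 2D section with a physical pixel size in µm."""

    channels: dict
    pixel_size_um: float
    roi: tuple | None = None   # (x0, y0, x1, y1) in µm

    def __post_init__(self):
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) > 1:
            raise ValueError(f"channels disagree in shape: {shapes}")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        for name, ch in self.channels.items():
            if not np.all(np.isfinite(ch)) or np.any(ch < 0):
                raise ValueError(f"channel {name!r} must be finite and >= 0")

    @property
    def shape(self):
        return next(iter(self.channels.values())).shape

    def to_tiff(self, path) -> None:
        names = list(self.channels)
        stack = np.stack([self.channels[n] for n in names]).astype(np.float32)
        meta = {"channel_names": names, "pixel_size_um": self.pixel_size_um}
        tifffile.imwrite(path, stack, description=json.dumps(meta),
                         photometric="minisblack")

    @classmethod
    def from_tiff(cls, path, pixel_size_um: float | None = None) -> "SectionImage":
        with tifffile.TiffFile(path) as tf:
            stack = tf.asarray()
            desc = tf.pages[0].description
        names = None
        if desc:
            try:
                meta = json.loads(desc)
                names = meta.get("channel_names")
                pixel_size_um = pixel_size_um or meta.get("pixel_size_um")
            except (ValueError, AttributeError):
                pass
        if pixel_size_um is None:
            raise ValueError("pixel size not in TIFF metadata; pass pixel_size_um")
        if stack.ndim == 2:
            stack = stack[None]
        if names is None:
            names = [f"ch{i}" for i in range(stack.shape[0])]
        return cls(channels={n: stack[i].astype(float) for i, n in enumerate(names)},
                   pixel_size_um=float(pixel_size_um))


@dataclass
class FibreClassMask:
    """Per-pixel {background, thin, thick} labels plus local thickness (µm)."""

    labels: np.ndarray            # uint8, values BACKGROUND/THIN/THICK
    thickness_um: np.ndarray      # NaN on background
    fibre_table: pd.DataFrame     # fibre_id, mean_width_um, fibre_class, area_px
    pixel_size_um: float
    provenance: dict = field(default_factory=dict)


@dataclass
class PointSet:
    """Detected point features (e.g. nucleus centres) in µm."""

    centres_um: np.ndarray        # (n, 2) as (x, y)
    labels: np.ndarray | None = None  # optional per-point marker positivity

    def __len__(self):
        return len(self.centres_um)


# --------------------------------------------------------------------------
# Local thickness
# --------------------------------------------------------------------------

def local_thickness_map(mask: np.ndarray, pixel_size_um: float) -> np.ndarray:
    """Local thickness: at each foreground pixel, the diameter (µm) of the
    largest open disk fully inside the foreground that contains the pixel.

    Computed by covering the foreground with maximal inscribed disks: every
    pixel c carries a disk of radius EDT(c); processing radii in descending
    order, each still-unassigned pixel within strict distance EDT(c) of any
    centre of that radius gets thickness 2·EDT(c).  Background is NaN.
    """
    mask = np.asarray(mask, bool)
    out = np.full(mask.shape, np.nan)
    if not mask.any():
        return out
    # pad with background: a disk crossing the image edge is not inside the
    # foreground, so the image boundary acts as background
    padded = np.pad(mask, 1)
    edt = ndimage.distance_transform_edt(padded)
    result = np.zeros(padded.shape)
    eps = 1e-9
    for r in np.unique(edt[padded])[::-1]:
        if r <= 0:
            break
        centres = edt == r
        unset = padded & (result == 0)
        if not unset.any():
            break
        # distance from every pixel to the nearest centre of this radius
        d = ndimage.distance_transform_edt(~centres)
        covered = unset & (d <= r + eps)
        result[covered] = 2.0 * r
    out[mask] = result[1:-1, 1:-1][mask] * pixel_size_um
    return out


def _skeleton_segments(fg: np.ndarray):
    """Skeletonize and split at junctions; returns (segment label raster, n)."""
    skel = morphology.skeletonize(fg)
    if not skel.any():
        return np.zeros(fg.shape, np.int32), 0
    deg = ndimage.convolve(skel.astype(np.uint8), np.ones((3, 3), np.uint8),
                           mode="constant") - 1
    body = skel & (deg <= 2)
    seg, n = ndimage.label(body, structure=np.ones((3, 3)))
    return seg.astype(np.int32), n


def segment_fibres(shg: np.ndarray, pixel_size_um: float,
                   intensity_threshold_mode="otsu") -> FibreClassMask:
    """Three-class collagen segmentation of an SHG raster.

    ``intensity_threshold_mode`` is ``"otsu"`` or a fixed numeric threshold.
    Foreground pixels are grouped into non-branching fibre segments via the
    skeleton; each segment's width is the mean local thickness sampled on
    its skeleton pixels, and the segment (with all foreground pixels nearest
    to it) is classed thin (≤ 10 µm) or thick (> 10 µm).
    """
    shg = np.asarray(shg, float)
    if intensity_threshold_mode == "otsu":
        thr = float(filters.threshold_otsu(shg)) if shg.max() > shg.min() else np.inf
    else:
        thr = float(intensity_threshold_mode)
    fg = shg > thr
    labels = np.zeros(shg.shape, np.uint8)
    thickness = local_thickness_map(fg, pixel_size_um)
    prov = {"threshold_mode": str(intensity_threshold_mode), "threshold": thr,
            "split_um": THIN_THICK_SPLIT_UM}
    if not fg.any():
        return FibreClassMask(labels, thickness,
                              pd.DataFrame(columns=["fibre_id", "mean_width_um",
                                                    "fibre_class", "area_px"]),
                              pixel_size_um, prov)

    seg, n_seg = _skeleton_segments(fg)
    if n_seg == 0:
        # degenerate foreground (e.g. single pixels): class by own thickness
        thin = fg & (thickness <= THIN_THICK_SPLIT_UM)
        labels[thin] = THIN
        labels[fg & ~thin] = THICK
        table = pd.DataFrame(columns=["fibre_id", "mean_width_um", "fibre_class", "area_px"])
        return FibreClassMask(labels, thickness, table, pixel_size_um, prov)

    # assign every foreground pixel to the nearest skeleton-segment pixel of
    # its own connected component (fibres never trade pixels across gaps)
    comp, n_comp = ndimage.label(fg, structure=np.ones((3, 3)))
    assign = np.zeros(shg.shape, np.int32)
    for ci, sl in enumerate(ndimage.find_objects(comp), start=1):
        sub_fg = comp[sl] == ci
        sub_seg = np.where(sub_fg, seg[sl], 0)
        if not (sub_seg > 0).any():
            continue
        _, (ir, ic) = ndimage.distance_transform_edt(sub_seg == 0,
                                                     return_indices=True)
        near = sub_seg[ir, ic]
        assign[sl] = np.where(sub_fg, near, assign[sl])

    rows = []
    widths = ndimage.labeled_comprehension(
        thickness, seg, np.arange(1, n_seg + 1), np.nanmean, float, np.nan)
    areas = ndimage.sum_labels(fg, assign, np.arange(1, n_seg + 1))
    class_of = np.zeros(n_seg + 1, np.uint8)
    for i in range(1, n_seg + 1):
        w = widths[i - 1]
        cls = THIN if w <= THIN_THICK_SPLIT_UM else THICK
        class_of[i] = cls
        rows.append({"fibre_id": i, "mean_width_um": float(w),
                     "fibre_class": "thin" if cls == THIN else "thick",
                     "area_px": int(areas[i - 1])})
    labels[fg] = class_of[assign[fg]]
    # degenerate foreground without a skeleton segment: class by own thickness
    orphan = fg & (assign == 0)
    if orphan.any():
        thin = orphan & (thickness <= THIN_THICK_SPLIT_UM)
        labels[thin] = THIN
        labels[orphan & ~thin] = THICK
    return FibreClassMask(labels, thickness, pd.DataFrame(rows), pixel_size_um, prov)


# --------------------------------------------------------------------------
# Nuclei and vessels
# --------------------------------------------------------------------------

def detect_nuclei(dapi: np.ndarray, pixel_size_um: float,
                  diameter_range_um=(4.0, 9.0),
                  detection_threshold: float = 0.1) -> PointSet:
    """Multiscale (Laplacian-of-Gaussian) blob detection of nuclei.

    Returns centres in µm; no two centres closer than half the minimum
    diameter.  ``detection_threshold`` is relative to the image maximum.
    """
    dapi = np.asarray(dapi, float)
    if dapi.max() <= 0:
        return PointSet(np.empty((0, 2)))
    d_lo, d_hi = diameter_range_um
    if d_lo / pixel_size_um < 2:
        raise ValueError("minimum nucleus diameter is below the resolvable scale")
    img = dapi / dapi.max()
    sig = 1.0 / (2.0 * np.sqrt(2.0))
    blobs = blob_log(img,
                     min_sigma=sig * d_lo / pixel_size_um,
                     max_sigma=sig * d_hi / pixel_size_um,
                     num_sigma=8, threshold=detection_threshold,
                     overlap=0.3)
    if len(blobs) == 0:
        return PointSet(np.empty((0, 2)))
    centres = np.column_stack([(blobs[:, 1] + 0.5) * pixel_size_um,
                               (blobs[:, 0] + 0.5) * pixel_size_um])
    # greedy minimum-separation suppression, strongest response first
    resp = np.array([img[int(r), int(c)] for r, c, _ in blobs])
    order = np.argsort(resp)[::-1]
    min_sep = d_lo / 2.0
    kept = []
    for i in order:
        if all(np.hypot(*(centres[i] - centres[j])) >= min_sep for j in kept):
            kept.append(i)
    kept.sort()
    return PointSet(centres[kept])


def vessel_mask(coliv: np.ndarray, region: np.ndarray,
                threshold="otsu"):
    """Binary vessel mask: threshold the COLIV channel within a dermis region.

    Returns ``(mask, provenance)``.  ``region`` is a boolean raster of the
    same shape; pixels outside it are never masked.
    """
    coliv = np.asarray(coliv, float)
    region = np.asarray(region, bool)
    if region.shape != coliv.shape:
        raise ValueError("region must match the image shape")
    if not region.any():
        raise ValueError("region is empty / outside the image")
    vals = coliv[region]
    if threshold == "otsu":
        thr = float(filters.threshold_otsu(vals)) if vals.max() > vals.min() else np.inf
    else:
        thr = float(threshold)
    mask = np.zeros(coliv.shape, bool)
    if vals.max() > vals.min():
        mask[region] = coliv[region] > thr
    elif vals.max() > 0:
        mask[region] = True   # saturated channel: everything stained
    prov = {"method": "otsu" if threshold == "otsu" else "fixed", "threshold": thr}
    return mask, prov
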