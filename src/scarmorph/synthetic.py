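"""Synthetic skin-section images and expression datasets with exact ground truth.

Every generator records, at generation time, the quantities the downstream
morphometry is supposed to recover (nucleus centres, per-fibre widths and
angles, true arc-chord ratio of the epidermal-dermal junction, painted pixel
areas), so parameter-recovery tests need no external data.

Coordinate convention: origin at the top-left corner, x rightward (parallel
to the epidermis), y downward (depth).  A pixel at array position
``(row, col)`` has its centre at ``((col + 0.5) * px, (row + 0.5) * px)`` µm.
Fibre orientation angles live in [0°, 180°), 0° meaning parallel to the
epidermis, measured toward +y (image-down) so that both the generator and the
structure-tensor estimator share one chart.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "SectionSpec",
    "GroundTruth",
    "generate_section_image",
    "generate_fibre_field",
    "generate_expression_dataset",
    "section_masks",
    "sinusoid_arc_chord",
]

# Fixed rendering constants (µm unless noted).  These are presentation
# details, not study parameters, so they are module-level rather than spec
# fields.
TOP_MARGIN_UM = 20.0          # flat top boundary of the viable epidermis
NUCLEUS_RADIUS_UM = 3.0       # nuclei are drawn as disks of this radius
NUCLEUS_INTENSITY = 200.0
KI67_INTENSITY = 200.0
VESSEL_WALL_UM = 2.5          # vessel basement-membrane ring thickness
VESSEL_OUTER_UM = (6.0, 12.0)  # outer radius range of vessel cross-sections
VESSEL_INTENSITY = 180.0
BM_EXCLUSION_UM = 12.0        # dermal analysis region starts this far below the EDJ


# --------------------------------------------------------------------------
# Specs and ground truth
# --------------------------------------------------------------------------

@dataclass
class SectionSpec:
    """Parameters of a synthetic layered skin section.

    Defaults emulate a mature scalp-scar biopsy ROI: 600 × 450 µm field,
    a thin (~50 µm) viable epidermis over a gently undulating EDJ, a
    basement-membrane band with a Gaussian cross-profile, sparse nuclei with
    a low proliferating fraction, ~6% vessel area, and a dermal collagen
    field mixing thin (6 µm) and thick (14 µm) fibres with a preferred
    orientation parallel to the epidermis.
    """

    width_um: float = 600.0
    height_um: float = 450.0
    pixel_size_um: float = 0.5
    epidermal_thickness_um: float = 50.0
    edj_amplitude_um: float = 10.0
    edj_period_um: float = 100.0
    bm_sigma_um: float = 2.0
    bm_peak: float = 100.0
    nuclei_density_per_mm2: float = 800.0
    ki67_fraction: float = 0.04
    vessel_area_fraction: float = 0.06
    fibre_widths_um: tuple = (6.0, 14.0)
    fibre_width_weights: tuple = (0.5, 0.5)
    orientation_kappa: float = 5.0
    mean_angle_deg: float = 0.0
    fibre_area_fraction: float = 0.25
    shg_fibre_intensity: float = 150.0
    shg_background_intensity: float = 50.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        positive = [
            "width_um", "height_um", "pixel_size_um", "epidermal_thickness_um",
            "edj_period_um", "bm_sigma_um",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValueError(f"SectionSpec.{name} must be > 0, got {getattr(self, name)!r}")
        for name in ["edj_amplitude_um", "bm_peak", "nuclei_density_per_mm2",
                     "shg_fibre_intensity", "shg_background_intensity", "noise_sd"]:
            if getattr(self, name) < 0:
                raise ValueError(f"SectionSpec.{name} must be >= 0, got {getattr(self, name)!r}")
        for name in ["ki67_fraction", "vessel_area_fraction", "fibre_area_fraction"]:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"SectionSpec.{name} must be in [0, 1], got {v!r}")
        if len(self.fibre_widths_um) != len(self.fibre_width_weights):
            raise ValueError("SectionSpec.fibre_width_weights length must match fibre_widths_um")
        if any(w <= 0 for w in self.fibre_widths_um):
            raise ValueError("SectionSpec.fibre_widths_um entries must be > 0")
        if abs(sum(self.fibre_width_weights) - 1.0) > 1e-9:
            raise ValueError("SectionSpec.fibre_width_weights must sum to 1")
        if self.fibre_area_fraction > 0 and self.pixel_size_um > min(self.fibre_widths_um) / 3.0:
            raise ValueError(
                "SectionSpec.pixel_size_um must be <= min(fibre width)/3 so widths are resolvable"
            )


@dataclass
class GroundTruth:
    """Everything the generator knows exactly about a rendered section."""

    spec: SectionSpec
    nucleus_centres_um: list          # [(x, y), ...] all nuclei
    nucleus_in_epidermis: list        # bool per nucleus
    ki67_positive: list               # bool per nucleus (False outside epidermis)
    fibre_table: list                 # dicts: fibre_id, width_um, angle_deg, area_px
    true_arc_chord: float             # per-period arc-chord ratio of the EDJ sinusoid
    true_collagen_fraction: float     # fibre px / dermal fibre-canvas px
    true_thick_area_proportion: float  # thick-class px / fibre px
    true_vessel_area_fraction: float  # vessel px / dermal analysis-region px
    fibre_canvas_top_um: float        # y where the fibre canvas starts
    epidermis_px: int
    dermis_px: int

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["spec"] = dataclasses.asdict(self.spec)
        d["spec"]["fibre_widths_um"] = list(self.spec.fibre_widths_um)
        d["spec"]["fibre_width_weights"] = list(self.spec.fibre_width_weights)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            d = json.load(fh)
        spec = d.pop("spec")
        spec["fibre_widths_um"] = tuple(spec["fibre_widths_um"])
        spec["fibre_width_weights"] = tuple(spec["fibre_width_weights"])
        d["nucleus_centres_um"] = [tuple(c) for c in d["nucleus_centres_um"]]
        return cls(spec=SectionSpec(**spec), **d)


# --------------------------------------------------------------------------
# Geometry helpers
# --------------------------------------------------------------------------

def edj_depth_um(spec: SectionSpec, x_um: np.ndarray) -> np.ndarray:
    """Depth (y, µm) of the EDJ at horizontal position x."""
    return (TOP_MARGIN_UM + spec.epidermal_thickness_um
            + spec.edj_amplitude_um * np.sin(2 * np.pi * np.asarray(x_um) / spec.edj_period_um))


def sinusoid_arc_chord(amplitude_um: float, period_um: float, n: int = 200_001) -> float:
    """Arc-chord ratio of one period of A·sin(2πx/L), by dense polyline summation."""
    x = np.linspace(0.0, period_um, n)
    y = amplitude_um * np.sin(2 * np.pi * x / period_um)
    arc = np.sum(np.hypot(np.diff(x), np.diff(y)))
    return float(arc / period_um)


def section_masks(spec: SectionSpec):
    """Epidermis / dermis / dermal-analysis masks for a spec's pixel grid.

    Returns ``(epidermis, dermis, dermal_region)`` boolean arrays.  The
    dermal analysis region is the dermis excluding a band of
    ``BM_EXCLUSION_UM`` below the EDJ, so basement-membrane staining does not
    leak into dermal vessel or fibre statistics.
    """
    ny = int(round(spec.height_um / spec.pixel_size_um))
    nx = int(round(spec.width_um / spec.pixel_size_um))
    x = (np.arange(nx) + 0.5) * spec.pixel_size_um
    y = (np.arange(ny) + 0.5) * spec.pixel_size_um
    edj = edj_depth_um(spec, x)[None, :]
    yy = y[:, None]
    epidermis = (yy >= TOP_MARGIN_UM) & (yy < edj)
    dermis = yy >= edj
    dermal_region = yy >= edj + BM_EXCLUSION_UM
    return epidermis, np.broadcast_to(dermis, (ny, nx)).copy(), \
        np.broadcast_to(dermal_region, (ny, nx)).copy()


def _sample_orientation(rng: np.random.Generator, mean_deg: float, kappa: float,
                        size: int) -> np.ndarray:
    """Orientation angles in [0, 180) with von Mises-concentrated doubled angles."""
    if np.isinf(kappa):
        return np.full(size, mean_deg % 180.0)
    doubled = rng.vonmises(np.deg2rad(2 * mean_deg), kappa, size)
    return (np.rad2deg(doubled) / 2.0) % 180.0


# --------------------------------------------------------------------------
# Fibre field
# --------------------------------------------------------------------------

def _stroke_footprint(shape, p0, p1, half_width_px):
    """Pixel mask of a constant-width stroke (round caps): dist(centre, segment) < w/2."""
    ny, nx = shape
    r0 = max(int(np.floor(min(p0[1], p1[1]) - half_width_px - 1)), 0)
    r1 = min(int(np.ceil(max(p0[1], p1[1]) + half_width_px + 1)), ny - 1)
    c0 = max(int(np.floor(min(p0[0], p1[0]) - half_width_px - 1)), 0)
    c1 = min(int(np.ceil(max(p0[0], p1[0]) + half_width_px + 1)), nx - 1)
    if r1 < r0 or c1 < c0:
        return None, None
    cols, rows = np.meshgrid(np.arange(c0, c1 + 1), np.arange(r0, r1 + 1))
    px = cols + 0.5
    py = rows + 0.5
    dx, dy = p1[0] - p0[0], p1[1] - p0[1]
    seg2 = dx * dx + dy * dy
    if seg2 == 0:
        dist = np.hypot(px - p0[0], py - p0[1])
    else:
        t = np.clip(((px - p0[0]) * dx + (py - p0[1]) * dy) / seg2, 0.0, 1.0)
        dist = np.hypot(px - (p0[0] + t * dx), py - (p0[1] + t * dy))
    return (slice(r0, r1 + 1), slice(c0, c1 + 1)), dist < half_width_px


def generate_fibre_field(
    widths_um: Sequence[float],
    weights: Sequence[float],
    kappa: float,
    area_fraction: float,
    seed,
    *,
    width_um: float = 300.0,
    height_um: float = 300.0,
    pixel_size_um: float = 0.5,
    mean_angle_deg: float = 0.0,
    stroke_length_um: tuple = (60.0, 150.0),
    gap_px: int = 2,
    max_rejects: int = 20000,
):
    """Pack non-overlapping constant-width curvilinear strokes into a raster.

    ``weights`` are *area* weights: each width class is grown until its share
    of the painted area reaches its weight.  Returns ``(labels, table,
    truth)`` where ``labels`` is an int32 raster of fibre ids (0 =
    background), ``table`` a DataFrame with one row per fibre (fibre_id,
    width_um, angle_deg, area_px, length_um) and ``truth`` a dict with the
    realized collagen fraction and thick-area proportion.

    Raises ``ValueError`` when the requested packing is infeasible (realized
    area fraction falls short of 90% of the request).
    """
    rng = np.random.default_rng(seed)
    widths_um = list(widths_um)
    weights = np.asarray(weights, float)
    if not np.all(np.asarray(widths_um) > 0):
        raise ValueError("fibre widths must be > 0")
    if not 0 < area_fraction < 1:
        raise ValueError("area_fraction must be in (0, 1)")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")

    ny = int(round(height_um / pixel_size_um))
    nx = int(round(width_um / pixel_size_um))
    labels = np.zeros((ny, nx), np.int32)
    occupied = np.zeros((ny, nx), bool)   # foreground dilated by gap_px
    target_px = area_fraction * ny * nx
    class_target = weights * target_px
    class_area = np.zeros(len(widths_um))
    rows = []
    rejects = 0
    fibre_id = 0
    while np.any(class_area < class_target) and rejects < max_rejects:
        k = int(np.argmax((class_target - class_area) / np.maximum(class_target, 1e-9)))
        w_px = widths_um[k] / pixel_size_um
        angle = float(_sample_orientation(rng, mean_angle_deg, kappa, 1)[0])
        length_px = rng.uniform(*stroke_length_um) / pixel_size_um
        # dense packings converge faster with shorter strokes once random
        # placement starts colliding
        if rejects > max_rejects // 4:
            length_px /= 2.0
        # trim the stroke so the class does not overshoot its area target
        deficit_px = class_target[k] - class_area[k]
        if length_px * w_px > deficit_px:
            length_px = max(deficit_px / w_px, 2 * w_px)
        theta = np.deg2rad(angle)
        d = np.array([np.cos(theta), np.sin(theta)])  # (x, y-down)
        # strokes stay fully interior so rendered widths equal nominal widths
        # (the image border counts as background for local thickness)
        ext = 0.5 * length_px * np.abs(d) + w_px / 2.0 + 1.0
        if 2 * ext[0] >= nx or 2 * ext[1] >= ny:
            length_px = max(min((nx - w_px - 2) / max(abs(d[0]), 1e-9),
                                (ny - w_px - 2) / max(abs(d[1]), 1e-9)), 2 * w_px)
            ext = 0.5 * length_px * np.abs(d) + w_px / 2.0 + 1.0
            if 2 * ext[0] >= nx or 2 * ext[1] >= ny:
                rejects += 1
                continue
        centre = rng.uniform(ext, [nx - ext[0], ny - ext[1]])
        p0 = centre - 0.5 * length_px * d
        p1 = centre + 0.5 * length_px * d
        sl, fp = _stroke_footprint((ny, nx), p0, p1, w_px / 2.0)
        if fp is None or not fp.any() or occupied[sl][fp].any():
            rejects += 1
            continue
        fibre_id += 1
        labels[sl][fp] = fibre_id
        grown = ndimage.binary_dilation(fp, iterations=gap_px)
        occupied[sl] |= grown
        area = int(fp.sum())
        class_area[k] += area
        rows.append({
            "fibre_id": fibre_id,
            "width_um": widths_um[k],
            "angle_deg": angle,
            "area_px": area,
            "length_um": float(np.hypot(*(p1 - p0)) * pixel_size_um),
        })
    realized = class_area.sum() / (ny * nx)
    if realized < 0.9 * area_fraction:
        raise ValueError(
            f"infeasible fibre packing: requested area fraction {area_fraction:.3f}, "
            f"realized only {realized:.3f}"
        )
    table = pd.DataFrame(rows)
    thick_px = sum(r["area_px"] for r in rows if r["width_um"] > 10.0)
    total_px = int(class_area.sum())
    truth = {
        "collagen_fraction": realized,
        "thick_area_proportion": (thick_px / total_px) if total_px else float("nan"),
        "pixel_size_um": pixel_size_um,
    }
    return labels, table, truth


# --------------------------------------------------------------------------
# Section image
# --------------------------------------------------------------------------

def _place_nuclei(rng, region_mask, pixel_size_um, density_per_mm2,
                  radius_um, max_attempts_factor=60):
    """Poisson-disk placement of non-overlapping nucleus centres inside a mask."""
    area_mm2 = region_mask.sum() * pixel_size_um**2 / 1e6
    n_target = int(round(density_per_mm2 * area_mm2))
    if n_target == 0:
        return np.empty((0, 2))
    ny, nx = region_mask.shape
    min_sep = 2 * radius_um + 1.0
    centres = []
    attempts = 0
    # coarse grid for neighbour queries
    cell = min_sep
    grid = {}
    while len(centres) < n_target and attempts < max_attempts_factor * n_target:
        attempts += 1
        x = rng.uniform(radius_um, nx * pixel_size_um - radius_um)
        y = rng.uniform(radius_um, ny * pixel_size_um - radius_um)
        r, c = int(y / pixel_size_um), int(x / pixel_size_um)
        if not region_mask[min(r, ny - 1), min(c, nx - 1)]:
            continue
        gi, gj = int(x / cell), int(y / cell)
        ok = True
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for (px, py) in grid.get((gi + di, gj + dj), ()):
                    if (px - x) ** 2 + (py - y) ** 2 < min_sep**2:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            centres.append((x, y))
            grid.setdefault((gi, gj), []).append((x, y))
    return np.array(centres)


def _paint_disks(raster, centres_um, radius_um, pixel_size_um, value):
    ny, nx = raster.shape
    r_px = radius_um / pixel_size_um
    for (x, y) in centres_um:
        cx, cy = x / pixel_size_um, y / pixel_size_um
        sl_r = slice(max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, ny))
        sl_c = slice(max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, nx))
        cols, rows = np.meshgrid(np.arange(sl_c.start, sl_c.stop),
                                 np.arange(sl_r.start, sl_r.stop))
        d = np.hypot(cols + 0.5 - cx, rows + 0.5 - cy)
        raster[sl_r, sl_c][d < r_px] = value


def generate_section_image(spec: SectionSpec):
    """Render a layered skin section; returns ``(SectionImage, GroundTruth)``.

    Channels: ``DAPI`` (nuclei), ``Ki67`` (proliferation marker), ``COLIV``
    (basement membrane band along the EDJ plus dermal vessel cross-sections)
    and ``SHG`` (dermal collagen fibre field over a uniform dermal
    background).  Intensities are noiseless unless ``spec.noise_sd > 0``.
    """
    from .segmentation import SectionImage  # local import to avoid a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ps = spec.pixel_size_um
    ny = int(round(spec.height_um / ps))
    nx = int(round(spec.width_um / ps))
    epidermis, dermis, dermal_region = section_masks(spec)

    # --- DAPI + Ki67: nuclei in epidermis and dermis ---
    tissue = epidermis | dermis
    centres = _place_nuclei(rng, tissue, ps, spec.nuclei_density_per_mm2,
                            NUCLEUS_RADIUS_UM)
    in_epi = []
    for (x, y) in centres:
        in_epi.append(bool(y < edj_depth_um(spec, x)) and y >= TOP_MARGIN_UM)
    in_epi = np.array(in_epi, bool) if len(centres) else np.empty(0, bool)
    ki67 = np.zeros(len(centres), bool)
    epi_idx = np.flatnonzero(in_epi)
    n_pos = int(round(spec.ki67_fraction * len(epi_idx)))
    if n_pos:
        ki67[rng.choice(epi_idx, n_pos, replace=False)] = True

    dapi = np.zeros((ny, nx))
    _paint_disks(dapi, centres, NUCLEUS_RADIUS_UM, ps, NUCLEUS_INTENSITY)
    ki67_ch = np.zeros((ny, nx))
    if ki67.any():
        _paint_disks(ki67_ch, centres[ki67], NUCLEUS_RADIUS_UM, ps, KI67_INTENSITY)

    # --- COLIV: Gaussian basement-membrane band + vessel rings ---
    x_um = (np.arange(nx) + 0.5) * ps
    edj_y = edj_depth_um(spec, x_um)
    # exact subpixel distance to the EDJ curve within a 6-sigma band
    from scipy.spatial import cKDTree
    xs = np.linspace(0, spec.width_um, 8 * nx)
    ys = edj_depth_um(spec, xs)
    tree = cKDTree(np.column_stack([xs, ys]))
    band = 6.0 * spec.bm_sigma_um
    ylo = max(int((ys.min() - band) / ps) - 1, 0)
    yhi = min(int((ys.max() + band) / ps) + 2, ny)
    coliv = np.zeros((ny, nx))
    if yhi > ylo:
        cols, rows = np.meshgrid(np.arange(nx), np.arange(ylo, yhi))
        pts = np.column_stack([(cols.ravel() + 0.5) * ps, (rows.ravel() + 0.5) * ps])
        d_um, _ = tree.query(pts, workers=-1)
        coliv[ylo:yhi, :] = (spec.bm_peak
                             * np.exp(-0.5 * (d_um / spec.bm_sigma_um) ** 2)
                             ).reshape(yhi - ylo, nx)

    vessel_mask = np.zeros((ny, nx), bool)
    region_px = int(dermal_region.sum())
    target_vessel_px = spec.vessel_area_fraction * region_px
    tries = 0
    while vessel_mask.sum() < target_vessel_px and tries < 20000:
        tries += 1
        r_out = rng.uniform(*VESSEL_OUTER_UM)
        x = rng.uniform(r_out, spec.width_um - r_out)
        y = rng.uniform(0, spec.height_um)
        if y < edj_depth_um(spec, x) + BM_EXCLUSION_UM + r_out:
            continue
        if y > spec.height_um - r_out:
            continue
        cx, cy = x / ps, y / ps
        r_px = r_out / ps
        w_px = VESSEL_WALL_UM / ps
        sl_r = slice(max(int(cy - r_px) - 1, 0), min(int(cy + r_px) + 2, ny))
        sl_c = slice(max(int(cx - r_px) - 1, 0), min(int(cx + r_px) + 2, nx))
        cols, rows = np.meshgrid(np.arange(sl_c.start, sl_c.stop),
                                 np.arange(sl_r.start, sl_r.stop))
        d = np.hypot(cols + 0.5 - cx, rows + 0.5 - cy)
        ring = (d < r_px) & (d >= r_px - w_px)
        if (vessel_mask[sl_r, sl_c] & ring).any():
            continue
        vessel_mask[sl_r, sl_c] |= ring
    coliv = np.maximum(coliv, vessel_mask * VESSEL_INTENSITY)
    true_vessel_frac = float(vessel_mask.sum() / region_px) if region_px else 0.0

    # --- SHG: fibre field in a rectangular dermal canvas ---
    fibre_top_um = float(edj_y.max() + BM_EXCLUSION_UM)
    canvas_h_um = spec.height_um - fibre_top_um
    shg = np.zeros((ny, nx))
    shg[dermis] = spec.shg_background_intensity
    fibre_rows = []
    coll_frac = float("nan")
    thick_prop = float("nan")
    if spec.fibre_area_fraction > 0 and canvas_h_um > 20:
        flabels, ftable, ftruth = generate_fibre_field(
            spec.fibre_widths_um, spec.fibre_width_weights,
            spec.orientation_kappa, spec.fibre_area_fraction,
            rng, width_um=spec.width_um, height_um=canvas_h_um,
            pixel_size_um=ps, mean_angle_deg=spec.mean_angle_deg,
        )
        r0 = int(round(fibre_top_um / ps))
        sub = shg[r0:r0 + flabels.shape[0], :]
        sub[flabels > 0] = spec.shg_fibre_intensity
        fibre_rows = ftable.to_dict("records")
        coll_frac = ftruth["collagen_fraction"]
        thick_prop = ftruth["thick_area_proportion"]

    if spec.noise_sd > 0:
        for ch in (dapi, ki67_ch, coliv, shg):
            ch += rng.normal(0.0, spec.noise_sd, ch.shape)
            np.clip(ch, 0.0, None, out=ch)

    image = SectionImage(
        channels={"DAPI": dapi, "COLIV": coliv, "Ki67": ki67_ch, "SHG": shg},
        pixel_size_um=ps,
    )
    truth = GroundTruth(
        spec=spec,
        nucleus_centres_um=[(float(x), float(y)) for (x, y) in centres],
        nucleus_in_epidermis=[bool(b) for b in in_epi],
        ki67_positive=[bool(b) for b in ki67],
        fibre_table=fibre_rows,
        true_arc_chord=(1.0 if spec.edj_amplitude_um == 0
                        else sinusoid_arc_chord(spec.edj_amplitude_um, spec.edj_period_um)),
        true_collagen_fraction=coll_frac,
        true_thick_area_proportion=thick_prop,
        true_vessel_area_fraction=true_vessel_frac,
        fibre_canvas_top_um=fibre_top_um,
        epidermis_px=int(epidermis.sum()),
        dermis_px=int(dermis.sum()),
    )
    return image, truth


# --------------------------------------------------------------------------
# Expression dataset
# --------------------------------------------------------------------------

TIMEPOINTS = (0, 2, 4, 6)


def generate_expression_dataset(
    n_genes: int,
    n_per_timepoint: int,
    planted: dict | None = None,
    effect_log2: float = 1.5,
    noise_sd: float = 0.5,
    seed=0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 1.0,
):
    """Simulate a 4-timepoint (0/2/4/6 months) log2 expression matrix.

    ``planted`` maps set names ``unique2``/``unique4``/``unique6``/``core``
    to either a gene count (effects of magnitude ``effect_log2``, random
    sign) or an explicit list of ``(gene_index, log2_effect)`` pairs.
    ``core`` genes are shifted at all three post-transplant timepoints,
    ``unique{t}`` genes only at timepoint ``t``.  Returns ``(dataset,
    truth)`` where ``truth`` maps each set name to its gene-id set and
    carries the effect table.
    """
    from .transcriptomics import ExpressionDataset  # avoid import cycle

    rng = np.random.default_rng(seed)
    planted = dict(planted or {})
    valid = {"unique2", "unique4", "unique6", "core"}
    if set(planted) - valid:
        raise ValueError(f"unknown planted set names: {sorted(set(planted) - valid)}")

    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    assignments = {}
    effects = {}
    free = list(range(n_genes))
    rng.shuffle(free)
    cursor = 0
    for name in sorted(planted):
        val = planted[name]
        if isinstance(val, int):
            idx = free[cursor:cursor + val]
            cursor += val
            assignments[name] = list(idx)
            for g in idx:
                effects[g] = float(effect_log2 * rng.choice([-1.0, 1.0]))
        else:
            assignments[name] = [g for g, _ in val]
            for g, e in val:
                effects[g] = float(e)
        if len(assignments[name]) != (val if isinstance(val, int) else len(val)):
            raise ValueError("not enough genes to plant the requested sets")

    min_detectable = noise_sd * np.sqrt(2.0 / max(n_per_timepoint, 1)) * 2.0
    if effects and min(abs(e) for e in effects.values()) < min_detectable:
        import logging
        logging.getLogger(__name__).warning(
            "planted effects below ~2 SE at n=%d, noise_sd=%.3g; recovery will be partial",
            n_per_timepoint, noise_sd)

    baselines = rng.normal(baseline_mean, baseline_sd, n_genes)
    cols, tps, subs = [], [], []
    data = np.empty((n_genes, 4 * n_per_timepoint))
    j = 0
    affected_at = {2: set(assignments.get("unique2", [])) | set(assignments.get("core", [])),
                   4: set(assignments.get("unique4", [])) | set(assignments.get("core", [])),
                   6: set(assignments.get("unique6", [])) | set(assignments.get("core", []))}
    for t in TIMEPOINTS:
        for k in range(n_per_timepoint):
            mu = baselines.copy()
            if t in affected_at:
                for g in affected_at[t]:
                    mu[g] += effects[g]
            data[:, j] = mu + (rng.normal(0.0, noise_sd, n_genes) if noise_sd > 0 else 0.0)
            cols.append(f"T{t}_R{k}")
            tps.append(t)
            subs.append(f"S{k}")
            j += 1
    matrix = pd.DataFrame(data, index=gene_ids, columns=cols)
    sheet = pd.DataFrame({"sample": cols, "timepoint": tps, "subject": subs})
    dataset = ExpressionDataset(matrix=matrix, sample_sheet=sheet)
    truth = {name: {gene_ids[g] for g in idx} for name, idx in assignments.items()}
    truth["effects"] = {gene_ids[g]: e for g, e in effects.items()}
    return dataset, truth
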