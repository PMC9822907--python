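"""End-to-end orchestration: simulate -> segment -> morphometry -> stats ->
transcriptomics -> report, with tidy CSV outputs and provenance.

The pipeline runs entirely on synthetic sections whose ground truth is
known, so the emitted per-metric statistics can be checked against the
generating parameters.  Sections are simulated per subject × timepoint ×
ROI; timepoint effects are multiplicative factors on the section
parameters, and a small section-to-section coefficient of variation stands
in for biological and sampling variability.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .synthetic import (SectionSpec, edj_depth_um, generate_expression_dataset,
                        generate_section_image, section_masks, TOP_MARGIN_UM)
from .segmentation import detect_nuclei, segment_fibres, vessel_mask
from .epidermis import (BoundaryCurve, arc_chord_ratio, edj_profiles,
                        epidermal_thickness, ki67_fraction, profile_width_peak)
from .dermis import (alignment_coefficient, collagen_fractions,
                     normalized_shg_intensity, orientation_field,
                     vessel_density)
from .stats import grubbs_test, select_and_run_test

logger = logging.getLogger(__name__)

TIMEPOINTS = (0, 2, 4, 6)


@dataclasses.dataclass
class MorphometryRecord:
    """One scalar metric value for one (subject, timepoint, ROI) cell —
    the row schema of the tidy ``metrics.csv``."""

    subject: str
    timepoint: int
    roi: str
    metric: str
    value: float

#: Default pipeline configuration.  Timepoint effects emulate the reported
#: course of scar remodelling after follicle transplantation: epidermis
#: thickens (×1.6/1.4/2.0), cell and vessel density rise, collagen fraction
#: and the thick-fibre share fall (52 -> 46/39/35 %), fibres disorganize
#: (lower orientation concentration), SHG intensity drops.
DEFAULT_CONFIG = {
    "seed": 0,
    "out_dir": "scarmorph_out",
    "stages": ["simulate", "segment", "morphometry", "stats",
               "transcriptomics", "report"],
    "subjects": 3,
    "rois_per_timepoint": 1,
    "section_cv": 0.05,
    "section": {
        "width_um": 400.0,
        "height_um": 300.0,
        "pixel_size_um": 1.0,
        "epidermal_thickness_um": 50.0,
        "nuclei_density_per_mm2": 600.0,
        "ki67_fraction": 0.04,
        "vessel_area_fraction": 0.06,
        "fibre_area_fraction": 0.30,
        "orientation_kappa": 5.0,
        "shg_fibre_intensity": 150.0,
        "shg_background_intensity": 50.0,
    },
    "timepoint_effects": {
        "epidermal_thickness_um": {0: 1.0, 2: 1.6, 4: 1.4, 6: 2.0},
        "nuclei_density_per_mm2": {0: 1.0, 2: 1.8, 4: 1.5, 6: 2.0},
        "ki67_fraction": {0: 1.0, 2: 1.0, 4: 2.25, 6: 3.75},
        "vessel_area_fraction": {0: 1.0, 2: 1.67, 4: 1.5, 6: 1.67},
        "fibre_area_fraction": {0: 1.0, 2: 0.77, 4: 0.63, 6: 0.67},
        "shg_fibre_intensity": {0: 1.0, 2: 0.83, 4: 0.48, 6: 0.53},
    },
    "thick_weight": {0: 0.52, 2: 0.46, 4: 0.39, 6: 0.35},
    "orientation_kappa": {0: 5.0, 2: 2.0, 4: 2.0, 6: 2.0},
    "edj_amplitude_um": {0: 6.0, 2: 6.0, 4: 7.2, 6: 7.8},
    "probes": {"n": 10, "spacing_um": 40.0},
    "arc_chord_section_um": 100.0,
    "expression": {
        "n_genes": 2000,
        "n_per_timepoint": 4,
        "planted": {"unique2": 30, "unique4": 30, "unique6": 30, "core": 30},
        "effect_log2": 1.5,
        "noise_sd": 0.4,
    },
    "grubbs_alpha": 0.05,
    "write_images": False,
}


def _merge(base: dict, override: dict | None) -> dict:
    out = copy.deepcopy(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path=None, overrides: dict | None = None) -> dict:
    cfg = copy.deepcopy(DEFAULT_CONFIG)
    if path is not None:
        import yaml
        with open(path) as fh:
            cfg = _merge(cfg, yaml.safe_load(fh) or {})
    return _merge(cfg, overrides)


def _section_spec(cfg: dict, timepoint: int, rng: np.random.Generator,
                  seed: int) -> SectionSpec:
    base = dict(cfg["section"])
    eff = cfg["timepoint_effects"]
    cv = cfg["section_cv"]
    for key, factors in eff.items():
        base[key] = base[key] * factors[timepoint]
    # section-to-section biological/sampling variability
    for key in eff:
        base[key] *= float(np.exp(rng.normal(0.0, cv)))
    base["ki67_fraction"] = min(base["ki67_fraction"], 1.0)
    base["vessel_area_fraction"] = min(base["vessel_area_fraction"], 0.9)
    tw = cfg["thick_weight"][timepoint]
    base["fibre_width_weights"] = (1.0 - tw, tw)
    base["fibre_widths_um"] = (6.0, 14.0)
    base["orientation_kappa"] = cfg["orientation_kappa"][timepoint]
    base["edj_amplitude_um"] = cfg["edj_amplitude_um"][timepoint]
    base["seed"] = seed
    return SectionSpec(**base)


def _measure_section(image, truth, cfg: dict) -> dict:
    """All scalar metrics for one rendered section."""
    spec = truth.spec
    ps = spec.pixel_size_um
    epi_mask, dermis_mask, dermal_region = section_masks(spec)
    top = BoundaryCurve.from_function(lambda x: np.full_like(x, TOP_MARGIN_UM),
                                      0.0, spec.width_um)
    edj = BoundaryCurve.from_function(lambda x: edj_depth_um(spec, x),
                                      0.0, spec.width_um)

    metrics = {}
    pr = cfg["probes"]
    thick_mean, _ = epidermal_thickness(top, edj, n_probes=pr["n"],
                                        spacing_um=pr["spacing_um"])
    metrics["epidermal_thickness_um"] = thick_mean
    metrics["arc_chord_ratio"] = arc_chord_ratio(edj, cfg["arc_chord_section_um"])[0]

    nuclei = detect_nuclei(image.channels["DAPI"], ps)
    pooled, _ = ki67_fraction(nuclei, image.channels["Ki67"], ps, epi_mask)
    metrics["ki67_pct"] = 100.0 * pooled

    area_mm2 = dermal_region.sum() * ps**2 / 1e6
    ny, nx = dermal_region.shape
    n_dermal = 0
    for (x, y) in nuclei.centres_um:
        r, c = min(int(y / ps), ny - 1), min(int(x / ps), nx - 1)
        n_dermal += bool(dermal_region[r, c])
    metrics["cell_density_per_mm2"] = n_dermal / area_mm2 if area_mm2 else float("nan")

    vmask, _ = vessel_mask(image.channels["COLIV"], dermal_region)
    metrics["vessel_density_pct"] = vessel_density(vmask, dermal_region)

    profiles = edj_profiles(image.channels["COLIV"], ps, edj, n_trajectories=15)
    widths, peaks = [], []
    for p in profiles:
        w, pk = profile_width_peak(p)
        if np.isfinite(w):
            widths.append(w)
        peaks.append(pk)
    metrics["bm_width_um"] = float(np.mean(widths)) if widths else float("nan")
    metrics["bm_peak"] = float(np.mean(peaks)) if peaks else float("nan")

    r0 = int(round(truth.fibre_canvas_top_um / ps))
    shg_canvas = image.channels["SHG"][r0:, :]
    fmask = segment_fibres(shg_canvas, ps)
    frac, thick_prop, mean_w = collagen_fractions(fmask)
    metrics["collagen_fraction"] = frac
    metrics["thick_proportion"] = thick_prop
    metrics["mean_fibre_thickness_um"] = mean_w
    fibre_fg = fmask.labels > 0
    if fibre_fg.any():
        ofield = orientation_field(shg_canvas, fibre_fg, ps)
        metrics["alignment_coefficient"] = alignment_coefficient(ofield)
        metrics["normalized_shg_intensity"] = normalized_shg_intensity(
            shg_canvas, fibre_fg, ~fibre_fg)
    else:
        metrics["alignment_coefficient"] = float("nan")
        metrics["normalized_shg_intensity"] = float("nan")
    return metrics


def run_pipeline(config: dict | None = None, config_path=None) -> dict:
    """Execute the configured stages; returns a dict of output paths.

    Emits ``metrics.csv`` (tidy: subject, timepoint, roi, metric, value),
    ``stats.csv`` + ``posthoc.csv`` per-metric decision-tree results,
    ``outliers.csv`` (Grubbs screen), the transcriptomics tables, figures,
    and ``provenance.json``.
    """
    cfg = load_config(config_path, config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    stages = list(cfg["stages"])
    outputs = {}
    t_start = time.time()
    root_seed = int(cfg["seed"])
    ss = np.random.SeedSequence(root_seed)

    records = []
    if {"simulate", "segment", "morphometry"} & set(stages):
        sim_dir = out_dir / "sections"
        child_seeds = iter(ss.spawn(4096))
        for subj in range(cfg["subjects"]):
            for t in TIMEPOINTS:
                for roi in range(cfg["rois_per_timepoint"]):
                    seq = next(child_seeds)
                    rng = np.random.default_rng(seq)
                    sec_seed = int(seq.generate_state(1)[0] % (2**31))
                    spec = _section_spec(cfg, t, rng, sec_seed)
                    t0 = time.time()
                    image, truth = generate_section_image(spec)
                    if cfg.get("write_images"):
                        sim_dir.mkdir(exist_ok=True)
                        stem = f"S{subj}_T{t}_R{roi}"
                        image.to_tiff(sim_dir / f"{stem}.tiff")
                        truth.to_json(sim_dir / f"{stem}.json")
                    metrics = _measure_section(image, truth, cfg)
                    logger.info("section S%d T%d R%d: %.2fs", subj, t, roi,
                                time.time() - t0)
                    for name, value in metrics.items():
                        records.append({"subject": f"S{subj}", "timepoint": t,
                                        "roi": f"R{roi}", "metric": name,
                                        "value": value})
        metrics_df = pd.DataFrame(records)
        metrics_path = out_dir / "metrics.csv"
        metrics_df.to_csv(metrics_path, index=False, float_format="%.6g")
        outputs["metrics"] = metrics_path

    if "stats" in stages and records:
        stat_rows, post_rows, outlier_rows = [], [], []
        for metric, sub in metrics_df.groupby("metric"):
            sub = sub.dropna(subset=["value"])
            groups, names = [], []
            for t in TIMEPOINTS:
                vals = sub.loc[sub["timepoint"] == t, "value"].to_numpy()
                if len(vals) >= 3:
                    groups.append(vals)
                    names.append(f"{t}mo")
                    idx = grubbs_test(vals, cfg["grubbs_alpha"])
                    if idx is not None:
                        outlier_rows.append({"metric": metric, "timepoint": t,
                                             "value": float(vals[idx])})
            if len(groups) < 2:
                continue
            tidy = sub.rename(columns={"value": "value"})
            res = select_and_run_test(groups, design="two-way", names=names,
                                      data=tidy)
            stat_rows.append({"metric": metric, "test": res.test_name,
                              "statistic": res.statistic, "p_value": res.p_value,
                              "branch": res.trace["branch"]})
            if res.posthoc is not None:
                for _, r in res.posthoc.iterrows():
                    post_rows.append({"metric": metric, **r.to_dict()})
        pd.DataFrame(stat_rows).to_csv(out_dir / "stats.csv", index=False,
                                       float_format="%.6g")
        pd.DataFrame(post_rows).to_csv(out_dir / "posthoc.csv", index=False,
                                       float_format="%.6g")
        pd.DataFrame(outlier_rows).to_csv(out_dir / "outliers.csv", index=False,
                                          float_format="%.6g")
        outputs["stats"] = out_dir / "stats.csv"

    if "transcriptomics" in stages:
        from .transcriptomics import (anova_de_filter, baseline_transform,
                                      hierarchical_cluster, pairwise_de,
                                      venn_core)
        ex = cfg["expression"]
        ds, truth_sets = generate_expression_dataset(
            ex["n_genes"], ex["n_per_timepoint"], ex["planted"],
            effect_log2=ex["effect_log2"], noise_sd=ex["noise_sd"],
            seed=np.random.SeedSequence([root_seed, 7]))
        ds = baseline_transform(ds)
        de = anova_de_filter(ds)
        de.table.to_csv(out_dir / "de_anova.csv", float_format="%.6g")
        sets = {t: pairwise_de(ds, t).passing for t in (2, 4, 6)}
        venn = venn_core(sets[2], sets[4], sets[6])
        rows = []
        for region in ("unique2", "unique4", "unique6", "core"):
            for g in sorted(getattr(venn, region)):
                rows.append({"gene": g, "region": region})
        pd.DataFrame(rows, columns=["gene", "region"]).to_csv(
            out_dir / "venn.csv", index=False)
        _, order, newick, prov = hierarchical_cluster(ds, genes=de.passing or None)
        (out_dir / "dendrogram.newick").write_text(newick + "\n")
        outputs["venn"] = out_dir / "venn.csv"
        outputs["de"] = out_dir / "de_anova.csv"

    if "report" in stages and records:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig_dir = out_dir / "figures"
        fig_dir.mkdir(exist_ok=True)
        for metric, sub in metrics_df.groupby("metric"):
            fig, ax = plt.subplots(figsize=(4, 3))
            for t in TIMEPOINTS:
                vals = sub.loc[sub["timepoint"] == t, "value"].dropna()
                ax.scatter(np.full(len(vals), t), vals, s=18, color="tab:blue",
                           alpha=0.7)
                if len(vals):
                    ax.hlines(vals.mean(), t - 0.4, t + 0.4, color="black")
            ax.set_xlabel("months post-transplant")
            ax.set_ylabel(metric)
            ax.set_xticks(TIMEPOINTS)
            fig.tight_layout()
            fig.savefig(fig_dir / f"{metric}.png", dpi=100)
            plt.close(fig)
        outputs["figures"] = fig_dir

    import scipy
    import skimage
    provenance = {
        "scarmorph": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "scikit-image": skimage.__version__,
        "pandas": pd.__version__,
        "seed": root_seed,
        "config": _jsonable(cfg),
        "elapsed_s": round(time.time() - t_start, 2),
    }
    with open(out_dir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=1)
    outputs["provenance"] = out_dir / "provenance.json"
    logger.info("pipeline finished in %.1fs", time.time() - t_start)
    return outputs


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
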