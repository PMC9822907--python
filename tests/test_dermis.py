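"""Dermal densities, collagen fractions, orientation and alignment."""

import dataclasses

import numpy as np
import pytest
from scipy.special import i0, i1

from scarmorph import (PointSet, SectionSpec, alignment_coefficient,
                       cell_density, collagen_fractions, detect_nuclei,
                       generate_fibre_field, generate_section_image,
                       normalized_shg_intensity, orientation_field,
                       orientation_histogram, section_masks, segment_fibres,
                       vessel_density, vessel_mask)


class TestCellDensity:
    def test_ninety_cells_in_300um_roi_is_1000_per_mm2(self, rng):
        pts = PointSet(rng.uniform(0, 300, (90, 2)))
        assert cell_density(pts, (0, 0, 300, 300)) == pytest.approx(1000.0)

    def test_empty_roi_is_zero(self):
        assert cell_density(PointSet(np.empty((0, 2))), (0, 0, 300, 300)) == 0.0

    def test_poisson_placement_recovers_intensity(self, rng):
        # 50 ROIs at lambda = 800 / mm^2: mean within 2 SE
        lam = 800.0
        area = 0.09
        densities = []
        for _ in range(50):
            n = rng.poisson(lam * area)
            pts = PointSet(rng.uniform(0, 300, (n, 2)))
            densities.append(cell_density(pts, (0, 0, 300, 300)))
        se = np.sqrt(lam / area) / np.sqrt(50)
        assert abs(np.mean(densities) - lam) <= 2 * se


class TestVesselDensity:
    def test_six_percent_mask(self):
        roi = np.ones((100, 100), bool)
        mask = np.zeros((100, 100), bool)
        mask[:6, :] = True
        assert vessel_density(mask, roi) == pytest.approx(6.0)

    def test_full_coverage_is_100(self):
        roi = np.ones((50, 50), bool)
        assert vessel_density(np.ones((50, 50), bool), roi) == 100.0

    def test_generator_ten_percent_recovered(self):
        spec = SectionSpec(width_um=400, height_um=300, pixel_size_um=1.0,
                           vessel_area_fraction=0.10, nuclei_density_per_mm2=0,
                           fibre_area_fraction=0, seed=5)
        image, truth = generate_section_image(spec)
        _, _, dermal = section_masks(spec)
        mask, _ = vessel_mask(image.channels["COLIV"], dermal)
        assert vessel_density(mask, dermal) == pytest.approx(10.0, abs=0.5)


class TestCollagenFractions:
    def test_all_background_roi(self):
        m = segment_fibres(np.zeros((50, 50)), 0.5, intensity_threshold_mode=10.0)
        frac, thick, mean = collagen_fractions(m)
        assert frac == 0.0 and np.isnan(thick) and np.isnan(mean)

    def test_single_thick_fibre_proportion_is_one(self):
        labels, _, _ = generate_fibre_field([14.0], [1.0], np.inf, 0.1, seed=2,
                                            width_um=150, height_um=100)
        m = segment_fibres(np.where(labels > 0, 100.0, 0.0), 0.5,
                           intensity_threshold_mode=50.0)
        _, thick, _ = collagen_fractions(m)
        assert thick == 1.0

    def test_mixed_field_matches_generator_within_five_percent(self):
        labels, table, truth = generate_fibre_field([6, 14], [0.5, 0.5], 2.0,
                                                    0.25, seed=8)
        m = segment_fibres(np.where(labels > 0, 150.0, 50.0), 0.5)
        frac, thick, mean = collagen_fractions(m)
        assert frac == pytest.approx(truth["collagen_fraction"], rel=0.05)
        assert thick == pytest.approx(truth["thick_area_proportion"], rel=0.05)

    def test_collagen_plus_background_is_one(self):
        labels, _, _ = generate_fibre_field([6, 14], [0.5, 0.5], 2.0, 0.2, seed=3)
        m = segment_fibres(np.where(labels > 0, 150.0, 50.0), 0.5)
        frac, _, _ = collagen_fractions(m)
        bg_frac = (m.labels == 0).mean()
        assert frac + bg_frac == pytest.approx(1.0, abs=1e-12)


class TestOrientationField:
    def _stripes(self, angle_deg, ps=0.5):
        labels, _, _ = generate_fibre_field([8.0], [1.0], np.inf, 0.25, seed=4,
                                            mean_angle_deg=angle_deg,
                                            width_um=200, height_um=200,
                                            pixel_size_um=ps)
        return np.where(labels > 0, 150.0, 50.0), labels > 0

    def test_parallel_stripes_at_30_degrees(self):
        img, mask = self._stripes(30.0)
        field = orientation_field(img, mask, 0.5)
        assert np.median(field.angles()) == pytest.approx(30.0, abs=2.0)

    def test_rotation_by_90_shifts_angles(self):
        img, mask = self._stripes(30.0)
        a = orientation_field(img, mask, 0.5)
        b = orientation_field(np.rot90(img), np.rot90(mask), 0.5)
        da = (np.median(b.angles()) - np.median(a.angles())) % 180.0
        assert min(da, 180.0 - da) == pytest.approx(90.0, abs=2.0)

    def test_isotropic_noise_has_low_coherence(self):
        meds = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            img = rng.random((200, 200)) * 100
            field = orientation_field(img, np.ones((200, 200), bool), 0.5,
                                      smoothing_scale_um=4.0)
            meds.append(np.median(field.coherence[field.mask]))
        assert np.median(meds) < 0.2

    def test_histogram_covers_180_one_degree_bins(self):
        img, mask = self._stripes(30.0)
        h = orientation_histogram(orientation_field(img, mask, 0.5))
        assert len(h) == 180
        assert h["count"].sum() == mask.sum()
        assert h.loc[h["count"].idxmax(), "angle_deg"] == pytest.approx(30, abs=3)


class TestAlignmentCoefficient:
    def test_identical_angles_is_one(self):
        assert alignment_coefficient([37.0] * 50) == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_equal_weight_pair_is_zero(self):
        assert alignment_coefficient([0.0, 90.0]) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_matches_bessel_ratio(self, rng):
        kappa = 2.0
        doubled = rng.vonmises(0.0, kappa, 10_000)
        angles = np.rad2deg(doubled) / 2.0 % 180.0
        expect = i1(kappa) / i0(kappa)
        assert alignment_coefficient(angles) == pytest.approx(expect, abs=0.02)

    def test_invariant_to_180_shift_and_global_rotation(self, rng):
        a = rng.uniform(0, 180, 500)
        base = alignment_coefficient(a)
        shifted = a.copy()
        shifted[::3] += 180.0
        assert alignment_coefficient(shifted) == pytest.approx(base, abs=1e-9)
        assert alignment_coefficient((a + 61.0) % 180.0) == pytest.approx(
            base, abs=1e-9)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            alignment_coefficient([])

    def test_coherence_votes_recover_truth_tighter_than_uniform(self):
        # fibre-interior pixels carry no gradient signal; coherence-weighted
        # votes should track the per-fibre truth more closely
        labels, table, _ = generate_fibre_field(
            [6, 14], [0.5, 0.5], 3.0, 0.25, seed=10,
            width_um=250, height_um=250, pixel_size_um=0.5)
        img = np.where(labels > 0, 150.0, 50.0)
        field = orientation_field(img, labels > 0, 0.5)
        true_r = alignment_coefficient(table["angle_deg"],
                                       weights=table["area_px"])
        err_coh = abs(alignment_coefficient(field) - true_r)
        err_uni = abs(alignment_coefficient(field, weights="uniform") - true_r)
        assert err_coh < err_uni
        assert err_coh <= 0.05


class TestNormalizedShgIntensity:
    def test_ratio_two(self):
        img = np.concatenate([np.full((10, 20), 200.0), np.full((10, 20), 100.0)])
        fibre = np.zeros((20, 20), bool)
        fibre[:10] = True
        assert normalized_shg_intensity(img, fibre, ~fibre) == pytest.approx(2.0)

    def test_uniform_image_is_one(self):
        img = np.full((20, 20), 70.0)
        fibre = np.zeros((20, 20), bool)
        fibre[:10] = True
        assert normalized_shg_intensity(img, fibre, ~fibre) == 1.0

    def test_zero_background_raises(self):
        img = np.zeros((10, 10))
        fibre = np.zeros((10, 10), bool)
        fibre[:5] = True
        with pytest.raises(ValueError):
            normalized_shg_intensity(img, fibre, ~fibre)

    def test_generator_intensities_with_noise(self):
        ratios = []
        for seed in range(10):
            spec = SectionSpec(width_um=300, height_um=250, pixel_size_um=1.0,
                               shg_fibre_intensity=150.0,
                               shg_background_intensity=50.0,
                               nuclei_density_per_mm2=0, vessel_area_fraction=0,
                               noise_sd=5.0, seed=seed)
            image, truth = generate_section_image(spec)
            ps = spec.pixel_size_um
            r0 = int(round(truth.fibre_canvas_top_um / ps))
            canvas = image.channels["SHG"][r0:, :]
            m = segment_fibres(canvas, ps)
            fg = m.labels > 0
            ratios.append(normalized_shg_intensity(canvas, fg, ~fg))
        assert np.mean(ratios) == pytest.approx(3.0, abs=0.1)


@pytest.fixture(scope="module")
def recoveries():
    """Twenty random section specs measured end to end against their truth."""
    import pandas as pd
    rng = np.random.default_rng(2024)
    rows = []
    for _ in range(20):
        w = float(rng.uniform(0.3, 0.7))
        spec = SectionSpec(
            width_um=300.0, height_um=250.0, pixel_size_um=1.0,
            nuclei_density_per_mm2=float(rng.uniform(400, 1000)),
            vessel_area_fraction=float(rng.uniform(0.04, 0.10)),
            fibre_area_fraction=float(rng.uniform(0.15, 0.35)),
            orientation_kappa=float(rng.uniform(1.0, 8.0)),
            fibre_width_weights=(1.0 - w, w),
            seed=int(rng.integers(2**31)),
        )
        image, truth = generate_section_image(spec)
        ps = spec.pixel_size_um
        _, _, dermal = section_masks(spec)

        pts = detect_nuclei(image.channels["DAPI"], ps)
        area_mm2 = dermal.sum() * ps**2 / 1e6
        ny, nx = dermal.shape
        n_in = sum(dermal[min(int(y / ps), ny - 1), min(int(x / ps), nx - 1)]
                   for x, y in pts.centres_um)
        truth_in = sum(dermal[min(int(y / ps), ny - 1), min(int(x / ps), nx - 1)]
                       for x, y in truth.nucleus_centres_um)

        vmask, _ = vessel_mask(image.channels["COLIV"], dermal)
        r0 = int(round(truth.fibre_canvas_top_um / ps))
        canvas = image.channels["SHG"][r0:, :]
        m = segment_fibres(canvas, ps)
        frac, thick, _ = collagen_fractions(m)
        fg = m.labels > 0
        field = orientation_field(canvas, fg, ps)
        ft = pd.DataFrame(truth.fibre_table)
        true_R = alignment_coefficient(ft["angle_deg"], weights=ft["area_px"])
        rows.append({
            "cell_density": n_in / area_mm2,
            "cell_density_true": truth_in / area_mm2,
            "vessel_pct": vessel_density(vmask, dermal),
            "vessel_pct_true": 100 * truth.true_vessel_area_fraction,
            "collagen": frac,
            "collagen_true": truth.true_collagen_fraction,
            "thick": thick,
            "thick_true": truth.true_thick_area_proportion,
            "align": alignment_coefficient(field),
            "align_true": true_R,
            "shg": normalized_shg_intensity(canvas, fg, ~fg),
            "shg_true": spec.shg_fibre_intensity / spec.shg_background_intensity,
        })
    return pd.DataFrame(rows)


class TestParameterRecovery:
    def test_cell_density_within_five_percent(self, recoveries):
        rel = np.abs(recoveries["cell_density"] - recoveries["cell_density_true"]
                     ) / recoveries["cell_density_true"]
        assert rel.max() <= 0.05

    def test_vessel_density_within_half_point(self, recoveries):
        err = np.abs(recoveries["vessel_pct"] - recoveries["vessel_pct_true"])
        assert err.max() <= 0.5

    def test_collagen_fraction_within_five_hundredths(self, recoveries):
        err = np.abs(recoveries["collagen"] - recoveries["collagen_true"])
        assert err.max() <= 0.05

    def test_thick_proportion_within_five_hundredths(self, recoveries):
        err = np.abs(recoveries["thick"] - recoveries["thick_true"])
        assert err.max() <= 0.05

    def test_alignment_within_five_hundredths(self, recoveries):
        err = np.abs(recoveries["align"] - recoveries["align_true"])
        assert err.max() <= 0.05

    def test_shg_ratio_within_five_percent(self, recoveries):
        rel = np.abs(recoveries["shg"] - recoveries["shg_true"]
                     ) / recoveries["shg_true"]
        assert rel.max() <= 0.05
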