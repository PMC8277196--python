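"""Tests for cell-mask estimation and peripheral-band statistics."""

import numpy as np
import pytest

from punctakit import (
    AcquisitionParams,
    TruthSpec,
    band_by_distance,
    calibrate,
    estimate_cell_mask,
    generate_cell,
    generate_peripheral_cohort,
    geometry_from_mask,
    overlay_stack,
    peripheral_band,
    peripheral_fraction,
    run_pipeline,
)

from tests_util import circular_mask, table_from_truth


class TestCellMask:
    def test_recovers_planted_cell_radius(self, noiseless_cell):
        stack, truth, _ = noiseless_cell
        geom = estimate_cell_mask(overlay_stack(stack))
        assert geom.equivalent_radius_um == pytest.approx(
            truth.cell_radius_um, rel=0.02
        )
        cx, cy = truth.cell_center_um
        assert geom.centroid_um[0] == pytest.approx(cx, abs=1.0)
        assert geom.centroid_um[1] == pytest.approx(cy, abs=1.0)

    def test_blank_image_rejected(self):
        img = calibrate(np.zeros((64, 64)), 0.5)
        with pytest.raises(ValueError, match="blank|foreground"):
            estimate_cell_mask(img)

    def test_user_supplied_mask_used_verbatim(self):
        mask = circular_mask((200, 200), (100, 100), 60)
        geom = geometry_from_mask(mask, 0.5)
        assert np.array_equal(geom.cell_mask, mask)
        assert geom.equivalent_radius_um == pytest.approx(60 * 0.5, rel=0.01)


class TestPeripheralBand:
    def test_band_area_matches_annulus_closed_form(self):
        um = 0.5
        R_px = 150  # 75 um radius
        mask = circular_mask((400, 400), (200, 200), R_px)
        geom = geometry_from_mask(mask, um)
        band = peripheral_band(geom, 10.0)
        R = R_px * um
        analytic = np.pi * (R**2 - (R - 10.0) ** 2)
        assert band.sum() * um**2 == pytest.approx(analytic, rel=0.03)

    def test_band_subset_of_mask_and_limits(self):
        mask = circular_mask((120, 120), (60, 60), 50)
        geom = geometry_from_mask(mask, 1.0)
        band = peripheral_band(geom, 10.0)
        assert not (band & ~geom.cell_mask).any()
        # w -> 0 gives an empty band
        assert peripheral_band(geom, 0.2).sum() == 0
        # w close to R covers nearly the whole cell
        wide = peripheral_band(geom, geom.equivalent_radius_um - 1.0)
        assert wide.sum() > 0.9 * mask.sum()
        with pytest.raises(ValueError):
            peripheral_band(geom, geom.equivalent_radius_um + 1)

    def test_erosion_band_equals_distance_transform_band(self):
        for R_px, w in [(80, 10.0), (100, 7.0), (60, 12.5)]:
            mask = circular_mask((220, 220), (110, 110), R_px)
            geom = geometry_from_mask(mask, 0.5)
            assert np.array_equal(
                peripheral_band(geom, w), band_by_distance(geom, w)
            )


class TestPeripheralFraction:
    def test_all_in_band_and_none_large(self, noiseless_acq):
        stack, truth = generate_peripheral_cohort(8, 1.0, seed=1, acq=noiseless_acq)
        geom = estimate_cell_mask(overlay_stack(stack))
        table = run_pipeline(stack)
        res = peripheral_fraction(table, geom)
        assert res.n_large >= 1
        assert res.fraction == 1.0
        # a cell with no large puncta reports a missing fraction, not zero
        small_stack, small_truth = generate_cell(
            TruthSpec(n_puncta=5, size_mixture=((1.0, 0.3, 0.6),)),
            noiseless_acq,
            seed=2,
        )
        small_geom = estimate_cell_mask(overlay_stack(small_stack))
        small_table = run_pipeline(small_stack)
        res0 = peripheral_fraction(small_table, small_geom)
        assert res0.n_large == 0 and res0.fraction is None

    def test_pooled_uniform_fraction_follows_annulus_law(self, noiseless_acq):
        """Centroid-rule membership against a pixel-accurate circular
        geometry reproduces the analytic annulus fraction at n=2000."""
        um = 0.25
        mask = circular_mask((320, 320), (160, 160), int(37.5 / um))
        geom = geometry_from_mask(mask, um)
        n_in = n_tot = 0
        for seed in range(25):
            _, truth = generate_peripheral_cohort(
                80, None, seed=seed, acq=noiseless_acq, render=False
            )
            table = table_from_truth(truth, um, center_px=(160, 160))
            res = peripheral_fraction(table, geom, min_area_um2=10.0)
            n_in += res.n_in_band
            n_tot += res.n_large
        assert n_tot == 2000
        p0 = 1 - (27.5 / 37.5) ** 2
        half_ci = 1.96 * np.sqrt(p0 * (1 - p0) / n_tot)
        assert abs(n_in / n_tot - p0) < half_ci

    def test_invariant_to_translation_and_rotation(self, noiseless_acq):
        _, truth = generate_peripheral_cohort(
            40, None, seed=9, acq=noiseless_acq, render=False
        )
        um = 0.25
        base_mask = circular_mask((320, 320), (160, 160), int(37.5 / um))

        def frac(center_px, rotate):
            mask = np.roll(
                base_mask,
                (center_px[0] - 160, center_px[1] - 160),
                axis=(0, 1),
            )
            table = table_from_truth(
                truth, um, center_px=center_px, rotate90=rotate
            )
            geom = geometry_from_mask(np.rot90(mask, rotate), um)
            return peripheral_fraction(table, geom).fraction

        f0 = frac((160, 160), 0)
        assert frac((150, 170), 0) == pytest.approx(f0, abs=1e-12)
        assert frac((160, 160), 1) == pytest.approx(f0, abs=1e-12)
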