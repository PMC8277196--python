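"""Tests for the synthetic-image generator and its ground truth."""

import numpy as np
import pytest

from punctakit import (
    AcquisitionParams,
    TruthSpec,
    generate_cell,
    generate_correlated_pair,
    generate_peripheral_cohort,
    overlay_stack,
)


class TestGenerateCell:
    def test_empty_cell_is_pure_background(self):
        acq = AcquisitionParams(noise_model="none", image_size_px=(96, 96))
        spec = TruthSpec(
            n_puncta=0, cell_diameter_um=18, nucleus_diameter_um=6,
            cell_interior_level=0.0, nucleus_level=0.0, band_width_um=4.0,
        )
        stack, truth = generate_cell(spec, acq, seed=1)
        assert truth.n_puncta == 0
        for sl in stack:
            assert np.allclose(sl.pixels, acq.background_level)

    def test_same_seed_bit_identical(self):
        a, ta = generate_cell(seed=7)
        b, tb = generate_cell(seed=7)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.pixels, sb.pixels)
        assert ta.to_json() == tb.to_json()

    def test_different_seed_differs(self):
        a, _ = generate_cell(seed=7)
        b, _ = generate_cell(seed=8)
        assert not all(np.array_equal(x.pixels, y.pixels) for x, y in zip(a, b))

    def test_truth_invariants(self):
        _, truth = generate_cell(seed=3)
        assert truth.cell_radius_um > truth.nucleus_radius_um
        cx, cy = truth.cell_center_um
        for p in truth.puncta:
            assert p.radius_um > 0
            d = np.hypot(p.centroid_um[0] - cx, p.centroid_um[1] - cy)
            assert d <= truth.cell_radius_um  # centroid inside the cell

    def test_rendered_disc_area_approaches_pi_r_squared(self):
        """On a fine pixel grid the rendered hard disc of radius 0.75 um
        covers pi * 0.75^2 = 1.767 um^2 within 5%."""
        acq = AcquisitionParams(
            um_per_pixel=0.05, image_size_px=(512, 512), n_slices=1,
            noise_model="none", psf_sigma_um=0.0,
        )
        spec = TruthSpec(
            n_puncta=1, size_mixture=((1.0, 1.76714, 1.76715),),
            cell_diameter_um=24, nucleus_diameter_um=8,
        )
        stack, truth = generate_cell(spec, acq, seed=5)
        p = truth.puncta[0]
        assert p.radius_um == pytest.approx(0.75, abs=1e-3)
        area_um2 = p.rendered_area_px * acq.um_per_pixel**2
        assert area_um2 == pytest.approx(np.pi * 0.75**2, rel=0.05)

    def test_rejects_unfittable_punctum(self):
        spec = TruthSpec(
            n_puncta=1, size_mixture=((1.0, 700.0, 710.0),),
            cell_diameter_um=30, nucleus_diameter_um=10,
        )
        acq = AcquisitionParams(image_size_px=(160, 160))
        with pytest.raises(ValueError, match="fit|room"):
            generate_cell(spec, acq, seed=0)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            AcquisitionParams(um_per_pixel=0.0)

    def test_punctum_on_home_slice_only_attenuates_away(self):
        acq = AcquisitionParams(noise_model="none")
        spec = TruthSpec(n_puncta=1, size_mixture=((1.0, 2.0, 3.0),))
        stack, truth = generate_cell(spec, acq, seed=9)
        p = truth.puncta[0]
        col = int(round(p.centroid_um[0] / acq.um_per_pixel))
        row = int(round(p.centroid_um[1] / acq.um_per_pixel))
        vals = np.array([sl.pixels[row, col] for sl in stack])
        assert vals.argmax() == p.home_slice
        far = [z for z in range(len(stack)) if abs(z - p.home_slice) >= 4]
        assert all(vals[z] < vals[p.home_slice] / 2 for z in far)


class TestCorrelatedPair:
    def test_fraction_one_identical_placement(self, noiseless_acq):
        (sa, sb), truth = generate_correlated_pair(1.0, noiseless_acq, seed=2)
        a = overlay_stack(sa).pixels
        b = overlay_stack(sb).pixels
        assert np.array_equal(a, b)  # same puncta, same noise-free rendering
        assert all(p.shared for p in truth.puncta)

    def test_fraction_zero_all_private(self, noiseless_acq):
        _, truth = generate_correlated_pair(0.0, noiseless_acq, seed=2)
        assert not any(p.shared for p in truth.puncta)
        assert len(truth.channel("ch0")) == len(truth.channel("ch1"))

    def test_half_fraction_deterministic_split(self, noiseless_acq):
        _, t1 = generate_correlated_pair(0.5, noiseless_acq, seed=3)
        _, t2 = generate_correlated_pair(0.5, noiseless_acq, seed=3)
        assert t1.to_json() == t2.to_json()
        n_shared = sum(p.shared for p in t1.channel("ch0"))
        assert n_shared == round(0.5 * len(t1.channel("ch0")))

    def test_fraction_out_of_range_rejected(self, noiseless_acq):
        with pytest.raises(ValueError):
            generate_correlated_pair(1.2, noiseless_acq, seed=0)


class TestPeripheralCohort:
    @pytest.mark.parametrize("bias,expect_in_band", [(1.0, True), (0.0, False)])
    def test_degenerate_bias(self, bias, expect_in_band, noiseless_acq):
        _, truth = generate_peripheral_cohort(
            12, bias, seed=4, acq=noiseless_acq, render=False
        )
        assert len(truth.puncta) == 12
        assert all(p.in_band is expect_in_band for p in truth.puncta)

    def test_band_membership_consistent_with_geometry(self, noiseless_acq):
        _, truth = generate_peripheral_cohort(
            30, None, seed=4, acq=noiseless_acq, render=False
        )
        cx, cy = truth.cell_center_um
        R, w = truth.cell_radius_um, truth.band_width_um
        for p in truth.puncta:
            d = np.hypot(p.centroid_um[0] - cx, p.centroid_um[1] - cy)
            assert p.in_band == (d > R - w)

    def test_uniform_placement_follows_annulus_law(self, noiseless_acq):
        """Uniform centroids in a 37.5 um disc: the fraction inside the
        outer 10 um band has expectation 1 - (27.5/37.5)^2 ~ 0.462."""
        n_in = n_tot = 0
        for seed in range(25):
            _, truth = generate_peripheral_cohort(
                80, None, seed=seed, acq=noiseless_acq, render=False
            )
            n_in += sum(p.in_band for p in truth.puncta)
            n_tot += len(truth.puncta)
        assert n_tot == 2000
        p0 = 1 - (27.5 / 37.5) ** 2
        half_ci = 1.96 * np.sqrt(p0 * (1 - p0) / n_tot)
        assert abs(n_in / n_tot - p0) < half_ci

    def test_band_wider_than_cell_rejected(self, noiseless_acq):
        spec = TruthSpec(cell_diameter_um=75, band_width_um=10)
        with pytest.raises(ValueError):
            generate_peripheral_cohort(
                5, 0.5, seed=0, acq=noiseless_acq,
                spec=TruthSpec(cell_diameter_um=18, nucleus_diameter_um=6,
                               band_width_um=10),
            )
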