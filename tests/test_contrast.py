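"""B0/B1-corrected contrast maps."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glucest.contrast import GluCESTMap, compute_glucest, correct_b0, correct_b1
from glucest.fieldmap import OffsetStack, estimate_field_maps
from glucest.pipeline import CorrectionSettings, contrast_map
from glucest.simulate import CEST_OFFSETS_PPM, batch_zspectra, default_cest_scheme


def two_lorentzian(offsets, shift=0.0):
    """Analytic two-dip spectrum (water at 0, solute at +3 ppm), displaced."""
    x = offsets - shift
    return (
        1.0
        - 0.45 / (1.0 + (x / 1.3) ** 2)
        - 0.05 / (1.0 + ((x - 3.0) / 0.9) ** 2)
    )


def stack_from_rows(rows):
    data = np.asarray(rows)[:, None, :]
    return OffsetStack(
        data, CEST_OFFSETS_PPM, default_cest_scheme(),
        mask=np.ones((data.shape[0], 1), dtype=bool),
    )


class TestCorrectB0:
    def test_zero_shift_reproduces_acquired_frames(self):
        z = two_lorentzian(CEST_OFFSETS_PPM)
        stack = stack_from_rows([z])
        z_neg, z_pos, valid = correct_b0(stack, np.zeros((1, 1)))
        assert valid[0, 0]
        assert z_neg[0, 0] == pytest.approx(stack.frame(-3.0)[0, 0], abs=1e-12)
        assert z_pos[0, 0] == pytest.approx(stack.frame(3.0)[0, 0], abs=1e-12)

    def test_shifted_spectrum_corrected_to_analytic_values(self):
        shift = 0.15
        acquired = two_lorentzian(CEST_OFFSETS_PPM, shift=shift)
        stack = stack_from_rows([acquired])
        z_neg, z_pos, valid = correct_b0(stack, np.full((1, 1), shift))
        truth = two_lorentzian(np.array([-3.0, 3.0]))
        assert valid[0, 0]
        assert z_neg[0, 0] == pytest.approx(truth[0], abs=1e-3)
        assert z_pos[0, 0] == pytest.approx(truth[1], abs=1e-3)

    def test_large_shift_invalidated_not_extrapolated(self):
        stack = stack_from_rows([two_lorentzian(CEST_OFFSETS_PPM)])
        z_neg, _, valid = correct_b0(stack, np.full((1, 1), 1.3))
        assert not valid[0, 0]
        assert np.isnan(z_neg[0, 0])

    def test_boundary_shift_still_valid(self):
        stack = stack_from_rows([two_lorentzian(CEST_OFFSETS_PPM)])
        _, _, valid = correct_b0(stack, np.full((1, 1), 1.19))
        assert valid[0, 0]

    def test_shape_mismatch_rejected(self):
        stack = stack_from_rows([two_lorentzian(CEST_OFFSETS_PPM)])
        with pytest.raises(ValueError):
            correct_b0(stack, np.zeros((2, 2)))


class TestComputeGlucest:
    def test_symmetric_spectrum_gives_zero(self):
        gmap = compute_glucest(np.array([[0.7]]), np.array([[0.7]]))
        assert gmap.percent[0, 0] == pytest.approx(0.0)

    def test_arithmetic_identity(self):
        gmap = compute_glucest(np.array([[0.60]]), np.array([[0.48]]))
        assert gmap.percent[0, 0] == pytest.approx(20.0)

    def test_nonpositive_reference_invalidated(self):
        gmap = compute_glucest(np.array([[0.0, -0.1]]), np.array([[0.1, 0.1]]))
        assert not gmap.valid.any()

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    def test_invariant_to_global_stack_rescale(self, scale):
        a = compute_glucest(np.array([[0.6]]), np.array([[0.5]]))
        b = compute_glucest(np.array([[0.6 * scale]]), np.array([[0.5 * scale]]))
        assert a.percent[0, 0] == pytest.approx(b.percent[0, 0], rel=1e-12)

    def test_noiseless_phantom_matches_simulator_prediction(
        self, trivial_phantom, calibration, pools
    ):
        """With B0 = 0 and kappa = 1 the contrast chain must reproduce the
        Bloch-McConnell prediction voxel for voxel.

        With the true (zero/unity) fields supplied, agreement is exact to
        numerical precision.  With estimated fields, agreement is limited by
        the water-line estimator's solute-asymmetry bias (about 1e-3 ppm,
        amplified by the z-spectrum slope at +-3 ppm), which bounds the
        deviation at the 0.1% contrast scale."""
        b = trivial_phantom
        brain = b.truth.brain_mask
        glu_values = np.unique(b.truth.glu_map[brain])
        from glucest.fieldmap import FieldMaps
        from glucest.simulate import amine_proton_fraction

        predicted = {}
        for glu in glu_values:
            z = batch_zspectra(
                pools, default_cest_scheme(), np.array([-3.0, 3.0]),
                solute_fraction=amine_proton_fraction(1.0) * glu,
            )
            predicted[glu] = 100 * (z[0] - z[1]) / z[0]

        exact_fields = FieldMaps(
            b0_ppm=np.zeros(brain.shape), kappa=np.ones(brain.shape), valid=brain
        )
        exact = contrast_map(b.cest, exact_fields, calibration, CorrectionSettings())
        fmaps = estimate_field_maps(b.wassr, b.b1_images, b.b1_angles_deg)
        estimated = contrast_map(b.cest, fmaps, calibration, CorrectionSettings())
        for glu in glu_values:
            sel = brain & (b.truth.glu_map == glu)
            assert np.abs(exact.percent[sel & exact.valid] - predicted[glu]).max() < 1e-6
            assert np.abs(
                estimated.percent[sel & estimated.valid] - predicted[glu]
            ).max() < 0.1


class TestCorrectB1:
    def test_unity_kappa_is_identity(self, calibration):
        raw = compute_glucest(np.array([[0.6, 0.7]]), np.array([[0.5, 0.6]]))
        out = correct_b1(raw, np.ones((1, 2)), calibration)
        assert np.allclose(out.percent, raw.percent, atol=1e-12)

    def test_out_of_range_kappa_invalid(self, calibration):
        raw = compute_glucest(np.array([[0.6]]), np.array([[0.5]]))
        out = correct_b1(raw, np.full((1, 1), 0.4), calibration)
        assert not out.valid[0, 0]

    def test_narrow_table_rejected(self, pools):
        from glucest.simulate import b1_calibration_curve, default_cest_scheme

        table = b1_calibration_curve(pools, default_cest_scheme(), [0.8, 1.0, 1.2])
        raw = compute_glucest(np.array([[0.6]]), np.array([[0.5]]))
        with pytest.raises(ValueError):
            correct_b1(raw, np.ones((1, 1)), table)

    def test_non_monotone_table_rejected(self, calibration):
        import pandas as pd

        bad = pd.DataFrame(
            {"kappa": [0.5, 1.0, 1.5], "glucest_percent": [1.0, 2.0, 1.5]}
        )
        raw = compute_glucest(np.array([[0.6]]), np.array([[0.5]]))
        with pytest.raises(ValueError):
            correct_b1(raw, np.ones((1, 1)), bad)

    def test_kappa_gradient_flattened_by_correction(
        self, uniform_kappa_phantom, calibration
    ):
        b = uniform_kappa_phantom
        fmaps = estimate_field_maps(b.wassr, b.b1_images, b.b1_angles_deg)
        corrected = contrast_map(b.cest, fmaps, calibration, CorrectionSettings())
        raw = contrast_map(b.cest, fmaps, calibration, CorrectionSettings(b1=False))

        def cv(gmap):
            v = gmap.percent[gmap.valid & b.truth.brain_mask]
            return v.std() / v.mean()

        assert cv(corrected) < 0.05
        assert cv(raw) > cv(corrected)


class TestGluCESTMapType:
    def test_invalid_voxels_carry_nan_sentinel(self):
        gmap = GluCESTMap(
            percent=np.array([[1.0, 2.0]]), valid=np.array([[True, False]])
        )
        assert np.isnan(gmap.percent[0, 1]) and gmap.percent[0, 0] == 1.0

    def test_nonfinite_valid_voxels_rejected(self):
        with pytest.raises(ValueError):
            GluCESTMap(percent=np.array([[np.inf]]), valid=np.array([[True]]))
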