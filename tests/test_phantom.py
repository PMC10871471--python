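"""Synthetic phantom and cohort generation."""

import numpy as np
import pytest

from glucest.fieldmap import estimate_field_maps
from glucest.phantom import (
    CohortConfig,
    PhantomConfig,
    _DispersedWassrTable,
    build_label_map,
    cohort_manifest,
    make_cohort,
    make_phantom,
    smooth_field,
)
from glucest.roi import REGION_LABELS
from glucest.simulate import (
    WASSR_OFFSETS_PPM,
    batch_zspectra,
    default_wassr_scheme,
)


class TestPhantomStructure:
    def test_default_stack_offsets(self, noiseless_phantom):
        assert noiseless_phantom.cest.offsets.size == 18
        assert noiseless_phantom.wassr.offsets.size == 21
        assert noiseless_phantom.b1_images.shape[-1] == 3

    def test_same_seed_reproduces_byte_identical_output(self):
        cfg = PhantomConfig(shape=(32, 22), noise_sigma=0.004)
        a = make_phantom(cfg, seed=99)
        b = make_phantom(cfg, seed=99)
        assert np.array_equal(a.cest.data, b.cest.data)
        assert np.array_equal(a.wassr.data, b.wassr.data)
        assert np.array_equal(a.b1_images, b.b1_images)
        c = make_phantom(cfg, seed=100)
        assert not np.array_equal(a.cest.data, c.cest.data)

    @pytest.mark.parametrize("shape", [(96, 64), (48, 32), (32, 22)])
    def test_labels_partition_brain_with_all_regions(self, shape):
        labels = build_label_map(shape)
        brain = labels > 0
        counts = {r: int((labels == code).sum()) for r, code in REGION_LABELS.items()}
        assert all(v > 0 for v in counts.values())
        assert (labels[~brain] == 0).all()
        assert sum(counts.values()) == int(brain.sum())

    def test_truth_invariants(self, noiseless_phantom):
        t = noiseless_phantom.truth
        assert (t.glu_map >= 0).all()
        assert (t.label_map[~t.brain_mask] == 0).all()
        assert np.abs(t.b0_map).max() <= 0.3 + 1e-12
        kb = t.kappa_map[t.brain_mask]
        assert kb.min() >= 0.8 - 1e-12 and kb.max() <= 1.2 + 1e-12

    def test_smooth_field_reaches_requested_amplitude(self):
        f = smooth_field((40, 30), 0.25)
        assert np.abs(f).max() == pytest.approx(0.25)

    def test_too_small_grid_rejected(self):
        with pytest.raises(ValueError):
            PhantomConfig(shape=(10, 8))

    def test_rician_noise_keeps_magnitudes_nonnegative(self):
        b = make_phantom(
            PhantomConfig(shape=(32, 22), noise_sigma=0.02, noise_model="rician"),
            seed=5,
        )
        assert (b.cest.data >= 0).all()


class TestWassrTable:
    def test_table_matches_brute_force_convolution(self, pools):
        """Dual route: lookup table versus direct trapezoid convolution of
        the Bloch-McConnell spectrum over the Gaussian B0 spread."""
        sigma = 0.07
        scheme = default_wassr_scheme()
        table = _DispersedWassrTable(
            pools, scheme, 0.8, 1.2, sigma, WASSR_OFFSETS_PPM, b0_extent=0.32
        )
        rng = np.random.default_rng(0)
        for _ in range(3):
            b0 = float(rng.uniform(-0.3, 0.3))
            kap = float(rng.uniform(0.8, 1.2))
            d = np.arange(-4.5 * sigma, 4.5 * sigma + 1e-9, 0.002)
            w = np.exp(-0.5 * (d / sigma) ** 2)
            w /= w.sum()
            brute = (
                w[:, None]
                * batch_zspectra(pools, scheme, WASSR_OFFSETS_PPM, b0 + d, kap)
            ).sum(axis=0)
            fast = table.evaluate(
                WASSR_OFFSETS_PPM, np.array([b0]), np.array([kap])
            )[0]
            assert np.abs(fast - brute).max() < 2e-4

    def test_table_requires_positive_dispersion(self, pools):
        with pytest.raises(ValueError):
            _DispersedWassrTable(
                pools, default_wassr_scheme(), 0.8, 1.2, 0.0, WASSR_OFFSETS_PPM, 0.3
            )


class TestRecovery:
    def test_unperturbed_phantom_recovered_to_estimator_resolution(
        self, trivial_phantom
    ):
        """B0 = 0 and kappa = 1 come back essentially exactly; the residual
        B0 offset (about a hundredth of the offset step) is the
        solute-asymmetry floor of any symmetry-based water-line estimator."""
        b = trivial_phantom
        fmaps = estimate_field_maps(b.wassr, b.b1_images, b.b1_angles_deg)
        brain = b.truth.brain_mask & fmaps.valid
        assert np.abs(fmaps.b0_ppm[brain]).max() < 2e-3
        assert np.abs(fmaps.kappa[brain] - 1.0).max() < 1e-6

    def test_noisy_phantom_field_rmse(self):
        b = make_phantom(PhantomConfig(shape=(48, 32), noise_sigma=0.005), seed=20240216)
        fmaps = estimate_field_maps(b.wassr, b.b1_images, b.b1_angles_deg)
        brain = b.truth.brain_mask & fmaps.valid
        b0_err = fmaps.b0_ppm[brain] - b.truth.b0_map[brain]
        k_err = fmaps.kappa[brain] - b.truth.kappa_map[brain]
        assert np.sqrt((b0_err**2).mean()) < 0.01
        assert np.sqrt((k_err**2).mean()) < 0.02


class TestCohort:
    def test_default_cohort_structure(self):
        cohort = make_cohort(CohortConfig(), seed=1, generate_phantoms=False)
        groups = [spec.group for spec, _, _ in cohort]
        assert len(cohort) == 19
        assert groups.count("non-smoker") == 10
        assert groups.count("smoker") == 9
        ns = [s for s, _, _ in cohort if s.group == "non-smoker"]
        assert {s.sex for s in ns} == {"F", "M"}
        for spec, _, _ in cohort:
            assert 20.0 <= spec.age <= 70.0
            assert 0 <= spec.seed < 2**31

    def test_degenerate_generator_gives_identical_truth(self):
        cfg = CohortConfig(subject_sd_mM=0.0)
        cohort = make_cohort(cfg, seed=2, generate_phantoms=False)
        glu0 = cohort[0][2]
        for _, _, glu in cohort:
            assert glu == glu0

    def test_injected_smoker_slope_changes_cg_only(self):
        cfg = CohortConfig(
            subject_sd_mM=0.0, age_slope_mM_per_year={("smoker", "CG"): -0.1}
        )
        cohort = make_cohort(cfg, seed=2, generate_phantoms=False)
        for spec, _, glu in cohort:
            expected = cfg.region_base_mM["CG"]
            if spec.group == "smoker":
                expected += -0.1 * (spec.age - cfg.reference_age)
            assert glu["CG"] == pytest.approx(max(expected, 0.0))
            assert glu["FP"] == pytest.approx(cfg.region_base_mM["FP"])

    def test_negative_group_size_rejected(self):
        with pytest.raises(ValueError):
            CohortConfig(n_smokers=-1)

    def test_manifest_layout(self):
        cohort = make_cohort(CohortConfig(), seed=3, generate_phantoms=False)
        manifest = cohort_manifest(cohort)
        assert list(manifest.columns) == ["subject_id", "group", "age", "sex", "seed"]
        assert len(manifest) == 19

    def test_cohort_determinism(self):
        cfg = CohortConfig(phantom=PhantomConfig(shape=(32, 22)))
        a = make_cohort(cfg, seed=7)
        b = make_cohort(cfg, seed=7)
        assert [s.subject_id for s, _, _ in a] == [s.subject_id for s, _, _ in b]
        assert np.array_equal(a[0][1].cest.data, b[0][1].cest.data)
        assert np.array_equal(a[-1][1].wassr.data, b[-1][1].wassr.data)
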