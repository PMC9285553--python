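import math

import numpy as np
import pytest

from dtiphantom.io import AcquisitionScheme, protocol_scheme
from dtiphantom.phantom import (
    NoiseModel,
    PhantomLayout,
    SiteAcquisition,
    SiteEffect,
    TubeSpec,
    add_rician_noise,
    axisymmetric_eigenvalues,
    simulate_signal,
    simulate_study,
    tube_masks,
)
from dtiphantom.qa import snr_map, snr_roi_mean
from dtiphantom.segment import circular_rois
from dtiphantom.tensor import fit_tensor_lls, select_bvalues, tensor_metrics


class TestSimulateSignal:
    def test_monoexponential_scalar_value(self, single_tube_layout):
        """Inside the tube, S = s0 * exp(-b * d) for any direction."""
        scheme = AcquisitionScheme(
            bvalues=[450.0, 450.0],
            directions=[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]],
        )
        stack = simulate_signal(single_tube_layout, scheme, s0=1000.0)
        mask = tube_masks(single_tube_layout)[1]
        expected = 1000.0 * math.exp(-450.0 * 1.113e-3)  # = 606.015...
        np.testing.assert_allclose(stack.signal[mask], expected, rtol=1e-12)

    def test_b0_returns_s0_inside_tubes(self, noise_free_stack, seven_tube_layout):
        masks = tube_masks(seven_tube_layout)
        b0 = noise_free_stack.scheme.bvalues == 0.0
        for mask in masks.values():
            np.testing.assert_allclose(noise_free_stack.signal[mask][:, b0], 1000.0)

    def test_isotropic_tube_direction_independent(self, noise_free_stack, seven_tube_layout):
        mask = tube_masks(seven_tube_layout)[3]
        b450 = noise_free_stack.scheme.bvalues == 450.0
        vals = noise_free_stack.signal[mask][:, b450]
        assert np.ptp(vals) == 0.0

    def test_signal_monotone_decreasing_in_b(self, noise_free_stack, seven_tube_layout):
        masks = tube_masks(seven_tube_layout)
        scheme = noise_free_stack.scheme
        order = [0.0, 100.0, 300.0, 450.0]
        for mask in masks.values():
            voxel = noise_free_stack.signal[mask][0]
            means = [voxel[scheme.bvalues == b].mean() for b in order]
            assert all(a > b > 0 for a, b in zip(means, means[1:]))

    def test_background_zero(self, noise_free_stack, seven_tube_layout):
        masks = tube_masks(seven_tube_layout)
        inside = np.zeros(seven_tube_layout.grid_shape, dtype=bool)
        for m in masks.values():
            inside |= m
        assert np.all(noise_free_stack.signal[~inside] == 0.0)

    def test_overlapping_tubes_raise(self):
        layout = PhantomLayout(
            tubes=(
                TubeSpec(1, 0.0, (15.0, 15.0), 10.0, 1.1e-3),
                TubeSpec(2, 2.5, (20.0, 15.0), 10.0, 1.0e-3),
            ),
            grid_shape=(16, 16, 1),
            voxel_size=(2.5, 2.5, 8.0),
        )
        with pytest.raises(ValueError, match="overlap"):
            simulate_signal(layout, protocol_scheme(0.0, 1))

    def test_anisotropic_tube_has_requested_fa(self):
        layout = PhantomLayout(
            tubes=(TubeSpec(1, 0.0, (15.0, 15.0), 10.0, 1.0e-3, true_fa=0.4),),
            grid_shape=(12, 12, 1),
            voxel_size=(2.5, 2.5, 8.0),
        )
        stack = simulate_signal(layout, protocol_scheme(0.0, 1))
        mask = tube_masks(layout)[1]
        field = fit_tensor_lls(stack, roi_mask=mask)
        md, fa = field.md[mask], field.fa[mask]
        np.testing.assert_allclose(md, 1.0e-3, rtol=1e-9)
        np.testing.assert_allclose(fa, 0.4, rtol=1e-8)

    def test_axisymmetric_eigenvalues_roundtrip(self):
        lam = axisymmetric_eigenvalues(0.9e-3, 0.25)
        md, fa = tensor_metrics(np.array(lam))
        assert md == pytest.approx(0.9e-3, rel=1e-12)
        assert fa == pytest.approx(0.25, rel=1e-12)


class TestRicianNoise:
    def test_high_snr_limit_returns_input(self, single_tube_layout):
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 1))
        noisy = add_rician_noise(stack, NoiseModel("rician", 1e9, seed=0))
        np.testing.assert_allclose(noisy.signal, stack.signal, rtol=1e-5, atol=1e-4)

    def test_same_seed_reproducible(self, single_tube_layout):
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 2))
        a = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=42))
        b = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=42))
        np.testing.assert_array_equal(a.signal, b.signal)
        c = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=43))
        assert not np.array_equal(a.signal, c.signal)

    def test_measured_snr_matches_target(self, seven_tube_layout):
        """The QA SNR definition recovers the requested SNR within 15%."""
        stack = simulate_signal(seven_tube_layout, protocol_scheme(0.0, 30))
        mask = tube_masks(seven_tube_layout)[1]
        roi = circular_rois([seven_tube_layout.tubes[0].centre_xy], 8.0,
                            seven_tube_layout.grid_shape, seven_tube_layout.voxel_size)[1]
        for seed in (0, 1, 2):
            noisy = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=seed),
                                     reference_mask=mask)
            measured = snr_roi_mean(snr_map(noisy), roi)
            assert measured == pytest.approx(20.0, rel=0.15)

    def test_low_snr_rician_floor_biases_md_down(self, single_tube_layout):
        """At SNR <= 2 the noise floor flattens the decay: fitted MD
        underestimates the truth."""
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 30))
        mask = tube_masks(single_tube_layout)[1]
        noisy = add_rician_noise(stack, NoiseModel("rician", 2.0, seed=0), reference_mask=mask)
        field = fit_tensor_lls(select_bvalues(noisy, (100, 450)), roi_mask=mask)
        md = np.nanmean(field.md[mask & field.valid])
        assert md < 1.113e-3

    def test_high_snr_md_bias_below_one_percent(self, single_tube_layout):
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 30))
        mask = tube_masks(single_tube_layout)[1]
        noisy = add_rician_noise(stack, NoiseModel("rician", 20.0, seed=0), reference_mask=mask)
        field = fit_tensor_lls(select_bvalues(noisy, (100, 450)), roi_mask=mask)
        md = np.nanmean(field.md[mask & field.valid])
        assert abs(md - 1.113e-3) / 1.113e-3 < 0.01


class TestSimulateStudy:
    def _configs(self, n_sites, **kw):
        return [
            SiteAcquisition(site=chr(65 + i), sequence_class="PGSE", n_repetitions=1, **kw)
            for i in range(n_sites)
        ]

    def test_two_scans_per_site(self, single_tube_layout):
        study = simulate_study(single_tube_layout, self._configs(10), seed=0)
        assert len(study) == 20
        assert all(scan in (1, 2) for (_, _, scan) in study)

    def test_duplicate_site_sequence_raises(self, single_tube_layout):
        cfgs = self._configs(2)
        cfgs[1] = SiteAcquisition(site="A", sequence_class="PGSE", n_repetitions=1)
        with pytest.raises(ValueError, match="duplicate"):
            simulate_study(single_tube_layout, cfgs, seed=0)

    def test_no_noise_no_effects_scans_identical(self, single_tube_layout):
        study = simulate_study(single_tube_layout, self._configs(2), seed=0)
        for site, seq in study.site_sequences():
            s1, s2 = study.scan_pair(site, seq)
            np.testing.assert_array_equal(s1.signal, s2.signal)

    def test_md_bias_scales_fitted_md(self, single_tube_layout):
        cfgs = [
            SiteAcquisition(site="A", sequence_class="PGSE", n_repetitions=1),
            SiteAcquisition(
                site="B", sequence_class="PGSE", n_repetitions=1,
                effects=SiteEffect(md_bias_fraction=0.02),
            ),
        ]
        study = simulate_study(single_tube_layout, cfgs, seed=0)
        mask = tube_masks(single_tube_layout)[1]
        mds = {}
        for site in ("A", "B"):
            field = fit_tensor_lls(study[(site, "PGSE", 1)], roi_mask=mask)
            mds[site] = np.nanmean(field.md[mask & field.valid])
        assert mds["B"] / mds["A"] == pytest.approx(1.02, rel=1e-9)

    def test_scan2_shift_applied_to_scan2_only(self, single_tube_layout):
        cfgs = [
            SiteAcquisition(
                site="A", sequence_class="PGSE", n_repetitions=1,
                effects=SiteEffect(scan2_shift_fraction=0.01),
            )
        ]
        study = simulate_study(single_tube_layout, cfgs, seed=0)
        mask = tube_masks(single_tube_layout)[1]
        md = {}
        for scan in (1, 2):
            field = fit_tensor_lls(study[("A", "PGSE", scan)], roi_mask=mask)
            md[scan] = np.nanmean(field.md[mask & field.valid])
        assert md[2] / md[1] == pytest.approx(1.01, rel=1e-9)
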