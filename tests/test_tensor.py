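import numpy as np
import pytest

from dtiphantom.io import AcquisitionScheme, DWIStack, protocol_scheme
from dtiphantom.phantom import simulate_signal, tensor_forward_signal, tube_masks
from dtiphantom.tensor import (
    build_bmatrix,
    design_matrix,
    fit_tensor_lls,
    repetition_series,
    select_bvalues,
    tensor_metrics,
)


def single_voxel_stack(tensor, scheme, s0=1000.0):
    signal = tensor_forward_signal(np.asarray(tensor), scheme, s0)
    return DWIStack(signal[None, None, None, :], (2.5, 2.5, 8.0), scheme)


class TestBMatrix:
    def test_axis_aligned(self):
        s = AcquisitionScheme(bvalues=[450.0], directions=[[1.0, 0.0, 0.0]])
        flat = build_bmatrix(s).flat[0]
        np.testing.assert_allclose(flat, [450.0, 0, 0, 0, 0, 0])

    def test_icosahedral_direction_outer_product(self):
        g = np.array([0.5257, 0.8507, 0.0])
        g = g / np.linalg.norm(g)
        s = AcquisitionScheme(bvalues=[450.0], directions=[g])
        B = build_bmatrix(s).matrices[0]
        expected = 450.0 * np.outer(g, g)  # independent outer-product arithmetic
        np.testing.assert_allclose(B, expected, atol=1e-12)
        assert B[0, 0] == pytest.approx(124.356, abs=0.01)
        assert B[1, 1] == pytest.approx(325.644, abs=0.01)
        assert B[0, 1] == pytest.approx(201.236, abs=0.01)

    def test_b0_zero_matrix(self):
        s = AcquisitionScheme(bvalues=[0.0], directions=[[0.0, 0.0, 0.0]])
        assert np.all(build_bmatrix(s).matrices[0] == 0.0)

    def test_trace_equals_b(self):
        s = protocol_scheme(76.0, 1)
        np.testing.assert_allclose(build_bmatrix(s).trace, s.bvalues, atol=1e-6)

    def test_positive_semidefinite(self):
        s = protocol_scheme(5.0, 1)
        eig = np.linalg.eigvalsh(build_bmatrix(s).matrices)
        assert np.all(eig >= -1e-9)


class TestSelectBValues:
    def test_pair_keeps_twelve_volumes_per_repetition(self, noise_free_stack):
        stack30 = noise_free_stack
        sub = select_bvalues(stack30, (100, 450))
        assert sub.signal.shape[-1] == 12 * stack30.scheme.n_repetitions

    def test_all_shells_is_identity(self, noise_free_stack):
        sub = select_bvalues(noise_free_stack, ("b_low", 100, 300, 450))
        np.testing.assert_array_equal(sub.signal, noise_free_stack.signal)

    def test_single_shell_underdetermined(self, noise_free_stack):
        with pytest.raises(ValueError, match="at least 7"):
            select_bvalues(noise_free_stack, (100,))

    def test_absent_bvalue_raises(self, noise_free_stack):
        with pytest.raises(ValueError, match="not present"):
            select_bvalues(noise_free_stack, (100, 200))


class TestTensorMetrics:
    def test_isotropic(self):
        md, fa = tensor_metrics(np.array([1.113e-3] * 3))
        assert md == pytest.approx(1.113e-3, rel=1e-12)
        assert fa == 0.0

    def test_stick_limit(self):
        md, fa = tensor_metrics(np.array([3e-3, 0.0, 0.0]))
        assert md == pytest.approx(1e-3, rel=1e-12)
        assert fa == pytest.approx(1.0, rel=1e-12)

    def test_prolate_value(self):
        # ((2-1)^2 + (2-1)^2 + 0) / (4+1+1) = 2/6 -> FA = sqrt(1/6)
        md, fa = tensor_metrics(np.array([2e-3, 1e-3, 1e-3]))
        assert fa == pytest.approx(np.sqrt(1.0 / 6.0), rel=1e-12)

    def test_all_zero_flagged_nan(self):
        _, fa = tensor_metrics(np.zeros(3))
        assert np.isnan(fa)

    def test_md_fa_order_invariant(self):
        lam = np.array([1.5e-3, 0.9e-3, 0.3e-3])
        md1, fa1 = tensor_metrics(lam)
        md2, fa2 = tensor_metrics(lam[::-1])
        assert md1 == md2 and fa1 == fa2


class TestFitTensorLLS:
    def test_noise_free_isotropic_exact(self, single_tube_layout):
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 1))
        mask = tube_masks(single_tube_layout)[1]
        field = fit_tensor_lls(stack, roi_mask=mask)
        md = field.md[mask & field.valid]
        fa = field.fa[mask & field.valid]
        np.testing.assert_allclose(md, 1.113e-3, rtol=1e-10)
        assert np.all(fa < 1e-8)

    def test_anisotropic_eigenvalue_recovery(self):
        tensor = np.diag([1.5e-3, 1.0e-3, 0.5e-3])
        stack = single_voxel_stack(tensor, protocol_scheme(0.0, 2))
        field = fit_tensor_lls(stack)
        np.testing.assert_allclose(
            field.eigenvalues[0, 0, 0], [1.5e-3, 1.0e-3, 0.5e-3], rtol=1e-9
        )

    def test_ln_s0_recovered(self):
        stack = single_voxel_stack(np.eye(3) * 1e-3, protocol_scheme(0.0, 1), s0=875.0)
        field = fit_tensor_lls(stack)
        assert field.ln_s0[0, 0, 0] == pytest.approx(np.log(875.0), abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        """One-voxel LLS equals the exhaustively computed normal-equations
        solution."""
        rng = np.random.default_rng(3)
        tensor = np.array(
            [[1.4, 0.1, 0.05], [0.1, 1.0, -0.08], [0.05, -0.08, 0.7]]
        ) * 1e-3
        scheme = protocol_scheme(5.0, 2)
        clean = tensor_forward_signal(tensor, scheme, 1000.0)
        noisy = clean * np.exp(rng.normal(0, 0.02, clean.size))  # log-domain noise
        stack = DWIStack(noisy[None, None, None, :], (2.5, 2.5, 8.0), scheme)
        field = fit_tensor_lls(stack)
        X = design_matrix(scheme)
        beta = np.linalg.solve(X.T @ X, X.T @ np.log(noisy))
        oracle = np.array(
            [
                [beta[1], beta[4], beta[5]],
                [beta[4], beta[2], beta[6]],
                [beta[5], beta[6], beta[3]],
            ]
        )
        np.testing.assert_allclose(field.tensor[0, 0, 0], oracle, atol=1e-10)
        assert field.ln_s0[0, 0, 0] == pytest.approx(beta[0], abs=1e-10)

    def test_md_rotation_invariant(self):
        """Rotating both tensor and gradient frame leaves MD unchanged."""
        from scipy.spatial.transform import Rotation

        tensor = np.diag([1.6e-3, 0.8e-3, 0.4e-3])
        scheme = protocol_scheme(0.0, 1)
        R = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        rotated_scheme = AcquisitionScheme(
            bvalues=scheme.bvalues,
            directions=scheme.directions @ R.T,
            b_low=0.0,
            n_repetitions=1,
        )
        f1 = fit_tensor_lls(single_voxel_stack(tensor, scheme))
        f2 = fit_tensor_lls(single_voxel_stack(R @ tensor @ R.T, rotated_scheme))
        assert f1.md[0, 0, 0] == pytest.approx(f2.md[0, 0, 0], rel=1e-9)

    def test_excluded_repetition_equals_reduced_fit(self):
        """Dropping a repetition's volumes reproduces the fit on the
        remaining data."""
        rng = np.random.default_rng(7)
        scheme = protocol_scheme(0.0, 3)
        clean = tensor_forward_signal(np.eye(3) * 1.1e-3, scheme, 1000.0)
        noisy = clean * np.exp(rng.normal(0, 0.03, clean.size))
        keep = scheme.repetition_index != 1
        full_minus_rep = DWIStack(
            noisy[None, None, None, keep], (2.5, 2.5, 8.0), scheme.subset(keep)
        )
        reduced = DWIStack(
            noisy[None, None, None, keep], (2.5, 2.5, 8.0), scheme.subset(keep)
        )
        f1 = fit_tensor_lls(full_minus_rep)
        f2 = fit_tensor_lls(reduced)
        np.testing.assert_allclose(f1.tensor[0, 0, 0], f2.tensor[0, 0, 0], atol=1e-15)

    def test_too_few_positive_signals_invalid(self):
        scheme = protocol_scheme(0.0, 1)
        signal = np.zeros((1, 1, 1, len(scheme)))
        signal[0, 0, 0, :6] = 100.0  # only 6 usable measurements
        stack = DWIStack(signal, (2.5, 2.5, 8.0), scheme)
        with pytest.raises(ValueError, match="no voxel"):
            fit_tensor_lls(stack)

    def test_negative_eigenvalues_not_clamped(self):
        """Under heavy noise some eigenvalues go negative and are kept."""
        rng = np.random.default_rng(11)
        scheme = protocol_scheme(0.0, 1)
        clean = tensor_forward_signal(np.eye(3) * 0.1e-3, scheme, 1000.0)
        found = False
        for _ in range(50):
            noisy = np.abs(clean + rng.normal(0, 300.0, clean.size))
            noisy[noisy == 0] = 1.0
            stack = DWIStack(noisy[None, None, None, :], (2.5, 2.5, 8.0), scheme)
            field = fit_tensor_lls(stack)
            if field.eigenvalues[0, 0, 0].min() < 0:
                found = True
                break
        assert found


class TestRepetitionSeries:
    def test_noise_free_constant_and_length(self, single_tube_layout):
        from dtiphantom.phantom import simulate_signal

        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 30))
        mask = tube_masks(single_tube_layout)[1]
        md, fa = repetition_series(stack, (100, 450), mask)
        assert md.size == 30 and fa.size == 30
        np.testing.assert_allclose(md, md[0], rtol=1e-10)

    def test_dw_signal_loss_drift_raises_md_trend(self, single_tube_layout):
        """A slow multiplicative loss of DW signal (b > 0 volumes only)
        inflates the apparent attenuation, so the per-repetition MD series
        trends upward."""
        stack = simulate_signal(single_tube_layout, protocol_scheme(0.0, 10))
        scheme = stack.scheme
        factors = np.ones(len(scheme))
        dw = scheme.bvalues > 0
        factors[dw] = (1.0 - 0.005) ** scheme.repetition_index[dw]
        drifted = stack.with_signal(stack.signal * factors)
        mask = tube_masks(single_tube_layout)[1]
        # the low-b volume anchors S0, so the DW-only loss shows up as MD
        md, _ = repetition_series(drifted, ("b_low", 100, 450), mask)
        slope = np.polyfit(np.arange(md.size), md, 1)[0]
        assert slope > 0
        assert np.all(np.diff(md) > 0)
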