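"""Tests of snapshot POD, spectra, ROM truncation and error metrics."""

import numpy as np
import pytest

from rpodflow import (
    SnapshotMatrix,
    SyntheticFlowSpec,
    ValidationError,
    build_snapshot_matrix,
    coefficient_spectrum,
    cumulative_energy_table,
    energy_fraction,
    generate_synthetic_flow,
    pod,
    reconstruct,
    reconstruction_error,
)


def matrix_as_snapshots(U):
    """Wrap a bare pre-centred matrix (rows split half u, half v)."""
    U = np.asarray(U, dtype=float)
    n = U.shape[0] // 2
    return SnapshotMatrix(
        U=U,
        mean_u=np.zeros(n),
        mean_v=np.zeros(n),
        x=np.arange(n, dtype=float),
        y=np.array([0.0]),
        mask=np.ones((1, n), dtype=bool),
        times=np.arange(U.shape[1], dtype=float),
        sample_rate=1.0,
    )


class TestPOD:
    def test_diagonal_spectrum_and_fractions(self):
        basis = pod(matrix_as_snapshots([[2.0, 0.0], [0.0, 1.0]]))
        assert np.allclose(basis.sigma, [2.0, 1.0])
        assert basis.fractions[0] == pytest.approx(0.8)

    def test_svd_identity(self, rng):
        U = rng.standard_normal((12, 8))
        U -= U.mean(axis=1, keepdims=True)
        basis = pod(matrix_as_snapshots(U))
        rebuilt = (basis.Phi * basis.sigma) @ basis.Psi.T
        assert np.linalg.norm(rebuilt - U) <= 1e-10 * np.linalg.norm(U)

    def test_orthonormality_and_coefficient_identity(self, clean_basis):
        G = clean_basis.Phi.T @ clean_basis.Phi
        assert np.abs(G - np.eye(clean_basis.N)).max() < 1e-10
        a = clean_basis.coefficients
        assert np.allclose(
            a, clean_basis.sigma[:, None] * clean_basis.Psi.T, atol=1e-10
        )
        # a_i(t) is also the projection Phi_i* U
        proj = clean_basis.Phi.T @ clean_basis.snapshots.U
        assert np.allclose(a, proj, atol=1e-10)

    def test_energy_conservation(self, clean_basis):
        total = (clean_basis.snapshots.U**2).sum()
        assert clean_basis.energies.sum() == pytest.approx(total, rel=1e-8)

    def test_fractions_sum_to_one(self, clean_basis):
        assert clean_basis.fractions.sum() == pytest.approx(1.0, abs=1e-12)

    def test_all_zero_matrix_gives_empty_basis(self):
        basis = pod(matrix_as_snapshots(np.zeros((6, 4))))
        assert basis.N == 0

    def test_sign_convention_max_entry_positive(self, clean_basis):
        for i in range(clean_basis.N):
            col = clean_basis.Phi[:, i]
            assert col[np.argmax(np.abs(col))] > 0

    def test_mode_recovery_against_ground_truth(self, clean_flow, clean_basis):
        _, truth = clean_flow
        for i in range(3):
            assert abs(clean_basis.Phi[:, i] @ truth.true_modes[:, i]) >= 0.99


class TestEnergyFraction:
    def test_arithmetic(self):
        assert np.allclose(energy_fraction([4.0, 1.0]), [0.8, 0.2])
        assert np.allclose(energy_fraction([1.0]), [1.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            energy_fraction([0.0, 0.0])


class TestReconstructionError:
    @pytest.mark.parametrize(
        "U,Ur,expected",
        [
            ([[1.0], [1.0]], [[1.0], [0.0]], 50.0),
            ([[1.0], [1.0]], [[1.0], [1.0]], 0.0),
            ([[1.0], [1.0]], [[0.0], [0.0]], 100.0),
        ],
    )
    def test_definition(self, U, Ur, expected):
        assert reconstruction_error(U, Ur) == pytest.approx(expected)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValidationError):
            reconstruction_error(np.zeros((2, 2)), np.ones((2, 2)))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            reconstruction_error(np.zeros((2, 2)), np.zeros((2, 3)))


class TestReconstruct:
    def test_full_rank_is_exact(self, clean_basis):
        rom = reconstruct(clean_basis, clean_basis.N)
        assert rom.error_pct <= 1e-8
        assert rom.cumulative_energy_pct == pytest.approx(100.0, abs=1e-6)

    def test_rank_one_source_exact_with_one_mode(self, rng):
        U = np.outer(rng.standard_normal(8), rng.standard_normal(5))
        U -= 0  # already treated as pre-centred fluctuations
        basis = pod(matrix_as_snapshots(U))
        rom = reconstruct(basis, 1, include_mean=False)
        assert rom.error_pct <= 1e-10

    def test_planted_spectrum_energy_arithmetic(self, clean_basis):
        rom = reconstruct(clean_basis, 2)
        assert rom.cumulative_energy_pct == pytest.approx(100 * 125 / 129, rel=1e-9)

    def test_out_of_range_rejected(self, clean_basis):
        for r in (0, clean_basis.N + 1):
            with pytest.raises(ValidationError):
                reconstruct(clean_basis, r)

    def test_frobenius_error_monotone_in_r(self, rng):
        # Eckart–Young: truncation error non-increasing as modes are added
        for _ in range(3):
            U = rng.standard_normal((14, 9))
            basis = pod(matrix_as_snapshots(U - U.mean(axis=1, keepdims=True)))
            errs = []
            for r in range(1, basis.N + 1):
                Ur = (basis.Phi[:, :r] * basis.sigma[:r]) @ basis.Psi[:, :r].T
                errs.append(np.linalg.norm(basis.snapshots.U - Ur))
            assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))

    def test_sign_flip_invariance(self, clean_basis):
        flipped_Phi = clean_basis.Phi.copy()
        flipped_Psi = clean_basis.Psi.copy()
        flipped_Phi[:, 1] *= -1
        flipped_Psi[:, 1] *= -1
        r = 3
        orig = (clean_basis.Phi[:, :r] * clean_basis.sigma[:r]) @ clean_basis.Psi[:, :r].T
        flip = (flipped_Phi[:, :r] * clean_basis.sigma[:r]) @ flipped_Psi[:, :r].T
        assert np.allclose(orig, flip, atol=1e-12)


class TestSpectrum:
    def test_single_tone_peak(self):
        t = np.arange(180) / 22.0
        res = coefficient_spectrum(np.sin(2 * np.pi * 1.22 * t), 22.0)
        df = res.freqs[1] - res.freqs[0]
        assert abs(res.peak_freq - 1.22) <= df / 2 + 1e-12

    def test_constant_series_has_no_ac_content(self):
        res = coefficient_spectrum(np.full(64, 3.3), 22.0)
        assert np.all(res.amplitude[1:] <= 1e-12)

    def test_two_tone_leading_peaks(self):
        t = np.arange(180) / 22.0
        a = np.sin(2 * np.pi * 1.22 * t) + 0.5 * np.sin(2 * np.pi * 2.44 * t)
        res = coefficient_spectrum(a, 22.0)
        order = np.argsort(res.amplitude[1:])[::-1] + 1
        top2 = sorted(res.freqs[order[:2]])
        assert top2[0] == pytest.approx(1.22, abs=22.0 / 180 / 2)
        assert top2[1] == pytest.approx(2.44, abs=22.0 / 180 / 2)

    def test_amplitude_calibration(self):
        # on-bin tone of amplitude A reports amplitude A
        m, fs = 88, 22.0
        f = 5 * fs / m
        t = np.arange(m) / fs
        res = coefficient_spectrum(1.7 * np.sin(2 * np.pi * f * t), fs)
        assert res.amplitude.max() == pytest.approx(1.7, rel=1e-9)

    def test_nonuniform_times_rejected(self):
        a = np.sin(np.arange(10.0))
        bad_times = np.array([0, 1, 2, 3.5, 4, 5, 6, 7, 8, 9], dtype=float)
        with pytest.raises(ValidationError):
            coefficient_spectrum(a, 1.0, times=bad_times)

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            coefficient_spectrum(np.ones(3), 1.0)


class TestCumulativeEnergyTable:
    def test_default_sets_shape_and_limits(self, clean_basis):
        table = cumulative_energy_table(clean_basis)
        assert len(table) == 4
        last = table.iloc[-1]
        assert last["modes"] == "all"
        assert last["energy_pct"] == pytest.approx(100.0, abs=1e-6)
        assert last["error_pct"] <= 1e-8

    def test_energy_non_decreasing_for_nested_sets(self, small_spec):
        series, _ = generate_synthetic_flow(small_spec)
        basis = pod(build_snapshot_matrix(series))
        table = cumulative_energy_table(basis)
        e = table["energy_pct"].to_numpy()
        assert np.all(np.diff(e) >= -1e-12)

    def test_planted_sigma_arithmetic(self, clean_basis):
        table = cumulative_energy_table(clean_basis, mode_sets=[(1, 2)])
        assert table["energy_pct"].iloc[0] == pytest.approx(100 * 125 / 129, rel=1e-9)

    def test_out_of_range_set_rejected(self, clean_basis):
        with pytest.raises(ValidationError):
            cumulative_energy_table(clean_basis, mode_sets=[(1, clean_basis.N + 5)])
        with pytest.raises(ValidationError):
            cumulative_energy_table(clean_basis, mode_sets=[])
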