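import numpy as np
import pytest

from tfantenna.antenna_kinetics import (
    AntennaPhysical,
    AntennaRates,
    build_rate_matrix,
    copy_number_partition,
    derive_rates,
    detailed_balance_residual,
    gillespie_stationary,
    pairwise_equilibrium,
    propagate,
    solve_kinetics,
)


class TestDeriveRates:
    def test_entry_and_escape_rates(self, phys):
        rates = derive_rates(phys)
        assert rates.k1 == pytest.approx(1e-3)
        # escape = entry * cell/antenna volume ratio = 30.3 1/s
        assert rates.k1_rev == pytest.approx(1e-3 * 1000 / 0.033)
        assert round(rates.k1_rev, 0) == 30

    def test_sliding_rates(self, phys):
        rates = derive_rates(phys)
        assert rates.k_sd == pytest.approx(80.0)  # 200 bp/ms / 2500 bp
        assert rates.k_ds == pytest.approx(80.0 / 90.0)  # detailed balance

    def test_dissociation_rates(self, phys):
        rates = derive_rates(phys)
        assert rates.k2_rev == pytest.approx(100.0)  # 1e9 * 1e-7
        assert rates.k3_rev == pytest.approx(10.0)  # 1e9 * 1e-8

    def test_reconciled_on_rates(self, phys):
        rates = derive_rates(phys)
        assert rates.k3 == pytest.approx(3.0e4)
        assert rates.k2 == pytest.approx(900 * 3.0e4)

    def test_invalid_physical_inputs(self):
        with pytest.raises(ValueError):
            AntennaPhysical(antenna_volume=0.0)
        with pytest.raises(ValueError):
            AntennaPhysical(kd_specific=1e-6, kd_degenerate=1e-7)


class TestRateMatrix:
    def test_columns_sum_to_zero(self, phys):
        mat = build_rate_matrix(derive_rates(phys))
        assert np.max(np.abs(mat.sum(axis=0))) < 1e-12 * np.max(np.abs(mat))

    def test_all_zero_rates(self):
        rates = AntennaRates(0, 0, 0, 0, 0, 0, 0, 0)
        assert np.all(build_rate_matrix(rates) == 0)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            AntennaRates(-1, 0, 0, 0, 0, 0, 0, 0)

    def test_antenna_free_diagonal_entry(self, phys):
        mat = build_rate_matrix(derive_rates(phys))
        # A_F loses to C_F (30.3), D_eg (2.7e7) and SB (3e4)
        assert mat[1, 1] == pytest.approx(-(1e-3 * 1000 / 0.033 + 2.7e7 + 3.0e4))


class TestSolveKinetics:
    def test_two_state_closed_form(self):
        a, b = 3.0, 7.0
        mat = np.array(
            [
                [-a, b, 0.0, 0.0],
                [a, -b, 0.0, 0.0],
                [0.0, 0.0, -1.0, 1.0],
                [0.0, 0.0, 1.0, -1.0],
            ]
        )
        # restrict to the two-state block by starting in it; check spectrum
        w = np.sort(np.abs(np.linalg.eigvals(mat[:2, :2])))
        assert w[0] == pytest.approx(0.0, abs=1e-12)
        assert w[1] == pytest.approx(a + b)
        stat2 = np.array([b, a]) / (a + b)
        # the full 4x4 has two zero modes (disconnected blocks) and cannot
        # be solved as a single ergodic generator; verify block stationarity
        assert np.allclose(mat[:2, :2] @ stat2, 0.0, atol=1e-12)

    def test_uniform_symmetric_ring_stationary(self):
        r = 2.5
        mat = np.zeros((4, 4))
        for i in range(4):
            j = (i + 1) % 4
            mat[j, i] += r
            mat[i, j] += r
        np.fill_diagonal(mat, -mat.sum(axis=0) + np.diag(mat))
        sol = solve_kinetics(mat)
        assert sol.stationary == pytest.approx([0.25] * 4, abs=1e-12)

    def test_reconciled_defaults_spectrum(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        rates = np.sort(sol.relaxation_rates)
        # two-significant-figure agreement with the published spectrum
        assert rates[0] == pytest.approx(1.1e-3, rel=0.05)
        assert rates[1] == pytest.approx(91.0, rel=0.05)
        assert rates[2] == pytest.approx(2.7e7, rel=0.05)

    def test_reconciled_defaults_stationary(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        assert sol.stationary[0] == pytest.approx(0.099, rel=0.02)
        assert sol.stationary[1] == pytest.approx(3.3e-6, rel=0.02)
        assert sol.stationary[2] == pytest.approx(0.891, rel=0.02)
        assert sol.stationary[3] == pytest.approx(0.0099, rel=0.02)
        assert sol.stationary.sum() == pytest.approx(1.0, abs=1e-12)

    def test_sb_finding_time_slightly_over_10_ms(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        t_mid = 1.0 / np.sort(sol.relaxation_rates)[1]
        assert 0.010 < t_mid < 0.012

    def test_amplitudes_reconstruct_initial_condition(self, phys):
        mat = build_rate_matrix(derive_rates(phys))
        init = np.array([1.0, 0.0, 0.0, 0.0])
        sol = solve_kinetics(mat, initial=init)
        # sum of modal amplitude vectors equals the initial populations
        assert np.real(sol.amplitudes.sum(axis=0)) == pytest.approx(init, abs=1e-9)

    def test_rejects_non_generator(self):
        with pytest.raises(ValueError):
            solve_kinetics(np.eye(4))


class TestDetailedBalance:
    def test_reconciled_cycle_closes_exactly(self, phys):
        assert detailed_balance_residual(derive_rates(phys)) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_rounded_slide_rate_residual(self, phys):
        rates = derive_rates(phys)
        rounded = AntennaRates(
            rates.k1, rates.k1_rev, rates.k2, rates.k2_rev, rates.k3,
            rates.k3_rev, 0.89, rates.k_sd,
        )
        assert detailed_balance_residual(rounded) == pytest.approx(1.0013, abs=2e-4)

    def test_literal_published_set_breaks_cycle(self, phys):
        rates = derive_rates(phys, reconcile=False)
        assert detailed_balance_residual(rates) > 1e3

    def test_zero_reverse_rate_flags_infinity(self):
        rates = AntennaRates(1, 1, 1, 0, 1, 1, 1, 1)
        assert detailed_balance_residual(rates) == np.inf

    def test_pairwise_equilibrium_matches_spectral_stationary(self, phys):
        rates = derive_rates(phys)
        sol = solve_kinetics(build_rate_matrix(rates))
        # eig on a generator spanning ten decades of rates carries ~1e-9
        # relative error; the analytic construction is the exact reference
        assert pairwise_equilibrium(rates) == pytest.approx(
            sol.stationary, rel=1e-6
        )


class TestCopyNumbers:
    def test_reconciled_partition(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        in_antenna, elsewhere = copy_number_partition(sol, 30000, 200)
        assert elsewhere <= 15.0
        assert in_antenna == pytest.approx(135, rel=0.02)

    def test_everything_elsewhere_when_unbound(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        sol.stationary = np.array([1.0, 0.0, 0.0, 0.0])
        in_antenna, elsewhere = copy_number_partition(sol, 1000, 10)
        assert in_antenna == 0.0
        assert elsewhere == pytest.approx(100.0)

    def test_zero_genes_rejected(self, phys):
        sol = solve_kinetics(build_rate_matrix(derive_rates(phys)))
        with pytest.raises(ValueError):
            copy_number_partition(sol, 1000, 0)


def moderate_antenna_matrix():
    """Antenna-topology generator with moderate rate separation.

    Same connectivity as the antenna model but rates within ~2 decades,
    so a jump simulation mixes across all four states.
    """
    rates = AntennaRates(
        k1=5.0, k1_rev=20.0, k2=50.0, k2_rev=10.0, k3=8.0, k3_rev=4.0,
        k_ds=2.0, k_sd=2.0 * (10.0 * 8.0) / (4.0 * 50.0) * 1.0,
    )
    # enforce exact detailed balance on the cycle for a clean reference
    k_sd = rates.k_ds * (rates.k2 / rates.k2_rev) * (rates.k3_rev / rates.k3)
    rates = AntennaRates(
        rates.k1, rates.k1_rev, rates.k2, rates.k2_rev, rates.k3,
        rates.k3_rev, rates.k_ds, k_sd,
    )
    return build_rate_matrix(rates)


def test_probability_conservation_over_ten_decades():
    mat = moderate_antenna_matrix()
    init = np.array([1.0, 0.0, 0.0, 0.0])
    times = np.logspace(-5, 5, 11)
    traj = propagate(mat, init, times)
    assert traj.sum(axis=1) == pytest.approx(np.ones(len(times)), abs=1e-9)
    assert traj[-1] == pytest.approx(solve_kinetics(mat).stationary, abs=1e-9)


def test_probability_conservation_stiff_reconciled_matrix(phys):
    # the reconciled generator spans ten decades of rates; expm in double
    # precision conserves probability to roundoff accumulation (~1e-8)
    mat = build_rate_matrix(derive_rates(phys))
    init = np.array([1.0, 0.0, 0.0, 0.0])
    times = np.logspace(-8, 2, 11)
    traj = propagate(mat, init, times)
    assert traj.sum(axis=1) == pytest.approx(np.ones(len(times)), abs=1e-6)
    assert np.all(traj >= -1e-9)


def test_gillespie_matches_spectral_stationary():
    mat = moderate_antenna_matrix()
    expected = solve_kinetics(mat).stationary
    mean, se = gillespie_stationary(mat, n_jumps=200_000, seed=12345)
    for i in range(4):
        assert abs(mean[i] - expected[i]) < 3 * se[i] + 1e-4
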