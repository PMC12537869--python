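"""Superoperator assembly: commutators, exchange, relaxation, thermalization."""

import numpy as np
import pytest

import liouvex as lx
from liouvex.constants import HBAR, KB
from liouvex.liouvillian import (commutator_superop, lindblad_thermalize,
                                 spin_exchange_superop, two_site_kex,
                                 _t1_superop, _t2_superop)
from liouvex.operators import parse_operator, spin_matrices, vec


class TestCommutatorSuperop:
    def test_zero(self):
        assert not commutator_superop(np.zeros((3, 3))).any()

    def test_sz_eigenoperator(self):
        """L vec(S+) = -i w vec(S+) for H = w Sz."""
        w = 2 * np.pi * 123.0
        sm = spin_matrices(0.5)
        L = commutator_superop(w * sm["z"])
        v = vec(sm["p"])
        assert np.allclose(L @ v, -1j * w * v)

    def test_antihermitian_for_hermitian_h(self):
        rng = np.random.default_rng(0)
        a = rng.standard_normal((4, 4)) + 1j * rng.standard_normal((4, 4))
        h = a + a.conj().T
        L = commutator_superop(h)
        assert np.allclose(L.conj().T, -L, atol=1e-12)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            commutator_superop(np.zeros((2, 3)))


class TestAssembly:
    def test_two_site_two_spin_is_32(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], powder="alpha0beta0")
        ex.add_interaction("dipole", (0, 1), delta=2e3, euler=[(0, 0, 0)])
        ex2 = ex.copy_with_new_orientation(0, [(0, 0.3, 0)])
        L = lx.Liouvillian([ex, ex2], kex=two_site_kex(1e-5))
        assert L.dim == 32
        assert L.L_at(0, 0.0).shape == (32, 32)

    def test_kex_validation(self):
        ex = lx.SpinSystem(9.4, ["13C"], powder="alpha0beta0")
        with pytest.raises(ValueError, match="sum to zero"):
            lx.Liouvillian([ex, ex.copy()], kex=np.array([[1.0, 0], [0, 1.0]]))
        with pytest.raises(ValueError, match="same spins"):
            lx.Liouvillian([ex, lx.SpinSystem(9.4, ["1H"],
                                              powder="alpha0beta0")])

    def test_exchange_conserves_population(self):
        ex = lx.SpinSystem(9.4, ["13C"], powder="alpha0beta0")
        L = lx.Liouvillian([ex, ex.copy()], kex=two_site_kex(1e-3, 0.3))
        lex = L.exchange_superop()
        ident = np.tile(vec(np.eye(2)), 2)
        assert np.allclose(ident @ lex, 0.0, atol=1e-12)

    def test_symmetric_exchange_equilibrates_sites(self):
        """Site populations relax to 1/2, 1/2 under symmetric kex."""
        ex = lx.SpinSystem(9.4, ["13C"], powder="alpha0beta0")
        L = lx.Liouvillian([ex, ex.copy()], kex=two_site_kex(1e-4))
        from scipy.linalg import expm
        rho = np.concatenate([vec(np.eye(2) / 2), np.zeros(4)])
        out = expm(L.L_at(0, 0.0) * 1e-2) @ rho
        assert out[0] + out[3] == pytest.approx(0.5, abs=1e-10)
        assert out[4] + out[7] == pytest.approx(0.5, abs=1e-10)


class TestSpinExchange:
    def test_identity_permutation_zero(self):
        ex = lx.SpinSystem(9.4, ["1H", "1H"], powder="alpha0beta0")
        assert not spin_exchange_superop(ex, [0, 1], 100.0).any()

    def test_cross_isotope_rejected(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], powder="alpha0beta0")
        with pytest.raises(ValueError, match="identical isotopes"):
            spin_exchange_superop(ex, [1, 0], 10.0)

    def test_two_spin_swap_rates(self):
        """<S1z - S2z> decays at 2k, <S1z + S2z> is conserved."""
        ex = lx.SpinSystem(9.4, ["1H", "1H"], powder="alpha0beta0")
        X = spin_exchange_superop(ex, [1, 0], 77.0)
        anti = vec(parse_operator("S0z", ex.isotopes, ex.spins)
                   - parse_operator("S1z", ex.isotopes, ex.spins))
        sym = vec(parse_operator("S0z", ex.isotopes, ex.spins)
                  + parse_operator("S1z", ex.isotopes, ex.spins))
        assert np.allclose(X @ anti, -2 * 77.0 * anti, atol=1e-10)
        assert np.allclose(X @ sym, 0.0, atol=1e-12)

    def test_three_site_cyclic_symmetric_invariant(self):
        """Methyl-like cyclic permutation leaves totally symmetric
        combinations untouched."""
        ex = lx.SpinSystem(9.4, ["1H"] * 3, powder="alpha0beta0")
        X = spin_exchange_superop(ex, [1, 2, 0], 55.0)
        tot = vec(sum(parse_operator(f"S{i}z", ex.isotopes, ex.spins)
                      for i in range(3)))
        assert np.allclose(X @ tot, 0.0, atol=1e-10)
        ident = vec(np.eye(8))
        assert np.allclose(ident @ X, 0.0, atol=1e-10)


class TestCartesianRelaxation:
    def test_t1_rate_on_sz(self, single_carbon):
        L1 = _t1_superop(single_carbon, 0, 1.0)
        v = vec(spin_matrices(0.5)["z"])
        assert np.allclose(L1 @ v, -v, atol=1e-12)

    def test_t1_pruning_leaves_coherences_undamped(self, single_carbon):
        L1 = _t1_superop(single_carbon, 0, 1.0)
        v = vec(spin_matrices(0.5)["p"])
        assert np.allclose(L1 @ v, 0.0, atol=1e-12)

    def test_t2_rates(self, single_carbon):
        L2 = _t2_superop(single_carbon, 0, 0.5)
        sm = spin_matrices(0.5)
        assert np.allclose(L2 @ vec(sm["p"]), -2.0 * vec(sm["p"]), atol=1e-12)
        assert np.allclose(L2 @ vec(sm["z"]), 0.0, atol=1e-12)
        assert np.allclose(L2 @ vec(sm["alpha"]), 0.0, atol=1e-12)

    def test_double_quantum_decays_at_squared_difference(self):
        """T2 on both of two like spins: DQ coherence rate = (1+1)^2/T2... the
        z-quantum difference squared, i.e. 4/T2 for S1+S2+."""
        ex = lx.SpinSystem(9.4, ["1H", "1H"], powder="alpha0beta0")
        T2 = 0.25
        L = _t2_superop(ex, 0, T2) + _t2_superop(ex, 1, T2)
        dq = vec(parse_operator("S0p", ex.isotopes, ex.spins)
                 @ parse_operator("S1p", ex.isotopes, ex.spins))
        # each spin's Lz^2 contributes 1/T2 on a +-1 coherence of that spin
        assert np.allclose(L @ dq, -(1 / T2 + 1 / T2) * dq, atol=1e-10)

    def test_t1_on_other_spin_leaves_uncoupled_spin(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], powder="alpha0beta0")
        L = lx.Liouvillian(ex)
        L.add_relax("T1", spin=0, value=0.01)
        rho = lx.DensityMatrix(L, "S1z", ["S1z"])
        tab = rho.det_prop(lx.Sequence(L, duration=0.05), n=5, reduce=False)
        # raw trace Tr(S1z^2) = 1 in the 2-spin space; constant in time
        assert np.allclose(np.real(tab["S1z"]), 1.0, atol=1e-10)

    def test_warning_without_t2(self, single_carbon):
        import warnings as _w
        L = lx.Liouvillian(single_carbon)
        with pytest.warns(UserWarning, match="without T2"):
            with _w.catch_warnings():
                _w.simplefilter("always")
                L.add_relax("T1", spin=0, value=1.0)

    def test_invalid_values(self, single_carbon):
        L = lx.Liouvillian(single_carbon)
        with pytest.raises(ValueError):
            L.add_relax("T2", spin=0, value=-1.0)
        with pytest.raises(ValueError):
            L.add_relax("T9", spin=0, value=1.0)


class TestEigenbasisRelaxation:
    def test_untilted_matches_cartesian(self):
        """Pure-Zeeman Hamiltonian: OS mode reproduces the Cartesian
        superoperators to 1e-10."""
        ex = lx.SpinSystem(9.4, ["13C"], vr=0, powder="alpha0beta0",
                           frames=["lab"])
        Lc = lx.Liouvillian(ex)
        Lc.add_relax("T1", spin=0, value=0.02)
        Lc.add_relax("T2", spin=0, value=0.01)
        Los = lx.Liouvillian(ex.copy())
        Los.add_relax("T1", spin=0, value=0.02, OS=True)
        Los.add_relax("T2", spin=0, value=0.01, OS=True)
        assert np.allclose(Lc.relax_superop(0), Los.relax_superop(0),
                           atol=1e-10)

    def test_tilted_electron_relaxes_along_quantization_axis(self):
        """With a g-tensor tilt, OS T1 drives exchange between the tilted
        eigenstates: the polarization along the tilted axis decays at 1/T1
        while the Cartesian implementation would mix T1 and T2."""
        ex = lx.SpinSystem(0.05, ["e-"], vr=0, powder="alpha0beta0",
                           frames=["lab"])
        # strong tilt: g anisotropy comparable to the Zeeman term
        ex.add_interaction("g", 0, delta=1.0, euler=[(0.0, np.pi / 3, 0.0)])
        L = lx.Liouvillian(ex)
        T1 = 1e-7
        L.add_relax("T1", spin=0, value=T1, OS=True)
        h = L.site_hamiltonian(0, 0, 0.0)
        _, V = np.linalg.eigh(h)
        pol = V @ np.diag([0.5, -0.5]) @ V.conj().T  # tilted-axis "Sz"
        R = L.relax_superop(0)
        assert np.allclose(R @ vec(pol), -vec(pol) / T1, atol=1e-3 / T1)


class TestLindblad:
    def test_zero_frequency_no_asymmetry(self, single_carbon):
        base = _t1_superop(single_carbon, 0, 1.0)
        na = lindblad_thermalize(base, np.zeros((2, 2)), 298.0)
        assert not np.abs(na).max() > 1e-20

    def test_asymmetry_factor_one_third(self):
        """With beta*omega = ln 2 the non-adiabatic part is 1/3 of the
        adiabatic rate."""
        ex = lx.SpinSystem(9.4, ["1H"], powder="alpha0beta0")
        base = _t1_superop(ex, 0, 1.0)
        w0 = 1e9  # rad/s, set T so that beta*w0 = ln 2
        T = HBAR * w0 / (KB * np.log(2))
        h = w0 * spin_matrices(0.5)["z"]
        na = lindblad_thermalize(base, h, T)
        assert abs(na[0, 3]) / abs(base[0, 3]) == pytest.approx(1 / 3,
                                                                rel=1e-10)

    def test_detailed_balance_exact(self):
        ex = lx.SpinSystem(9.4, ["1H"], T=298.0, powder="alpha0beta0")
        L = lx.Liouvillian(ex)
        L.add_relax("T1", spin=0, value=1e-3)
        L.add_relax("Thermal")
        W = L.relax_superop(0)
        h = L.site_lab_hamiltonian(0, 0, 0.0)
        beta = HBAR / (KB * 298.0)
        w_sr = (h[1, 1] - h[0, 0]).real  # beta state minus alpha state
        assert (W[3, 0] / W[0, 3]).real == pytest.approx(
            np.exp(-beta * w_sr), rel=1e-12)

    def test_thermalized_steady_state_matches_equilibrium(self):
        """Random 1- and 2-spin systems reach rho_eq within 1e-6."""
        rng = np.random.default_rng(5)
        for isotopes in (["1H"], ["1H", "13C"]):
            ex = lx.SpinSystem(9.4, isotopes, T=40.0, powder="alpha0beta0")
            if len(isotopes) == 2:
                ex.add_interaction("j", (0, 1), iso=rng.uniform(10, 50))
            L = lx.Liouvillian(ex)
            for i in range(len(isotopes)):
                L.add_relax("T1", spin=i, value=1e-3)
                L.add_relax("T2", spin=i, value=1e-3)
            L.add_relax("Thermal")
            rho = lx.DensityMatrix(L, np.eye(ex.dim_H) / ex.dim_H, ["S0z"])
            rho.prop(L.U(duration=1e-3) ** np.inf)
            eq = ex.equilibrium_reference()
            assert np.abs(rho.states[0] - eq.rho_vec).max() < 1e-6


class TestDynamicThermalization:
    def _two_site(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], powder="alpha0beta0")
        ex.add_interaction("dipole", (0, 1), delta=2e3, euler=[(0, 0, 0)])
        ex2 = ex.copy_with_new_orientation(0, [(0, 0.3, 0)])
        L = lx.Liouvillian([ex, ex2], kex=two_site_kex(1e-5))
        L.add_relax("DynamicThermal")
        return L

    def test_identity_column_indices(self):
        L = self._two_site()
        assert list(L.identity_columns()) == [0, 5, 10, 15, 16, 21, 26, 31]

    def test_correction_only_in_identity_columns(self):
        L = self._two_site()
        s = L.state_scale
        bare = L._bare(0, 0.0) * (s[:, None] / s[None, :])
        diff = np.abs(L.L_at(0, 0.0) - bare)
        cols = np.unique(np.nonzero(diff > 1e-25)[1])
        assert set(cols) <= set(L.identity_columns())

    def test_equilibrium_is_stationary(self):
        L = self._two_site()
        rr = L.rho_eq(0) * L.state_scale
        res = np.linalg.norm(L.L_at(0, 0.0) @ rr)
        assert res < 1e-10 * np.linalg.norm(L.L_at(0, 0.0))

    def test_modes_exclusive(self):
        L = self._two_site()
        with pytest.raises(ValueError, match="already set"):
            L.add_relax("Thermal")
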