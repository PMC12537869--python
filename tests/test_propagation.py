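"""Propagator construction, eigenbasis powers, caching, basis reduction."""

import warnings

import numpy as np
import pytest

import liouvex as lx
from liouvex.defaults import Defaults
from liouvex.operators import vec
from liouvex.propagation import eigen_cleanup_values, reduce_basis


class TestPropagatorBasics:
    def test_short_duration_near_identity(self, single_carbon):
        L = lx.Liouvillian(single_carbon)
        U = L.U(duration=1e-15)
        assert np.allclose(U.matrices[0], np.eye(4), atol=1e-10)

    def test_precession_phase_convention(self, single_carbon):
        single_carbon.add_interaction("cs", 0, iso=250.0)
        L = lx.Liouvillian(single_carbon)
        rho = lx.DensityMatrix(L, "S0x", ["S0p"])
        t = 1.3e-3
        rho.prop(L.U(duration=t))
        want = 0.5 * np.exp(-2j * np.pi * 250.0 * t)
        assert rho.detect_now()[0] == pytest.approx(want, abs=1e-10)

    def test_pi_pulse_inversion(self, single_carbon):
        L = lx.Liouvillian(single_carbon)
        tau = 2e-5
        seq = lx.Sequence(L, duration=tau).add_channel("13C",
                                                       amplitude=1 / (2 * tau))
        rho = lx.DensityMatrix(L, "S0z", ["S0z"])
        rho.prop(seq)
        assert rho.detect_now()[0].real == pytest.approx(-0.5, abs=1e-10)

    def test_lazy_then_sticky(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        U = L.U()
        assert not U.computed
        m1 = U.matrices
        assert U.computed
        assert U.matrices is m1

    def test_trace_conservation_coherent(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        ident = vec(np.eye(L.dim_H))
        out = ident @ L.U().matrices[0]
        assert np.allclose(out, ident, atol=1e-12)


class TestPowers:
    def test_power_one_is_exact(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        U = L.U()
        assert np.allclose((U ** 1).matrices[0], U.matrices[0], atol=1e-10)

    def test_power_matches_repeated_composition(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        U = L.U()
        M = np.eye(L.dim, dtype=complex)
        for _ in range(64):
            M = U.matrices[0] @ M
        assert np.abs((U ** 64).matrices[0] - M).max() < 1e-10

    def test_power_requires_integer_rotor_periods(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        U = L.U(duration=0.4 * L.rotor_period)
        with pytest.raises(ValueError, match="integer"):
            U ** 2

    def test_power_inf_projects_on_equilibrium(self):
        ex = lx.SpinSystem(9.4, ["1H"], T=200.0, powder="alpha0beta0")
        L = lx.Liouvillian(ex)
        L.add_relax("T1", spin=0, value=1e-3)
        L.add_relax("T2", spin=0, value=1e-3)
        L.add_relax("Thermal")
        Uinf = L.U(duration=1e-3) ** np.inf
        eq = ex.equilibrium_reference().rho_vec
        for seed in range(3):
            rng = np.random.default_rng(seed)
            a = rng.standard_normal((2, 2)) + 1j * rng.standard_normal((2, 2))
            rho = a @ a.conj().T
            rho /= np.trace(rho).real
            out = Uinf.matrices[0] @ vec(rho)
            assert np.abs(out - eq).max() < 1e-8

    def test_compose_timing_warning(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        U1 = L.U()
        U2 = L.U(duration=0.5 * L.rotor_period)
        with pytest.warns(UserWarning, match="timing"):
            U2 * U2  # second factor ends mid-period where first expects 0


class TestEigenCleanup:
    def test_unit_circle_reset(self):
        w = np.array([1.0 + 1e-14, 0.5, 1.2j])
        out = eigen_cleanup_values(w, thermalized=False)
        assert np.all(np.abs(out) <= 1.0 + 1e-15)

    def test_thermalized_pins_exactly_one(self):
        w = np.array([0.999999, 0.5 + 0.1j, -0.3])
        out = eigen_cleanup_values(w, thermalized=True)
        assert np.sum(out == 1.0) == 1

    def test_unitary_untouched(self):
        w = np.exp(1j * np.linspace(0, 2, 5))
        w = w / np.abs(w)
        out = eigen_cleanup_values(w, thermalized=False)
        assert np.allclose(out, w, atol=0, rtol=0)


class TestCache:
    def test_gamma_recycling_matches_direct(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=10e3, n_gamma=30,
                           powder="rep10")
        ex.add_interaction("dipole", (0, 1), delta=44e3)
        L = lx.Liouvillian(ex)
        U = L.U()
        U.matrices
        assert L.prop_cache.misses == 10 * 30  # unique (base, shifted-step)
        assert L.prop_cache.hits == 10 * 30 * 29
        Defaults["cache"] = False
        try:
            L2 = lx.Liouvillian(ex)
            U2 = L2.U()
            err = max(np.abs(a - b).max()
                      for a, b in zip(U.matrices, U2.matrices))
        finally:
            Defaults["cache"] = True
        assert err < 1e-12

    def test_different_rf_amplitude_not_recycled(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=10e3, n_gamma=6,
                           powder="alpha0beta45")
        ex.add_interaction("dipole", (0, 1), delta=44e3)
        L = lx.Liouvillian(ex)
        s1 = lx.Sequence(L).add_channel("13C", amplitude=10e3)
        s2 = lx.Sequence(L).add_channel("13C", amplitude=20e3)
        lx.Propagator(L, 0.0, s1).matrices
        m0 = L.prop_cache.misses
        lx.Propagator(L, 0.0, s2).matrices
        assert L.prop_cache.misses == m0 + 6  # all recomputed


class TestBasisReduction:
    def _r1rho_setup(self):
        ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=10e3, n_gamma=6,
                           powder="alpha0beta45")
        ex.add_interaction("dipole", (0, 1), delta=44e3, euler=[(0, 0, 0)])
        ex2 = ex.copy_with_new_orientation(0, [(0, np.radians(15), 0)])
        L = lx.Liouvillian([ex, ex2], kex=lx.two_site_kex(1e-6))
        seq = lx.Sequence(L).add_channel("13C", amplitude=50e3)
        return L, seq

    def test_r1rho_retains_16_of_32(self):
        L, seq = self._r1rho_setup()
        rho = lx.DensityMatrix(L, "13Cx", ["13Cp"])
        rmap = rho.reduced_setup(sequences=[seq])
        assert (rmap.dim_full, rmap.dim) == (32, 16)

    def test_reduced_equals_full_detection(self):
        L, seq = self._r1rho_setup()
        r_red = lx.DensityMatrix(L, "13Cx", ["13Cp"])
        t_red = r_red.det_prop(seq, n=20, reduce=True)
        L2, seq2 = self._r1rho_setup()
        r_full = lx.DensityMatrix(L2, "13Cx", ["13Cp"])
        t_full = r_full.det_prop(seq2, n=20, reduce=False)
        assert np.abs(t_red["13Cp"] - t_full["13Cp"]).max() < 1e-10

    def test_randomized_reduced_vs_full(self):
        """Random shift/dipole systems: reduction never changes signals."""
        rng = np.random.default_rng(42)
        for _ in range(6):
            ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=0,
                               powder="alpha0beta0")
            ex.add_interaction("cs", 1, iso=rng.uniform(-500, 500))
            ex.add_interaction("dipole", (0, 1), delta=rng.uniform(1e3, 5e3),
                               euler=[tuple(rng.uniform(0, np.pi, 3))])
            L = lx.Liouvillian(ex)
            seq = lx.Sequence(L, duration=1e-4).add_channel(
                "13C", amplitude=rng.uniform(1e3, 1e4))
            a = lx.DensityMatrix(L, "13Cx", ["13Cp"]).det_prop(
                seq, n=10, reduce=True)
            b = lx.DensityMatrix(L, "13Cx", ["13Cp"]).det_prop(
                seq, n=10, reduce=False)
            assert np.abs(a["13Cp"] - b["13Cp"]).max() < 1e-10

    def test_shift_only_retains_one_per_site(self, single_carbon):
        single_carbon.add_interaction("cs", 0, iso=100.0)
        L = lx.Liouvillian(single_carbon)
        rmap = reduce_basis(L, vec(np.array([[0, 1], [0, 0.0]])).astype(complex),
                            [vec(np.array([[0, 1], [0, 0.0]])).astype(complex)])
        assert rmap.dim == 1

    def test_disconnected_raises(self, single_carbon):
        single_carbon.add_interaction("cs", 0, iso=100.0)
        L = lx.Liouvillian(single_carbon)
        from liouvex.operators import spin_matrices
        with pytest.raises(ValueError, match="disconnected"):
            reduce_basis(L, vec(spin_matrices(0.5)["p"]),
                         [vec(spin_matrices(0.5)["z"])])

    def test_identity_detector_keeps_everything(self, hc_pair_mas):
        L = lx.Liouvillian(hc_pair_mas)
        ident = vec(np.eye(L.dim_H)).astype(complex) + 1.0
        rmap = reduce_basis(L, ident, [ident])
        assert rmap.dim == L.dim


class TestDiscretization:
    def test_halving_step_shrinks_error_quadratically(self):
        """Doubling n_gamma reduces the MAS signal change ~4x (midpoint
        rule is second order)."""
        def run(ng):
            ex = lx.SpinSystem(9.4, ["1H", "13C"], vr=10e3, n_gamma=ng,
                               powder="alpha0beta45")
            ex.add_interaction("dipole", (0, 1), delta=44e3,
                               euler=[(0, 0.5, 0)])
            L = lx.Liouvillian(ex)
            seq = lx.Sequence(L).add_channel("13C", amplitude=50e3)
            return lx.DensityMatrix(L, "13Cx", ["13Cp"]).det_prop(
                seq, n=12, reduce=False)["13Cp"]
        s10, s20, s80 = run(10), run(20), run(80)
        e1 = np.abs(s10 - s80).max()
        e2 = np.abs(s20 - s80).max()
        assert e1 / e2 > 3.0
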