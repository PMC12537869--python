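"""Multi-site Liouvillians: coherent + exchange + relaxation terms.

The total generator is L = L_coh + L_ex + L_relax. Density matrices are
column-stacked; the coherent part of each site is

    L = -i (H (x) 1 - 1 (x) H^T),

sites occupy consecutive diagonal blocks, and an N x N exchange matrix
(columns summing to zero) couples corresponding states of the site
replicas through kex (x) I.

Relaxation is phenomenological: T1 as a one-spin random-field
implementation (with the implicit T2 pruned away), T2 as the squared
z-commutator, both optionally re-expressed in the eigenbasis of the
Hamiltonian ("OS" mode) for tilted/mixed systems. Thermalization either
follows the Lindblad detailed-balance construction (forward/backward
rates ratio exp(-beta_theta w_sr)) or the "dynamic" scheme that inserts
L.rho_eq into the identity-aligned columns of the Liouvillian.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.linalg import expm

from .constants import HBAR, KB
from .operators import spin_op, vec
from .hamiltonian import rotating_components, rf_hamiltonian
from .spin_system import SpinSystem

TWO_PI = 2.0 * np.pi

__all__ = [
    "commutator_superop", "left_right_superop", "spin_exchange_superop",
    "lindblad_thermalize", "two_site_kex", "validate_kex", "Liouvillian",
]


def commutator_superop(H: np.ndarray) -> np.ndarray:
    """L = -i (H (x) 1 - 1 (x) H^T) acting on column-stacked rho."""
    H = np.asarray(H)
    if H.ndim != 2 or H.shape[0] != H.shape[1]:
        raise ValueError("H must be square")
    d = H.shape[0]
    eye = np.eye(d)
    return -1j * (np.kron(eye, H) - np.kron(H.T, eye))


def left_right_superop(op: np.ndarray) -> np.ndarray:
    """Commutator superoperator without the -i: op (x) 1 - 1 (x) op^T."""
    d = op.shape[0]
    eye = np.eye(d)
    return np.kron(eye, op) - np.kron(op.T, eye)


def _t1_superop(system: SpinSystem, spin: int, T1: float,
                prune: bool = True) -> np.ndarray:
    """Random-field T1 superoperator for one spin, optionally pruned.

    Pruning removes diagonal damping terms with no off-diagonal partner
    (the implicit T2 that comes along with T1).
    """
    lp = left_right_superop(spin_op("p", spin, system.spins))
    lm = left_right_superop(spin_op("m", spin, system.spins))
    L = -(lp @ lm + lm @ lp) / (4.0 * T1)
    if prune:
        off = np.abs(L - np.diag(np.diag(L))) > 1e-14 * max(1.0, np.abs(L).max())
        partner = off.any(axis=0) | off.any(axis=1)
        keep = np.where(partner, np.diag(L), 0.0)
        L = L - np.diag(np.diag(L)) + np.diag(keep)
    return L


def _t2_superop(system: SpinSystem, spin: int, T2: float) -> np.ndarray:
    """xy-plane T2: minus the squared z-commutator (coherences decay)."""
    lz = left_right_superop(spin_op("z", spin, system.spins))
    return -(lz @ lz) / T2


def _eig_transform(V: np.ndarray):
    """Superoperator transforms to/from the Hamiltonian eigenbasis.

    T vec(rho) = vec(V^dag rho V); returns (T, T^-1).
    """
    return np.kron(V.T, V.conj().T), np.kron(V.conj(), V)


def _expected_transitions(system: SpinSystem, spin: int) -> int:
    """Ordered count of single-quantum T1 transitions of one spin."""
    s = system.spins[spin]
    d_other = system.dim_H // int(round(2 * s + 1))
    return int(round(2 * 2 * s * d_other))


def _os_t1(system: SpinSystem, spin: int, T1: float, V: np.ndarray) -> np.ndarray:
    """T1 as exchange between Hamiltonian eigenstates (Eq.-style "OS" mode)."""
    if system.spins[spin] > 1:
        warnings.warn("eigenbasis T1 is not recommended for spins with S > 1")
    T, Ti = _eig_transform(V)
    base = T @ _t1_superop(system, spin, T1, prune=False) @ Ti
    m = _expected_transitions(system, spin)
    off = base.copy()
    np.fill_diagonal(off, 0.0)
    mags = np.abs(off).ravel()
    order = np.argsort(mags)[::-1]
    if mags[order[m - 1]] < 1e-12:
        raise ValueError("could not identify T1 transitions in the eigenbasis")
    if m < mags.size and np.isclose(mags[order[m - 1]], mags[order[m]],
                                    rtol=1e-9, atol=0.0) and \
            mags[order[m]] > 1e-12 * mags[order[0]]:
        # tie across the selection boundary: take all tied elements, which
        # keeps the superoperator population conserving for symmetric cases
        thresh = mags[order[m - 1]] * (1 - 1e-9)
        sel = np.flatnonzero(mags >= thresh)
    else:
        sel = order[:m]
    d2 = base.shape[0]
    out = np.zeros_like(base)
    rate = 1.0 / (2.0 * T1)
    for flat in sel:
        r, s = divmod(int(flat), d2)
        ph = off[r, s] / abs(off[r, s])
        out[r, s] += rate * ph
        out[s, s] -= rate
    return Ti @ out @ T


def _os_t2(system: SpinSystem, spin: int, T2: float, V: np.ndarray) -> np.ndarray:
    """T2 destroying coherences between eigenstates only."""
    T, Ti = _eig_transform(V)
    tot = np.zeros((system.dim_H ** 2,) * 2, dtype=complex)
    for ax in "xyz":
        lq = left_right_superop(spin_op(ax, spin, system.spins))
        tot += lq @ lq
    m = T @ tot @ Ti
    d = system.dim_H
    vals = np.diag(m).copy()
    vals[np.arange(d) * (d + 1)] = 0.0  # discard T1 (population) diagonals
    return Ti @ np.diag(-vals / (2.0 * T2)) @ T


def lindblad_thermalize(L_relax: np.ndarray, H: np.ndarray, T: float,
                        V: np.ndarray | None = None) -> np.ndarray:
    """Non-adiabatic (antisymmetric) thermalizing addition to ``L_relax``.

    Off-diagonal elements of the result satisfy detailed balance,
    W_{r->s} / W_{s->r} = exp(-beta_theta * w_sr) with
    beta_theta = hbar/(kB T) and w_s the mean of the two Hamiltonian
    diagonal elements (eigenvalues if ``V`` is given) behind Liouville
    index s. Diagonals conserve population; for complex adiabatic
    elements the off-diagonal additions retain the phase while diagonals
    use the absolute value with the sign of (1 - exp(-beta w)).
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    d = H.shape[0]
    if V is not None:
        hdiag = np.real(np.diag(V.conj().T @ H @ V))
    else:
        hdiag = np.real(np.diag(H))
    p_idx, q_idx = np.meshgrid(np.arange(d), np.arange(d), indexing="ij")
    omega = 0.5 * (hdiag[p_idx] + hdiag[q_idx]).reshape(-1, order="F")
    beta = HBAR / (KB * T)
    na = np.zeros_like(L_relax)
    rows, cols = np.nonzero(np.abs(L_relax) > 1e-30)
    for r, s in zip(rows, cols):
        if r == s:
            continue
        # L[r, s] = W_{s->r}^{ad}; detailed balance fixes the na part
        w_rs = omega[r] - omega[s]
        x = beta * w_rs
        fac = -(1.0 - np.exp(-x)) / (1.0 + np.exp(-x))
        ad = L_relax[r, s]
        w_na = ad * fac  # phase retained
        na[r, s] += w_na
        na[s, s] -= abs(w_na) * np.sign(fac) if fac != 0 else 0.0
    return na


def spin_exchange_superop(system: SpinSystem, permutation, k: float) -> np.ndarray:
    """Exchange that swaps spin states within one replica at rate ``k``.

    ``permutation`` maps old spin position -> new spin position; it must
    map identical isotopes onto each other. The superoperator is
    k (P (x) P - 1) with P the Hilbert-space permutation operator.
    """
    perm = list(permutation)
    n = system.nspins
    if sorted(perm) != list(range(n)):
        raise ValueError("not a permutation of the spins")
    for i, j in enumerate(perm):
        if system.isotopes[i] != system.isotopes[j]:
            raise ValueError("permutation must map identical isotopes")
    dims = system.dims
    d = system.dim_H
    P = np.zeros((d, d))
    for idx in range(d):
        # decode mixed-radix state, permute spin states, re-encode
        rem, states = idx, [0] * n
        for i in range(n - 1, -1, -1):
            states[i] = rem % dims[i]
            rem //= dims[i]
        new_states = [states[perm[i]] for i in range(n)]
        new = 0
        for i in range(n):
            new = new * dims[i] + new_states[i]
        P[new, idx] = 1.0
    return k * (np.kron(P, P) - np.eye(d * d))


def validate_kex(kex: np.ndarray) -> np.ndarray:
    kex = np.asarray(kex, dtype=float)
    if kex.ndim != 2 or kex.shape[0] != kex.shape[1]:
        raise ValueError("exchange matrix must be square")
    off = kex - np.diag(np.diag(kex))
    if np.any(off < -1e-12):
        raise ValueError("off-diagonal exchange rates must be nonnegative")
    colsum = kex.sum(axis=0)
    if np.abs(colsum).max() > 1e-8 * max(1.0, np.abs(kex).max()):
        raise ValueError("exchange matrix columns must sum to zero")
    return kex


def two_site_kex(tauc: float, p1: float = 0.5) -> np.ndarray:
    """Two-site exchange with correlation time tauc and population p1."""
    if tauc <= 0 or not 0 < p1 < 1:
        raise ValueError("need tauc > 0 and 0 < p1 < 1")
    k1 = (1 - p1) / tauc  # site0 -> site1
    k2 = p1 / tauc
    return np.array([[-k1, k2], [k1, -k2]])


def _stationary(kex: np.ndarray) -> np.ndarray:
    n = kex.shape[0]
    if not kex.any():
        return np.full(n, 1.0 / n)
    w, v = np.linalg.eig(kex)
    i = int(np.argmin(np.abs(w)))
    p = np.real(v[:, i])
    p = np.abs(p)
    return p / p.sum()


class Liouvillian:
    """Total superoperator bundle for N spin systems in exchange."""

    def __init__(self, sites, kex=None):
        if isinstance(sites, SpinSystem):
            sites = [sites]
        self.sites: list[SpinSystem] = list(sites)
        ref = self.sites[0]
        for s in self.sites[1:]:
            if s.isotopes != ref.isotopes or s.dims != ref.dims:
                raise ValueError("all exchange sites must share the same spins")
        self.N = len(self.sites)
        if kex is None:
            kex = np.zeros((self.N, self.N))
        self.kex = validate_kex(kex)
        if self.kex.shape[0] != self.N:
            raise ValueError("exchange matrix size must match the site count")
        self.expsys = ref
        (self.alpha, self.beta, self.gamma, self.weight,
         self.orient_base, self.gamma_idx) = ref.powder.orientations(ref.n_gamma)
        self.n_orient = self.alpha.size
        self.relax_specs: list[dict] = []
        self.thermal: str | None = None
        self.spin_exchange_terms: list[np.ndarray] = []
        self._rc = {}       # (site, orient) -> RotatingHamiltonian
        self._relax_cache = {}
        self._rho_eq_cache = {}
        self._dyn_scale = None
        self.prop_cache = None  # installed by propagation

    # -- dimensions --------------------------------------------------------
    @property
    def dim_H(self) -> int:
        return self.expsys.dim_H

    @property
    def dim_site(self) -> int:
        return self.dim_H ** 2

    @property
    def dim(self) -> int:
        return self.N * self.dim_site

    @property
    def rotor_period(self) -> float:
        return 1.0 / self.expsys.vr if self.expsys.vr else np.inf

    @property
    def static(self) -> bool:
        return self.expsys.vr == 0.0

    def identity_columns(self) -> np.ndarray:
        """Column indices aligned with the identity components of vec(rho)."""
        d = self.dim_H
        one = np.arange(d) * (d + 1)
        return np.concatenate([one + i * self.dim_site for i in range(self.N)])

    def __repr__(self):
        return (f"Liouvillian({self.N} site(s), dim {self.dim}, "
                f"thermal={self.thermal!r}, "
                f"{len(self.relax_specs)} relaxation term(s))")

    # -- configuration -----------------------------------------------------
    def add_relax(self, kind: str, spin: int | None = None,
                  value: float | None = None, OS: bool = False) -> "Liouvillian":
        """Add T1/T2 relaxation or select a thermalization mode.

        ``kind`` is "T1", "T2" (with ``spin`` and ``value`` in seconds;
        ``OS=True`` moves the term into the Hamiltonian eigenbasis),
        "Thermal" (Lindblad) or "DynamicThermal".
        """
        kind_l = kind.lower()
        if kind_l == "dynamicthermal":
            if self.thermal == "lindblad":
                raise ValueError("thermalization mode already set to lindblad")
            self.thermal = "dynamic"
            return self
        if kind_l == "thermal":
            if self.thermal == "dynamic":
                raise ValueError("thermalization mode already set to dynamic")
            self.thermal = "lindblad"
            return self
        if kind_l not in ("t1", "t2"):
            raise ValueError(f"unknown relaxation kind {kind!r}")
        if value is None or value <= 0:
            raise ValueError(f"{kind} requires a positive time constant")
        if spin is None or not 0 <= spin < self.expsys.nspins:
            raise ValueError("valid spin index required")
        if kind_l == "t1" and not any(
                s["kind"] == "t2" and s["spin"] == spin for s in self.relax_specs):
            warnings.warn(f"T1 added on spin {spin} without T2; transverse "
                          "relaxation will be absent for that spin")
        self.relax_specs.append({"kind": kind_l, "spin": spin,
                                 "value": float(value), "OS": bool(OS)})
        self._relax_cache.clear()
        return self

    def add_spin_exchange(self, permutation, k: float) -> "Liouvillian":
        """Spin exchange (state swap) within each replica at rate ``k``."""
        self.spin_exchange_terms.append(
            spin_exchange_superop(self.expsys, permutation, k))
        return self

    # -- pieces ------------------------------------------------------------
    def _components(self, isite: int, io: int):
        key = (isite, io)
        if key not in self._rc:
            orient = (self.alpha[io], self.beta[io], self.gamma[io])
            self._rc[key] = rotating_components(self.sites[isite], orient)
        return self._rc[key]

    def site_hamiltonian(self, isite: int, io: int, t: float) -> np.ndarray:
        return self._components(isite, io).at(t)

    def site_lab_hamiltonian(self, isite: int, io: int, t: float) -> np.ndarray:
        """Working Hamiltonian plus re-added Zeeman of rotating-frame spins."""
        sys_ = self.sites[isite]
        h = self.site_hamiltonian(isite, io, t)
        for i, frame in enumerate(sys_.frames):
            if frame == "rotating":
                h = h + sys_.larmor[i] * spin_op("z", i, sys_.spins)
        return h

    def coherent(self, io: int, t: float) -> np.ndarray:
        """Block-diagonal coherent Liouvillian at time t for orientation io."""
        blocks = []
        n = np.arange(-2, 3)
        for isite in range(self.N):
            rc = self._components(isite, io)
            ph = np.exp(-1j * n * rc.omega_r * t)
            h = sum(c * hn for c, hn in zip(ph, rc.Hn))
            blocks.append(commutator_superop(h))
        return _blockdiag(blocks)

    def exchange_superop(self) -> np.ndarray:
        L = np.kron(self.kex, np.eye(self.dim_site)).astype(complex)
        for term in self.spin_exchange_terms:
            L += _blockdiag([term] * self.N)
        return L

    def _phase_key(self, t: float):
        if self.static:
            return 0
        frac = (t % self.rotor_period) / self.rotor_period
        return int(round(frac * 2 * self.expsys.n_gamma)) % (2 * self.expsys.n_gamma)

    def relax_superop(self, io: int, t: float = 0.0) -> np.ndarray:
        """Relaxation (+ Lindblad thermalization) superoperator at (io, t)."""
        key = (io, self._phase_key(t))
        if key in self._relax_cache:
            return self._relax_cache[key]
        blocks = []
        for isite in range(self.N):
            sys_ = self.sites[isite]
            base = np.zeros((self.dim_site, self.dim_site), dtype=complex)
            needs_eig = any(s["OS"] for s in self.relax_specs)
            V = None
            if needs_eig:
                h_work = self.site_hamiltonian(isite, io, t)
                _, V = np.linalg.eigh((h_work + h_work.conj().T) / 2)
            for spec in self.relax_specs:
                if spec["kind"] == "t1":
                    base += (_os_t1(sys_, spec["spin"], spec["value"], V)
                             if spec["OS"] else
                             _t1_superop(sys_, spec["spin"], spec["value"]))
                else:
                    base += (_os_t2(sys_, spec["spin"], spec["value"], V)
                             if spec["OS"] else
                             _t2_superop(sys_, spec["spin"], spec["value"]))
            if self.thermal == "lindblad" and self.relax_specs:
                h_lab = self.site_lab_hamiltonian(isite, io, t)
                if V is not None:
                    base += lindblad_thermalize(base, h_lab, sys_.T, V=V)
                else:
                    base += lindblad_thermalize(base, h_lab, sys_.T)
            blocks.append(base)
        out = _blockdiag(blocks)
        from .defaults import Defaults
        if Defaults["cache"]:
            self._relax_cache[key] = out
        return out

    # -- thermal equilibrium ----------------------------------------------
    def rho_eq(self, io: int = 0, t: float = 0.0) -> np.ndarray:
        """Vectorized thermal state over all sites (total trace 1)."""
        key = (io, self._phase_key(t))
        if key in self._rho_eq_cache:
            return self._rho_eq_cache[key]
        p = _stationary(self.kex)
        parts = []
        for isite in range(self.N):
            h = self.site_lab_hamiltonian(isite, io, t)
            beta = HBAR / (KB * self.sites[isite].T)
            rho = expm(-beta * h)
            rho /= np.trace(rho).real
            parts.append(p[isite] * vec(rho))
        out = np.concatenate(parts)
        self._rho_eq_cache[key] = out
        return out

    # -- assembly ----------------------------------------------------------
    def _dynamic_correction(self, L: np.ndarray, io: int, t: float) -> np.ndarray:
        v = L @ self.rho_eq(io, t)
        C = np.zeros_like(L)
        C[:, self.identity_columns()] = -v[:, None]
        return C

    @property
    def state_scale(self) -> np.ndarray | None:
        """Similarity-transform vector for dynamic-thermalization stability.

        Identity components of the working state vector are scaled down by
        f while the correction columns scale up by f; detection undoes it.
        """
        if self.thermal != "dynamic":
            return None
        if self._dyn_scale is None:
            L = self._bare(0, 0.0)
            v = L @ self.rho_eq(0, 0.0)
            nv = np.linalg.norm(v)
            f = 1.0 if nv == 0 else float(
                np.clip(np.linalg.norm(L) / (nv * np.sqrt(L.shape[0])), 1.0, 1e12))
            s = np.ones(self.dim)
            s[self.identity_columns()] = 1.0 / f
            self._dyn_scale = s
        return self._dyn_scale

    def _bare(self, io: int, t: float, L_rf: np.ndarray | None = None) -> np.ndarray:
        L = self.coherent(io, t) + self.exchange_superop()
        if self.relax_specs:
            L = L + self.relax_superop(io, t)
        if L_rf is not None:
            L = L + L_rf
        return L

    def L_at(self, io: int, t: float, L_rf: np.ndarray | None = None) -> np.ndarray:
        """Full (thermalized, scaled) Liouvillian at orientation io, time t."""
        L = self._bare(io, t, L_rf)
        if self.thermal == "dynamic":
            L = L + self._dynamic_correction(self._bare(io, t), io, t)
            s = self.state_scale
            L = L * (s[:, None] / s[None, :])
        return L

    def rf_superop(self, fields: dict, steps_per_cycle: int = 2):
        """Commutator superoperator of the RF Hamiltonian + lab-frame plans."""
        H, plans = rf_hamiltonian(self.expsys, fields, steps_per_cycle)
        return _blockdiag([commutator_superop(H)] * self.N), plans

    # -- conveniences ------------------------------------------------------
    def sequence(self, duration: float | None = None):
        from .propagation import Sequence
        return Sequence(self, duration)

    def U(self, duration: float | None = None, t0: float = 0.0, sequence=None):
        from .propagation import Propagator, Sequence
        if sequence is None:
            sequence = Sequence(self, duration)
        elif duration is not None:
            raise ValueError("give either a duration or a sequence")
        return Propagator(self, t0, sequence)

    def rho(self, rho0, detect, thermal: bool = False):
        from .density_state import DensityMatrix
        return DensityMatrix(self, rho0, detect, thermal=thermal)


def _blockdiag(blocks) -> np.ndarray:
    n = sum(b.shape[0] for b in blocks)
    out = np.zeros((n, n), dtype=complex)
    at = 0
    for b in blocks:
        out[at:at + b.shape[0], at:at + b.shape[0]] = b
        at += b.shape[0]
    return out
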