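"""Experimental spin systems: conditions, spins, interactions, frames.

A :class:`SpinSystem` holds everything orientation-independent about one
exchange site: the static field, isotopes, interactions (with their PAS
tensors and Euler angles), rotor settings, temperature and the per-spin
rotating/lab frame choice. Several systems differing in one or more
interactions are later coupled by an exchange matrix.

Frequencies are entered in Hz and converted to rad/s at the Hamiltonian
boundary; angles are radians throughout the API.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field

import numpy as np

from .constants import HBAR, KB, MU_B, isotope
from .operators import spin_matrices, spin_op, vec
from .powder import PowderAverage, load_powder

MAGIC_ANGLE = np.arccos(1.0 / np.sqrt(3.0))

_SPIN_FIELD = {"cs", "csa", "g", "quadrupole"}
_SPIN_SPIN = {"dipole", "j", "hyperfine"}


@dataclass
class Interaction:
    """One interaction term.

    delta/iso are in Hz, except for kind "g" where they are unitless
    g-anisotropy / isotropic g-shift relative to the free electron.
    ``euler`` is an ordered list of (alpha, beta, gamma) triples in
    radians, applied in sequence (PAS -> molecular frame).
    """

    kind: str
    spins: tuple
    delta: float = 0.0
    eta: float = 0.0
    euler: list = field(default_factory=list)
    iso: float = 0.0

    def __post_init__(self):
        if self.kind not in _SPIN_FIELD | _SPIN_SPIN:
            raise ValueError(f"unknown interaction kind {self.kind!r}")
        want = 1 if self.kind in _SPIN_FIELD else 2
        if len(self.spins) != want:
            raise ValueError(
                f"{self.kind!r} takes {want} spin(s), got {len(self.spins)}")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError(f"eta must be in [0, 1], got {self.eta}")
        self.spins = tuple(int(s) for s in self.spins)
        self.euler = [tuple(float(x) for x in e) for e in (self.euler or [])]

    @property
    def anisotropic(self) -> bool:
        return self.delta != 0.0


@dataclass
class EquilibriumReference:
    """Thermal-equilibrium reference: vec(rho_eq) and per-spin polarization."""

    rho_vec: np.ndarray          # vectorized rho_eq, unit trace
    populations: np.ndarray      # diagonal of rho_eq
    polarization: np.ndarray     # 2<S_z> per spin


class SpinSystem:
    """One exchange site ("experimental system").

    Parameters
    ----------
    B0 : float
        Static field, Tesla.
    isotopes : sequence of str
        e.g. ("1H", "13C"); resolved against the packaged isotope table.
    vr : float
        Rotor (MAS) frequency in Hz; 0 for static/solution work.
    rotor_angle : float or None
        Radians; defaults to the magic angle when spinning. Forced to 0
        when ``vr == 0``.
    n_gamma : int
        Steps per rotor period (also the gamma-angle count for
        alpha/beta-only powder averages).
    T : float
        Temperature in Kelvin.
    frames : sequence of {"rotating", "lab"} or None
        Per-spin frame choice; default all rotating.
    powder : str | int | PowderAverage
        Powder average name (see :func:`liouvex.powder.load_powder`).
    """

    def __init__(self, B0, isotopes, vr=0.0, rotor_angle=None, n_gamma=30,
                 T=298.0, frames=None, powder="JCP59", powder_kwargs=None,
                 gamma_encoded=None):
        if B0 <= 0:
            raise ValueError("B0 must be positive")
        if T <= 0:
            raise ValueError("temperature must be positive")
        if int(n_gamma) < 1:
            raise ValueError("n_gamma must be >= 1")
        self.B0 = float(B0)
        self.isotopes = [isotope(lbl).label for lbl in isotopes]
        self._specs = [isotope(lbl) for lbl in isotopes]
        self.vr = float(vr)
        if self.vr == 0.0:
            self.rotor_angle = 0.0  # static: rotor frame aligned with B0
        else:
            self.rotor_angle = MAGIC_ANGLE if rotor_angle is None else float(rotor_angle)
        self.n_gamma = int(n_gamma)
        self.T = float(T)
        self.frames = list(frames) if frames is not None else ["rotating"] * len(self._specs)
        if len(self.frames) != len(self._specs):
            raise ValueError("one frame flag per spin required")
        for f in self.frames:
            if f not in ("rotating", "lab"):
                raise ValueError(f"frame must be 'rotating' or 'lab', got {f!r}")
        if isinstance(powder, PowderAverage):
            self.powder = powder
        else:
            self.powder = load_powder(powder, **(powder_kwargs or {}))
        if gamma_encoded is not None:
            self.powder.gamma_encoded = bool(gamma_encoded)
        self.interactions: list[Interaction] = []

    # -- structure ---------------------------------------------------------
    @property
    def nspins(self) -> int:
        return len(self._specs)

    @property
    def spins(self) -> list[float]:
        return [s.spin for s in self._specs]

    @property
    def dims(self) -> list[int]:
        return [s.multiplicity for s in self._specs]

    @property
    def dim_H(self) -> int:
        return int(np.prod(self.dims))

    @property
    def dim_L(self) -> int:
        return self.dim_H ** 2

    @property
    def gammas(self) -> np.ndarray:
        return np.array([s.gamma for s in self._specs])

    @property
    def larmor(self) -> np.ndarray:
        """Larmor frequencies w0_i = -gamma_i B0 (rad/s)."""
        return -self.gammas * self.B0

    def __repr__(self):
        ints = ", ".join(f"{i.kind}{i.spins}" for i in self.interactions)
        return (f"SpinSystem({self.isotopes}, B0={self.B0} T, vr={self.vr} Hz, "
                f"T={self.T} K, interactions=[{ints}])")

    # -- interactions ------------------------------------------------------
    def add_interaction(self, kind, spins, delta=0.0, eta=0.0, euler=None,
                        iso=0.0) -> "SpinSystem":
        """Append an interaction; returns self for chaining."""
        if isinstance(spins, (int, np.integer)):
            spins = (spins,)
        inter = Interaction(kind, tuple(spins), float(delta), float(eta),
                            euler, float(iso))
        for s in inter.spins:
            if not 0 <= s < self.nspins:
                raise ValueError(f"spin index {s} out of range")
        if kind == "quadrupole" and self.spins[inter.spins[0]] < 1:
            raise ValueError("quadrupole coupling is undefined for spin-1/2")
        if kind == "g" and self.isotopes[inter.spins[0]] != "e-":
            raise ValueError("g-tensor interactions act on electrons")
        self.interactions.append(inter)
        return self

    def copy(self) -> "SpinSystem":
        return _copy.deepcopy(self)

    def copy_with_new_orientation(self, index, euler) -> "SpinSystem":
        """Deep copy differing only in interaction ``index``'s Euler angles."""
        return self.modified_copy(index, euler=euler)

    def modified_copy(self, index, delta=None, eta=None, euler=None,
                      iso=None) -> "SpinSystem":
        """Deep copy with one interaction's magnitude and/or orientation changed."""
        if not 0 <= index < len(self.interactions):
            raise IndexError(f"interaction index {index} out of range")
        new = self.copy()
        it = new.interactions[index]
        if delta is not None:
            it.delta = float(delta)
        if eta is not None:
            if not 0.0 <= eta <= 1.0:
                raise ValueError("eta must be in [0, 1]")
            it.eta = float(eta)
        if euler is not None:
            it.euler = [tuple(float(x) for x in e) for e in euler]
        if iso is not None:
            it.iso = float(iso)
        return new

    # -- thermal equilibrium ----------------------------------------------
    def lab_hamiltonian(self, orientation=(0.0, 0.0, 0.0)) -> np.ndarray:
        """Static Hamiltonian (rad/s) with all Zeeman terms re-added.

        Used for thermal-equilibrium energies: spins simulated in the
        rotating frame have no Zeeman term in the working Hamiltonian, but
        Boltzmann populations follow the lab energies.
        """
        from .hamiltonian import rotating_components  # local: avoid cycle

        comps = rotating_components(self, orientation)
        h = comps.static()
        for i, frame in enumerate(self.frames):
            if frame == "rotating":
                h = h + self.larmor[i] * spin_op("z", i, self.spins)
        return h

    def equilibrium_reference(self, orientation=(0.0, 0.0, 0.0)) -> EquilibriumReference:
        """rho_eq proportional to exp(-hbar H / kB T), unit trace."""
        from scipy.linalg import expm

        h = self.lab_hamiltonian(orientation)
        beta = HBAR / (KB * self.T)
        ex = expm(-beta * h)
        rho = ex / np.trace(ex).real
        pol = np.array([2.0 * np.trace(rho @ spin_op("z", i, self.spins)).real
                        for i in range(self.nspins)])
        return EquilibriumReference(vec(rho), np.diag(rho).real.copy(), pol)
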