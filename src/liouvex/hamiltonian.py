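"""Rotating Hamiltonian components and RF fields.

Each interaction contributes to the five rotating components H_n
(n = -2..2) of the Hamiltonian for one orientation,

    H_n = sum_i sum_q (-1)^q d^(2)_{n,q}(theta_r) A^(i,RF)_{2,n} T^(i)_{2,-q},

with isotropic terms entering only H_0. The spherical tensor operators
are truncated according to the per-spin rotating/lab frame choice
(secular approximation): rotating-frame spin pairs keep only T_{2,0}
(with the flip-flop term retained for homonuclear pairs), lab-frame
spins keep all components.

RF fields on rotating-frame spins are static,
w1 (cos(phi) Sx + sin(phi) Sy) - dw Sz. Continuous irradiation of a
lab-frame spin is handled by a square-wave scheme: two steps per Larmor
cycle with constant fields +-(pi/2) w1 Sy, composed into a one-cycle
propagator that is raised (through its eigenbasis) to span a rotor step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import HBAR, MU_B
from .operators import spin_op, embed, spin_matrices
from .rotations import pas_components, rotate_components, wigner_d2
from .spin_system import SpinSystem, Interaction

SQRT6 = np.sqrt(6.0)
TWO_PI = 2.0 * np.pi


def _delta_rad(system: SpinSystem, inter: Interaction) -> float:
    """Anisotropy in rad/s (g-anisotropy converted via the Bohr magneton)."""
    if inter.kind == "g":
        return inter.delta * MU_B * system.B0 / HBAR
    return TWO_PI * inter.delta


def _iso_hamiltonian(system: SpinSystem, inter: Interaction) -> np.ndarray | None:
    """Isotropic (rank-0) part of an interaction, as a Hamiltonian in rad/s."""
    if inter.iso == 0.0:
        return None
    S = system.spins
    if inter.kind in ("cs", "csa"):
        return TWO_PI * inter.iso * spin_op("z", inter.spins[0], S)
    if inter.kind == "g":
        w = inter.iso * MU_B * system.B0 / HBAR
        return w * spin_op("z", inter.spins[0], S)
    if inter.kind in ("j", "hyperfine"):
        i, j = inter.spins
        fr = (system.frames[i], system.frames[j])
        homo = system.isotopes[i] == system.isotopes[j]
        zz = spin_op("z", i, S) @ spin_op("z", j, S)
        if fr == ("lab", "lab") or (fr == ("rotating", "rotating") and homo):
            full = (zz
                    + spin_op("x", i, S) @ spin_op("x", j, S)
                    + spin_op("y", i, S) @ spin_op("y", j, S))
            return TWO_PI * inter.iso * full
        return TWO_PI * inter.iso * zz
    return None


def tensor_operators(system: SpinSystem, inter: Interaction) -> list[np.ndarray]:
    """Rank-2 spherical tensor operators T_{2,q}, truncated per frame choice.

    Returns a list of 5 product-space matrices indexed q+2; dropped
    components are zero matrices.
    """
    S = system.spins
    d = system.dim_H
    T = [np.zeros((d, d), dtype=complex) for _ in range(5)]
    fr = [system.frames[i] for i in inter.spins]
    if inter.kind in ("cs", "csa", "g"):
        i = inter.spins[0]
        z, p, m = (spin_op(k, i, S) for k in "zpm")
        T[2] = np.sqrt(2.0 / 3.0) * z
        if fr[0] == "lab":
            T[3] = -0.5 * p
            T[1] = +0.5 * m
    elif inter.kind == "quadrupole":
        i = inter.spins[0]
        z, p, m = (spin_op(k, i, S) for k in "zpm")
        s = S[i]
        T[2] = (3 * z @ z - s * (s + 1) * np.eye(d)) / SQRT6
        if fr[0] == "lab":
            T[3] = -0.5 * (z @ p + p @ z)
            T[1] = +0.5 * (z @ m + m @ z)
            T[4] = 0.5 * p @ p
            T[0] = 0.5 * m @ m
    else:  # dipole / anisotropic hyperfine
        i, j = inter.spins
        homo = system.isotopes[i] == system.isotopes[j]
        z1, p1, m1 = (spin_op(k, i, S) for k in "zpm")
        z2, p2, m2 = (spin_op(k, j, S) for k in "zpm")
        zz = z1 @ z2
        both_lab = fr == ["lab", "lab"]
        both_rot = fr == ["rotating", "rotating"]
        if both_lab or (both_rot and homo):
            flip = 0.5 * (p1 @ m2 + m1 @ p2)
            T[2] = (3 * zz - (zz + flip)) / SQRT6
        else:
            T[2] = 2.0 * zz / SQRT6
        if both_lab:
            T[3] = -0.5 * (p1 @ z2 + z1 @ p2)
            T[1] = +0.5 * (m1 @ z2 + z1 @ m2)
            T[4] = 0.5 * p1 @ p2
            T[0] = 0.5 * m1 @ m2
        elif fr == ["lab", "rotating"]:
            T[3] = -0.5 * p1 @ z2
            T[1] = +0.5 * m1 @ z2
        elif fr == ["rotating", "lab"]:
            T[3] = -0.5 * z1 @ p2
            T[1] = +0.5 * z1 @ m2
    return T


@dataclass
class RotatingHamiltonian:
    """The five rotating components H_n of one site at one orientation."""

    Hn: list  # 5 complex matrices, index n+2
    omega_r: float

    def at(self, t: float) -> np.ndarray:
        """H(t) = sum_n exp(-i n w_r t) H_n."""
        n = np.arange(-2, 3)
        ph = np.exp(-1j * n * self.omega_r * t)
        return sum(c * h for c, h in zip(ph, self.Hn))

    def static(self) -> np.ndarray:
        return self.at(0.0)


def rotating_components(system: SpinSystem, orientation) -> RotatingHamiltonian:
    """Assemble H_n for one powder orientation (alpha, beta, gamma)."""
    d = system.dim_H
    Hn = [np.zeros((d, d), dtype=complex) for _ in range(5)]
    theta = system.rotor_angle
    dth = wigner_d2(theta)
    sign = (-1.0) ** np.arange(-2, 3)
    orientation = tuple(orientation)
    for inter in system.interactions:
        iso = _iso_hamiltonian(system, inter)
        if iso is not None:
            Hn[2] += iso
        if not inter.anisotropic:
            continue
        a = pas_components(_delta_rad(system, inter), inter.eta)
        if inter.euler:
            a = rotate_components(a, inter.euler)  # PAS -> MF
        a_rf = rotate_components(a, [orientation])  # MF -> RF
        T = tensor_operators(system, inter)
        for n in range(-2, 3):
            coef = a_rf[n + 2]
            if coef == 0:
                continue
            for q in range(-2, 3):
                Tq = T[2 - q]  # T_{2,-q}
                if not Tq.any():
                    continue
                Hn[n + 2] = Hn[n + 2] + sign[q + 2] * dth[n + 2, q + 2] * coef * Tq
    # Zeeman terms for lab-frame spins (removed by the rotating frame)
    for i, frame in enumerate(system.frames):
        if frame == "lab":
            Hn[2] += system.larmor[i] * spin_op("z", i, system.spins)
    return RotatingHamiltonian(Hn, TWO_PI * system.vr)


@dataclass
class LabRFPlan:
    """Square-wave irradiation plan for one lab-frame spin."""

    spin: int
    omega1: float          # rad/s
    phase: float
    carrier: float         # rad/s, Larmor + offset
    steps_per_cycle: int = 2


def resolve_channel(system: SpinSystem, channel) -> list[int]:
    """A channel is an isotope label or a spin index."""
    if isinstance(channel, (int, np.integer)):
        if not 0 <= channel < system.nspins:
            raise ValueError(f"spin index {channel} out of range")
        return [int(channel)]
    members = [i for i, iso in enumerate(system.isotopes) if iso == channel]
    if not members:
        raise ValueError(f"no spin of isotope {channel!r} in system")
    return members


def rf_hamiltonian(system: SpinSystem, fields: dict,
                   steps_per_cycle: int = 2):
    """RF Hamiltonian for rotating-frame spins plus lab-frame plans.

    ``fields`` maps channel -> (amplitude_Hz, phase_rad, offset_Hz).
    Returns ``(H_rf, plans)`` with H_rf in rad/s.
    """
    d = system.dim_H
    H = np.zeros((d, d), dtype=complex)
    plans: list[LabRFPlan] = []
    for channel, (amp, phase, offset) in fields.items():
        w1 = TWO_PI * amp
        dw = TWO_PI * offset
        for i in resolve_channel(system, channel):
            if system.frames[i] == "rotating":
                if w1 != 0.0:
                    H += w1 * (np.cos(phase) * spin_op("x", i, system.spins)
                               + np.sin(phase) * spin_op("y", i, system.spins))
                if dw != 0.0:
                    H -= dw * spin_op("z", i, system.spins)
            elif w1 != 0.0:
                plans.append(LabRFPlan(i, w1, phase,
                                       abs(system.larmor[i]) + dw,
                                       steps_per_cycle))
    if len(plans) > 1 and steps_per_cycle == 2:
        warnings.warn("lab-frame irradiation on multiple channels with 2 "
                      "steps per Larmor cycle; raise steps_per_cycle")
    return H, plans


def lab_rf_segments(plan: LabRFPlan, system: SpinSystem):
    """Piecewise-constant fields over one Larmor cycle of the carrier.

    Returns (durations, hamiltonians). Two steps per cycle use the exact
    square-wave +-(pi/2) w1 Sy; more steps sample the cosine at interval
    midpoints with a 1/sinc(1/s) correction of the fundamental.
    """
    s = plan.steps_per_cycle
    T0 = TWO_PI / plan.carrier
    sy = (np.cos(plan.phase) * spin_op("y", plan.spin, system.spins)
          - np.sin(plan.phase) * spin_op("x", plan.spin, system.spins))
    if s == 2:
        amps = np.array([+np.pi / 2, -np.pi / 2]) * plan.omega1
    else:
        k = np.arange(s)
        gain = np.sinc(1.0 / s)  # zero-order-hold fundamental attenuation
        amps = 2.0 * plan.omega1 * np.cos(TWO_PI * (k + 0.5) / s) / gain / 2.0
    durs = np.full(s, T0 / s)
    return durs, [a * sy for a in amps]
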