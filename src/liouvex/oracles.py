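"""Independent analytic references for validation.

These deliberately avoid the simulator's fast paths: the two-site
lineshape and R1rho dispersion are closed forms, and
:func:`brute_force_signal` propagates with plain matrix exponentials on
a finer time grid with no caching, no basis reduction and no eigenbasis
tricks. They serve as oracles in the test suite and in the ``validate``
command.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .liouvillian import Liouvillian, commutator_superop, _blockdiag
from .operators import vec
from .density_state import SignalTable, _resolve
from .propagation import Sequence

__all__ = ["TwoSiteParams", "bloch_mcconnell_spectrum", "fast_exchange_r1rho",
           "brute_force_signal"]


@dataclass
class TwoSiteParams:
    """Two-site exchange parameters for the closed-form references.

    Shifts are offsets in rad/s; rates in 1/s.
    """

    p1: float
    domega: float          # shift difference omega_2 - omega_1 (rad/s)
    kex: float             # k_12 + k_21
    R2: float = 0.0
    omega1: float = 0.0    # spin-lock amplitude (rad/s)
    offset: float = 0.0    # spin-lock offset from the mean shift (rad/s)

    def __post_init__(self):
        if not 0 < self.p1 < 1:
            raise ValueError("p1 must be in (0, 1)")
        if self.kex < 0 or self.R2 < 0:
            raise ValueError("rates must be nonnegative")

    @property
    def p2(self):
        return 1.0 - self.p1


def bloch_mcconnell_spectrum(params: TwoSiteParams, freq_hz: np.ndarray,
                             center: float = 0.0) -> np.ndarray:
    """Absorption lineshape of two exchanging shifts (Bloch-McConnell).

    The evolution matrix of the two transverse magnetizations is
    A = i diag(w1, w2) - R2 + K; the spectrum is
    Re[ 1^T (i w - A)^-1 p ] / pi on the requested frequency grid (Hz).
    Sites are placed at the population-weighted mean ``center`` +-
    according to ``domega``.
    """
    w1 = center - params.p2 * params.domega
    w2 = center + params.p1 * params.domega
    k12 = params.p2 * params.kex
    k21 = params.p1 * params.kex
    A = np.array([[1j * w1 - params.R2 - k12, k21],
                  [k12, 1j * w2 - params.R2 - k21]])
    p = np.array([params.p1, params.p2])
    one = np.ones(2)
    out = np.empty(freq_hz.size)
    for i, f in enumerate(freq_hz):
        w = 2 * np.pi * f
        out[i] = (one @ np.linalg.solve(1j * w * np.eye(2) - A, p)).real / np.pi
    return out


def fast_exchange_r1rho(params: TwoSiteParams) -> tuple[float, bool]:
    """Fast-exchange exchange contribution to R1rho.

    R_ex = p1 p2 domega^2 kex / (kex^2 + w_e^2), with the effective field
    w_e^2 = w1^2 + offset^2. Returns (rate, valid) where ``valid`` flags
    the fast-exchange regime kex >> |domega|.
    """
    we2 = params.omega1 ** 2 + params.offset ** 2
    if params.kex == 0:
        return 0.0, False
    rate = params.p1 * params.p2 * params.domega ** 2 * params.kex \
        / (params.kex ** 2 + we2)
    return rate, params.kex > 5 * abs(params.domega)


def brute_force_signal(L: Liouvillian, rho0, detectors, sequence: Sequence,
                       n: int, oversample: int = 10) -> SignalTable:
    """Reference detect/propagate loop at a finer step grid.

    Builds every step propagator directly as exp(L(t_mid) dt) with
    ``oversample`` times more rotor steps than the fast path, bypassing
    the propagator cache, eigenbasis propagation and basis reduction.
    Limited to small problems (<= 3 spins, <= 3 sites).
    """
    if L.expsys.nspins > 3 or L.N > 3:
        raise ValueError("brute-force oracle is limited to <= 3 spins "
                         "and <= 3 sites")
    sysd = L.expsys
    det_site = [vec(_resolve(d, sysd)) for d in detectors]
    dets = [np.tile(dv, L.N) for dv in det_site]
    from .liouvillian import _stationary
    p = _stationary(L.kex)
    r0 = np.concatenate([p[i] * vec(_resolve(rho0, sysd)) for i in range(L.N)])
    scale = L.state_scale
    dur = sequence.duration
    t_axis = dur * np.arange(n)
    sig = np.zeros((len(dets), n), dtype=complex)
    for io in range(L.n_orient):
        w = L.weight[io]
        rho = r0.astype(complex)
        if scale is not None:
            rho = rho * scale
        t = 0.0
        for k in range(n):
            for i, d in enumerate(dets):
                dv = d / scale if scale is not None else d
                sig[i, k] += w * (np.conj(dv) @ rho)
            bounds = [t, t + dur]
            for bp in sequence.breakpoints:
                if 0 < bp < dur:
                    bounds.append(t + bp)
            if not L.static:
                dt = L.rotor_period / (sysd.n_gamma * oversample)
                kk = int(np.floor(t / dt)) + 1
                while kk * dt < t + dur - 1e-14 * dur:
                    bounds.append(kk * dt)
                    kk += 1
            else:
                fine = np.linspace(t, t + dur, oversample + 1)[1:-1]
                bounds.extend(fine)
            bounds = np.sort(np.unique(bounds))
            for a, b in zip(bounds[:-1], bounds[1:]):
                tm = 0.5 * (a + b)
                fields = sequence.fields_at((tm - t) % dur) \
                    if sequence.channels else {}
                L_rf, plans = L.rf_superop(fields)
                if plans:
                    raise NotImplementedError("brute-force oracle does not "
                                              "support lab-frame irradiation")
                rho = expm(L.L_at(io, tm, L_rf) * (b - a)) @ rho
            t += dur
    names = [d if isinstance(d, str) else f"det{i}"
             for i, d in enumerate(detectors)]
    return SignalTable(t_axis, dict(zip(names, sig)))
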