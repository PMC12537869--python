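"""Rank-0/2 spherical-component algebra and Wigner rotations.

Components are stored as length-5 complex arrays indexed q = -2..2
(array index q+2). Euler convention is z-y-z, active, applied as

    A_q^out = sum_q' exp(-i alpha q') d^(2)_{q',q}(beta) exp(-i gamma q) A_q'^in

and iterated in order for multiple Euler sets (PAS -> molecular frame ->
rotor frame). The rotor spinning adds a time-dependent z-rotation
exp(-i q' w_r t) and the tilt by the rotor angle before reaching the lab
frame.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "pas_components",
    "reduced_wigner",
    "wigner_d2",
    "rotate_components",
    "rotor_frame_components",
    "a_qn_table",
]

SQ32 = np.sqrt(1.5)
SQ38 = np.sqrt(3.0 / 8.0)


def pas_components(delta: float, eta: float) -> np.ndarray:
    """Rank-2 components in the interaction's principal axis system.

    A_{2,0} = sqrt(3/2) delta, A_{2,+-1} = 0, A_{2,+-2} = -delta*eta/2.
    ``delta`` carries the unit of the anisotropy (the caller fixes it),
    ``eta`` in [0, 1].
    """
    if not 0.0 <= eta <= 1.0:
        raise ValueError(f"eta must be in [0, 1], got {eta}")
    a = np.zeros(5, dtype=complex)
    a[2] = SQ32 * delta
    a[0] = a[4] = -0.5 * delta * eta
    return a


def wigner_d2(beta: float) -> np.ndarray:
    """Full reduced Wigner matrix d^(2)_{m',m}(beta).

    Returned array is indexed ``d[m'+2, m+2]`` for m', m in -2..2.
    """
    c, s = np.cos(beta), np.sin(beta)
    # rows m' = 2, 1, 0, -1, -2; columns m likewise (descending)
    dsc = np.array([
        [0.25 * (1 + c) ** 2, -0.5 * s * (1 + c), SQ38 * s * s,
         -0.5 * s * (1 - c), 0.25 * (1 - c) ** 2],
        [0.5 * s * (1 + c), 0.5 * (1 + c) * (2 * c - 1), -SQ32 * s * c,
         0.5 * (1 - c) * (2 * c + 1), -0.5 * s * (1 - c)],
        [SQ38 * s * s, SQ32 * s * c, 0.5 * (3 * c * c - 1),
         -SQ32 * s * c, SQ38 * s * s],
        [0.5 * s * (1 - c), 0.5 * (1 - c) * (2 * c + 1), SQ32 * s * c,
         0.5 * (1 + c) * (2 * c - 1), -0.5 * s * (1 + c)],
        [0.25 * (1 - c) ** 2, 0.5 * s * (1 - c), SQ38 * s * s,
         0.5 * s * (1 + c), 0.25 * (1 + c) ** 2],
    ])
    # re-index to ascending m', m
    return dsc[::-1, ::-1].copy()


def reduced_wigner(l: int, n: int, q: int, beta: float) -> float:
    """Reduced Wigner matrix element d^(l)_{n,q}(beta) for l in {0, 2}."""
    if l == 0:
        if n != 0 or q != 0:
            raise ValueError("rank-0 has only the (0,0) element")
        return 1.0
    if l != 2:
        raise ValueError("only ranks 0 and 2 are supported")
    if abs(n) > 2 or abs(q) > 2:
        raise ValueError(f"invalid indices (n={n}, q={q}) for rank 2")
    return float(wigner_d2(beta)[n + 2, q + 2])


def rotate_components(a: np.ndarray, euler) -> np.ndarray:
    """Apply D^(2) for one Euler triple or, in order, a list of triples."""
    a = np.asarray(a, dtype=complex).copy()
    if len(euler) == 0:
        return a
    sets = euler if hasattr(euler[0], "__len__") else [euler]
    q = np.arange(-2, 3)
    for (al, be, ga) in sets:
        d = wigner_d2(be)
        phase_in = np.exp(-1j * al * q)    # on the summed index q'
        phase_out = np.exp(-1j * ga * q)   # on the output index q
        a = phase_out * ((phase_in * a) @ d)
    return a


def a_qn_table(a_rf: np.ndarray, theta_r: float) -> np.ndarray:
    """The A_q^n table: A_q^n = d^(2)_{n,q}(theta_r) A^RF_{2,n}.

    Returns a 5x5 array indexed [n+2, q+2]. At theta_r = 0 it is diagonal.
    """
    d = wigner_d2(theta_r)
    return d * np.asarray(a_rf, dtype=complex)[:, None]


def rotor_frame_components(a_rf: np.ndarray, theta_r: float, t: float,
                           omega_r: float) -> np.ndarray:
    """Lab-frame components from rotor-frame ones at time ``t``.

    A^LF_q = sum_n e^{-i n w_r t} d^(2)_{n,q}(theta_r) A^RF_{2,n}.
    With theta_r = 0 the final rotation has no effect (a rotation about
    the field axis only shifts the azimuthal origin), so A^LF = A^RF.
    """
    if theta_r == 0.0:
        return np.asarray(a_rf, dtype=complex).copy()
    tab = a_qn_table(a_rf, theta_r)
    n = np.arange(-2, 3)
    phase = np.exp(-1j * n * omega_r * t)
    return phase @ tab
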