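"""N-site orientational exchange models mimicking isotropic tumbling.

A tumbling model replicates a spin system over a set of Euler angles
(appended to every anisotropic interaction) and couples the replicas
with an exchange matrix built from nearest-neighbor hops:

* beta-only: 10q uniformly spaced beta angles, 2 neighbors each;
* two-angle: magic-angle hopping (q=0, 3 axes), tetrahedral hopping
  (q=1), REPULSION sets for q >= 2;
* three-angle: JCP59 sets, 15 neighbors.

Hop rates are proportional to 1/D^2 (squared angular distance between
frames), adjusted pairwise for detailed balance against the orientation
weights, and globally scaled so the amplitude-weighted mean rate matches
the requested correlation time, tau_c = (sum_i A_i k_i)^-1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .liouvillian import Liouvillian
from .powder import load_powder, JCP59_COUNTS
from .rotations import pas_components, rotate_components
from .spin_system import SpinSystem

__all__ = ["setup_tumbling", "angular_distance2", "balanced_rates",
           "scale_to_tauc", "l2a_diagnostics", "TumblingModel",
           "TumblingDiagnostics", "NEIGHBORS_2ANGLE", "N_NEIGHBORS_3ANGLE"]

NEIGHBORS_2ANGLE = {0: 2, 1: 3, 2: 5, 3: 6, 4: 6, 5: 6, 6: 6}
N_NEIGHBORS_3ANGLE = 15
REPULSION_2ANGLE = {2: 10, 3: 20, 4: 30, 5: 66, 6: 100}

_TET = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]) / np.sqrt(3)


@dataclass
class TumblingModel:
    mode: str                      # "beta" | "2angle" | "3angle"
    q: int
    euler_sets: np.ndarray         # (N, 3) radians
    weights: np.ndarray
    n_neighbors: int               # nearest-neighbor selection count per site
    neighbor_lists: list           # directed selection, exactly n per site
    K: np.ndarray                  # scaled exchange matrix
    tauc: float
    solid: bool = False
    qualitative: bool = False


@dataclass
class TumblingDiagnostics:
    """Model-quality numbers: per-interaction S2 and rate amplitudes."""

    S2: list                       # residual order parameter per interaction
    p_eq: np.ndarray               # stationary populations of the angles
    tauc_list: np.ndarray          # 1/k_i for the nonzero eigenvalues
    amplitudes: list               # per interaction: A_i array (sums to 1)
    qualitative: bool = False


def _axes(euler) -> np.ndarray:
    """Images of the x, y, z axes under the z-y-z rotation (columns)."""
    al, be, ga = euler
    ca, sa = np.cos(al), np.sin(al)
    cb, sb = np.cos(be), np.sin(be)
    cg, sg = np.cos(ga), np.sin(ga)
    rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return rz1 @ ry @ rz2


def angular_distance2(euler_j, euler_k) -> float:
    """Sum of squared angular distances between the two frames' axes."""
    aj, ak = _axes(euler_j), _axes(euler_k)
    dots = np.clip(np.einsum("ij,ij->j", aj, ak), -1.0, 1.0)
    return float(np.sum(np.arccos(dots) ** 2))


def balanced_rates(k0: float, w_j: float, w_k: float) -> tuple[float, float]:
    """Detailed-balance pair (k_{j,k}, k_{k,j}) around the base rate k0.

    k_{j,k} (the k -> j rate) = k0 (1 + (1-r)/(1+r)) with r = w_k/w_j,
    so that k_{j,k} w_k = k_{k,j} w_j.
    """
    if w_j <= 0 or w_k <= 0 or k0 <= 0:
        raise ValueError("weights and base rate must be positive")
    r = w_k / w_j
    f = (1.0 - r) / (1.0 + r)
    return k0 * (1.0 + f), k0 * (1.0 - f)


def _angle_sets(mode: str, q: int):
    if mode == "beta":
        n = 10 * q
        if n < 1:
            raise ValueError("beta tumbling needs q >= 1")
        beta = np.pi * (np.arange(n) + 0.5) / n
        sets = np.column_stack([np.zeros(n), beta, np.zeros(n)])
        w = np.sin(beta)
        return sets, w / w.sum(), 2
    if mode == "2angle":
        if q == 0:
            ab = [(0.0, 0.0), (0.0, np.pi / 2), (np.pi / 2, np.pi / 2)]
        elif q == 1:
            ab = [(np.arctan2(v[1], v[0]) % (2 * np.pi), np.arccos(v[2]))
                  for v in _TET]
        elif q in REPULSION_2ANGLE:
            pw = load_powder(f"rep{REPULSION_2ANGLE[q]}")
            ab = list(zip(pw.alpha, pw.beta))
        else:
            raise ValueError(f"unsupported quality q={q} for 2-angle tumbling")
        sets = np.array([(a, b, 0.0) for a, b in ab])
        w = np.full(len(ab), 1.0 / len(ab))
        return sets, w, NEIGHBORS_2ANGLE[q]
    if mode == "3angle":
        if q not in JCP59_COUNTS:
            raise ValueError(f"unsupported quality q={q} for 3-angle tumbling")
        pw = load_powder("JCP59", q=q)
        sets = np.column_stack([pw.alpha, pw.beta, pw.gamma])
        return sets, pw.weight.copy(), N_NEIGHBORS_3ANGLE
    raise ValueError(f"unknown tumbling mode {mode!r}")


def _build_kex(sets, weights, n_neighbors):
    """Unscaled exchange matrix from the nearest-neighbor hop graph."""
    n = len(sets)
    if n_neighbors >= n:
        raise ValueError("more neighbors requested than orientations")
    D2 = np.zeros((n, n))
    for j in range(n):
        for k in range(j + 1, n):
            D2[j, k] = D2[k, j] = angular_distance2(sets[j], sets[k])
    neighbor_lists = []
    for j in range(n):
        order = np.argsort(D2[j] + np.where(np.arange(n) == j, np.inf, 0.0),
                           kind="stable")
        neighbor_lists.append(sorted(order[:n_neighbors].tolist()))
    edges = set()
    for j, lst in enumerate(neighbor_lists):
        for k in lst:
            edges.add((min(j, k), max(j, k)))
    K = np.zeros((n, n))
    for (j, k) in sorted(edges):
        k0 = 1.0 / max(D2[j, k], 1e-12)
        kjk, kkj = balanced_rates(k0, weights[j], weights[k])
        K[j, k] += kjk   # k -> j
        K[k, j] += kkj   # j -> k
    np.fill_diagonal(K, 0.0)
    K -= np.diag(K.sum(axis=0))
    return K, neighbor_lists


def _mode_amplitudes(sets, weights, K, f_components=None):
    """Eigenmode rates k_i and amplitudes A_i of a rank-2 correlation.

    ``f_components`` gives the molecular-frame rank-2 components of the
    probed interaction before the tumbling rotation (default: z-aligned,
    delta = 1). Returns (k_i, A_i, S2, i_zero data).
    """
    n = len(sets)
    base = pas_components(1.0, 0.0) if f_components is None else f_components
    f = np.array([rotate_components(base, [tuple(s)]) for s in sets])  # (n, 5)
    w_eig, R = np.linalg.eig(K)
    Li = np.linalg.inv(R)
    a = np.zeros(n, dtype=complex)
    for m in range(5):
        fm = f[:, m]
        a += (np.conj(fm) @ R) * (Li @ (weights * fm))
    c0 = float(np.sum(weights[:, None] * np.abs(f) ** 2))
    i0 = int(np.argmin(np.abs(w_eig)))
    s2 = float(np.real(a[i0])) / c0
    rest = np.delete(np.arange(n), i0)
    k_i = -np.real(w_eig[rest])
    A_i = np.real(a[rest])
    tot = A_i.sum()
    if abs(tot) > 1e-14:
        A_i = A_i / tot
    return k_i, A_i, s2, i0


def scale_to_tauc(K: np.ndarray, tauc: float,
                  sets=None, weights=None) -> np.ndarray:
    """Scale K so (sum_i A_i k_i)^-1 equals the requested tau_c.

    A_i are computed for an interaction initially along the z-axis.
    """
    if tauc <= 0:
        raise ValueError("tauc must be positive")
    w_eig = np.linalg.eigvals(K)
    if np.abs(w_eig).min() > 1e-8 * max(np.abs(w_eig).max(), 1e-30):
        raise ValueError("exchange matrix lacks the required zero eigenvalue")
    if sets is None:
        raise ValueError("the Euler-angle sets are needed to compute A_i")
    k_i, A_i, _, _ = _mode_amplitudes(sets, weights, K)
    mean_rate = float(A_i @ k_i)
    if mean_rate <= 0:
        raise ValueError("degenerate tumbling model: nonpositive mean rate")
    return K / (tauc * mean_rate)


def setup_tumbling(system: SpinSystem, tauc: float, angles=("alpha", "beta", "gamma"),
                   q: int = 3, solid: bool = False) -> Liouvillian:
    """Build the tumbling Liouvillian for ``system``.

    ``angles`` selects which Euler angles vary ("beta" alone, alpha+beta,
    or all three); ``q`` is the quality factor (Table-style counts).
    Unless ``solid`` is set, the powder average collapses to a single
    z-aligned orientation, the rotor angle to 0 and the spinning
    frequency to 0 (solution conditions).
    """
    angles = tuple(angles)
    if angles == ("beta",):
        mode = "beta"
    elif angles == ("alpha", "beta"):
        mode = "2angle"
    elif angles == ("alpha", "beta", "gamma"):
        mode = "3angle"
    else:
        raise ValueError("angles must be ('beta',), ('alpha','beta') or "
                         "('alpha','beta','gamma')")
    sets, weights, n_nb = _angle_sets(mode, q)
    K0, neighbor_lists = _build_kex(sets, weights, n_nb)
    K = scale_to_tauc(K0, tauc, sets=sets, weights=weights)
    sites = []
    for s in sets:
        cp = system.copy()
        if not solid:
            cp.vr = 0.0
            cp.rotor_angle = 0.0
            cp.powder = load_powder("alpha0beta0")
        for inter in cp.interactions:
            if inter.anisotropic:
                inter.euler = inter.euler + [tuple(s)]
        sites.append(cp)
    L = Liouvillian(sites, kex=K)
    L.tumbling = TumblingModel(mode, q, sets, weights, n_nb, neighbor_lists,
                               K, tauc, solid,
                               qualitative=(mode == "2angle" and q <= 1))
    if L.tumbling.qualitative:
        warnings.warn("2-angle tumbling with q <= 1 often returns only "
                      "qualitative results")
    return L


def l2a_diagnostics(L: Liouvillian) -> TumblingDiagnostics:
    """S2, stationary populations, correlation times and amplitudes.

    One S2/A_i entry per anisotropic interaction of the underlying
    system; correlation times are the inverse nonzero eigenvalues of the
    exchange matrix.
    """
    model = getattr(L, "tumbling", None)
    if model is None:
        raise ValueError("Liouvillian was not built by setup_tumbling")
    sets, weights, K = model.euler_sets, model.weights, model.K
    w_eig, R = np.linalg.eig(K)
    i0 = int(np.argmin(np.abs(w_eig)))
    p = np.abs(np.real(R[:, i0]))
    p_eq = p / p.sum()
    rest = np.delete(np.arange(len(sets)), i0)
    tauc_list = 1.0 / np.maximum(-np.real(w_eig[rest]), 1e-300)
    S2, amps = [], []
    for inter in L.sites[0].interactions:
        if not inter.anisotropic:
            continue
        base = pas_components(inter.delta, inter.eta)
        if len(inter.euler) > 1:  # original PAS->MF sets minus the appended one
            base = rotate_components(base, inter.euler[:-1])
        k_i, A_i, s2, _ = _mode_amplitudes(sets, weights, K,
                                           f_components=base)
        S2.append(s2)
        amps.append(A_i)
    return TumblingDiagnostics(S2, p_eq, tauc_list, amps,
                               qualitative=model.qualitative)
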