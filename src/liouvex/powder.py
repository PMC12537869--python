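"""Powder averages: packaged tables and generators.

All angles are stored in radians internally; packaged files use the
SIMPSON-style whitespace-separated three-column ``alpha beta weight``
format with angles in degrees.

Sets that define only (alpha, beta) are gamma-stepped at simulation time
(``n_gamma`` uniform gamma angles per orientation) unless
``gamma_encoded`` is set; single-orientation sets default to
``gamma_encoded = True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = ["PowderAverage", "load_powder", "JCP59_COUNTS"]

# Cheng-Suzukawa-Wolfsberg three-angle set sizes per quality factor, with
# the coprime lattice generators used for the alpha/gamma phases.
JCP59_COUNTS = {2: 49, 3: 99, 4: 143, 5: 199, 6: 299}
_JCP59_GEN = {49: (13, 20), 99: (34, 61), 143: (34, 89),
              199: (61, 122), 299: (55, 89)}

DEFAULT_QUALITY = 2  # 49 orientations


@dataclass
class PowderAverage:
    """A weighted set of crystallite orientations.

    ``gamma`` is None for alpha/beta-only sets (gamma stepped later).
    Weights are normalized to sum to 1.
    """

    name: str
    alpha: np.ndarray
    beta: np.ndarray
    weight: np.ndarray
    gamma: np.ndarray | None = None
    gamma_encoded: bool = False
    quality: int | None = None

    def __post_init__(self):
        self.alpha = np.atleast_1d(np.asarray(self.alpha, float))
        self.beta = np.atleast_1d(np.asarray(self.beta, float))
        w = np.atleast_1d(np.asarray(self.weight, float))
        if np.any(w < 0):
            raise ValueError("powder weights must be nonnegative")
        self.weight = w / w.sum()
        if self.gamma is not None:
            self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        if np.any((self.beta < -1e-12) | (self.beta > np.pi + 1e-12)):
            raise ValueError("beta angles must lie in [0, pi]")

    def __len__(self) -> int:
        return self.alpha.size

    @property
    def has_gamma(self) -> bool:
        return self.gamma is not None

    def orientations(self, n_gamma: int):
        """Expand to the full orientation list used in a simulation.

        Returns (alpha, beta, gamma, weight, base_index, gamma_index)
        arrays. ``base_index`` identifies the parent (alpha, beta) pair and
        ``gamma_index`` the position on the uniform gamma grid (or -1 when
        the gamma angle is not on that grid), used for propagator
        recycling.
        """
        if self.has_gamma or self.gamma_encoded:
            g = self.gamma if self.has_gamma else np.zeros(len(self))
            base = np.arange(len(self))
            gidx = np.full(len(self), -1, dtype=int)
            return self.alpha, self.beta, g, self.weight, base, gidx
        m = int(n_gamma)
        gammas = 2 * np.pi * np.arange(m) / m
        al = np.repeat(self.alpha, m)
        be = np.repeat(self.beta, m)
        ga = np.tile(gammas, len(self))
        w = np.repeat(self.weight, m) / m
        base = np.repeat(np.arange(len(self)), m)
        gidx = np.tile(np.arange(m), len(self))
        return al, be, ga, w, base, gidx


def _read_table(fname: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ref = resources.files("liouvex").joinpath(f"data/powder/{fname}")
    if not ref.is_file():
        raise FileNotFoundError(f"packaged powder table {fname!r} not found")
    dat = np.loadtxt(str(ref))
    return np.radians(dat[:, 0]), np.radians(dat[:, 1]), dat[:, 2]


def _jcp59(q: int) -> PowderAverage:
    if q not in JCP59_COUNTS:
        raise ValueError(f"JCP59 quality must be one of {sorted(JCP59_COUNTS)}")
    n = JCP59_COUNTS[q]
    g1, g2 = _JCP59_GEN[n]
    j = np.arange(n)
    alpha = 2 * np.pi * ((j * g1) % n) / n
    gamma = 2 * np.pi * ((j * g2) % n) / n
    beta = np.arccos(2 * (j + 0.5) / n - 1)
    w = np.full(n, 1.0 / n)
    return PowderAverage(f"JCP59_q{q}", alpha, beta, w, gamma=gamma,
                         gamma_encoded=True, quality=q)


def _zcw(m: int) -> PowderAverage:
    """Fibonacci-lattice (ZCW-type) alpha/beta set; m indexes the size."""
    fib = [1, 2]
    while len(fib) < m + 3:
        fib.append(fib[-1] + fib[-2])
    n, g = fib[m + 2], fib[m]
    j = np.arange(n)
    alpha = 2 * np.pi * ((j * g) % n) / n
    beta = np.arccos(2 * (j + 0.5) / n - 1)
    return PowderAverage(f"zcw{n}", alpha, beta, np.full(n, 1.0 / n))


def _grid(na: int, nb: int, ng: int) -> PowderAverage:
    a = 2 * np.pi * np.arange(na) / na
    b = np.pi * (np.arange(nb) + 0.5) / nb
    g = 2 * np.pi * np.arange(ng) / ng
    A, B, G = np.meshgrid(a, b, g, indexing="ij")
    w = np.sin(B).ravel()
    return PowderAverage(f"grid{na}x{nb}x{ng}", A.ravel(), B.ravel(), w,
                         gamma=G.ravel(), gamma_encoded=True)


def _beta_only(n: int) -> PowderAverage:
    b = np.pi * (np.arange(n) + 0.5) / n
    return PowderAverage(f"beta{n}", np.zeros(n), b, np.sin(b))


_SINGLE = {
    "alpha0beta0": 0.0,
    "alpha0beta45": np.pi / 4,
    "alpha0beta90": np.pi / 2,
}


def load_powder(name: str | int = "JCP59", **params) -> PowderAverage:
    """Look up or generate a powder average by name.

    Supported names: "alpha0beta0"/"alpha0beta45"/"alpha0beta90",
    "JCP59" (kw ``q``, default 2 -> 49 orientations), "zcw" (kw ``m``),
    "grid" (kw ``na``, ``nb``, ``ng``), "beta" (kw ``n``), and packaged
    REPULSION files "rep10"/"rep20"/"rep30"/"rep66"/"rep100" (or
    "repulsion" with kw ``n``). An integer selects JCP59 at that quality.
    """
    if isinstance(name, (int, np.integer)):
        return _jcp59(int(name))
    key = name.lower()
    if key in _SINGLE:
        return PowderAverage(key, [0.0], [_SINGLE[key]], [1.0],
                             gamma_encoded=True)
    if key == "jcp59":
        return _jcp59(int(params.get("q", DEFAULT_QUALITY)))
    if key == "zcw":
        return _zcw(int(params.get("m", 5)))
    if key == "grid":
        return _grid(int(params.get("na", 10)), int(params.get("nb", 10)),
                     int(params.get("ng", 5)))
    if key == "beta":
        return _beta_only(int(params.get("n", 30)))
    if key == "repulsion":
        key = f"rep{int(params['n'])}"
    if key.startswith("rep"):
        a, b, w = _read_table(f"{key}.txt")
        return PowderAverage(key, a, b, w)
    if key.startswith("lebedev"):
        raise FileNotFoundError(
            "no Lebedev table is packaged with this build")
    raise ValueError(f"unknown powder average {name!r}")
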