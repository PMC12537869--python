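"""Spin matrices and product-basis operators.

Basis ordering: for each spin, Zeeman states are ordered by decreasing
magnetic quantum number (m = S, S-1, ..., -S), so index 0 is "alpha" for a
spin-1/2. Multi-spin operators live in the Kronecker-product space with
spin 0 as the leftmost factor.

Ladder operators are the standard ones, S+- = Sx +- i Sy.
"""

from __future__ import annotations

import re

import numpy as np


def spin_matrices(S: float) -> dict[str, np.ndarray]:
    """Single-spin operators for spin quantum number ``S``.

    Returns a dict with keys x, y, z, p, m, alpha, beta, id.
    ``alpha``/``beta`` are the m=+1/2 / m=-1/2 projectors (spin-1/2 only;
    for higher spins they are the projectors on the extreme states).
    """
    n = int(round(2 * S + 1))
    m = S - np.arange(n)  # descending
    sz = np.diag(m).astype(complex)
    # <m+1|S+|m> = sqrt(S(S+1) - m(m+1)); with descending order that is
    # element (i-1, i) for state index i.
    amp = np.sqrt(S * (S + 1) - m[1:] * (m[1:] + 1))
    sp = np.zeros((n, n), dtype=complex)
    sp[np.arange(n - 1), np.arange(1, n)] = amp
    sm = sp.conj().T
    sx = 0.5 * (sp + sm)
    sy = -0.5j * (sp - sm)
    alpha = np.zeros((n, n), dtype=complex)
    alpha[0, 0] = 1.0
    beta = np.zeros((n, n), dtype=complex)
    beta[-1, -1] = 1.0
    return {
        "x": sx, "y": sy, "z": sz, "p": sp, "m": sm,
        "alpha": alpha, "beta": beta, "id": np.eye(n, dtype=complex),
    }


def embed(op: np.ndarray, index: int, dims: list[int]) -> np.ndarray:
    """Embed a single-spin operator at position ``index`` in the product space."""
    out = np.eye(1, dtype=complex)
    for i, d in enumerate(dims):
        out = np.kron(out, op if i == index else np.eye(d, dtype=complex))
    return out


def spin_op(kind: str, index: int, spins: list[float]) -> np.ndarray:
    """Product-space operator ``kind`` (x|y|z|p|m|alpha|beta) for one spin."""
    dims = [int(round(2 * s + 1)) for s in spins]
    return embed(spin_matrices(spins[index])[kind], index, dims)


_SPIN_RE = re.compile(r"^S(\d+)(x|y|z|p|m|alpha|beta)$")
_NUC_RE = re.compile(r"^((?:\d+[A-Za-z]+)|e-)(x|y|z|p|m)$")


def parse_operator(text: str, isotopes: list[str], spins: list[float]) -> np.ndarray:
    """Resolve an operator string to a product-basis matrix.

    Grammar: ``S<index><axis>`` acts on one spin; ``<isotope><axis>`` sums
    over every spin of the matching isotope (e.g. "1Hp" -> sum_i S_i^+).
    """
    m = _SPIN_RE.match(text)
    if m:
        idx = int(m.group(1))
        if idx >= len(spins):
            raise ValueError(f"spin index {idx} out of range in {text!r}")
        return spin_op(m.group(2), idx, spins)
    m = _NUC_RE.match(text)
    if m:
        label, axis = m.group(1), m.group(2)
        members = [i for i, iso in enumerate(isotopes) if iso == label]
        if not members:
            raise ValueError(f"isotope {label!r} absent from system ({text!r})")
        out = np.zeros((int(np.prod([2 * s + 1 for s in spins])),) * 2, dtype=complex)
        for i in members:
            out = out + spin_op(axis, i, spins)
        return out
    raise ValueError(f"cannot parse operator string {text!r}")


def vec(rho: np.ndarray) -> np.ndarray:
    """Column-stacking vectorization (columns collected one after the other)."""
    return rho.reshape(-1, order="F")


def unvec(v: np.ndarray) -> np.ndarray:
    d = int(round(np.sqrt(v.size)))
    return v.reshape(d, d, order="F")
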