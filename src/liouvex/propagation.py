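"""Propagators, sequences, the step cache, and exact basis reduction.

Propagation is piecewise-constant: the rotor period is discretized into
``n_gamma`` steps and additionally broken wherever an applied field's
amplitude, phase, or offset changes; each step uses the Liouvillian at
the step midpoint. Propagators are lazy (matrices are computed on first
use), can be composed and raised to powers through their
eigendecomposition (with numerical cleanup of eigenvalues), and
rotor-step propagators are recycled across the uniform gamma grid when

    (gamma - gamma')/dgamma mod M = (m' - m) mod M

and the RF state matches (per-field caches, LRU beyond 10 field states).
"""

from __future__ import annotations

import warnings
from collections import OrderedDict
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .defaults import Defaults
from .liouvillian import Liouvillian, commutator_superop, _blockdiag
from .hamiltonian import lab_rf_segments, resolve_channel, tensor_operators, _iso_hamiltonian
from .operators import spin_op, vec

_TOL = 1e-12


# ---------------------------------------------------------------------------
# sequences
# ---------------------------------------------------------------------------
class Sequence:
    """Piecewise-constant per-channel RF timeline.

    By default one rotor period long (spinning systems); static systems
    need an explicit duration. Channels are isotope labels or spin
    indices; segment values are (amplitude_Hz, phase_rad, offset_Hz).
    """

    def __init__(self, L: Liouvillian, duration: float | None = None):
        self.L = L
        if duration is None and not L.static:
            duration = L.rotor_period
        self.duration = duration
        self.channels: dict = {}
        self.steps_per_cycle = 2

    def add_channel(self, channel, t=None, amplitude=0.0, phase=0.0,
                    offset=0.0) -> "Sequence":
        """Constant field (scalars) or a breakpoint timeline (arrays).

        ``t`` lists segment start times (first 0); each segment holds
        until the next start or the sequence end.
        """
        resolve_channel(self.L.expsys, channel)  # validate early
        if t is None:
            t = [0.0]
            amplitude, phase, offset = [amplitude], [phase], [offset]
        else:
            t = [float(x) for x in t]
            k = len(t)
            amplitude = list(np.broadcast_to(amplitude, k).astype(float))
            phase = list(np.broadcast_to(phase, k).astype(float))
            offset = list(np.broadcast_to(offset, k).astype(float))
            if t[0] != 0.0:
                raise ValueError("first breakpoint must be t = 0")
            if any(b <= a for a, b in zip(t, t[1:])):
                raise ValueError("breakpoints must be strictly increasing")
            if self.duration is None:
                self.duration = t[-1]
        self.channels[channel] = (t, amplitude, phase, offset)
        if self.duration is None:
            raise ValueError("static sequences need an explicit duration")
        return self

    @property
    def breakpoints(self) -> np.ndarray:
        pts = {0.0}
        for t, *_ in self.channels.values():
            pts.update(x for x in t if 0.0 <= x < self.duration)
        return np.array(sorted(pts))

    def fields_at(self, tau: float) -> dict:
        out = {}
        for ch, (t, a, p, o) in self.channels.items():
            i = int(np.searchsorted(t, tau + _TOL) - 1)
            i = max(i, 0)
            out[ch] = (a[i], p[i], o[i])
        return out

    def field_key(self, tau: float):
        return (tuple(sorted((str(ch), *v) for ch, v in self.fields_at(tau).items())),
                self.steps_per_cycle)

    def __repr__(self):
        chs = ", ".join(str(c) for c in self.channels)
        return f"Sequence(duration={self.duration}, channels=[{chs}])"


# ---------------------------------------------------------------------------
# step cache
# ---------------------------------------------------------------------------
class PropCache:
    """Per-field-state cache of rotor-step propagators (LRU over fields)."""

    def __init__(self, max_fields: int | None = None):
        self.max_fields = max_fields or Defaults["n_field_cache"]
        self.caches: OrderedDict = OrderedDict()
        self.hits = 0
        self.misses = 0

    def _bucket(self, field_key):
        if field_key not in self.caches:
            if len(self.caches) >= self.max_fields:
                self.caches.popitem(last=False)
            self.caches[field_key] = {}
        self.caches.move_to_end(field_key)
        return self.caches[field_key]

    def get(self, field_key, step_key):
        m = self._bucket(field_key).get(step_key)
        if m is None:
            self.misses += 1
        else:
            self.hits += 1
        return m

    def put(self, field_key, step_key, mat):
        self._bucket(field_key)[step_key] = mat


# ---------------------------------------------------------------------------
# propagators
# ---------------------------------------------------------------------------
class Propagator:
    """Time-stamped evolution operator over all powder orientations.

    Lazy: matrices are computed on first use and stored. Supports
    composition (``U2 * U1``, U1 applied first), integer powers and
    ``U ** np.inf`` through the eigendecomposition.
    """

    def __init__(self, L: Liouvillian, t0: float, sequence: Sequence | None,
                 _mats=None, _factors=None, duration=None, reduced=False):
        self.L = L
        self.t0 = float(t0)
        self.sequence = sequence
        self.duration = float(sequence.duration if sequence is not None else duration)
        self._mats = _mats
        self._factors = _factors
        self._eig = None
        self.reduced = reduced
        if L.prop_cache is None:
            L.prop_cache = PropCache()

    # -- basic algebra -----------------------------------------------------
    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    @property
    def computed(self) -> bool:
        return self._mats is not None

    @property
    def matrices(self) -> list:
        if self._mats is None:
            if self._factors is not None:
                mats = [m.copy() for m in self._factors[0].matrices]
                for f in self._factors[1:]:
                    mats = [a @ b for a, b in zip(mats, f.matrices)]
                # factors stored application-last -> first; composed above
                self._mats = mats
            elif Defaults["parallel"] and self.L.n_orient > 1:
                from joblib import Parallel, delayed
                self._mats = Parallel(n_jobs=-1, backend="threading")(
                    delayed(self._build)(io) for io in range(self.L.n_orient))
            else:
                self._mats = [self._build(io) for io in range(self.L.n_orient)]
        return self._mats

    def __mul__(self, other):
        if isinstance(other, Propagator):
            if not _commensurate(other.t_end - self.t0, self.L.rotor_period):
                warnings.warn("propagator timing mismatch: first factor ends at "
                              f"t={other.t_end:.3e}s but second starts at "
                              f"t={self.t0:.3e}s (mod rotor period)")
            return Propagator(self.L, other.t0, None,
                              _factors=[self, other],
                              duration=self.duration + other.duration,
                              reduced=self.reduced)
        return NotImplemented

    def __pow__(self, n):
        if n is np.inf or (isinstance(n, str) and n == "inf") or \
                (isinstance(n, float) and np.isinf(n)):
            return self._power(None)
        if not float(n).is_integer() or n < 0:
            raise ValueError("propagator powers must be nonnegative integers or inf")
        return self._power(int(n))

    def eig(self):
        """Cleaned eigendecomposition [(w, V, Vinv), ...] per orientation."""
        if self._eig is None:
            self._eig = []
            for m in self.matrices:
                w, V = np.linalg.eig(m)
                w = eigen_cleanup_values(
                    w, thermalized=(self.L.thermal is not None
                                    and not self.reduced))
            # Vinv computed per orientation below
                self._eig.append((w, V, np.linalg.inv(V)))
        return self._eig

    def _power(self, n: int | None) -> "Propagator":
        if not self.L.static and not _commensurate(self.duration, self.L.rotor_period):
            raise ValueError("powers require a propagator spanning an integer "
                             "number of rotor periods")
        mats = []
        for (w, V, Vi) in self.eig():
            if n is None:
                d = np.where(np.abs(w - 1.0) < 1e-10, 1.0, 0.0)
                if d.sum() == 0:
                    d[np.argmin(np.abs(w - 1.0))] = 1.0
            else:
                d = w ** n
            mats.append((V * d) @ Vi)
        dur = self.duration * (n if n is not None else 1)
        return Propagator(self.L, self.t0, None, _mats=mats, duration=dur,
                          reduced=self.reduced)

    def project(self, rmap: "ReductionMap") -> "Propagator":
        mats = [rmap.project_mat(m) for m in self.matrices]
        return Propagator(self.L, self.t0, None, _mats=mats,
                          duration=self.duration, reduced=True)

    # -- construction ------------------------------------------------------
    def _build(self, io: int) -> np.ndarray:
        L = self.L
        seq = self.sequence
        t0, dur = self.t0, self.duration
        bounds = [t0, t0 + dur]
        if seq is not None and seq.channels:
            k0 = int(np.floor(t0 / seq.duration + _TOL))
            for rep in range(k0, int(np.ceil((t0 + dur) / seq.duration)) + 1):
                for bp in seq.breakpoints:
                    x = rep * seq.duration + bp
                    if t0 + _TOL < x < t0 + dur - _TOL:
                        bounds.append(x)
        if not L.static:
            dt = L.rotor_period / L.expsys.n_gamma
            k = int(np.floor(t0 / dt)) + 1
            while k * dt < t0 + dur - _TOL * dur - 1e-30:
                if k * dt > t0 + _TOL:
                    bounds.append(k * dt)
                k += 1
        bounds = _merge_close(np.sort(np.unique(bounds)), dur)
        U = np.eye(L.dim, dtype=complex)
        for a, b in zip(bounds[:-1], bounds[1:]):
            U = self._step(io, a, b) @ U
        return U

    def _step(self, io: int, a: float, b: float) -> np.ndarray:
        L = self.L
        seq = self.sequence
        tmid = 0.5 * (a + b)
        if seq is not None and seq.channels:
            tau = (tmid - self.t0) % seq.duration
            fields = seq.fields_at(tau)
            fkey = seq.field_key(tau)
            spc = seq.steps_per_cycle
        else:
            fields, fkey, spc = {}, ((), 2), 2
        cacheable = False
        step_key = None
        if Defaults["cache"] and not L.static:
            dt = L.rotor_period / L.expsys.n_gamma
            m = a / dt
            if (abs(m - round(m)) < 1e-6 and abs((b - a) - dt) < 1e-9 * dt):
                m = int(round(m)) % L.expsys.n_gamma
                g = L.gamma_idx[io]
                if g >= 0:
                    step_key = (int(L.orient_base[io]), (m + g) % L.expsys.n_gamma)
                else:
                    step_key = (io, m)
                cached = L.prop_cache.get(fkey, step_key)
                if cached is not None:
                    return cached
                cacheable = True
        mat = self._compute_step(io, tmid, b - a, fields, spc)
        if cacheable:
            L.prop_cache.put(fkey, step_key, mat)
        return mat

    def _compute_step(self, io, tmid, dt, fields, steps_per_cycle):
        L = self.L
        L_rf, plans = L.rf_superop(fields, steps_per_cycle)
        if not plans:
            return expm(L.L_at(io, tmid, L_rf) * dt)
        # lab-frame irradiation: square-wave one-carrier-cycle propagator,
        # raised to the (generally fractional) number of cycles in dt
        if len(plans) > 1:
            raise NotImplementedError("simultaneous lab-frame irradiation of "
                                      "multiple channels is not supported")
        plan = plans[0]
        durs, hams = lab_rf_segments(plan, L.expsys)
        T0 = durs.sum()
        Uc = np.eye(L.dim, dtype=complex)
        for dk, hk in zip(durs, hams):
            Lk = L.L_at(io, tmid, L_rf + _blockdiag(
                [commutator_superop(hk)] * L.N))
            Uc = expm(Lk * dk) @ Uc
        p = dt / T0
        if abs(p - round(p)) < 1e-9 and p < 1e6:
            return np.linalg.matrix_power(Uc, int(round(p)))
        w, V = np.linalg.eig(Uc)
        return (V * (w.astype(complex) ** p)) @ np.linalg.inv(V)

    def __repr__(self):
        return (f"Propagator(t0={self.t0:.3e}s, dur={self.duration:.3e}s, "
                f"{'computed' if self.computed else 'lazy'}"
                f"{', reduced' if self.reduced else ''})")


def eigen_cleanup_values(w: np.ndarray, thermalized: bool) -> np.ndarray:
    """Reset |lambda| > 1 to the unit circle; pin the near-1 eigenvalue.

    Roundoff can put eigenvalues marginally outside the unit circle (an
    unphysical growing mode); those are rescaled to modulus 1. For a
    thermalized, unreduced system exactly one eigenvalue must equal 1
    (the equilibrium), so the eigenvalue closest to 1 is set to 1.
    """
    w = np.asarray(w).astype(complex).copy()
    bad = np.abs(w) > 1.0
    w[bad] = w[bad] / np.abs(w[bad])
    if thermalized and w.size:
        w[np.argmin(np.abs(w - 1.0))] = 1.0
    return w


def power(U: Propagator, n) -> Propagator:
    return U ** n


def power_inf(U: Propagator) -> Propagator:
    return U ** np.inf


def _commensurate(x: float, period: float) -> bool:
    if not np.isfinite(period):
        return True
    r = (x / period) % 1.0
    return min(r, 1.0 - r) < 1e-6


def _merge_close(b: np.ndarray, scale: float) -> np.ndarray:
    out = [b[0]]
    for x in b[1:]:
        if x - out[-1] > 1e-12 * max(scale, 1e-30):
            out.append(x)
    return np.array(out)


# ---------------------------------------------------------------------------
# exact basis reduction
# ---------------------------------------------------------------------------
@dataclass
class ReductionMap:
    """Retained Liouville-basis indices and the projection maps."""

    indices: np.ndarray
    dim_full: int

    @property
    def dim(self) -> int:
        return self.indices.size

    def project_vec(self, v: np.ndarray) -> np.ndarray:
        return np.asarray(v)[..., self.indices]

    def project_mat(self, m: np.ndarray) -> np.ndarray:
        return np.asarray(m)[np.ix_(self.indices, self.indices)]

    def lift_vec(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros(v.shape[:-1] + (self.dim_full,), dtype=complex)
        out[..., self.indices] = v
        return out


def _site_h_pattern(L: Liouvillian, sequences) -> np.ndarray:
    d = L.dim_H
    pat = np.zeros((d, d), dtype=bool)
    tol = 1e-12
    for site in L.sites:
        for inter in site.interactions:
            for Tq in tensor_operators(site, inter):
                pat |= np.abs(Tq) > tol
            iso = _iso_hamiltonian(site, inter)
            if iso is not None:
                pat |= np.abs(iso) > tol
    sys_ = L.expsys
    active = set()
    for seq in sequences or []:
        for ch, (t, amps, phases, offs) in seq.channels.items():
            if any(a != 0 for a in amps) or any(o != 0 for o in offs):
                active.update(resolve_channel(sys_, ch))
    for i in active:
        for ax in "xyz":
            pat |= np.abs(spin_op(ax, i, sys_.spins)) > tol
    for i, fr in enumerate(sys_.frames):
        if fr == "lab":
            pat |= np.abs(spin_op("z", i, sys_.spins)) > tol
    return pat


def coupling_pattern(L: Liouvillian, sequences=None) -> np.ndarray:
    """Boolean superset of the nonzero pattern of every applied superoperator."""
    d = L.dim_H
    hp = _site_h_pattern(L, sequences)
    eye = np.eye(d, dtype=bool)
    lp = np.kron(eye, hp) | np.kron(hp.T, eye)
    if any(s["OS"] for s in L.relax_specs):
        # eigenbasis relaxation patterns are orientation dependent; be exact
        # by keeping the whole site block connected
        lp |= True
    full = np.zeros((L.dim, L.dim), dtype=bool)
    for i in range(L.N):
        sl = slice(i * L.dim_site, (i + 1) * L.dim_site)
        full[sl, sl] = lp
    full |= np.kron(np.abs(L.kex) > 1e-30, np.eye(L.dim_site, dtype=bool))
    for term in L.spin_exchange_terms:
        tp = np.abs(term) > 1e-30
        for i in range(L.N):
            sl = slice(i * L.dim_site, (i + 1) * L.dim_site)
            full[sl, sl] |= tp
    if L.relax_specs:
        full |= np.abs(L.relax_superop(0, 0.0)) > 1e-30
    if L.thermal == "dynamic":
        rho_pat = (np.abs(L.rho_eq(0)) > 1e-30).astype(int)
        rows = (full.astype(int) @ rho_pat) > 0
        full[np.ix_(rows, L.identity_columns())] = True
    return full


def reduce_basis(L: Liouvillian, rho0_vec: np.ndarray, det_vecs,
                 sequences=None) -> ReductionMap:
    """Block-diagonalize and keep blocks touching rho0 and a detector.

    The combined sparsity pattern of every superoperator (coherent
    components over the Zeeman product basis, RF fields of the supplied
    sequences, exchange, relaxation, thermalization) is split into
    connected components; components that do not overlap nonzero elements
    of both the initial density matrix and at least one detector are
    discarded. Detected signals are identical to the full-space ones.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    pat = coupling_pattern(L, sequences)
    sym = pat | pat.T
    n_comp, labels = connected_components(csr_matrix(sym), directed=False)
    rho_sup = np.abs(np.asarray(rho0_vec)) > 1e-14
    det_sup = np.zeros(L.dim, dtype=bool)
    for dv in det_vecs:
        det_sup |= np.abs(np.asarray(dv)) > 1e-14
    keep = []
    for c in range(n_comp):
        mask = labels == c
        if (rho_sup & mask).any() and (det_sup & mask).any():
            keep.append(c)
    if not keep:
        raise ValueError(
            "basis reduction found no block connecting the initial density "
            "matrix to any detection operator; rho0 and the detectors live "
            "in disconnected subspaces")
    idx = np.flatnonzero(np.isin(labels, keep))
    return ReductionMap(idx, L.dim)
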