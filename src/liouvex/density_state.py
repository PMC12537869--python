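"""Density matrices, detection, the detect-propagate driver, spectra.

Detection follows <O>(t) = vec(O)^dag . vec(rho(t)) (the detector is
complex-transposed before vectorization), summed over powder
orientations with their weights. Operator strings resolve either to one
spin ("S0x", "S1p", ...) or to the sum over all spins of an isotope
("13Cx", "1Hp", ...).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .liouvillian import Liouvillian, _stationary
from .operators import parse_operator, vec
from .propagation import Propagator, Sequence, ReductionMap, reduce_basis

__all__ = ["DensityMatrix", "SignalTable", "detect", "downmix", "spectrum"]


def _resolve(op, system) -> np.ndarray:
    """Operator string or matrix -> Hilbert-space matrix."""
    if isinstance(op, str):
        return parse_operator(op, system.isotopes, system.spins)
    m = np.asarray(op, dtype=complex)
    if m.shape != (system.dim_H, system.dim_H):
        raise ValueError(f"operator matrix must be {system.dim_H}x{system.dim_H}")
    return m


def detect(state_vec: np.ndarray, detector_vec: np.ndarray) -> complex:
    """Raw Liouville-space detection: conj(detector) . state."""
    if state_vec.shape[-1] != detector_vec.shape[-1]:
        raise ValueError("dimension mismatch between state and detector")
    return complex(np.conj(detector_vec) @ state_vec)


@dataclass
class SignalTable:
    """Detected time-domain signals, one complex column per detector."""

    t: np.ndarray
    data: dict = field(default_factory=dict)  # name -> complex array

    def __getitem__(self, name):
        return self.data[name]

    @property
    def names(self):
        return list(self.data)

    def to_csv(self, path):
        names = self.names
        with open(path, "w") as fh:
            fh.write("t_s," + ",".join(f"{n}_re,{n}_im" for n in names) + "\n")
            for i, t in enumerate(self.t):
                row = [f"{t:.9e}"]
                for n in names:
                    z = self.data[n][i]
                    row += [f"{z.real:.9e}", f"{z.imag:.9e}"]
                fh.write(",".join(row) + "\n")


class DensityMatrix:
    """Vectorized density matrix over sites and powder orientations.

    The initial operator is replicated across exchange sites weighted by
    the stationary site populations. ``thermal=True`` starts from the
    thermal equilibrium state instead.
    """

    def __init__(self, L: Liouvillian, rho0, detect, thermal: bool = False):
        self.L = L
        self.rho0_spec = rho0
        self.detect_specs = [detect] if isinstance(detect, (str, np.ndarray)) \
            else list(detect)
        self.thermal = thermal
        det_site = [vec(_resolve(d, L.expsys)) for d in self.detect_specs]
        self._det_full = [np.tile(dv, L.N) for dv in det_site]
        self._map: ReductionMap | None = None
        self.reset()

    # -- state handling ----------------------------------------------------
    def _initial_states(self) -> np.ndarray:
        L = self.L
        if self.thermal:
            return np.stack([L.rho_eq(io) for io in range(L.n_orient)])
        r = vec(_resolve(self.rho0_spec, L.expsys))
        p = _stationary(L.kex)
        full = np.concatenate([p[i] * r for i in range(L.N)])
        return np.tile(full, (L.n_orient, 1))

    def reset(self):
        """Return to the initial state at t = 0 and clear stored signals."""
        states = self._initial_states().astype(complex)
        s = self.L.state_scale
        if s is not None:
            states = states * s
        if self._map is not None:
            states = self._map.project_vec(states)
        self.states = states
        self.t = 0.0
        self._t_list: list[float] = []
        self._sig: list[np.ndarray] = []
        return self

    @property
    def detectors(self) -> list[np.ndarray]:
        dets = self._det_full
        s = self.L.state_scale
        if s is not None:
            # states carry the scale; undo it inside the dot product
            dets = [d / s for d in dets]
        if self._map is not None:
            dets = [self._map.project_vec(d) for d in dets]
        return dets

    # -- reduction ---------------------------------------------------------
    def reduced_setup(self, sequences=None) -> ReductionMap:
        """Activate exact basis reduction for manual propagation loops."""
        if self._map is None:
            rho0 = self._initial_states()[0]
            self._map = reduce_basis(self.L, rho0, self._det_full,
                                     sequences=sequences)
            self.states = self._map.project_vec(self.states)
        return self._map

    # -- detection / propagation -------------------------------------------
    def detect_now(self) -> np.ndarray:
        """Powder-weighted expectation value of every detector."""
        w = self.L.weight
        out = np.empty(len(self.detectors), dtype=complex)
        for i, d in enumerate(self.detectors):
            out[i] = (w * (self.states @ np.conj(d))).sum()
        return out

    def __call__(self) -> np.ndarray:
        vals = self.detect_now()
        self._t_list.append(self.t)
        self._sig.append(vals)
        return vals

    def prop(self, U) -> "DensityMatrix":
        """Apply a propagator (or sequence, converted at the current time)."""
        if isinstance(U, Sequence):
            U = Propagator(self.L, self.t, U)
        if not _close_mod(U.t0, self.t, self.L.rotor_period):
            warnings.warn(f"propagator starts at t={U.t0:.3e}s but the density "
                          f"matrix is at t={self.t:.3e}s (mod rotor period)")
        mats = U.matrices
        if self._map is not None and not U.reduced:
            mats = [self._map.project_mat(m) for m in mats]
        for io in range(self.states.shape[0]):
            self.states[io] = mats[io] @ self.states[io]
        self.t += U.duration
        return self

    # -- the DetProp driver --------------------------------------------------
    def det_prop(self, U, n: int = 1, reduce: bool = True) -> SignalTable:
        """Repeated detect-then-propagate, with reduction by default.

        ``U`` may be a Propagator (eigenbasis path when it spans an
        integer number of rotor periods) or a Sequence (stepwise loop
        with propagators memoized per rotor phase).
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        L = self.L
        if reduce and self._map is None:
            seqs = [U] if isinstance(U, Sequence) else \
                ([U.sequence] if U.sequence is not None else None)
            try:
                self.reduced_setup(sequences=seqs)
            except ValueError:
                raise
        if isinstance(U, Propagator):
            use_eig = L.static or _int_rotor(U.duration, L.rotor_period)
            if not use_eig:
                warnings.warn("propagator does not span integer rotor periods;"
                              " falling back to stepwise propagation")
                return self._det_prop_loop(U, n)
            return self._det_prop_eig(U, n)
        return self._det_prop_loop(U, n)

    def _det_prop_eig(self, U: Propagator, n: int) -> SignalTable:
        if self._map is not None and not U.reduced:
            U = U.project(self._map)
        sig = np.zeros((len(self.detectors), n), dtype=complex)
        w = self.L.weight
        from .propagation import eigen_cleanup_values
        for io in range(self.states.shape[0]):
            vals, V = np.linalg.eig(U.matrices[io])
            vals = eigen_cleanup_values(
                vals, thermalized=(self.L.thermal is not None and
                                   self._map is None and not U.reduced))
            Vi = np.linalg.inv(V)
            c = Vi @ self.states[io]
            powers = vals[None, :] ** np.arange(n)[:, None]  # (n, dim)
            for i, d in enumerate(self.detectors):
                row = np.conj(d) @ V  # (dim,)
                sig[i] += w[io] * (powers * (row * c)[None, :]).sum(axis=1)
            self.states[io] = V @ (vals ** n * c)
        t = self.t + U.duration * np.arange(n)
        self.t += U.duration * n
        return self._store(t, sig)

    def _det_prop_loop(self, seq_or_U, n: int) -> SignalTable:
        L = self.L
        cache: dict = {}
        sig = np.zeros((len(self.detectors), n), dtype=complex)
        t = np.empty(n)
        for k in range(n):
            t[k] = self.t
            sig[:, k] = self.detect_now()
            if isinstance(seq_or_U, Sequence):
                key = L._phase_key(self.t)
                U = cache.get(key)
                if U is None:
                    U = Propagator(L, self.t, seq_or_U)
                    if self._map is not None:
                        U = U.project(self._map)
                    U.matrices  # force
                    cache[key] = U
                else:
                    U = Propagator(L, self.t, None, _mats=U.matrices,
                                   duration=U.duration, reduced=U.reduced)
            else:
                U = seq_or_U
            self.prop(U)
        return self._store(t, sig)

    def _store(self, t, sig) -> SignalTable:
        names = [s if isinstance(s, str) else f"det{i}"
                 for i, s in enumerate(self.detect_specs)]
        for tt, col in zip(t, sig.T):
            self._t_list.append(tt)
            self._sig.append(col)
        return SignalTable(np.asarray(t), dict(zip(names, sig)))

    @property
    def table(self) -> SignalTable:
        names = [s if isinstance(s, str) else f"det{i}"
                 for i, s in enumerate(self.detect_specs)]
        sig = np.array(self._sig).T if self._sig else \
            np.zeros((len(names), 0), complex)
        return SignalTable(np.asarray(self._t_list), dict(zip(names, sig)))


def downmix(table: SignalTable, f_ref: float) -> SignalTable:
    """Demodulate lab-frame signals at a reference frequency (Hz)."""
    t = table.t
    ph = np.exp(2j * np.pi * f_ref * t)
    return SignalTable(t.copy(), {k: v * ph for k, v in table.data.items()})


def spectrum(table: SignalTable, name=None, zero_fill: int | None = None,
             lb: float = 0.0):
    """FFT spectrum of one detector column.

    First point halved; optional exponential apodization ``lb`` (Hz) and
    zero filling. Returns (freq_Hz, complex spectrum).
    """
    t = table.t
    if t.size < 2:
        raise ValueError("need at least two points")
    dt = np.diff(t)
    if np.abs(dt - dt[0]).max() > 1e-9 * dt[0]:
        raise ValueError("spectrum requires a uniform time grid")
    name = name or table.names[0]
    s = table.data[name].astype(complex).copy()
    if lb:
        s *= np.exp(-np.pi * lb * (t - t[0]))
    s[0] *= 0.5
    npts = zero_fill or s.size
    spec = np.fft.fftshift(np.fft.fft(s, n=npts))
    freq = np.fft.fftshift(np.fft.fftfreq(npts, d=dt[0]))
    # sign convention: a coherence evolving as e^{-i 2 pi nu t} (isotropic
    # shift +nu) appears at +nu on the frequency axis
    return -freq[::-1], spec[::-1]


def _close_mod(a, b, period):
    if not np.isfinite(period):
        return True
    r = ((a - b) / period) % 1.0
    return min(r, 1 - r) < 1e-6


def _int_rotor(duration, period):
    if not np.isfinite(period):
        return True
    r = (duration / period) % 1.0
    return min(r, 1 - r) < 1e-6
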