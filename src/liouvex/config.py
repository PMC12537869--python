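"""Declarative (YAML/dict) simulation configurations.

Angles are degrees and frequencies Hz in configs; the library API uses
radians internally. See :mod:`liouvex.fixtures` for worked examples of
the schema.
"""

from __future__ import annotations

import numpy as np
import yaml

from .liouvillian import Liouvillian, two_site_kex
from .density_state import DensityMatrix, SignalTable
from .propagation import Sequence
from .spin_system import SpinSystem
from .tumbling import setup_tumbling

__all__ = ["load_config", "build_system", "build_liouvillian",
           "build_sequence", "run_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _euler_rad(euler_deg):
    return [tuple(np.radians(e)) for e in (euler_deg or [])]


def build_system(cfg: dict) -> SpinSystem:
    sc = cfg["system"]
    powder = sc.get("powder", "JCP59")
    pk = {}
    if isinstance(powder, dict):
        powder, pk = powder["name"], {k: v for k, v in powder.items()
                                      if k != "name"}
    rotor = sc.get("rotor_angle_deg")
    sys_ = SpinSystem(
        B0=sc["B0"], isotopes=sc["isotopes"], vr=sc.get("vr", 0.0),
        rotor_angle=np.radians(rotor) if rotor is not None else None,
        n_gamma=sc.get("n_gamma", 30), T=sc.get("T", 298.0),
        frames=sc.get("frames"), powder=powder, powder_kwargs=pk,
        gamma_encoded=sc.get("gamma_encoded"))
    for it in sc.get("interactions", []):
        sys_.add_interaction(it["kind"], tuple(it["spins"]),
                             delta=it.get("delta", 0.0),
                             eta=it.get("eta", 0.0),
                             euler=_euler_rad(it.get("euler_deg")),
                             iso=it.get("iso", 0.0))
    return sys_


def build_liouvillian(cfg: dict) -> Liouvillian:
    base = build_system(cfg)
    if "tumbling" in cfg:
        tc = cfg["tumbling"]
        L = setup_tumbling(base, tc["tauc"],
                           angles=tuple(tc.get("angles",
                                               ("alpha", "beta", "gamma"))),
                           q=tc.get("q", 3), solid=tc.get("solid", False))
    else:
        sites = [base]
        for mods in cfg.get("sites", []):
            cp = base
            for m in mods:
                cp = cp.modified_copy(
                    m["interaction"], delta=m.get("delta"),
                    eta=m.get("eta"), iso=m.get("iso"),
                    euler=_euler_rad(m["euler_deg"]) if "euler_deg" in m else None)
            sites.append(cp)
        kex = None
        exc = cfg.get("exchange")
        if exc:
            if "matrix" in exc:
                kex = np.asarray(exc["matrix"], float)
            else:
                kex = two_site_kex(exc["tauc"], exc.get("p1", 0.5))
        L = Liouvillian(sites, kex=kex)
    for r in cfg.get("relax", []):
        L.add_relax(r["kind"], spin=r.get("spin"), value=r.get("value"),
                    OS=r.get("OS", False))
    therm = cfg.get("thermalization", "none")
    if therm == "lindblad":
        L.add_relax("Thermal")
    elif therm == "dynamic":
        L.add_relax("DynamicThermal")
    return L


def build_sequence(L: Liouvillian, cfg: dict, key: str = "sequence") -> Sequence:
    sc = cfg.get(key) or {}
    seq = Sequence(L, duration=sc.get("duration"))
    for ch in sc.get("channels", []):
        t = ch.get("t")
        phase = ch.get("phase_deg", 0.0)
        phase = np.radians(phase).tolist() if t is not None else \
            float(np.radians(phase))
        seq.add_channel(ch["channel"], t=t,
                        amplitude=ch.get("amplitude", 0.0),
                        phase=phase, offset=ch.get("offset", 0.0))
    if "steps_per_cycle" in sc:
        seq.steps_per_cycle = int(sc["steps_per_cycle"])
    return seq


def run_config(cfg: dict) -> SignalTable:
    """Build everything and run the detect-propagate driver."""
    L = build_liouvillian(cfg)
    seq = build_sequence(L, cfg)
    rho = DensityMatrix(L, cfg.get("initial", "S0x"),
                        cfg.get("detect", ["S0p"]),
                        thermal=cfg.get("thermal_start", False))
    n = int(cfg.get("n", 1))
    return rho.det_prop(seq, n=n, reduce=cfg.get("reduce", True))
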