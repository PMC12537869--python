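"""Canned example experiments as declarative configs.

Parameter values not dictated by physics (couplings, shift differences,
field strengths) are explicit, representative defaults chosen from
typical literature ranges; treat them as a starting point, not as
reference data.
"""

from __future__ import annotations

import copy


def fixtures() -> dict:
    """Named configuration dictionaries for the packaged examples."""
    figs = {}

    # 13C R1rho from a 15-degree hop of a 1H-13C dipole, tau_c = 1 us,
    # continuous spin-lock on 13C under MAS.
    figs["fig1_r1rho"] = {
        "system": {
            "B0": 9.4, "isotopes": ["1H", "13C"], "vr": 10e3, "n_gamma": 30,
            "T": 298.0,
            "powder": {"name": "JCP59", "q": 2},
            "interactions": [
                {"kind": "dipole", "spins": [0, 1], "delta": 44e3,
                 "euler_deg": [[0, 0, 0]]},
            ],
        },
        "sites": [[{"interaction": 0, "euler_deg": [[0, 15, 0]]}]],
        "exchange": {"tauc": 1e-6, "p1": 0.5},
        "sequence": {"channels": [
            # 50 kHz lock = 5 nutation cycles per rotor period, so the
            # rotor-synchronized detection hides the rotary transients
            {"channel": "13C", "amplitude": 50e3, "phase_deg": 0.0},
        ]},
        "initial": "13Cx", "detect": ["13Cp"], "n": 4000,
    }

    # RECRR building blocks: one-rotor-period +-x spin locks and
    # two-rotor-period refocusing blocks with a centered pi pulse.
    tr = 1.0 / 10e3
    recrr = copy.deepcopy(figs["fig1_r1rho"])
    recrr["n"] = 1
    recrr["sequences"] = {
        "cwx": {"channels": [
            {"channel": "13C", "amplitude": 25e3, "phase_deg": 0.0}]},
        "cwmx": {"channels": [
            {"channel": "13C", "amplitude": 25e3, "phase_deg": 180.0}]},
        # pi pulse (10 us at 50 kHz) centered in 2 rotor periods, phase +y
        "refA": {"duration": 2 * tr, "channels": [
            {"channel": "13C", "t": [0.0, tr - 5e-6, tr + 5e-6],
             "amplitude": [25e3, 50e3, 25e3],
             "phase_deg": [0.0, 90.0, 0.0]}]},
        "refB": {"duration": 2 * tr, "channels": [
            {"channel": "13C", "t": [0.0, tr - 5e-6, tr + 5e-6],
             "amplitude": [25e3, 50e3, 25e3],
             "phase_deg": [180.0, 90.0, 180.0]}]},
    }
    figs["recrr"] = recrr

    # EXSY-style asymmetric chemical-shift exchange, single 13C.
    figs["exsy"] = {
        "system": {
            "B0": 9.4, "isotopes": ["13C"], "vr": 0.0,
            "powder": "alpha0beta0",
            "interactions": [{"kind": "cs", "spins": [0], "iso": -200.0}],
        },
        "sites": [[{"interaction": 0, "iso": 200.0}]],
        "exchange": {"tauc": 20e-3, "p1": 0.7},
        "relax": [{"kind": "T2", "spin": 0, "value": 0.05}],
        "sequence": {"duration": 1e-3},
        "initial": "S0p", "detect": ["S0p"], "n": 512,
    }

    # CEST: dilute site 1 kHz away, weak saturation field.
    figs["cest"] = {
        "system": {
            "B0": 9.4, "isotopes": ["13C"], "vr": 0.0,
            "powder": "alpha0beta0",
            "interactions": [{"kind": "cs", "spins": [0], "iso": 0.0}],
        },
        "sites": [[{"interaction": 0, "iso": 1000.0}]],
        "exchange": {"tauc": 10e-3, "p1": 0.9},
        "relax": [{"kind": "T2", "spin": 0, "value": 0.02},
                  {"kind": "T1", "spin": 0, "value": 1.0}],
        "thermalization": "lindblad",
        "saturation": {"amplitude": 25.0, "time": 0.5},
        "initial": "S0z", "detect": ["S0z"],
    }

    # T1/NOE from three-angle tumbling of an 15N-1H pair in the lab frame.
    figs["noe_t1_tumbling"] = {
        "system": {
            "B0": 14.1, "isotopes": ["15N", "1H"], "vr": 0.0,
            "frames": ["lab", "lab"],
            "interactions": [
                {"kind": "dipole", "spins": [0, 1], "delta": 22e3},
            ],
        },
        "tumbling": {"angles": ["alpha", "beta", "gamma"], "q": 2,
                     "tauc": 2e-9},
        "thermalization": "dynamic",
        "initial": "15Nz", "detect": ["15Nz", "1Hz"],
        "sequence": {"duration": 10e-3}, "n": 200,
    }

    # REDOR-style dephasing: 15N-1H dipole hopping between two sites,
    # rotor-synchronized pi pulses on 1H (centers of each half period).
    vr = 10e3
    tr = 1.0 / vr
    tp = 4e-6  # pi at 125 kHz
    figs["redor_2site"] = {
        "system": {
            "B0": 14.1, "isotopes": ["15N", "1H"], "vr": vr, "n_gamma": 30,
            "powder": {"name": "JCP59", "q": 2},
            "interactions": [
                {"kind": "dipole", "spins": [0, 1], "delta": 2e3,
                 "euler_deg": [[0, 0, 0]]},
            ],
        },
        "sites": [[{"interaction": 0, "euler_deg": [[0, 30, 0]]}]],
        "exchange": {"tauc": 1e-4, "p1": 0.5},
        "sequence": {"duration": tr, "channels": [
            {"channel": "1H",
             "t": [0.0, tr / 4 - tp / 2, tr / 4 + tp / 2,
                   3 * tr / 4 - tp / 2, 3 * tr / 4 + tp / 2],
             "amplitude": [0.0, 125e3, 0.0, 125e3, 0.0],
             "phase_deg": [0.0, 0.0, 0.0, 90.0, 0.0]}]},
        "initial": "15Nx", "detect": ["15Nx"], "n": 64,
    }

    # Pseudocontact shift in solution: anisotropic g electron + 1H,
    # 10-orientation tumbling, eigenbasis relaxation on the electron,
    # Lindblad thermalization.
    # The electron must relax faster than the tumbling so its polarization
    # follows the orientation-dependent (g-tilted) quantization axis.
    figs["pcs_solution"] = {
        "system": {
            "B0": 3.0, "isotopes": ["e-", "1H"], "vr": 0.0,
            "frames": ["lab", "lab"], "T": 290.0,
            "interactions": [
                {"kind": "g", "spins": [0], "delta": 0.5, "eta": 0.0},
                {"kind": "hyperfine", "spins": [0, 1], "delta": 5e6,
                 "euler_deg": [[0, 90, 0]]},
            ],
        },
        "tumbling": {"angles": ["alpha", "beta"], "q": 2, "tauc": 50e-12},
        "relax": [{"kind": "T2", "spin": 0, "value": 2e-12, "OS": True},
                  {"kind": "T1", "spin": 0, "value": 2e-12, "OS": True}],
        "thermalization": "lindblad",
        "initial": "1Hx", "detect": ["1Hp"],
    }

    pcs_mas = copy.deepcopy(figs["pcs_solution"])
    pcs_mas["system"]["vr"] = 10e3
    pcs_mas["system"]["n_gamma"] = 30
    pcs_mas["system"]["powder"] = {"name": "JCP59", "q": 2}
    pcs_mas["tumbling"]["solid"] = True
    figs["pcs_mas"] = pcs_mas

    return figs
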