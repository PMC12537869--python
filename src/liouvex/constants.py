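"""Physical constants (SI) and the packaged isotope table."""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

HBAR = 1.054571817e-34   # J s
KB = 1.380649e-23        # J/K
MU_B = 9.2740100783e-24  # J/T, Bohr magneton
H_PLANCK = 6.62607015e-34
G_E = 2.00231930436      # free-electron g factor


@dataclass(frozen=True)
class IsotopeSpec:
    """One entry of the isotope table.

    Attributes
    ----------
    label : str
        e.g. "1H", "13C", "15N", "e-".
    spin : float
        Spin quantum number (half-integer or integer, >= 1/2).
    gamma : float
        Gyromagnetic ratio in rad s^-1 T^-1 (signed).
    """

    label: str
    spin: float
    gamma: float

    @property
    def multiplicity(self) -> int:
        return int(round(2 * self.spin + 1))


def _load_table() -> dict[str, IsotopeSpec]:
    text = resources.files("liouvex").joinpath("data/isotopes.json").read_text()
    raw = json.loads(text)
    return {k: IsotopeSpec(k, v["spin"], v["gamma"]) for k, v in raw.items()}


ISOTOPES: dict[str, IsotopeSpec] = _load_table()


def isotope(label: str) -> IsotopeSpec:
    """Resolve an isotope label against the packaged table."""
    try:
        return ISOTOPES[label]
    except KeyError:
        raise KeyError(
            f"unknown isotope label {label!r}; known: {sorted(ISOTOPES)}"
        ) from None
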