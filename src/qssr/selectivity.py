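"""Enantiomeric ratio <-> free-energy selectivity conversion.

Under transition-state theory the enantiomer distribution of a kinetically
controlled reaction reflects the difference in activation free energies of
the two diastereomeric pathways:

    ddG = R * T * ln(er_major / er_minor)

The regression response is this ddG (kcal/mol), taken as a magnitude: the
major enantiomer is whichever is formed in excess, and its identity is
metadata rather than a sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import math

GAS_CONSTANT_KCAL = 1.98720425864083e-3  # kcal / (mol K)
DEFAULT_TEMPERATURE = 298.15  # K, room-temperature catalysis

__all__ = [
    "GAS_CONSTANT_KCAL",
    "DEFAULT_TEMPERATURE",
    "SelectivityRecord",
    "er_to_ddg",
    "ddg_to_er",
]


def er_to_ddg(
    er_major: float, er_minor: float, temperature: float = DEFAULT_TEMPERATURE
) -> float:
    """ddG (kcal/mol) from an enantiomeric ratio given as percentages.

    ``er_major``/``er_minor`` must sum to 100 (e.g. 97.5 and 2.5) with the
    major component first; a racemate (50:50) maps to exactly 0.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if er_minor <= 0:
        raise ValueError(
            "er_minor must be > 0: an infinitely selective reaction has no "
            "finite ddG"
        )
    if er_major < er_minor:
        raise ValueError(
            "er_major < er_minor: pass the major enantiomer first "
            "(swap the two percentages)"
        )
    if abs(er_major + er_minor - 100.0) > 1e-9:
        raise ValueError(
            f"e.r. percentages must sum to 100, got {er_major} + {er_minor}"
        )
    return GAS_CONSTANT_KCAL * temperature * math.log(er_major / er_minor)


def ddg_to_er(
    ddg: float, temperature: float = DEFAULT_TEMPERATURE
) -> tuple[float, float]:
    """Inverse of :func:`er_to_ddg`: (er_major, er_minor) percentages."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (kelvin)")
    if ddg < 0:
        raise ValueError("ddG must be >= 0 (major over minor convention)")
    ratio = math.exp(ddg / (GAS_CONSTANT_KCAL * temperature))
    er_major = 100.0 * ratio / (1.0 + ratio)
    return er_major, 100.0 - er_major


@dataclass(frozen=True)
class SelectivityRecord:
    """An experimental e.r. with its derived free-energy response."""

    er_major: float
    er_minor: float
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        # er_to_ddg performs the full invariant check
        er_to_ddg(self.er_major, self.er_minor, self.temperature)

    @property
    def ddg(self) -> float:
        return er_to_ddg(self.er_major, self.er_minor, self.temperature)
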