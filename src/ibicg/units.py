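"""Physical constants and the unit system shared by every module.

The toolkit works in GROMACS-consistent molecular-dynamics units
throughout: length in nm, time in ps, mass in amu (g/mol), energy in
kJ/mol and temperature in K.  In this system the acceleration obtained
from F/m with F in kJ/(mol nm) and m in amu comes out directly in
nm/ps^2, so no hidden conversion factors appear anywhere in the
integrator.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Boltzmann constant in kJ/(mol K), GROMACS value.
KB = 0.0083144621


@dataclass(frozen=True)
class UnitSystem:
    """Record of the unit convention; informational, not converted."""

    length: str = "nm"
    time: str = "ps"
    mass: str = "amu"
    energy: str = "kJ/mol"
    temperature: str = "K"
    kB: float = KB


UNITS = UnitSystem()


def thermal_energy(T: float) -> float:
    """Return kB*T in kJ/mol for an absolute temperature T in K.

    Raises
    ------
    ValueError
        If T is not strictly positive.
    """
    if T <= 0:
        raise ValueError(f"temperature must be positive, got {T} K")
    return KB * T


def beta(T: float) -> float:
    """Return 1/(kB*T) in mol/kJ; the inverse thermal energy."""
    return 1.0 / thermal_energy(T)
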