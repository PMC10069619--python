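"""Physical constants and the repo-wide unit conventions.

All quantities in the package use one fixed unit system:

* length        — nanometre (nm)
* time          — microsecond (µs); the Monte Carlo step is 1 µs
* diffusivity   — nm²/µs  (numerically identical to µm²/s)
* concentration — micromolar (µM) at API surfaces, molar internally
* rate          — s⁻¹ (per-step probabilities are converted with the step)

Every conversion between these and the mixed literature units
(µm²/s, mM⁻¹s⁻¹, kDa …) goes through the helpers below.
"""

from __future__ import annotations

#: Avogadro's number, 1/mol.
N_AVOGADRO = 6.02214076e23

#: Litres per cubic nanometre.
LITRE_PER_NM3 = 1e-24

#: Microseconds per second.
US_PER_S = 1e6


def molar_to_per_nm3(concentration_molar: float) -> float:
    """Convert a molar concentration to a number density in nm⁻³."""
    return concentration_molar * N_AVOGADRO * LITRE_PER_NM3


def per_nm3_to_molar(density_per_nm3: float) -> float:
    """Convert a number density in nm⁻³ to a molar concentration."""
    return density_per_nm3 / (N_AVOGADRO * LITRE_PER_NM3)


def micromolar_to_molar(concentration_um: float) -> float:
    return concentration_um * 1e-6


def molar_to_micromolar(concentration_m: float) -> float:
    return concentration_m * 1e6


def per_step_to_per_second(p: float, time_step_us: float) -> float:
    """Convert a per-step probability to an equivalent rate in s⁻¹."""
    return p / (time_step_us / US_PER_S)


def per_second_to_per_step(rate_s: float, time_step_us: float) -> float:
    """Convert a rate in s⁻¹ to a per-step probability (small-p regime)."""
    return rate_s * (time_step_us / US_PER_S)
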