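"""Physical constants and unit conventions.

All energies inside the package are **molar** (J/mol) and all temperatures
are kelvin.  The literature on channel gating often writes per-molecule
energies with the Boltzmann constant k_B; the two conventions differ by
Avogadro's number and are interconvertible with the helpers below.
Voltages are millivolts, rates are 1/s.
"""

from __future__ import annotations

#: Gas constant R [J/(mol K)] (CODATA 2018, exact).
R_GAS = 8.31446261815324

#: Boltzmann constant k_B [J/K] (exact).
K_BOLTZMANN = 1.380649e-23

#: Avogadro constant [1/mol] (exact).
N_AVOGADRO = 6.02214076e23

#: Absolute zero offset for Celsius <-> kelvin conversion.
CELSIUS_OFFSET = 273.15


def per_molecule_to_molar(energy_j: float) -> float:
    """Convert a per-molecule energy [J] to a molar energy [J/mol]."""
    return energy_j * N_AVOGADRO


def molar_to_per_molecule(energy_j_mol: float) -> float:
    """Convert a molar energy [J/mol] to a per-molecule energy [J]."""
    return energy_j_mol / N_AVOGADRO


def celsius_to_kelvin(t_c: float) -> float:
    """Celsius is accepted only at I/O boundaries; internals are kelvin."""
    return t_c + CELSIUS_OFFSET


def kelvin_to_celsius(t_k: float) -> float:
    return t_k - CELSIUS_OFFSET
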