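"""Eyring rate laws and the gating energy epsilon(T).

The open/closed transition rates follow an attempt-frequency/barrier form

    k_{o,c}(T) = nu0 * exp(-dG_{o,c} / (R*T)),

with a linear voltage correction k(0)*(1 - beta*Vs) for a small driving
signal Vs on top of the static holding voltage V0.  The temperature
sensitivity of the channel is carried by the free-energy asymmetry between
the open and closed conformations

    epsilon(T) = dH - T*dS + R*T*ln(1 + k_c1(T)*tau_r),

whose last term is the non-Markovian memory correction: k_c1 is the exit
rate of the deep closed state and tau_r the relaxation (memory) time of the
environment.  Sign convention (fixed here): epsilon > 0 favours the closed
conformation, so the equilibrium open probability is the Boltzmann/Fermi
function P_O = 1 / (1 + exp(epsilon/(R*T))), which crosses 1/2 at the
half-activation temperature T* = dH/dS when the memory term vanishes.

Energies are molar (J/mol, gas constant R); see :mod:`trpgating.constants`
for the per-molecule (k_B) conversion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Literal

import numpy as np

from .constants import R_GAS

__all__ = [
    "ThermoParams",
    "rate_constant",
    "linearized_rate",
    "memory_product",
    "epsilon_T",
    "equilibrium_open_probability",
]

Transition = Literal["open_transition", "close_transition"]
EpsilonForm = Literal["barrier_form", "enthalpy_form"]


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of a gating scheme.

    Parameters
    ----------
    dH : float
        Enthalpy difference H_O - H_C [J/mol].
    dS : float
        Entropy difference S_O - S_C [J/(mol K)].
    dG_barrier_o, dG_barrier_c : float
        Static barrier free energies at the holding voltage governing the
        opening / closing transitions [J/mol].
    nu0 : float
        Attempt frequency [1/s].  Held fixed during fitting (the
        barrier/prefactor product is not identifiable).
    beta_o, beta_c : float
        Voltage sensitivities of the two rates [1/mV].
    V0 : float
        Static holding voltage [mV].
    k_c1 : float
        Exit rate of the deep closed state at the reference temperature
        ``T_ref`` [1/s]; enters the memory term of epsilon(T).
    tau_r : float
        Memory / relaxation time [s].
    dH_c1 : float
        Arrhenius activation enthalpy of k_c1 [J/mol].  0 (the default)
        makes the memory product k_c1*tau_r temperature-independent.
    T_ref : float
        Reference temperature at which ``k_c1`` is quoted [K].
    """

    dH: float = 0.0
    dS: float = 0.0
    dG_barrier_o: float = 0.0
    dG_barrier_c: float = 0.0
    nu0: float = 1e6
    beta_o: float = 0.0
    beta_c: float = 0.0
    V0: float = 0.0
    k_c1: float = 0.0
    tau_r: float = 0.0
    dH_c1: float = 0.0
    T_ref: float = 310.0

    def __post_init__(self) -> None:
        if not self.nu0 > 0:
            raise ValueError("attempt frequency nu0 must be > 0")
        if self.tau_r < 0:
            raise ValueError("memory time tau_r must be >= 0")
        if self.k_c1 < 0:
            raise ValueError("rate k_c1 must be >= 0")
        if self.dG_barrier_o < 0 or self.dG_barrier_c < 0:
            raise ValueError("barrier free energies must be >= 0")
        if not self.T_ref > 0:
            raise ValueError("reference temperature must be > 0 K")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d) -> "ThermoParams":
        return cls(**d)


def _check_temperature(T) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("absolute temperature must be > 0 K")
    return T


def rate_constant(thermo: ThermoParams, which: Transition, T):
    """Static Eyring rate nu0*exp(-dG/(R*T)) [1/s] for the requested direction."""
    T = _check_temperature(T)
    if which == "open_transition":
        dG = thermo.dG_barrier_o
    elif which == "close_transition":
        dG = thermo.dG_barrier_c
    else:
        raise ValueError(f"unknown transition {which!r}")
    out = thermo.nu0 * np.exp(-dG / (R_GAS * T))
    return float(out) if out.ndim == 0 else out


def linearized_rate(k0: float, beta: float, Vs_t):
    """First-order voltage correction k0*(1 - beta*Vs).

    The linearization can go negative for large drivings; a negative rate is
    unphysical, so the result is clamped at 0 with a warning.
    """
    if not k0 > 0:
        raise ValueError("base rate k0 must be > 0")
    Vs_t = np.asarray(Vs_t, dtype=float)
    out = k0 * (1.0 - beta * Vs_t)
    if np.any(out < 0):
        warnings.warn(
            "linearized rate clamped at 0: driving |beta*Vs| > 1 is outside "
            "the validity of the first-order expansion",
            RuntimeWarning,
            stacklevel=2,
        )
        out = np.clip(out, 0.0, None)
    return float(out) if out.ndim == 0 else out


def memory_product(thermo: ThermoParams, T):
    """Memory product m(T) = k_c1(T)*tau_r with Arrhenius-scaled k_c1.

    k_c1(T) = k_c1(T_ref)*exp[-(dH_c1/R)(1/T - 1/T_ref)]; with the default
    dH_c1 = 0 this is the constant product k_c1*tau_r.
    """
    T = _check_temperature(T)
    scale = np.exp(-(thermo.dH_c1 / R_GAS) * (1.0 / T - 1.0 / thermo.T_ref))
    out = thermo.k_c1 * thermo.tau_r * scale
    return float(out) if out.ndim == 0 else out


def epsilon_T(thermo: ThermoParams, T, form: EpsilonForm = "enthalpy_form"):
    """Gating energy epsilon(T) [J/mol].

    ``enthalpy_form``: dH - T*dS + R*T*ln(1 + k_c1(T)*tau_r)
    ``barrier_form``:  dG_barrier_o - dG_barrier_c + R*T*ln(1 + k_c1(T)*tau_r)

    The two agree whenever the barrier difference equals dH - T*dS.
    """
    T = _check_temperature(T)
    mem = np.log1p(memory_product(thermo, T))
    if form == "enthalpy_form":
        base = thermo.dH - T * thermo.dS
    elif form == "barrier_form":
        base = thermo.dG_barrier_o - thermo.dG_barrier_c
    else:
        raise ValueError(f"unknown epsilon form {form!r}")
    out = base + R_GAS * T * mem
    return float(out) if np.ndim(out) == 0 else out


def equilibrium_open_probability(eps, T):
    """Boltzmann open probability P_O = 1/(1 + exp(eps/(R*T))).

    Strictly decreasing in eps, equal to 1/2 at eps = 0, and confined to
    (0, 1) up to floating-point saturation at the extremes.
    """
    T = _check_temperature(T)
    x = np.asarray(eps, dtype=float) / (R_GAS * T)
    # logistic in -x, computed stably on both sides
    out = np.where(x >= 0, np.exp(-np.clip(x, 0, None)) / (1.0 + np.exp(-np.clip(x, 0, None))),
                   1.0 / (1.0 + np.exp(np.clip(x, None, 0))))
    return float(out) if out.ndim == 0 else out
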