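"""Synthetic conductance-temperature-voltage datasets and dwell event lists.

Emulates the structure of whole-cell recordings from heat-activated
(TRPV1-like) and cold-activated (TRPM8-like) channels: a voltage ladder from
-120 mV to +160 mV in 20 mV steps, conductance-vs-temperature curves, and
idealized dwell-time event lists.  The default thermodynamic parameters are
synthetic conventions with the right activation polarity and steepness
(half-activation near 42 degC for the heat profile and near 15 degC for the
cold profile); they are NOT fitted values from any real recording, and every
generated dataset records its full parameter set and seed in the metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gv import GVDataset
from .schemes import GatingScheme
from .thermo import ThermoParams, epsilon_T, equilibrium_open_probability

__all__ = [
    "GeneratorProfile",
    "trpv1_like",
    "trpm8_like",
    "voltage_factor",
    "generate_gv_dataset",
    "generate_dwell_events",
]

#: Default voltage ladder of the recording protocol [mV].
DEFAULT_V_LADDER = tuple(range(-120, 161, 20))

#: Voltage-coupling defaults: a shallow Boltzmann factor (slope ~40 mV,
#: i.e. an effective gating charge below 1 e) normalized to 1 at +160 mV so
#: the top of the ladder reports the bare open probability.
DEFAULT_V_HALF = 0.0
DEFAULT_V_SLOPE = 40.0
V_NORM = 160.0


@dataclass(frozen=True)
class GeneratorProfile:
    """A stated synthetic world: thermodynamics, grids, noise and seed."""

    name: str
    thermo: ThermoParams
    T_grid: tuple
    V_ladder: tuple = DEFAULT_V_LADDER
    noise_sd: float = 0.02
    n_replicates: int = 1
    seed: int = 0
    voltage_coupling: bool = True
    v_half_mV: float = DEFAULT_V_HALF
    v_slope_mV: float = DEFAULT_V_SLOPE
    heteroscedastic: bool = False

    def __post_init__(self) -> None:
        if self.name not in ("trpv1_like", "trpm8_like", "custom"):
            raise ValueError("profile name must be trpv1_like, trpm8_like or custom")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if len(self.T_grid) == 0 or len(self.V_ladder) == 0:
            raise ValueError("temperature grid and voltage ladder must be non-empty")
        if self.name == "trpv1_like" and not (self.thermo.dH > 0 and self.thermo.dS > 0):
            raise ValueError("trpv1_like (heat-activated) requires dH > 0 and dS > 0")
        if self.name == "trpm8_like" and not (self.thermo.dH < 0 and self.thermo.dS < 0):
            raise ValueError("trpm8_like (cold-activated) requires dH < 0 and dS < 0")

    @property
    def T_star_K(self) -> float:
        return self.thermo.dH / self.thermo.dS

    def with_overrides(self, **kwargs) -> "GeneratorProfile":
        return replace(self, **kwargs)


def trpv1_like(**overrides) -> GeneratorProfile:
    """Heat-activated profile: dH = 200 kJ/mol, dS = 635 J/(mol K), T* ~ 315 K.

    Places half-activation just above 42 degC, the qualitative activation
    threshold of a noxious-heat sensor.
    """
    thermo = overrides.pop("thermo", ThermoParams(dH=200e3, dS=635.0))
    T_grid = overrides.pop("T_grid", tuple(np.linspace(301.0, 329.0, 8)))
    return GeneratorProfile("trpv1_like", thermo, tuple(T_grid), **overrides)


def trpm8_like(**overrides) -> GeneratorProfile:
    """Cold-activated profile: dH = -150 kJ/mol, dS = -520 J/(mol K), T* ~ 288 K.

    The open state is favoured as temperature falls (half-activation near
    15 degC, a menthol-receptor-like cool threshold).
    """
    thermo = overrides.pop("thermo", ThermoParams(dH=-150e3, dS=-520.0))
    T_grid = overrides.pop("T_grid", tuple(np.linspace(275.0, 303.0, 8)))
    return GeneratorProfile("trpm8_like", thermo, tuple(T_grid), **overrides)


def voltage_factor(V_mV, v_half_mV=DEFAULT_V_HALF, v_slope_mV=DEFAULT_V_SLOPE):
    """Multiplicative Boltzmann voltage modulation, normalized to 1 at +160 mV."""
    V = np.asarray(V_mV, dtype=float)
    b = 1.0 / (1.0 + np.exp((v_half_mV - V) / v_slope_mV))
    b_norm = 1.0 / (1.0 + np.exp((v_half_mV - V_NORM) / v_slope_mV))
    out = b / b_norm
    return float(out) if out.ndim == 0 else out


def noiseless_surface(profile: GeneratorProfile) -> pd.DataFrame:
    """The exact g(T, V) surface the generator perturbs."""
    T = np.asarray(profile.T_grid, dtype=float)
    V = np.asarray(profile.V_ladder, dtype=float)
    TT, VV = np.meshgrid(T, V, indexing="ij")
    p = equilibrium_open_probability(epsilon_T(profile.thermo, TT.ravel()), TT.ravel())
    g = p * (
        voltage_factor(VV.ravel(), profile.v_half_mV, profile.v_slope_mV)
        if profile.voltage_coupling
        else 1.0
    )
    return pd.DataFrame(
        {"temperature_K": TT.ravel(), "voltage_mV": VV.ravel(), "g_norm": np.clip(g, 0.0, 1.0)}
    )


def generate_gv_dataset(profile: GeneratorProfile) -> GVDataset:
    """Generate a G-T-V dataset from the profile's stated world.

    g(T, V) = P_open(epsilon(T), T) * b(V), perturbed with Gaussian noise
    truncated (clipped) to [0, 1]; with ``heteroscedastic`` the per-record sd
    scales as g(1-g).  Fully reproducible from (profile, seed).
    """
    rng = np.random.default_rng(profile.seed)
    base = noiseless_surface(profile)
    frames = []
    for rep in range(profile.n_replicates):
        df = base.copy()
        df["replicate"] = rep
        g = df["g_norm"].to_numpy()
        sd = profile.noise_sd * (4.0 * g * (1.0 - g) if profile.heteroscedastic else 1.0)
        sd = np.asarray(sd, dtype=float) * np.ones_like(g)
        if profile.noise_sd > 0:
            noisy = g + rng.normal(0.0, 1.0, g.size) * sd
            df["g_norm"] = np.clip(noisy, 0.0, 1.0)  # truncated at the physical bounds
        df["sd"] = sd
        frames.append(df)
    records = pd.concat(frames, ignore_index=True)
    if profile.n_replicates == 1:
        records = records.drop(columns="replicate")
    metadata = {
        "profile": profile.name,
        "seed": profile.seed,
        "noise_sd": profile.noise_sd,
        "n_replicates": profile.n_replicates,
        "voltage_coupling": profile.voltage_coupling,
        "v_half_mV": profile.v_half_mV,
        "v_slope_mV": profile.v_slope_mV,
        "heteroscedastic": profile.heteroscedastic,
        "thermo": profile.thermo.to_dict(),
        "synthetic": True,
        "note": "synthetic stand-in parameters; not fitted values from real recordings",
    }
    return GVDataset(records, metadata)


def generate_dwell_events(
    scheme: GatingScheme, n_events: int, seed, start_state: str | None = None
) -> pd.DataFrame:
    """Idealized dwell event list: ``n_events`` alternating (state, duration_s).

    A synthetic stand-in for an idealized single-channel recording;
    reproducible from the seed.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    rng = np.random.default_rng(seed)
    current = start_state or scheme.labels[0]
    scheme.state(current)
    states, durations = [], []
    for _ in range(n_events):
        states.append(current)
        durations.append(float(scheme.law(current).sample(rng)))
        u = rng.random() if (scheme.topology == "three_state_linear" and current == "C2") else None
        current = scheme.next_state(current, u_branch=u)
    return pd.DataFrame({"state": states, "duration_s": durations})
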