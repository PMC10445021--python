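"""Conductance-voltage (G-V) and conductance-temperature (G-T) analysis.

Turns plateau-current tables into normalized conductance curves and extracts
the standard thermodynamic descriptors of a thermosensitive channel:

* a Boltzmann fit of G vs V at fixed temperature (V_half, slope, g_max);
* a van't Hoff fit of the open-probability equilibrium constant
  K(T) = p/(1-p) at fixed voltage, ln K = -dH/(R T) + dS/R, giving the
  gating enthalpy dH, entropy dS and half-activation temperature
  T* = dH/dS;
* the Q10 thermosensitivity index (k2/k1)^(10/(T2-T1)).

Inputs are assumed to be pre-processed plateau currents (no leak or series
resistance corrections are attempted).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .constants import R_GAS, celsius_to_kelvin

__all__ = [
    "GVDataset",
    "BoltzmannFit",
    "VantHoffFit",
    "FitFailure",
    "conductance_from_current",
    "boltzmann_fit",
    "vant_hoff_fit",
    "q10",
    "g_vs_temperature",
]

#: Clip bounds applied to open probabilities before forming ln K; saturated
#: conductances would otherwise produce infinities.  At this level the clip
#: changes |ln K| by at most |ln(1e-6/(1-1e-6))| ~ 13.8 per affected record.
P_CLIP = 1e-6

REQUIRED_COLUMNS = ("temperature_K", "voltage_mV", "g_norm")


class FitFailure(RuntimeError):
    """A curve fit could not produce meaningful parameters.

    Carries a ``report`` dict with residual diagnostics rather than
    returning spurious estimates.
    """

    def __init__(self, message: str, report: dict | None = None):
        super().__init__(message)
        self.report = report or {}


@dataclass(frozen=True)
class GVDataset:
    """Normalized conductance records indexed by (temperature, voltage).

    ``records`` columns: temperature_K, voltage_mV, g_norm in [0, 1] and an
    optional per-record noise ``sd``.  ``metadata`` carries the profile label
    and, for synthetic data, every generating parameter and the seed.
    """

    records: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.records).copy()
        if "temperature_C" in df.columns and "temperature_K" not in df.columns:
            df["temperature_K"] = celsius_to_kelvin(df.pop("temperature_C"))
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"GVDataset records missing columns {missing}")
        if df["g_norm"].lt(0).any() or df["g_norm"].gt(1).any():
            raise ValueError("g_norm must lie in [0, 1]")
        if df.duplicated(["temperature_K", "voltage_mV", *(["replicate"] if "replicate" in df else [])]).any():
            raise ValueError("duplicate (temperature, voltage) records; add a 'replicate' column")
        object.__setattr__(self, "records", df.reset_index(drop=True))
        object.__setattr__(self, "metadata", dict(self.metadata))

    @property
    def temperatures(self) -> np.ndarray:
        return np.sort(self.records["temperature_K"].unique())

    @property
    def voltages(self) -> np.ndarray:
        return np.sort(self.records["voltage_mV"].unique())

    def at_voltage(self, V: float) -> pd.DataFrame:
        sub = self.records[np.isclose(self.records["voltage_mV"], V)]
        if sub.empty:
            raise KeyError(
                f"voltage {V} mV not in ladder; available: {self.voltages.tolist()}"
            )
        return sub.sort_values("temperature_K").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, metadata: dict | None = None) -> "GVDataset":
        return cls(pd.read_csv(path), metadata or {})


def conductance_from_current(I_pA, V_mV, E_rev_mV: float = 0.0):
    """Chord conductance G = I/(V - E_rev) [nS] from pA and mV.

    Records at the reversal potential are returned as NaN (flagged for
    exclusion), never divided.
    """
    I = np.asarray(I_pA, dtype=float)
    V = np.asarray(V_mV, dtype=float)
    dV = V - E_rev_mV
    with np.errstate(divide="ignore", invalid="ignore"):
        G = np.where(dV == 0, np.nan, I / np.where(dV == 0, np.nan, dV))
    return float(G) if G.ndim == 0 else G


@dataclass(frozen=True)
class BoltzmannFit:
    V_half_mV: float
    slope_mV: float
    g_max: float
    residual_rss: float
    se: dict


def boltzmann_fit(V_mV, g, p0=None) -> BoltzmannFit:
    """Least-squares Boltzmann fit g = g_max / (1 + exp((V_half - V)/slope)).

    Requires >= 5 voltage points spanning the transition; refuses flat data
    with a :class:`FitFailure` report instead of returning spurious
    parameters.
    """
    V = np.asarray(V_mV, dtype=float)
    g = np.asarray(g, dtype=float)
    if V.size < 5:
        raise ValueError("boltzmann_fit needs at least 5 voltage points")
    span = g.max() - g.min()
    if span < 1e-10 or span < 0.02 * max(g.max(), 1e-12):
        raise FitFailure(
            "no voltage dependence detected; Boltzmann parameters are not identified",
            {"g_range": float(span), "g_mean": float(g.mean())},
        )

    def model(v, v_half, slope, g_max):
        return g_max / (1.0 + np.exp((v_half - v) / slope))

    if p0 is None:
        g_max0 = g.max()
        v_half0 = float(np.interp(0.5 * g_max0, g, V, left=V[0], right=V[-1]))
        slope0 = max((V.max() - V.min()) / 8.0, 1.0)
        p0 = (v_half0, slope0, g_max0)
    try:
        popt, pcov = optimize.curve_fit(model, V, g, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        resid = g - model(V, *p0)
        raise FitFailure(
            f"Boltzmann fit did not converge: {exc}",
            {"residual_rss": float(resid @ resid), "p0": list(p0)},
        ) from exc
    resid = g - model(V, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    return BoltzmannFit(
        V_half_mV=float(popt[0]),
        slope_mV=float(popt[1]),
        g_max=float(popt[2]),
        residual_rss=float(resid @ resid),
        se={"V_half_mV": float(se[0]), "slope_mV": float(se[1]), "g_max": float(se[2])},
    )


@dataclass(frozen=True)
class VantHoffFit:
    dH: float  # [J/mol]
    dS: float  # [J/(mol K)]
    T_star_K: float  # dH/dS; NaN when dS = 0 (undefined)
    se: dict
    r_squared: float
    n_clipped: int

    @property
    def is_heat_activated(self) -> bool:
        return self.dH > 0 and self.dS > 0


def vant_hoff_fit(T_K, p_open, weights=None) -> VantHoffFit:
    """van't Hoff regression of ln K = ln[p/(1-p)] on 1/T.

    slope = -dH/R, intercept = dS/R.  Open probabilities are clipped to
    [P_CLIP, 1-P_CLIP] (with a count reported) before the logit.  Ordinary
    least squares by default; per-point ``weights`` switch to weighted LS.
    """
    T = np.asarray(T_K, dtype=float)
    p = np.asarray(p_open, dtype=float)
    if T.size < 4:
        raise ValueError("van't Hoff fit needs at least 4 temperatures")
    if np.any(T <= 0):
        raise ValueError("temperatures must be positive kelvin")
    n_clipped = int(np.sum((p < P_CLIP) | (p > 1 - P_CLIP)))
    p = np.clip(p, P_CLIP, 1 - P_CLIP)
    x = 1.0 / T
    y = np.log(p / (1.0 - p))
    if weights is None:
        res = stats.linregress(x, y)
        slope, intercept = res.slope, res.intercept
        slope_se, intercept_se = res.stderr, res.intercept_stderr
        r2 = res.rvalue**2
    else:
        w = np.asarray(weights, dtype=float)
        X = np.column_stack([x, np.ones_like(x)])
        W = np.diag(w)
        beta, *_ = np.linalg.lstsq(np.sqrt(W) @ X, np.sqrt(w) * y, rcond=None)
        slope, intercept = beta
        resid = y - X @ beta
        dof = max(x.size - 2, 1)
        sigma2 = float(resid @ (w * resid)) / dof
        cov = sigma2 * np.linalg.inv(X.T @ W @ X)
        slope_se, intercept_se = np.sqrt(np.diag(cov))
        ss_tot = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 1.0
    dH = -slope * R_GAS
    dS = intercept * R_GAS
    T_star = dH / dS if dS != 0 else math.nan
    return VantHoffFit(
        dH=float(dH),
        dS=float(dS),
        T_star_K=float(T_star),
        se={"dH": float(slope_se * R_GAS), "dS": float(intercept_se * R_GAS)},
        r_squared=float(r2),
        n_clipped=n_clipped,
    )


def q10(k_T1: float, k_T2: float, T1_K: float, T2_K: float) -> float:
    """Thermosensitivity index Q10 = (k_T2/k_T1)^(10/(T2-T1))."""
    if not (k_T1 > 0 and k_T2 > 0):
        raise ValueError("rates must be > 0")
    if T1_K == T2_K:
        raise ValueError("T1 and T2 must differ")
    return float((k_T2 / k_T1) ** (10.0 / (T2_K - T1_K)))


def g_vs_temperature(dataset: GVDataset, V_mV: float) -> pd.DataFrame:
    """Replicate-averaged conductance vs temperature at a fixed ladder voltage.

    Returns a tidy frame (temperature_K, g_norm, n_replicates) with the
    Spearman trend statistic attached in ``DataFrame.attrs`` ("spearman_rho",
    "spearman_p"); single-temperature datasets carry no trend statistics.
    """
    sub = dataset.at_voltage(V_mV)
    curve = (
        sub.groupby("temperature_K", as_index=False)
        .agg(g_norm=("g_norm", "mean"), n_replicates=("g_norm", "size"))
        .sort_values("temperature_K")
        .reset_index(drop=True)
    )
    if len(curve) > 1:
        rho, pval = stats.spearmanr(curve["temperature_K"], curve["g_norm"])
        curve.attrs["spearman_rho"] = float(rho)
        curve.attrs["spearman_p"] = float(pval)
    return curve
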