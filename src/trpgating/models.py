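"""Model fitting: equilibrium gating models and dwell-law maximum likelihood.

The central object is :class:`EquilibriumGatingModel`, built from a
:class:`~trpgating.gv.GVDataset` in the statsmodels mould: the model holds
the data and configuration, ``fit()`` runs seeded multi-start least squares
and returns an :class:`EquilibriumGatingResults` carrying estimates,
standard errors, covariance, information criteria and a ``summary()`` table.

Model tags
----------
``markov_2`` / ``markov_3``
    Equilibrium open probability from epsilon(T) = dH - T*dS with no memory
    term; the three-state variant adds a C1<->C2 free-energy gap that is
    *fixed by configuration* (identifiability: six rate coefficients would
    be needed to define the three-state scheme but only four independent
    parameters are determinable, so the inner gap is not freed by default).
``nonmarkov_2`` / ``nonmarkov_3``
    Add the memory correction R*T*ln(1 + m(T)) with
    m(T) = m_ref * exp[-(dH_c1/R)(1/T - 1/T_ref)]; the fitted parameter is
    ln m_ref, while the Arrhenius enthalpy dH_c1 of the deep-closed exit
    rate is fixed by configuration (freeing it alongside m_ref would
    reintroduce the prefactor/barrier degeneracy).

Dwell-time event lists are fitted per state by :class:`DwellTimeModel`
(closed-form or scipy MLE within a family) with a Kolmogorov-Smirnov
goodness-of-fit distance.
"""

from __future__ import annotations

import hashlib
import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .constants import R_GAS
from .dwell import DwellLaw
from .gv import GVDataset
from .synthetic import voltage_factor

__all__ = [
    "MODEL_TAGS",
    "ParameterCount",
    "count_parameters",
    "IdentifiabilityError",
    "FitConfig",
    "EquilibriumGatingModel",
    "EquilibriumGatingResults",
    "fit_equilibrium_model",
    "DwellTimeModel",
    "DwellFitResults",
    "fit_dwell_laws",
    "compare_models",
]

MODEL_TAGS = ("markov_2", "markov_3", "nonmarkov_2", "nonmarkov_3")


class ParameterCount(NamedTuple):
    n_rate_coefficients: int
    n_identifiable: int


#: Raw rate-coefficient counts vs identifiable parameters per scheme.
#: markov_3: six rate coefficients define the scheme but only four
#: independent parameters are determinable from data.  markov_2: both rates
#: are determinable from the two observable dwell distributions.  The
#: non-Markov counts are this package's convention (documented in the
#: methods note): each state contributes a mean and a shape parameter, the
#: three-state chain adds the C2 branch probability, and aggregation of the
#: closed states leaves 5 of the 7 determinable.
_COUNTS = {
    "markov_2": ParameterCount(2, 2),
    "markov_3": ParameterCount(6, 4),
    "nonmarkov_2": ParameterCount(4, 4),
    "nonmarkov_3": ParameterCount(7, 5),
}


def count_parameters(model_tag: str) -> ParameterCount:
    """(raw rate coefficients, identifiable parameters) for a model tag."""
    try:
        return _COUNTS[model_tag]
    except KeyError:
        raise ValueError(f"unknown model tag {model_tag!r}; choose from {MODEL_TAGS}") from None


class IdentifiabilityError(ValueError):
    """Requested free parameters exceed the identifiable cap for the scheme."""


@dataclass(frozen=True)
class FitConfig:
    """Configuration for equilibrium fits.

    ``dH_c1``/``T_ref`` parameterize the Arrhenius temperature dependence of
    the deep-closed exit rate in the memory term (fixed, not fitted).
    ``inner_dH``/``inner_dS`` fix the C1<->C2 gap of three-state models.
    ``extra_free`` may name additional parameters to free; the fit refuses
    (rather than silently proceeding) when the total exceeds the
    identifiable cap.
    """

    n_starts: int = 8
    dH_c1: float = 150e3  # [J/mol] activation enthalpy of k_c1
    T_ref: float = 310.0  # [K] reference temperature for m_ref
    inner_dH: float = 100e3  # [J/mol] fixed C1<->C2 enthalpy gap (3-state)
    inner_dS: float = 320.0  # [J/(mol K)] fixed C1<->C2 entropy gap (3-state)
    voltage_coupling: bool | None = None  # None: auto (on iff >1 ladder voltage)
    v_half_mV: float = 0.0
    v_slope_mV: float = 40.0
    use_weights: bool = True  # per-record sd column when present
    extra_free: tuple = ()


_FREE_PARAMS = {
    "markov_2": ("dH", "dS"),
    "markov_3": ("dH", "dS"),
    "nonmarkov_2": ("dH", "dS", "ln_m_ref"),
    "nonmarkov_3": ("dH", "dS", "ln_m_ref"),
}


class EquilibriumGatingModel:
    """Equilibrium gating model over a G-T(-V) dataset.

    Parameters
    ----------
    dataset : GVDataset
        Records with temperature_K, voltage_mV, g_norm (optional sd).
    model_tag : str
        One of ``markov_2``, ``markov_3``, ``nonmarkov_2``, ``nonmarkov_3``.
    config : FitConfig, optional
    """

    def __init__(self, dataset: GVDataset, model_tag: str = "markov_2",
                 config: FitConfig | None = None):
        if model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model tag {model_tag!r}; choose from {MODEL_TAGS}")
        self.dataset = dataset
        self.model_tag = model_tag
        self.config = config or FitConfig()
        df = dataset.records
        if df["temperature_K"].nunique() < 4:
            raise ValueError("equilibrium fit needs records spanning >= 4 temperatures")
        self.free_names = _FREE_PARAMS[model_tag] + tuple(self.config.extra_free)
        cap = count_parameters(model_tag).n_identifiable
        if len(self.free_names) > cap:
            raise IdentifiabilityError(
                f"{model_tag}: {len(self.free_names)} free parameters requested "
                f"({', '.join(self.free_names)}) but only {cap} are identifiable; "
                f"fix {len(self.free_names) - cap} of them by configuration instead"
            )
        unknown = set(self.config.extra_free) - {"inner_dH", "inner_dS"}
        if unknown:
            raise IdentifiabilityError(
                f"parameters {sorted(unknown)} cannot be freed: nu0 and the memory "
                f"Arrhenius enthalpy are fixed by design, and dwell shapes are not "
                f"observable from equilibrium G-T data"
            )
        # sorted copy: fitting is invariant to record order by construction
        self._df = df.sort_values(["temperature_K", "voltage_mV"]).reset_index(drop=True)
        self._T = self._df["temperature_K"].to_numpy()
        self._V = self._df["voltage_mV"].to_numpy()
        self._g = self._df["g_norm"].to_numpy()
        vc = self.config.voltage_coupling
        self._use_voltage = (len(dataset.voltages) > 1) if vc is None else vc
        if self.config.use_weights and "sd" in self._df and self._df["sd"].gt(0).all():
            self._w = 1.0 / self._df["sd"].to_numpy()
        else:
            self._w = np.ones_like(self._g)
        fingerprint = hashlib.sha256(
            np.ascontiguousarray(np.column_stack([self._T, self._V, self._g])).tobytes()
        ).hexdigest()
        self.data_fingerprint = fingerprint

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, model_tag: str = "markov_2",
                       config: FitConfig | None = None, metadata: dict | None = None):
        return cls(GVDataset(df, metadata or {}), model_tag, config)

    # -- forward model ---------------------------------------------------------
    def _theta_to_params(self, theta: np.ndarray) -> dict:
        # internal scaling: dH in kJ/mol keeps the optimizer well conditioned
        out = {}
        for name, value in zip(self.free_names, theta):
            out[name] = value * 1e3 if name in ("dH", "inner_dH") else value
        return out

    def predict(self, params: dict, T=None, V=None) -> np.ndarray:
        """Predicted normalized conductance for parameter dict ``params``."""
        T = self._T if T is None else np.asarray(T, dtype=float)
        V = self._V if V is None else np.asarray(V, dtype=float)
        cfg = self.config
        eps = params["dH"] - T * params["dS"]
        if self.model_tag.startswith("nonmarkov"):
            m = math.exp(min(params["ln_m_ref"], 50.0)) * np.exp(
                -(cfg.dH_c1 / R_GAS) * (1.0 / T - 1.0 / cfg.T_ref)
            )
            eps = eps + R_GAS * T * np.log1p(m)
        x = np.clip(eps / (R_GAS * T), -500, 500)
        if self.model_tag.endswith("_3"):
            inner_dH = params.get("inner_dH", cfg.inner_dH)
            inner_dS = params.get("inner_dS", cfg.inner_dS)
            x2 = np.clip((inner_dH - T * inner_dS) / (R_GAS * T), -500, 500)
            p = 1.0 / (1.0 + np.exp(x) * (1.0 + np.exp(x2)))
        else:
            p = 1.0 / (1.0 + np.exp(x))
        if self._use_voltage:
            p = p * voltage_factor(V, cfg.v_half_mV, cfg.v_slope_mV)
        return p

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        return self._w * (self.predict(self._theta_to_params(theta)) - self._g)

    # -- starting values -------------------------------------------------------
    def _starts(self, seed) -> list:
        """One logit-regression informed start plus seeded random restarts.

        Random starts are drawn from documented ranges: |dH| in [50, 400]
        kJ/mol with dS sign-matched so T* falls inside the data's span
        (the dH/dS ridge makes joint draws essential), ln m_ref in
        [ln 0.1, ln 10].
        """
        rng = np.random.default_rng(seed)
        T, g = self._T, self._g
        gv = g / voltage_factor(self._V, self.config.v_half_mV, self.config.v_slope_mV) \
            if self._use_voltage else g
        p = np.clip(gv, 1e-4, 1 - 1e-4)
        slope, intercept = np.polyfit(1.0 / T, np.log(p / (1.0 - p)), 1)
        dH0, dS0 = -slope * R_GAS, intercept * R_GAS
        starts = [self._pack(dH0, dS0, 0.0)]
        for _ in range(max(self.config.n_starts - 1, 0)):
            dH = rng.uniform(50e3, 400e3) * math.copysign(1.0, dH0 if dH0 else 1.0)
            T_star = rng.uniform(T.min(), T.max())
            dS = dH / T_star
            ln_m = rng.uniform(math.log(0.1), math.log(10.0))
            starts.append(self._pack(dH, dS, ln_m))
        return starts

    def _pack(self, dH, dS, ln_m) -> np.ndarray:
        vals = {"dH": dH / 1e3, "dS": dS, "ln_m_ref": ln_m,
                "inner_dH": self.config.inner_dH / 1e3, "inner_dS": self.config.inner_dS}
        return np.array([vals[name] for name in self.free_names], dtype=float)

    # -- fitting ----------------------------------------------------------------
    def fit(self, seed: int = 0) -> "EquilibriumGatingResults":
        """Seeded multi-start least squares; returns the best of the restarts."""
        best = None
        for theta0 in self._starts(seed):
            try:
                res = optimize.least_squares(
                    self._residuals, theta0, method="lm", max_nfev=10000
                )
            except Exception:
                continue
            if best is None or res.cost < best.cost:
                best = res
        if best is None:
            raise RuntimeError("all restarts of the equilibrium fit failed")
        theta = best.x
        resid = self._residuals(theta)
        n, k = resid.size, len(self.free_names)
        rss = float(resid @ resid)
        dof = max(n - k, 1)
        sigma2 = rss / dof
        JtJ = best.jac.T @ best.jac
        try:
            cov_theta = sigma2 * np.linalg.inv(JtJ)
        except np.linalg.LinAlgError:
            cov_theta = sigma2 * np.linalg.pinv(JtJ)
        # rescale covariance back to natural units (dH in J/mol)
        scale = np.array([1e3 if nm in ("dH", "inner_dH") else 1.0 for nm in self.free_names])
        cov = cov_theta * np.outer(scale, scale)
        cov = 0.5 * (cov + cov.T)
        params = self._theta_to_params(theta)
        return EquilibriumGatingResults(
            model=self,
            params=params,
            cov=pd.DataFrame(cov, index=self.free_names, columns=self.free_names),
            rss=rss,
            n_obs=n,
            seed=seed,
            n_starts=self.config.n_starts,
        )


@dataclass(frozen=True)
class EquilibriumGatingResults:
    """Estimates, uncertainties and diagnostics of an equilibrium fit."""

    model: EquilibriumGatingModel
    params: dict
    cov: pd.DataFrame
    rss: float
    n_obs: int
    seed: int
    n_starts: int

    @property
    def model_tag(self) -> str:
        return self.model.model_tag

    @property
    def k_params(self) -> int:
        """Free mean-model parameters plus the noise variance."""
        return len(self.model.free_names) + 1

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.cov.index, name="bse")

    @property
    def llf(self) -> float:
        n = self.n_obs
        return -0.5 * n * (math.log(2.0 * math.pi * self.rss / n) + 1.0)

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.llf

    @property
    def aicc(self) -> float:
        """Small-sample corrected AIC (the default ranking criterion when
        n/k < 40, which covers every realistic G-T dataset here)."""
        n, k = self.n_obs, self.k_params
        if n - k - 1 <= 0:
            return math.inf
        return self.aic + 2.0 * k * (k + 1) / (n - k - 1)

    @property
    def bic(self) -> float:
        return self.k_params * math.log(self.n_obs) - 2.0 * self.llf

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.model.predict(self.params)

    @property
    def resid(self) -> np.ndarray:
        return self.model._g - self.fittedvalues

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        dof = max(self.n_obs - len(self.model.free_names), 1)
        tq = stats.t.ppf(1.0 - alpha / 2.0, dof)
        est = pd.Series({k: self.params[k] for k in self.cov.index})
        se = self.bse
        return pd.DataFrame({"lower": est - tq * se, "upper": est + tq * se})

    def runs_test(self) -> tuple:
        """Wald-Wolfowitz runs test on residual signs ordered by (T, V).

        A small p-value flags a systematic residual trend, the signature of
        a misspecified (memoryless) model fitted to data with memory.
        """
        from statsmodels.sandbox.stats.runs import runstest_1samp

        z, p = runstest_1samp(self.resid, cutoff=0, correction=False)
        return float(z), float(p)

    @property
    def T_star_K(self) -> float:
        dS = self.params["dS"]
        return self.params["dH"] / dS if dS != 0 else math.nan

    def to_dict(self) -> dict:
        """JSON-ready fit report echoing seeds and configuration."""
        from dataclasses import asdict

        return {
            "model_tag": self.model_tag,
            "params": {k: float(v) for k, v in self.params.items()},
            "bse": {k: float(v) for k, v in self.bse.items()},
            "cov": self.cov.to_dict(),
            "rss": self.rss,
            "n_obs": self.n_obs,
            "aic": self.aic,
            "aicc": self.aicc,
            "bic": self.bic,
            "T_star_K": self.T_star_K,
            "seed": self.seed,
            "n_starts": self.n_starts,
            "config": asdict(self.model.config),
            "data_fingerprint": self.model.data_fingerprint,
        }

    def summary(self) -> str:
        """Human-readable fit summary table."""
        ci = self.conf_int()
        lines = [
            "Equilibrium gating model fit",
            "=" * 64,
            f"model tag:      {self.model_tag}",
            f"n records:      {self.n_obs}   free params: {len(self.model.free_names)}",
            f"weighted RSS:   {self.rss:.6g}",
            f"AIC: {self.aic:.3f}   AICc: {self.aicc:.3f}   BIC: {self.bic:.3f}",
            "-" * 64,
            f"{'parameter':<12}{'estimate':>14}{'std err':>12}{'[0.025':>13}{'0.975]':>12}",
        ]
        units = {"dH": "J/mol", "dS": "J/(mol K)", "ln_m_ref": "-",
                 "inner_dH": "J/mol", "inner_dS": "J/(mol K)"}
        for name in self.cov.index:
            lines.append(
                f"{name:<12}{self.params[name]:>14.6g}{self.bse[name]:>12.3g}"
                f"{ci.loc[name, 'lower']:>13.6g}{ci.loc[name, 'upper']:>12.6g}"
                f"  {units.get(name, '')}"
            )
        if not math.isnan(self.T_star_K):
            lines.append("-" * 64)
            lines.append(f"half-activation temperature T* = dH/dS = {self.T_star_K:.2f} K")
        if self.model_tag.startswith("nonmarkov"):
            m_ref = math.exp(self.params["ln_m_ref"])
            lines.append(
                f"memory product m_ref = k_c1*tau_r at T_ref="
                f"{self.model.config.T_ref:.1f} K: {m_ref:.4g}"
            )
        return "\n".join(lines)


def fit_equilibrium_model(dataset: GVDataset, model_tag: str = "markov_2",
                          config: FitConfig | None = None, seed: int = 0
                          ) -> EquilibriumGatingResults:
    """Functional wrapper: build the model and fit it in one call."""
    return EquilibriumGatingModel(dataset, model_tag, config).fit(seed=seed)


def compare_models(results: Sequence[EquilibriumGatingResults]) -> pd.DataFrame:
    """Rank fits of the *same* dataset by AICc; reports dAIC and Akaike weights."""
    results = list(results)
    if not results:
        raise ValueError("need at least one fit result")
    prints = {r.model.data_fingerprint for r in results}
    if len(prints) > 1:
        raise ValueError("model comparison requires fits of the identical dataset")
    rows = [
        {"model_tag": r.model_tag, "k_params": r.k_params, "rss": r.rss,
         "aic": r.aic, "aicc": r.aicc, "bic": r.bic}
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values("aicc", kind="stable").reset_index(drop=True)
    table["delta_aicc"] = table["aicc"] - table["aicc"].iloc[0]
    rel = np.exp(-0.5 * table["delta_aicc"].to_numpy())
    table["akaike_weight"] = rel / rel.sum()
    return table


# ---------------------------------------------------------------------------
# dwell-time maximum likelihood
# ---------------------------------------------------------------------------

class DwellTimeModel:
    """Maximum-likelihood fit of a dwell-law family to one state's durations."""

    MIN_EVENTS = 50

    def __init__(self, durations, family: str, min_events: int | None = None):
        d = np.asarray(durations, dtype=float)
        if d.size == 0:
            raise ValueError("empty dwell event list")
        if np.any(d <= 0):
            raise ValueError("dwell durations must be > 0")
        self.durations = d
        self.family = family
        self.min_events = self.MIN_EVENTS if min_events is None else min_events
        if family not in ("exponential", "gamma", "stretched_exponential", "pareto"):
            raise ValueError(f"unknown dwell family {family!r}")

    def fit(self) -> "DwellFitResults":
        d = self.durations
        n = d.size
        small_sample = n < self.min_events
        if small_sample:
            warnings.warn(
                f"only {n} events (< {self.min_events}); shape estimates will have "
                f"wide confidence intervals",
                RuntimeWarning,
                stacklevel=2,
            )
        if self.family == "exponential":
            lam = 1.0 / d.mean()
            law = DwellLaw.exponential(lam)
            se = {"lam": lam / math.sqrt(n)}
        elif self.family == "gamma":
            shape, _, scale = stats.gamma.fit(d, floc=0)
            law = DwellLaw.gamma(shape, scale)
            se = self._gamma_se(shape, scale, n)
        elif self.family == "stretched_exponential":
            stretch, _, scale = stats.weibull_min.fit(d, floc=0)
            law = DwellLaw.stretched_exponential(scale, min(stretch, 1.0))
            se = {}
        else:  # pareto
            t_min = d.min()
            alpha = n / np.sum(np.log(d / t_min))
            law = DwellLaw.pareto(alpha, t_min)
            se = {"alpha": alpha / math.sqrt(n)}
        loglik = float(np.sum(np.log(np.clip(law.pdf(d), 1e-300, None))))
        ks = stats.kstest(d, law.cdf)
        k = {"exponential": 1, "gamma": 2, "stretched_exponential": 2, "pareto": 2}[self.family]
        return DwellFitResults(
            law=law, n_events=n, loglik=loglik, k_params=k,
            ks_distance=float(ks.statistic), ks_pvalue=float(ks.pvalue),
            se=se, small_sample=small_sample,
        )

    @staticmethod
    def _gamma_se(shape, scale, n) -> dict:
        # observed-information standard errors for the gamma MLE
        i_kk = special.polygamma(1, shape)
        info = n * np.array([[i_kk, 1.0 / scale], [1.0 / scale, shape / scale**2]])
        try:
            cov = np.linalg.inv(info)
            return {"shape": math.sqrt(cov[0, 0]), "scale": math.sqrt(cov[1, 1])}
        except np.linalg.LinAlgError:
            return {}


@dataclass(frozen=True)
class DwellFitResults:
    law: DwellLaw
    n_events: int
    loglik: float
    k_params: int
    ks_distance: float
    ks_pvalue: float
    se: dict
    small_sample: bool

    @property
    def aic(self) -> float:
        return 2.0 * self.k_params - 2.0 * self.loglik

    def summary(self) -> str:
        p = ", ".join(f"{k}={v:.5g}" for k, v in self.law.params.items())
        return (
            f"DwellTimeModel fit: {self.law.family}({p})\n"
            f"n={self.n_events}  loglik={self.loglik:.2f}  AIC={self.aic:.2f}\n"
            f"KS distance={self.ks_distance:.4f} (p={self.ks_pvalue:.3g})"
        )


def fit_dwell_laws(events: pd.DataFrame, family: str | dict = "exponential",
                   min_events: int | None = None) -> dict:
    """Per-state MLE dwell-law fits from an event list (state, duration_s).

    ``family`` may be a single family name or a mapping state -> family.
    Returns {state_label: DwellFitResults}.
    """
    if not {"state", "duration_s"}.issubset(events.columns):
        raise ValueError("event list needs columns 'state' and 'duration_s'")
    if events.empty:
        raise ValueError("empty dwell event list")
    out = {}
    for state, grp in events.groupby("state"):
        fam = family[state] if isinstance(family, dict) else family
        out[state] = DwellTimeModel(
            grp["duration_s"].to_numpy(), fam, min_events=min_events
        ).fit()
    return out
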