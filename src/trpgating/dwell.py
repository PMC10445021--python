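"""Residence-time (dwell) distribution families.

A semi-Markov gating scheme attaches to every kinetic state a law for the
time spent there before the next transition.  Four families are supported:

``exponential``
    rate ``lam`` [1/s] — the memoryless Markov limit.
``gamma``
    shape ``shape`` (kappa), scale ``scale`` (theta_s) [s] — an increasing
    hazard for shape > 1; models a state hiding several fast sub-steps.
``stretched_exponential``
    scale ``scale`` [s], stretch exponent ``stretch`` (b) in (0, 1] — the
    Weibull/Kohlrausch survival exp[-(t/scale)^b], a canonical "broad
    distribution of rates".
``pareto``
    tail exponent ``alpha`` > 0, minimum time ``t_min`` [s] — a power-law
    tail; the mean is infinite for alpha <= 1, the regime in which the
    gating process acquires genuinely non-Markovian long-time memory.

Every law exposes the density psi(t), survival Phi(t) = 1 - CDF, hazard
psi/Phi, mean, Laplace transform psi_hat(s) (complex-plane capable where a
closed form exists) and inverse-CDF sampling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import integrate, special, stats

__all__ = ["DwellLaw", "FAMILIES", "InfiniteMeanError"]

FAMILIES = ("exponential", "gamma", "stretched_exponential", "pareto")


class InfiniteMeanError(ValueError):
    """Raised when a finite mean is required but the law has none."""


def _check_positive(name: str, value: float) -> None:
    if not (value > 0) or not math.isfinite(value):
        raise ValueError(f"parameter {name!r} must be a positive finite number, got {value!r}")


@dataclass(frozen=True)
class DwellLaw:
    """A residence-time distribution family with fixed parameters."""

    family: str
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown dwell-law family {self.family!r}; choose from {FAMILIES}")
        object.__setattr__(self, "params", dict(self.params))
        required = {
            "exponential": ("lam",),
            "gamma": ("shape", "scale"),
            "stretched_exponential": ("scale", "stretch"),
            "pareto": ("alpha", "t_min"),
        }[self.family]
        for name in required:
            if name not in self.params:
                raise ValueError(f"{self.family} law requires parameter {name!r}")
            _check_positive(name, self.params[name])
        extra = set(self.params) - set(required)
        if extra:
            raise ValueError(f"unexpected parameters for {self.family}: {sorted(extra)}")
        if self.family == "stretched_exponential" and not (self.params["stretch"] <= 1.0):
            raise ValueError("stretch exponent must lie in (0, 1]")

    # -- convenience constructors -------------------------------------------------
    @classmethod
    def exponential(cls, lam: float) -> "DwellLaw":
        return cls("exponential", {"lam": lam})

    @classmethod
    def gamma(cls, shape: float, scale: float) -> "DwellLaw":
        return cls("gamma", {"shape": shape, "scale": scale})

    @classmethod
    def stretched_exponential(cls, scale: float, stretch: float) -> "DwellLaw":
        return cls("stretched_exponential", {"scale": scale, "stretch": stretch})

    @classmethod
    def pareto(cls, alpha: float, t_min: float) -> "DwellLaw":
        return cls("pareto", {"alpha": alpha, "t_min": t_min})

    # -- scipy frozen distribution backing ----------------------------------------
    @property
    def _dist(self):
        p = self.params
        if self.family == "exponential":
            return stats.expon(scale=1.0 / p["lam"])
        if self.family == "gamma":
            return stats.gamma(p["shape"], scale=p["scale"])
        if self.family == "stretched_exponential":
            return stats.weibull_min(p["stretch"], scale=p["scale"])
        return stats.pareto(p["alpha"], scale=p["t_min"])

    # -- densities and moments -----------------------------------------------------
    def pdf(self, t):
        """Density psi(t) [1/s]; domain t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("dwell times are non-negative; got t < 0")
        return self._dist.pdf(t)

    def cdf(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("dwell times are non-negative; got t < 0")
        return self._dist.cdf(t)

    def survival(self, t):
        """Phi(t) = P(dwell > t) = 1 - CDF; Phi(0) = 1."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("dwell times are non-negative; got t < 0")
        return self._dist.sf(t)

    def hazard(self, t):
        """Instantaneous transition rate psi(t)/Phi(t) [1/s].

        Constant only for the exponential family; its time dependence is the
        operational signature of non-Markovian gating.
        """
        t = np.asarray(t, dtype=float)
        sf = self.survival(t)
        if np.any(sf <= 0.0):
            raise FloatingPointError("survival underflowed to 0; hazard undefined at this t")
        return self.pdf(t) / sf

    @property
    def has_finite_mean(self) -> bool:
        return self.family != "pareto" or self.params["alpha"] > 1.0

    def mean(self) -> float:
        """Mean residence time [s]; ``math.inf`` for a pareto tail alpha <= 1."""
        p = self.params
        if self.family == "exponential":
            return 1.0 / p["lam"]
        if self.family == "gamma":
            return p["shape"] * p["scale"]
        if self.family == "stretched_exponential":
            return p["scale"] * math.gamma(1.0 + 1.0 / p["stretch"])
        if p["alpha"] <= 1.0:
            return math.inf
        return p["alpha"] * p["t_min"] / (p["alpha"] - 1.0)

    def finite_mean(self) -> float:
        """Mean, raising :class:`InfiniteMeanError` when it does not exist."""
        m = self.mean()
        if not math.isfinite(m):
            raise InfiniteMeanError(
                f"pareto law with alpha={self.params['alpha']} <= 1 has an infinite mean"
            )
        return m

    # -- Laplace transform ----------------------------------------------------------
    def laplace(self, s):
        """psi_hat(s) = E[exp(-s*theta)] = int_0^inf exp(-st) psi(t) dt.

        Closed forms for exponential and gamma (valid on the complex plane by
        analytic continuation); adaptive quadrature for the stretched
        exponential and pareto families (requires Re(s) >= 0).
        psi_hat(0) = 1 for every law.
        """
        p = self.params
        if np.iterable(s) and not np.isscalar(s):
            return np.array([self.laplace(si) for si in np.asarray(s)])
        if isinstance(s, complex) or np.iscomplexobj(s):
            s = complex(s)
        else:
            s = float(s)
            if s < 0:
                raise ValueError("Laplace variable s must be >= 0")
        if self.family == "exponential":
            lam = p["lam"]
            return lam / (lam + s)
        if self.family == "gamma":
            return (1.0 + p["scale"] * s) ** (-p["shape"])
        # quadrature families: need a decaying integrand
        if isinstance(s, complex) and s.real < 0:
            raise ValueError(
                f"{self.family} Laplace transform is only evaluable for Re(s) >= 0"
            )
        return self._laplace_quad(s)

    def _laplace_quad(self, s):
        if s == 0:
            return 1.0 if not isinstance(s, complex) else complex(1.0)

        # integrate exp(-st) psi(t); split real/imaginary parts for complex s
        pdf = self.pdf
        lower = self.params["t_min"] if self.family == "pareto" else 0.0

        if isinstance(s, complex):
            sr, si = s.real, s.imag

            def f_re(t):
                return math.exp(-sr * t) * math.cos(si * t) * float(pdf(t))

            def f_im(t):
                return -math.exp(-sr * t) * math.sin(si * t) * float(pdf(t))

            re, _ = integrate.quad(f_re, lower, np.inf, limit=400)
            im, _ = integrate.quad(f_im, lower, np.inf, limit=400)
            return complex(re, im)

        def f(t):
            return math.exp(-s * t) * float(pdf(t))

        val, _ = integrate.quad(f, lower, np.inf, limit=400)
        return val

    # -- sampling --------------------------------------------------------------------
    def ppf(self, q):
        """Inverse CDF (quantile function) [s]."""
        p = self.params
        q = np.asarray(q, dtype=float)
        if self.family == "exponential":
            return -np.log1p(-q) / p["lam"]
        if self.family == "stretched_exponential":
            return p["scale"] * (-np.log1p(-q)) ** (1.0 / p["stretch"])
        if self.family == "pareto":
            return p["t_min"] * (1.0 - q) ** (-1.0 / p["alpha"])
        return special.gammaincinv(p["shape"], q) * p["scale"]

    def sample(self, rng: np.random.Generator, size=None):
        """Draw dwell times by inverse-CDF sampling (reproducible given rng)."""
        u = rng.random(size)
        return self.ppf(u)

    # -- temperature coupling ----------------------------------------------------------
    def with_mean(self, new_mean: float) -> "DwellLaw":
        """Shape-preserving rescale of the time axis so the mean equals ``new_mean``.

        This is how a thermodynamic rate k(T) couples to a non-exponential
        law: the mean is pinned to 1/k(T) and the shape parameters are left
        untouched.  Undefined for an infinite-mean pareto law.
        """
        _check_positive("new_mean", new_mean)
        p = self.params
        if self.family == "exponential":
            return DwellLaw.exponential(1.0 / new_mean)
        if self.family == "gamma":
            return DwellLaw.gamma(p["shape"], new_mean / p["shape"])
        if self.family == "stretched_exponential":
            return DwellLaw.stretched_exponential(
                new_mean / math.gamma(1.0 + 1.0 / p["stretch"]), p["stretch"]
            )
        if p["alpha"] <= 1.0:
            raise InfiniteMeanError("cannot mean-rescale a pareto law with alpha <= 1")
        return DwellLaw.pareto(p["alpha"], new_mean * (p["alpha"] - 1.0) / p["alpha"])

    def to_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DwellLaw":
        return cls(d["family"], d["params"])
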