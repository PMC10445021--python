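"""Alternating-renewal (semi-Markov) gating engine.

Simulates single-channel gating trajectories whose residence times follow
arbitrary dwell laws, estimates state occupancies by Monte Carlo, solves the
two-state generalized master equation in the Laplace domain

    P_O_hat(s | start in C) = psi_C(s) (1 - psi_O(s)) / ( s (1 - psi_C psi_O) )

(with the symmetric formula when starting in O), inverts it numerically, and
classifies the long-time relaxation regime by the small-s (Tauberian)
expansion of the dwell-law transforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .schemes import GatingScheme
from .thermo import ThermoParams, rate_constant

__all__ = [
    "Trajectory",
    "OccupancyCurve",
    "TailDescriptor",
    "LaplaceInversionError",
    "sample_trajectory",
    "mc_occupancy",
    "master_equation_occupancy",
    "gme_occupancy_laplace",
    "gme_occupancy",
    "invert_laplace",
    "tauberian_tail",
    "dwell_statistics",
    "temperature_rate_sweep",
    "geometric_grid",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Trajectory:
    """An alternating sequence of states and dwell durations.

    The final dwell straddles ``total_duration`` and is stored at its full
    sampled length; statistics treat it as right-censored.
    """

    start_state: str
    states: tuple
    durations: np.ndarray
    total_duration: float

    def __post_init__(self) -> None:
        durations = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "durations", durations)
        object.__setattr__(self, "states", tuple(self.states))
        if len(self.states) != len(durations):
            raise ValueError("states and durations must have equal length")
        if np.any(durations <= 0):
            raise ValueError("all dwell durations must be > 0")

    @property
    def dwells(self):
        """Sequence of (state_label, duration) pairs."""
        return list(zip(self.states, self.durations))

    @property
    def n_dwells(self) -> int:
        return len(self.states)

    def entry_times(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum(self.durations)[:-1]))

    def state_at(self, t):
        """State label(s) occupied at time(s) t in [0, total_duration]."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0) or np.any(t > self.total_duration):
            raise ValueError("t outside [0, total_duration]")
        edges = np.cumsum(self.durations)
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(self.states) - 1)
        # scalar idx indexes out a plain str; array idx keeps an object array
        return np.asarray(self.states, dtype=object)[idx]

    def to_frame(self) -> pd.DataFrame:
        """Event-list export: columns (state, duration_s)."""
        return pd.DataFrame({"state": self.states, "duration_s": self.durations})


@dataclass(frozen=True)
class OccupancyCurve:
    """State occupancy probabilities on a time grid.

    ``n_trajectories`` is 0 for analytic curves, in which case ``stderr`` is
    None; for Monte-Carlo curves ``stderr`` maps each state to its binomial
    standard error per grid point.
    """

    times: np.ndarray
    probs: dict
    n_trajectories: int = 0
    stderr: dict | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        probs = {k: np.asarray(v, dtype=float) for k, v in self.probs.items()}
        object.__setattr__(self, "probs", probs)
        total = sum(probs.values())
        if np.any(np.abs(total - 1.0) > 1e-9):
            raise ValueError("state probabilities must sum to 1 at every time point")
        for v in probs.values():
            if np.any(v < -1e-12) or np.any(v > 1 + 1e-12):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def p_open(self) -> np.ndarray:
        return self.probs["O"]

    @property
    def p_closed(self) -> np.ndarray:
        closed = [v for k, v in self.probs.items() if k != "O"]
        return np.sum(closed, axis=0)

    def to_frame(self) -> pd.DataFrame:
        out = {"time_s": self.times, "p_open": self.p_open, "p_closed": self.p_closed}
        for lbl in ("C1", "C2"):
            if lbl in self.probs:
                out[f"p_{lbl.lower()}"] = self.probs[lbl]
        if self.stderr is not None:
            out["stderr_open"] = self.stderr["O"]
        return pd.DataFrame(out)


def geometric_grid(t_min: float, t_max: float, n: int = 50, include_zero: bool = True):
    """Log-spaced time grid (optionally prepended with 0) resolving fast
    relaxation and slow tails simultaneously."""
    if not (0 < t_min < t_max):
        raise ValueError("need 0 < t_min < t_max")
    g = np.geomspace(t_min, t_max, n)
    return np.concatenate(([0.0], g)) if include_zero else g


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_trajectory(
    scheme: GatingScheme, start_state: str, duration: float, seed
) -> Trajectory:
    """Simulate one alternating-renewal trajectory of length ``duration``.

    Dwells are drawn by inverse-CDF sampling from the occupied state's law;
    the three-state chain resolves the C2 exit by a competing-risks branch
    variate.  Bitwise reproducible for a given integer seed.
    """
    if not duration > 0:
        raise ValueError("duration must be > 0")
    scheme.state(start_state)  # raises KeyError for unknown labels
    rng = _as_rng(seed)
    states: list = []
    durations: list = []
    t = 0.0
    current = start_state
    while t < duration:
        theta = float(scheme.law(current).sample(rng))
        if theta <= 0.0:  # guard against underflow to exactly 0
            theta = np.nextafter(0.0, 1.0)
        states.append(current)
        durations.append(theta)
        t += theta
        u = rng.random() if (scheme.topology == "three_state_linear" and current == "C2") else None
        current = scheme.next_state(current, u_branch=u)
    return Trajectory(start_state, tuple(states), np.array(durations), duration)


def mc_occupancy(
    scheme: GatingScheme, start_state: str, grid, n_traj: int, seed
) -> OccupancyCurve:
    """Monte-Carlo occupancy estimate on an ascending grid starting at 0.

    One root seed spawns an independent child stream per trajectory, so the
    result is invariant under any parallel partition of the trajectories.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("time grid must be non-empty")
    if grid[0] != 0.0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending and start at 0")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    duration = float(grid[-1]) * (1 + 1e-12) + 1e-300
    counts = {lbl: np.zeros(grid.size) for lbl in scheme.labels}
    children = np.random.SeedSequence(seed).spawn(n_traj)
    for child in children:
        traj = sample_trajectory(scheme, start_state, duration, np.random.default_rng(child))
        labels = traj.state_at(np.minimum(grid, traj.total_duration))
        for lbl in scheme.labels:
            counts[lbl] += labels == lbl
    probs = {lbl: c / n_traj for lbl, c in counts.items()}
    stderr = {lbl: np.sqrt(p * (1 - p) / n_traj) for lbl, p in probs.items()}
    return OccupancyCurve(grid, probs, n_trajectories=n_traj, stderr=stderr)


# ---------------------------------------------------------------------------
# Markov closed form
# ---------------------------------------------------------------------------

def master_equation_occupancy(
    k_open: float, k_close: float, p_open0: float, grid
) -> OccupancyCurve:
    """Two-state Markov master-equation solution.

    p_O(t) = p_inf + (p_open0 - p_inf) exp[-(k_open+k_close) t],
    p_inf = k_open/(k_open+k_close).
    """
    if not (k_open > 0 and k_close > 0):
        raise ValueError("rates must be > 0")
    grid = np.asarray(grid, dtype=float)
    p_inf = k_open / (k_open + k_close)
    p_o = p_inf + (p_open0 - p_inf) * np.exp(-(k_open + k_close) * grid)
    return OccupancyCurve(grid, {"O": p_o, "C": 1.0 - p_o})


# ---------------------------------------------------------------------------
# Laplace-domain generalized master equation
# ---------------------------------------------------------------------------

def gme_occupancy_laplace(scheme: GatingScheme, start_state: str, s):
    """Laplace transform P_O_hat(s) of the two-state open occupancy.

    Standard alternating-renewal result: with psi_C, psi_O the dwell-law
    transforms,

        start in C:  psi_C (1 - psi_O) / ( s (1 - psi_C psi_O) )
        start in O:  (1 - psi_O)       / ( s (1 - psi_C psi_O) )

    The final-value theorem gives s*P_O_hat(s) -> <tau_O>/(<tau_C>+<tau_O>)
    as s -> 0 when both means are finite.  Accepts complex ``s`` when both
    laws have closed-form transforms (needed by Talbot inversion).
    """
    if scheme.topology != "two_state":
        raise NotImplementedError("Laplace-domain GME is implemented for the two-state scheme")
    if start_state not in ("C", "O"):
        raise KeyError(f"unknown start state {start_state!r}")
    if not isinstance(s, complex) and not np.iscomplexobj(s):
        if np.any(np.asarray(s) <= 0):
            raise ValueError("Laplace variable s must be > 0")
    psi_c = scheme.law("C").laplace(s)
    psi_o = scheme.law("O").laplace(s)
    num = psi_c * (1.0 - psi_o) if start_state == "C" else (1.0 - psi_o)
    return num / (s * (1.0 - psi_c * psi_o))


def gme_occupancy(
    scheme: GatingScheme,
    start_state: str,
    grid,
    accuracy_target: float = 1e-6,
    method: str = "talbot",
) -> OccupancyCurve:
    """Occupancy curve from numerical inversion of the Laplace-domain GME.

    Grid points at t = 0 are filled with the exact initial condition.
    """
    grid = np.asarray(grid, dtype=float)
    fn = lambda s: gme_occupancy_laplace(scheme, start_state, s)
    p_o = np.empty_like(grid)
    positive = grid > 0
    p_o[~positive] = 1.0 if start_state == "O" else 0.0
    if np.any(positive):
        p_o[positive] = invert_laplace(fn, grid[positive], accuracy_target, method=method)
    p_o = np.clip(p_o, 0.0, 1.0)
    return OccupancyCurve(grid, {"O": p_o, "C": 1.0 - p_o})


class LaplaceInversionError(RuntimeError):
    """Numerical Laplace inversion failed to meet the accuracy target."""


def _talbot(fn, t: float, M: int) -> float:
    # fixed-Talbot contour (Abate & Valko); fn must accept complex s
    r = 2.0 * M / (5.0 * t)
    acc = 0.5 * complex(fn(complex(r, 0.0))).real * math.exp(r * t)
    for k in range(1, M):
        theta = k * math.pi / M
        cot = math.cos(theta) / math.sin(theta)
        s = complex(r * theta * cot, r * theta)
        sigma = theta + (theta * cot - 1.0) * cot
        term = np.exp(t * s) * complex(fn(s)) * complex(1.0, sigma)
        acc += term.real
    return acc * r / M


_STEHFEST_CACHE: dict = {}


def _stehfest_weights(N: int) -> np.ndarray:
    if N in _STEHFEST_CACHE:
        return _STEHFEST_CACHE[N]
    V = np.zeros(N)
    for k in range(1, N + 1):
        acc = 0.0
        for j in range((k + 1) // 2, min(k, N // 2) + 1):
            acc += (
                j ** (N // 2)
                * math.factorial(2 * j)
                / (
                    math.factorial(N // 2 - j)
                    * math.factorial(j)
                    * math.factorial(j - 1)
                    * math.factorial(k - j)
                    * math.factorial(2 * j - k)
                )
            )
        V[k - 1] = (-1) ** (k + N // 2) * acc
    _STEHFEST_CACHE[N] = V
    return V


def _stehfest(fn, t: float, N: int) -> float:
    # Gaver-Stehfest: real-axis evaluations only; ~1e-8 attainable for smooth f
    V = _stehfest_weights(N)
    ln2_t = math.log(2.0) / t
    return ln2_t * sum(V[k - 1] * float(np.real(fn(k * ln2_t))) for k in range(1, N + 1))


def invert_laplace(transformed_fn, t_grid, accuracy_target: float = 1e-6, method: str = "talbot"):
    """Numerically invert a Laplace transform on a grid of positive times.

    ``talbot`` (default) deforms the Bromwich contour and requires
    ``transformed_fn`` to accept complex s; ``stehfest`` uses only real
    s > 0 (for transforms defined by quadrature on the right half-plane)
    at reduced attainable accuracy (use targets no tighter than ~1e-3).
    Each point is computed at two internal orders; disagreement beyond
    ``accuracy_target`` (relative to max(|f|, 1), so absolute for values
    below 1) raises :class:`LaplaceInversionError` with diagnostics.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    scalar = t_grid.ndim == 0
    t_flat = np.atleast_1d(t_grid)
    if np.any(t_flat <= 0):
        raise ValueError("inversion times must be > 0")
    out = np.empty_like(t_flat)
    for i, t in enumerate(t_flat):
        if method == "talbot":
            lo, hi = _talbot(transformed_fn, t, 28), _talbot(transformed_fn, t, 40)
        elif method == "stehfest":
            lo, hi = _stehfest(transformed_fn, t, 12), _stehfest(transformed_fn, t, 16)
        else:
            raise ValueError(f"unknown inversion method {method!r}")
        # mixed criterion: relative for O(1)-and-larger values, absolute below
        err = abs(hi - lo) / max(abs(hi), 1.0)
        if err > accuracy_target:
            raise LaplaceInversionError(
                f"inversion at t={t:g} did not converge: order-doubling "
                f"discrepancy {err:.2e} exceeds target {accuracy_target:.0e} "
                f"(method={method}); consider the other method or a looser target"
            )
        out[i] = hi
    return float(out[0]) if scalar else out


# ---------------------------------------------------------------------------
# Tauberian long-time classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TailDescriptor:
    """Long-time relaxation regime of a two-state scheme."""

    regime: str  # "exponential_relaxation" | "power_law"
    rate: float | None = None  # [1/s] for exponential relaxation
    exponent: float | None = None  # tail exponent alpha for power-law
    note: str = ""


def tauberian_tail(scheme: GatingScheme) -> TailDescriptor:
    """Classify the long-time approach of p_open to its limit.

    Both laws exponential (rates k_o = lam_C, k_c = lam_O): the occupancy
    relaxes exponentially at rate k_o + k_c.  A pareto closed-dwell law with
    alpha in (0, 1) has psi_C(s) ~ 1 - Gamma(1-alpha) (t_min s)^alpha for
    small s; by the Tauberian correspondence the closed-state survival decays
    as t^{-alpha} and p_open(t) relaxes with a t^{-alpha}-type power-law
    correction (for alpha < 1 the open occupancy itself decays to 0 like
    t^{alpha-1} since the mean closed time is infinite).
    """
    if scheme.topology != "two_state":
        raise NotImplementedError("tail classification is implemented for two-state schemes")
    law_c, law_o = scheme.law("C"), scheme.law("O")
    if law_c.family == "exponential" and law_o.family == "exponential":
        rate = law_c.params["lam"] + law_o.params["lam"]
        return TailDescriptor("exponential_relaxation", rate=rate,
                              note="Markov limit: relaxation rate k_o + k_c")
    if law_c.family == "pareto" and law_c.params["alpha"] < 1.0 and law_o.has_finite_mean:
        alpha = law_c.params["alpha"]
        return TailDescriptor(
            "power_law",
            exponent=alpha,
            note=(
                "psi_C(s) ~ 1 - Gamma(1-alpha)(t_min*s)^alpha as s->0; closed-state "
                "survival ~ t^-alpha and p_open decays ~ t^(alpha-1)"
            ),
        )
    raise NotImplementedError(
        f"tail classification not implemented for families "
        f"(C={law_c.family}, O={law_o.family})"
    )


# ---------------------------------------------------------------------------
# dwell statistics and temperature sweeps
# ---------------------------------------------------------------------------

def dwell_statistics(trajectories) -> pd.DataFrame:
    """Per-state mean residence times and effective rates from trajectories.

    The final (right-censored) dwell of each trajectory is excluded to avoid
    a length-biased underestimate.  States with no completed dwell are
    reported with ``n_events = 0`` and NaN statistics, never as zero.
    Effective rates are the reciprocal mean 1/<tau>.
    """
    if isinstance(trajectories, Trajectory):
        trajectories = [trajectories]
    trajectories = list(trajectories)
    if not trajectories:
        raise ValueError("need at least one trajectory")
    pools: dict = {}
    for traj in trajectories:
        for lbl in set(traj.states):
            pools.setdefault(lbl, [])
        for lbl, theta in list(zip(traj.states, traj.durations))[:-1]:  # drop censored tail
            pools.setdefault(lbl, []).append(theta)
    rows = []
    for lbl, values in sorted(pools.items()):
        n = len(values)
        mean = float(np.mean(values)) if n else math.nan
        rows.append(
            {
                "state": lbl,
                "n_events": n,
                "mean_dwell_s": mean,
                "effective_rate_per_s": 1.0 / mean if n else math.nan,
            }
        )
    return pd.DataFrame(rows).set_index("state")


def temperature_rate_sweep(
    thermo: ThermoParams,
    scheme: GatingScheme,
    T_grid,
    method: str = "analytic",
    n_traj: int = 200,
    duration_cycles: float = 50.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Effective opening/closing rates across a temperature grid.

    At each temperature the closed- and open-state dwell laws are rescaled so
    their means equal 1/k(T) with k(T) the Eyring rate for that direction
    (shape parameters untouched: the minimal temperature coupling).  The
    effective rate is 1/<tau>; ``method='analytic'`` reports it exactly
    (1/<tau> = k(T) by construction), ``method='mc'`` estimates it from
    simulated trajectories via :func:`dwell_statistics`.
    """
    T_grid = np.atleast_1d(np.asarray(T_grid, dtype=float))
    if np.any((T_grid <= 250.0) | (T_grid >= 400.0)):
        raise ValueError("temperature grid must lie within (250 K, 400 K)")
    if scheme.topology != "two_state":
        raise NotImplementedError("temperature sweep is implemented for two-state schemes")
    rows = []
    for i, T in enumerate(T_grid):
        k_o = rate_constant(thermo, "open_transition", T)
        k_c = rate_constant(thermo, "close_transition", T)
        if method == "analytic":
            k_o_eff, k_c_eff = k_o, k_c
        elif method == "mc":
            sch_T = GatingScheme.two_state(
                scheme.law("C").with_mean(1.0 / k_o), scheme.law("O").with_mean(1.0 / k_c)
            )
            duration = duration_cycles * (1.0 / k_o + 1.0 / k_c)
            children = np.random.SeedSequence((seed, i)).spawn(n_traj)
            trajs = [
                sample_trajectory(sch_T, "C", duration, np.random.default_rng(c))
                for c in children
            ]
            stats = dwell_statistics(trajs)
            k_o_eff = stats.loc["C", "effective_rate_per_s"]
            k_c_eff = stats.loc["O", "effective_rate_per_s"]
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"temperature_K": T, "k_open_eff": k_o_eff, "k_close_eff": k_c_eff})
    return pd.DataFrame(rows)
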