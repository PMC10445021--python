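"""Kinetic gating schemes: states, topology and their dwell laws.

Two topologies are supported, both linear chains:

* ``two_state``         C <-> O
* ``three_state_linear``  C1 <-> C2 <-> O

Each state carries the residence-time law that governs how long the channel
stays there before exiting.  In the three-state chain the middle state C2
can exit either back to C1 or on to O; the branch is resolved by a
competing-risks branch probability ``branch_open_prob`` (the probability of
the C2 -> O choice), with the dwell duration drawn from C2's own law.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .dwell import DwellLaw
from .thermo import ThermoParams

__all__ = ["State", "GatingScheme", "load_scheme_json", "dump_scheme_json"]

TOPOLOGIES = ("two_state", "three_state_linear")
_STATE_ORDER = {"two_state": ("C", "O"), "three_state_linear": ("C1", "C2", "O")}


@dataclass(frozen=True)
class State:
    """A kinetic state: a label and its conductance weight (0 closed, 1 open)."""

    label: str
    conductance_weight: float

    def __post_init__(self) -> None:
        if self.label not in ("C", "O", "C1", "C2"):
            raise ValueError(f"unknown state label {self.label!r}")
        if self.conductance_weight not in (0.0, 1.0, 0, 1):
            raise ValueError("conductance_weight must be 0 (closed) or 1 (open)")

    @property
    def is_open(self) -> bool:
        return self.conductance_weight == 1


@dataclass(frozen=True)
class GatingScheme:
    """A linear-chain kinetic scheme with one dwell law per state."""

    topology: str
    dwell_laws: Mapping[str, DwellLaw]
    branch_open_prob: float = 0.5  # C2 -> O branch probability (three-state only)
    states: Sequence[State] = field(default=())

    def __post_init__(self) -> None:
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}; choose from {TOPOLOGIES}")
        labels = _STATE_ORDER[self.topology]
        if not self.states:
            object.__setattr__(
                self,
                "states",
                tuple(State(lbl, 1.0 if lbl == "O" else 0.0) for lbl in labels),
            )
        if tuple(s.label for s in self.states) != labels:
            raise ValueError(f"{self.topology} scheme must have states {labels}")
        object.__setattr__(self, "dwell_laws", dict(self.dwell_laws))
        if set(self.dwell_laws) != set(labels):
            raise ValueError(
                f"need exactly one dwell law per state {labels}, got {sorted(self.dwell_laws)}"
            )
        if not 0.0 <= self.branch_open_prob <= 1.0:
            raise ValueError("branch_open_prob must lie in [0, 1]")

    # -- constructors -----------------------------------------------------------
    @classmethod
    def two_state(cls, closed_law: DwellLaw, open_law: DwellLaw) -> "GatingScheme":
        return cls("two_state", {"C": closed_law, "O": open_law})

    @classmethod
    def three_state(
        cls,
        c1_law: DwellLaw,
        c2_law: DwellLaw,
        open_law: DwellLaw,
        branch_open_prob: float = 0.5,
    ) -> "GatingScheme":
        return cls(
            "three_state_linear",
            {"C1": c1_law, "C2": c2_law, "O": open_law},
            branch_open_prob=branch_open_prob,
        )

    @classmethod
    def two_state_markov(cls, k_open: float, k_close: float) -> "GatingScheme":
        """Markov limit: exponential dwells with opening rate 1/<tau_C> = k_open."""
        return cls.two_state(DwellLaw.exponential(k_open), DwellLaw.exponential(k_close))

    # -- queries ----------------------------------------------------------------
    @property
    def labels(self) -> tuple:
        return tuple(s.label for s in self.states)

    def state(self, label: str) -> State:
        for s in self.states:
            if s.label == label:
                return s
        raise KeyError(f"state {label!r} not in scheme {self.labels}")

    def law(self, label: str) -> DwellLaw:
        return self.dwell_laws[self.state(label).label]

    def open_labels(self) -> tuple:
        return tuple(s.label for s in self.states if s.is_open)

    def next_state(self, label: str, u_branch: float | None = None) -> str:
        """Successor of ``label`` along the chain.

        For C2 in a three-state chain the exit branches: it goes to O with
        probability ``branch_open_prob``, decided by the uniform variate
        ``u_branch``.
        """
        if self.topology == "two_state":
            return {"C": "O", "O": "C"}[self.state(label).label]
        if label == "C1":
            return "C2"
        if label == "O":
            return "C2"
        if label == "C2":
            if u_branch is None:
                raise ValueError("C2 exit requires a branch variate u_branch")
            return "O" if u_branch < self.branch_open_prob else "C1"
        raise KeyError(f"state {label!r} not in scheme {self.labels}")

    def to_dict(self) -> dict:
        return {
            "topology": self.topology,
            "dwell_laws": {lbl: law.to_dict() for lbl, law in self.dwell_laws.items()},
            "branch_open_prob": self.branch_open_prob,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GatingScheme":
        return cls(
            d["topology"],
            {lbl: DwellLaw.from_dict(ld) for lbl, ld in d["dwell_laws"].items()},
            branch_open_prob=d.get("branch_open_prob", 0.5),
        )


def dump_scheme_json(scheme: GatingScheme, thermo: ThermoParams | None, path) -> None:
    """Serialize a scheme (+ optional thermodynamic block) to a JSON document.

    Units: energies J/mol, rates 1/s, voltages mV, temperatures K.
    """
    doc = {"scheme": scheme.to_dict()}
    if thermo is not None:
        doc["thermo"] = thermo.to_dict()
    Path(path).write_text(json.dumps(doc, indent=2))


def load_scheme_json(path) -> tuple[GatingScheme, ThermoParams | None]:
    """Load and validate a scheme/thermo JSON document written by dump_scheme_json."""
    doc = json.loads(Path(path).read_text())
    if "scheme" not in doc:
        raise ValueError("scheme JSON must contain a 'scheme' block")
    scheme = GatingScheme.from_dict(doc["scheme"])
    thermo = ThermoParams.from_dict(doc["thermo"]) if "thermo" in doc else None
    return scheme, thermo
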