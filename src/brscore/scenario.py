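"""Scenario container and named-parameter access.

A scenario bundles everything needed to run the framework once: the
branching assumptions, the per-leaf effect weights, the counting mode
and descriptive metadata.  Sensitivity analyses address individual
quantities by name through :func:`get_parameter` / :func:`with_parameter`:

probability / size parameters
    ``cohort_size``, ``p_intent``, ``p_positive``, ``p_correct``,
    ``adherence.willing_positive``, ``adherence.willing_negative``,
    ``adherence.decliner_positive``, ``adherence.decliner_negative``
weight parameters (BRS is exactly linear in these)
    ``benefit_scale``, ``placebo_nocebo_scale``, ``side_effect_scale``
    (multiplicative, relative to the scenario's current weights; their
    current value therefore reads as 1), and single entries
    ``benefit[i]``, ``placebo_nocebo[i]``, ``side_effect[i]`` with a
    1-based leaf index.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Any

from .cohort import Adherence, BranchingAssumptions, LeafAllocation, allocate
from .errors import ValidationError
from .scoring import BRSResult, EffectWeights, compute_brs
from .tree import N_LEAVES

PROBABILITY_PARAMETERS = (
    "p_intent",
    "p_positive",
    "p_correct",
    "adherence.willing_positive",
    "adherence.willing_negative",
    "adherence.decliner_positive",
    "adherence.decliner_negative",
)
SCALE_PARAMETERS = ("benefit_scale", "placebo_nocebo_scale", "side_effect_scale")
_WEIGHT_ENTRY = re.compile(r"^(benefit|placebo_nocebo|side_effect)\[(\d+)\]$")


@dataclass(frozen=True)
class Scenario:
    """A fully specified benefit-risk scenario."""

    name: str
    assumptions: BranchingAssumptions
    weights: EffectWeights
    whole_patients: bool = False
    description: str = ""
    metadata: dict = field(default_factory=dict)

    def allocation(self) -> LeafAllocation:
        return allocate(self.assumptions, whole_patients=self.whole_patients)

    def run(self) -> BRSResult:
        """Allocate the cohort and evaluate the Benefit-Risk Score."""
        return compute_brs(self.allocation(), self.weights)

    def replace(self, **changes: Any) -> "Scenario":
        return _dc_replace(self, **changes)


def is_weight_parameter(name: str) -> bool:
    """True if BRS is exactly linear in this parameter (weight or scale)."""
    return name in SCALE_PARAMETERS or _WEIGHT_ENTRY.match(name) is not None


def parameter_domain(name: str) -> tuple[float, float]:
    """Valid (closed) range of a named parameter."""
    if name in PROBABILITY_PARAMETERS:
        return (0.0, 1.0)
    if name == "cohort_size":
        return (0.0, float("inf"))
    if is_weight_parameter(name):
        return (float("-inf"), float("inf"))
    raise ValidationError(f"unknown parameter {name!r}")


def get_parameter(scenario: Scenario, name: str) -> float:
    """Current value of a named parameter (scales read as 1)."""
    a = scenario.assumptions
    if name == "cohort_size":
        return a.cohort_size
    if name in ("p_intent", "p_positive", "p_correct"):
        return getattr(a, name)
    if name.startswith("adherence."):
        cell = name.split(".", 1)[1]
        if name in PROBABILITY_PARAMETERS:
            return getattr(a.adherence, cell)
    if name in SCALE_PARAMETERS:
        return 1.0
    m = _WEIGHT_ENTRY.match(name)
    if m:
        component, idx = m.group(1), int(m.group(2))
        if not 1 <= idx <= N_LEAVES:
            raise ValidationError(f"leaf index out of range in parameter {name!r}")
        return float(getattr(scenario.weights, component)[idx - 1])
    raise ValidationError(f"unknown parameter {name!r}")


def with_parameter(scenario: Scenario, name: str, value: float) -> Scenario:
    """Copy of the scenario with one named parameter set to ``value``.

    Raises :class:`ValidationError` for unknown names or out-of-domain
    values (probabilities outside [0, 1], non-positive cohort size).
    """
    value = float(value)
    a = scenario.assumptions
    if name == "cohort_size":
        return scenario.replace(assumptions=_dc_replace(a, cohort_size=value))
    if name in ("p_intent", "p_positive", "p_correct"):
        return scenario.replace(assumptions=_dc_replace(a, **{name: value}))
    if name.startswith("adherence.") and name in PROBABILITY_PARAMETERS:
        cell = name.split(".", 1)[1]
        adherence = Adherence(
            **{
                c: (value if c == cell else getattr(a.adherence, c))
                for c in (
                    "willing_positive",
                    "willing_negative",
                    "decliner_positive",
                    "decliner_negative",
                )
            }
        )
        return scenario.replace(assumptions=_dc_replace(a, adherence=adherence))
    if name in SCALE_PARAMETERS:
        return scenario.replace(weights=scenario.weights.scaled(**{name: value}))
    m = _WEIGHT_ENTRY.match(name)
    if m:
        component, idx = m.group(1), int(m.group(2))
        if not 1 <= idx <= N_LEAVES:
            raise ValidationError(f"leaf index out of range in parameter {name!r}")
        return scenario.replace(
            weights=scenario.weights.with_value(component, idx, value)
        )
    raise ValidationError(f"unknown parameter {name!r}")
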