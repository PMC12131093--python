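"""Sensitivity analysis: one-way sweeps, BRS = 0 thresholds, partial rollout.

BRS is multilinear in the branching probabilities and exactly linear in
the effect weights, so it is continuous in every named parameter.  The
threshold finder exploits this: for weight parameters the root of
BRS(x) = 0 is solved in closed form from two evaluations; for
probability parameters plain bisection is used (and cross-checked in the
test-suite against the closed form where both apply).

Partial implementation models the clinician-gatekeeper rollout in which
the tool is offered only to one a priori intent stratum (typically the
decliners): the exposed stratum follows the tool-influenced allocation,
the unexposed stratum keeps following its own intent and — since the
weights are deltas against exactly that behaviour — contributes zero
effect-points.  Adherence within the exposed stratum is kept unchanged;
how gatekeeping itself shifts adherence is not modelled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import LeafAllocation
from .errors import ValidationError
from .scoring import REFRAIN, BRSResult, compute_brs
from .scenario import (
    Scenario,
    get_parameter,
    is_weight_parameter,
    parameter_domain,
    with_parameter,
)

#: |BRS| at an accepted root, relative to cohort size (effect-points are
#: O(cohort_size)).
THRESHOLD_RTOL = 1e-6

EXPOSURE_RULES = ("all", "willing", "decliners", "none")


@dataclass(frozen=True)
class SweepResult:
    """BRS totals along a strictly increasing parameter grid."""

    parameter: str
    grid: np.ndarray
    totals: np.ndarray
    results: tuple[BRSResult, ...]
    crossings: tuple[float, ...]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.grid,
                "total_points": self.totals,
                "per_capita": [r.per_capita for r in self.results],
                "decision": [r.decision for r in self.results],
            }
        )


def _evaluate(scenario: Scenario, parameter: str, value: float) -> BRSResult:
    return with_parameter(scenario, parameter, value).run()


def one_way_sweep(scenario: Scenario, parameter: str, grid) -> SweepResult:
    """Recompute allocation and BRS at each grid value, all else fixed.

    The grid must be strictly increasing and inside the parameter's
    domain.  Sign changes between adjacent grid points are reported as
    linearly interpolated crossing locations.
    """
    values = np.asarray(list(grid), dtype=float)
    if values.size == 0:
        raise ValidationError("sweep grid is empty")
    if values.size > 1 and not np.all(np.diff(values) > 0):
        raise ValidationError("sweep grid must be strictly increasing")
    lo, hi = parameter_domain(parameter)
    if np.any(values < lo) or np.any(values > hi):
        raise ValidationError(
            f"grid values outside the domain [{lo}, {hi}] of {parameter!r}"
        )
    results = tuple(_evaluate(scenario, parameter, v) for v in values)
    totals = np.array([r.total_points for r in results])
    crossings = []
    for k in range(len(values) - 1):
        a, b = totals[k], totals[k + 1]
        if a == 0.0:
            crossings.append(float(values[k]))
        elif a * b < 0:
            crossings.append(float(values[k] - a * (values[k + 1] - values[k]) / (b - a)))
    if len(values) and totals[-1] == 0.0:
        crossings.append(float(values[-1]))
    return SweepResult(parameter, values, totals, results, tuple(crossings))


def _bisect(f, a: float, b: float, fa: float, fb: float, tol: float) -> float:
    for _ in range(200):
        mid = 0.5 * (a + b)
        fm = f(mid)
        if abs(fm) <= tol or (b - a) < 1e-15 * max(1.0, abs(a) + abs(b)):
            return mid
        if fa * fm <= 0:
            b, fb = mid, fm
        else:
            a, fa = mid, fm
    return 0.5 * (a + b)


def threshold(
    scenario: Scenario, parameter: str, interval: tuple[float, float]
) -> float | None:
    """Parameter value at which BRS crosses zero, or None.

    For weight parameters the score is exactly linear, so the root comes
    from a closed-form two-point solve; otherwise bisection is used.
    Returns None when BRS has the same (nonzero) sign at both interval
    ends.  If the score is identically zero on the interval every value
    is a root; the interval start is returned with a degeneracy warning.
    """
    a, b = float(interval[0]), float(interval[1])
    if not a < b:
        raise ValidationError("threshold interval must satisfy lower < upper")
    lo, hi = parameter_domain(parameter)
    if a < lo or b > hi:
        raise ValidationError(
            f"interval outside the domain [{lo}, {hi}] of {parameter!r}"
        )
    tol = THRESHOLD_RTOL * scenario.assumptions.cohort_size
    f = lambda x: _evaluate(scenario, parameter, x).total_points  # noqa: E731
    fa, fb = f(a), f(b)
    if fa == 0.0 and fb == 0.0:
        warnings.warn(
            f"BRS is identically zero across the interval for {parameter!r}; "
            "every value is a root",
            stacklevel=2,
        )
        return a
    if abs(fa) <= tol:
        return a
    if abs(fb) <= tol:
        return b
    if fa * fb > 0:
        return None
    if is_weight_parameter(parameter):
        root = a - fa * (b - a) / (fb - fa)
    else:
        root = _bisect(f, a, b, fa, fb, tol)
    if abs(f(root)) > tol:
        raise ValidationError(
            f"root refinement failed for {parameter!r}: |BRS| above tolerance"
        )
    return float(root)


def partial_implementation(scenario: Scenario, expose: str = "decliners") -> BRSResult:
    """BRS contribution of a gatekeeper rollout restricted by a priori intent.

    Parameters
    ----------
    scenario : Scenario
        Full-population scenario.
    expose : {"all", "willing", "decliners", "none"}
        Which a priori intent stratum is offered the tool.  Unexposed
        patients follow their own intent, which by construction of the
        delta weights contributes zero effect-points; the returned score
        is the exposed-stratum contribution only, with per-capita taken
        over the exposed patients.
    """
    if expose not in EXPOSURE_RULES:
        raise ValidationError(
            f"expose must be one of {EXPOSURE_RULES}, got {expose!r}"
        )
    full = scenario.allocation()
    mask = np.array(
        [
            expose == "all"
            or (expose == "willing" and leaf.intent)
            or (expose == "decliners" and not leaf.intent)
            for leaf in full.leaves
        ]
    )
    counts = np.where(mask, full.counts, 0.0)
    exposed = float(counts.sum())
    if exposed <= 0.0:
        warnings.warn(
            f"exposure rule {expose!r} selects no patients; BRS is 0", stacklevel=2
        )
        return BRSResult(
            total_points=0.0,
            per_capita=0.0,
            decision=REFRAIN,
            harmed_count=0.0,
            cohort_size=0.0,
        )
    allocation = LeafAllocation(counts, exposed, full.leaves)
    return compute_brs(allocation, scenario.weights)
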