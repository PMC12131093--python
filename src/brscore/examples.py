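"""Packaged worked example, random scenarios, and the microsimulation oracle.

The microsimulation draws individual synthetic patients through the four
sequential decisions (a priori intent, prediction, participation,
would-benefit status), accumulates each patient's effect triplet from
the leaf they land in, and rescales to the cohort size.  It shares no
code path with the analytic allocation and therefore serves as an
independent check that the expected-count model and the score formula
agree.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .cohort import Adherence, BranchingAssumptions
from .errors import ValidationError
from .io import load_scenario, scenario_from_dict
from .scenario import Scenario
from .scoring import EffectWeights
from .tree import N_LEAVES

#: Weight palettes the random generator draws from (the published scale).
_BENEFIT_PALETTE = (-3, -1, 0, 1, 3)
_MINOR_PALETTE = (-1, 0, 1)


@dataclass(frozen=True)
class ScenarioFixture:
    """A packaged scenario with its expected totals and provenance."""

    name: str
    scenario: Scenario
    expected_total_points: float | None = None
    expected_total_points_se_tripled: float | None = None
    expected_harmed_rounded: int | None = None
    provenance: str = ""


def osteoarthritis_scenario() -> ScenarioFixture:
    """The packaged osteoarthritis worked example.

    1000 patients, half a priori willing, improvement predicted for
    three quarters, aligned-prediction adherence 29/30, decliner
    conversion 1/2, willing persistence under a negative prediction 1/3,
    prediction correctness 3/5, whole-patient counting, and the pinned
    weight table.  Expected totals: 832 effect-points (1026 with
    side-effect weights at +-3) and 40 harmed patients.
    """
    with resources.as_file(
        resources.files("brscore.data").joinpath("osteoarthritis.yaml")
    ) as path:
        scenario = load_scenario(path)
    expected = scenario.metadata.get("expected", {})
    return ScenarioFixture(
        name=scenario.name,
        scenario=scenario,
        expected_total_points=expected.get("total_points"),
        expected_total_points_se_tripled=expected.get("total_points_se_tripled"),
        expected_harmed_rounded=expected.get("harmed_rounded"),
        provenance=str(expected.get("provenance", "")),
    )


def list_examples() -> tuple[str, ...]:
    return ("osteoarthritis",)


def random_scenario(seed: int, cohort_size: float | None = None) -> ScenarioFixture:
    """A valid random scenario, deterministic per seed.

    Probabilities are uniform on [0, 1]; weights are drawn from the
    published discrete palette ({-3,-1,0,1,3} for B, {-1,0,1} for PNE
    and SE); the cohort size, unless given, is uniform on [100, 10000].
    """
    rng = np.random.default_rng(seed)
    if cohort_size is None:
        cohort_size = float(rng.uniform(100.0, 10_000.0))
    probs = rng.uniform(0.0, 1.0, size=7)
    assumptions = BranchingAssumptions(
        cohort_size=cohort_size,
        p_intent=probs[0],
        p_positive=probs[1],
        adherence=Adherence(*probs[2:6]),
        p_correct=probs[6],
    )
    weights = EffectWeights(
        rng.choice(_BENEFIT_PALETTE, size=N_LEAVES).astype(float),
        rng.choice(_MINOR_PALETTE, size=N_LEAVES).astype(float),
        rng.choice(_MINOR_PALETTE, size=N_LEAVES).astype(float),
    )
    scenario = Scenario(
        name=f"random-{seed}",
        assumptions=assumptions,
        weights=weights,
        whole_patients=False,
    )
    return ScenarioFixture(
        name=scenario.name, scenario=scenario, provenance=f"random draw, seed={seed}"
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Monte-Carlo estimate of the BRS from individual patient draws."""

    total_points: float
    standard_error: float
    leaf_counts: np.ndarray  # simulated patients per leaf (out of m)
    m: int
    seed: int

    def leaf_frequencies(self) -> np.ndarray:
        return self.leaf_counts / self.m


def microsim_oracle(scenario: Scenario, m: int, seed: int) -> MicrosimResult:
    """Simulate ``m`` patients and estimate total effect-points.

    Each patient is drawn through intent -> prediction -> participation
    -> would-benefit status, scored with the per-leaf triplet sum of the
    scenario's weights, and the mean is rescaled to the cohort size.
    The reported standard error is the sample standard error of the
    rescaled mean (zero when all probabilities are degenerate).
    """
    if m < 1:
        raise ValidationError(f"microsimulation needs m >= 1, got {m}")
    a = scenario.assumptions
    rng = np.random.default_rng(seed)
    intent = rng.random(m) < a.p_intent
    prediction = rng.random(m) < a.p_positive
    # participation probability per patient from the intent x prediction cell
    p_part = np.choose(
        intent.astype(int) * 2 + prediction.astype(int),
        [
            a.adherence.decliner_negative,
            a.adherence.decliner_positive,
            a.adherence.willing_negative,
            a.adherence.willing_positive,
        ],
    )
    participation = rng.random(m) < p_part
    p_benefit = np.where(prediction, a.p_correct, 1.0 - a.p_correct)
    outcome = rng.random(m) < p_benefit

    # canonical leaf position (0-based): attribute "yes" sorts first
    pos = (
        (~intent).astype(int) * 8
        + (~prediction).astype(int) * 4
        + (~participation).astype(int) * 2
        + (~outcome).astype(int)
    )
    leaf_counts = np.bincount(pos, minlength=N_LEAVES).astype(float)
    points = scenario.weights.combined()[pos]
    scale = a.cohort_size
    total = float(points.mean() * scale)
    if m > 1:
        se = float(points.std(ddof=1) / np.sqrt(m) * scale)
    else:
        se = float("inf")
    return MicrosimResult(
        total_points=total,
        standard_error=se,
        leaf_counts=leaf_counts,
        m=m,
        seed=seed,
    )


__all__ = [
    "MicrosimResult",
    "ScenarioFixture",
    "list_examples",
    "microsim_oracle",
    "osteoarthritis_scenario",
    "random_scenario",
    "scenario_from_dict",
]
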