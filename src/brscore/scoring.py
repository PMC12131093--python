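"""Per-leaf effect weights and the Benefit-Risk Score.

The Benefit-Risk Score (BRS) condenses the population-level consequences
of implementing a personalized prognostic tool into one number:

    BRS = sum_{i=1..16} n_i * (B_i + PNE_i + SE_i)

where n_i is the number of patients in leaf i and the triplet
(B_i, PNE_i, SE_i) quantifies, on one common additive scale, how much a
patient in that leaf gains or loses *relative to the no-tool world* in
direct benefit/harm (B), placebo/nocebo effect (PNE) and treatment side
effects (SE).  BRS > 0 favours implementing the tool; BRS <= 0 favours
refraining.

The default weights encode the published palette:

* B = +3 / -3 for a decision flipped into / away from a treatment the
  patient would benefit from; +1 / -1 when the flip merely avoids or
  wastes effort (flipped away from / into a non-beneficial treatment);
  0 for unchanged decisions.
* PNE = +1 for every treated patient under an improvement prediction
  (positive expectations can act even without true benefit); -1 for a
  treated patient under a no-improvement prediction *who would benefit*
  (a nocebo can only dampen an improvement that would otherwise occur);
  0 elsewhere.
* SE = +1 / -1 for patients flipped into / out of treatment when the
  treatment's side-effect profile is favourable (sign reversed for an
  adverse profile, 0 for neutral); aligned leaves keep their baseline
  side effects, so their delta is 0.

A per-leaf ``catastrophic`` veto flag is provided for harms that no sum
of benefits may outweigh: if any occupied leaf is marked catastrophic the
decision is forced to "refrain" regardless of the score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import LeafAllocation
from .errors import ValidationError
from .tree import N_LEAVES, OutcomeLeaf, build_tree, classify_leaf

IMPLEMENT = "implement"
REFRAIN = "refrain"

#: Discrete palette the published example draws its weights from.
BENEFIT_PALETTE = (-3, -1, 0, 1, 3)
MINOR_PALETTE = (-1, 0, 1)


@dataclass(frozen=True)
class SideEffectProfile:
    """Treatment side-effect sign and expectation-effect applicability.

    Parameters
    ----------
    sign : int
        +1 if the treatment's side effects are on balance favourable
        (e.g. exercise therapy improving general health), -1 if adverse,
        0 if negligible.
    placebo_applies : bool
        Whether communicated positive predictions can raise outcomes of
        treated patients.
    nocebo_requires_benefit : bool
        If True (default), the nocebo penalty is restricted to treated
        patients who would actually improve — negative expectations
        dampen an improvement, they do not create one to lose.
    """

    sign: int = 0
    placebo_applies: bool = True
    nocebo_requires_benefit: bool = True

    def __post_init__(self) -> None:
        if self.sign not in (-1, 0, 1):
            raise ValidationError(
                f"side-effect profile sign must be -1, 0 or +1, got {self.sign!r}"
            )

    @classmethod
    def positive(cls) -> "SideEffectProfile":
        return cls(sign=1)

    @classmethod
    def neutral(cls) -> "SideEffectProfile":
        return cls(sign=0)

    @classmethod
    def negative(cls) -> "SideEffectProfile":
        return cls(sign=-1)


def _weight_array(name: str, values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.shape != (N_LEAVES,):
        raise ValidationError(f"{name} must have one value per leaf (16), got {arr.shape}")
    if np.any(np.isnan(arr)):
        raise ValidationError(f"{name} contains NaN")
    arr.setflags(write=False)
    return arr


@dataclass(frozen=True)
class EffectWeights:
    """Per-leaf (B_i, PNE_i, SE_i) triplets on one common additive scale.

    Scale coherence is the user's contract: if the true benefit is three
    times the placebo effect, B_i should be three times PNE_i.  The
    arrays are in canonical leaf order (index i at position i-1).
    """

    benefit: np.ndarray
    placebo_nocebo: np.ndarray
    side_effect: np.ndarray
    catastrophic: np.ndarray = field(
        default_factory=lambda: np.zeros(N_LEAVES, dtype=bool)
    )

    def __post_init__(self) -> None:
        object.__setattr__(self, "benefit", _weight_array("benefit", self.benefit))
        object.__setattr__(
            self, "placebo_nocebo", _weight_array("placebo_nocebo", self.placebo_nocebo)
        )
        object.__setattr__(
            self, "side_effect", _weight_array("side_effect", self.side_effect)
        )
        cat = np.asarray(self.catastrophic, dtype=bool)
        if cat.shape != (N_LEAVES,):
            raise ValidationError("catastrophic flags must have one entry per leaf")
        cat.setflags(write=False)
        object.__setattr__(self, "catastrophic", cat)

    @classmethod
    def zeros(cls) -> "EffectWeights":
        return cls(np.zeros(N_LEAVES), np.zeros(N_LEAVES), np.zeros(N_LEAVES))

    def triplet(self, index: int) -> tuple[float, float, float]:
        """(B_i, PNE_i, SE_i) for a 1-based leaf index."""
        if not 1 <= index <= N_LEAVES:
            raise KeyError(index)
        i = index - 1
        return (
            float(self.benefit[i]),
            float(self.placebo_nocebo[i]),
            float(self.side_effect[i]),
        )

    def combined(self) -> np.ndarray:
        """B_i + PNE_i + SE_i per leaf."""
        return self.benefit + self.placebo_nocebo + self.side_effect

    def scaled(
        self,
        benefit_scale: float = 1.0,
        placebo_nocebo_scale: float = 1.0,
        side_effect_scale: float = 1.0,
    ) -> "EffectWeights":
        """Multiply each component by a scalar (used in sensitivity sweeps)."""
        return EffectWeights(
            self.benefit * benefit_scale,
            self.placebo_nocebo * placebo_nocebo_scale,
            self.side_effect * side_effect_scale,
            self.catastrophic,
        )

    def with_value(self, component: str, index: int, value: float) -> "EffectWeights":
        """Return a copy with one weight replaced (1-based leaf index)."""
        if component not in ("benefit", "placebo_nocebo", "side_effect"):
            raise ValidationError(f"unknown weight component {component!r}")
        if not 1 <= index <= N_LEAVES:
            raise ValidationError(f"leaf index must be in 1..16, got {index}")
        arr = np.array(getattr(self, component))
        arr[index - 1] = float(value)
        return replace(self, **{component: arr})


def default_weights(
    tree: tuple[OutcomeLeaf, ...] | None = None,
    profile: SideEffectProfile | None = None,
) -> EffectWeights:
    """Rule-derived weights relative to the follow-own-intent world.

    Encodes the published palette (see module docstring).  With the
    favourable side-effect profile this reproduces the packaged
    osteoarthritis weight table exactly.

    Parameters
    ----------
    tree : tuple of OutcomeLeaf, optional
        Canonical tree; built if omitted.
    profile : SideEffectProfile, optional
        Treatment profile; defaults to the favourable profile of
        education-and-exercise therapy.
    """
    if profile is None:
        profile = SideEffectProfile.positive()
    if not isinstance(profile, SideEffectProfile):
        raise ValidationError("profile must be a SideEffectProfile")
    leaves = tree if tree is not None else build_tree()
    benefit = np.zeros(N_LEAVES)
    pne = np.zeros(N_LEAVES)
    side = np.zeros(N_LEAVES)
    for leaf in leaves:
        cls = classify_leaf(leaf)
        i = leaf.index - 1
        if cls.flipped:
            if leaf.participation:
                benefit[i] = 3.0 if leaf.outcome else -1.0
            else:
                benefit[i] = -3.0 if leaf.outcome else 1.0
            side[i] = profile.sign * (1.0 if leaf.participation else -1.0)
        if cls.placebo_affected and profile.placebo_applies:
            pne[i] = 1.0
        elif cls.nocebo_affected:
            if leaf.outcome or not profile.nocebo_requires_benefit:
                pne[i] = -1.0
    return EffectWeights(benefit, pne, side)


@dataclass(frozen=True)
class BRSResult:
    """Outcome of the Benefit-Risk Score computation.

    ``harmed_count`` is the fractional expected number of patients in
    harm-pattern leaves (a priori willing, untreated, would benefit);
    ``harmed_rounded`` is its report-level integer.
    """

    total_points: float
    per_capita: float
    decision: str
    harmed_count: float
    cohort_size: float
    vetoed: bool = False

    @property
    def harmed_rounded(self) -> int:
        return int(math.floor(self.harmed_count + 0.5))


def harmed_count(
    allocation: LeafAllocation, tree: tuple[OutcomeLeaf, ...] | None = None
) -> float:
    """Expected patients harmed by forgoing a treatment they needed.

    Sums n_i over leaves where an a priori willing patient ends up
    untreated although they would have benefited — the severe-harm
    pattern (false-negative-driven flips) plus its unlikely
    positive-prediction counterpart.
    """
    leaves = tree if tree is not None else allocation.leaves
    return float(
        sum(
            allocation[leaf.index]
            for leaf in leaves
            if leaf.intent and not leaf.participation and leaf.outcome
        )
    )


def compute_brs(
    allocation: LeafAllocation,
    weights: EffectWeights,
    tree: tuple[OutcomeLeaf, ...] | None = None,
) -> BRSResult:
    """Evaluate BRS = sum_i n_i (B_i + PNE_i + SE_i) over the 16 leaves.

    Parameters
    ----------
    allocation : LeafAllocation
        Patient counts per leaf (fractional or whole).
    weights : EffectWeights
        Per-leaf effect triplets on a common scale.
    tree : tuple of OutcomeLeaf, optional
        Leaf set; must match the allocation's.

    Returns
    -------
    BRSResult
        Total effect-points, per-capita score, implement/refrain
        decision (implement iff total > 0 and no catastrophic leaf is
        occupied) and the harmed-subgroup count.
    """
    if not isinstance(allocation, LeafAllocation):
        raise ValidationError("allocation must be a LeafAllocation")
    if not isinstance(weights, EffectWeights):
        raise ValidationError("weights must be an EffectWeights")
    leaves = tree if tree is not None else allocation.leaves
    if tuple(leaves) != tuple(allocation.leaves):
        raise ValidationError("allocation and weights must cover the same 16 leaves")
    total = float(allocation.counts @ weights.combined())
    vetoed = bool(np.any(weights.catastrophic & (allocation.counts > 0)))
    decision = IMPLEMENT if (total > 0 and not vetoed) else REFRAIN
    return BRSResult(
        total_points=total,
        per_capita=total / allocation.cohort_size,
        decision=decision,
        harmed_count=harmed_count(allocation, leaves),
        cohort_size=allocation.cohort_size,
        vetoed=vetoed,
    )


def decide(result: BRSResult) -> str:
    """Implement/refrain rule: implement iff total_points > 0.

    A score of exactly zero (to floating tolerance) is treated as
    refrain and raises a warning, since it means the stated benefits and
    harms balance and the comparison carries no signal.  A catastrophic
    veto always forces refrain.
    """
    if result.vetoed:
        warnings.warn(
            "a catastrophic leaf is occupied: decision forced to refrain", stacklevel=2
        )
        return REFRAIN
    if result.total_points == 0:
        warnings.warn(
            "BRS is exactly zero: benefits and harms balance, refraining", stacklevel=2
        )
        return REFRAIN
    return IMPLEMENT if result.total_points > 0 else REFRAIN
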