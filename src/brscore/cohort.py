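"""Analytic allocation of a patient cohort across the 16 outcome leaves.

Given stated branching probabilities — a priori willingness, positive
prediction rate, adherence to the prediction in each intent x prediction
cell, and prediction correctness — the expected number of patients in
leaf *i* is the product of the probabilities along its path:

    n_i = N * P(intent) * P(prediction) * P(participation | intent, prediction)
            * P(would-benefit | prediction)

Correctness is conditioned on the prediction sign only:
P(would-benefit | improve) = p_correct and
P(would-benefit | no-improve) = 1 - p_correct.  Prediction is assumed
independent of a priori intent; a correlation hook exists in the schema
but is rejected until its semantics are validated.

Two counting modes are provided.  The default yields exact fractional
expected counts.  ``whole_patients=True`` emulates a spreadsheet filled
with whole patients: at every binary split the first branch is rounded
half away from zero and the sibling receives the remainder, so the
cohort total is conserved exactly.  The packaged osteoarthritis worked
example uses the whole-patient mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .tree import (
    INTENT_LABELS,
    N_LEAVES,
    OUTCOME_LABELS,
    PARTICIPATION_LABELS,
    PREDICTION_LABELS,
    OutcomeLeaf,
    build_tree,
)

_REL_TOL = 1e-9


def _check_probability(name: str, value: float) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"{name} must be a number, got {value!r}") from None
    if not 0.0 <= value <= 1.0 or math.isnan(value):
        raise ValidationError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class Adherence:
    """Participation probabilities per a priori intent x prediction cell.

    ``willing_positive`` is the probability that an a priori willing
    patient treated to an improvement prediction actually participates
    (follows the aligned positive prediction); ``decliner_negative`` the
    probability that an a priori decliner participates despite an aligned
    negative prediction (so 1 minus it is their adherence to that
    prediction); the two cross cells are the conversion probabilities.
    """

    willing_positive: float
    willing_negative: float
    decliner_positive: float
    decliner_negative: float

    def __post_init__(self) -> None:
        for name in (
            "willing_positive",
            "willing_negative",
            "decliner_positive",
            "decliner_negative",
        ):
            object.__setattr__(
                self, name, _check_probability(f"adherence.{name}", getattr(self, name))
            )

    def probability(self, intent: bool, prediction: bool) -> float:
        """P(participation | intent, prediction)."""
        if intent:
            return self.willing_positive if prediction else self.willing_negative
        return self.decliner_positive if prediction else self.decliner_negative

    @classmethod
    def follow_intent(cls) -> "Adherence":
        """Adherence cells of the no-tool world: participation == intent."""
        return cls(1.0, 1.0, 0.0, 0.0)


@dataclass(frozen=True)
class BranchingAssumptions:
    """The probabilities that allocate a cohort across the tree.

    Parameters
    ----------
    cohort_size : float
        Number of patients, > 0.  Fractional sizes are allowed in the
        expected-count mode.
    p_intent : float
        Probability a patient is a priori willing to follow the
        recommended treatment.
    p_positive : float
        Probability the tool predicts an improvement.
    adherence : Adherence
        Participation probabilities per intent x prediction cell.
    p_correct : float
        Probability a prediction is correct regarding benefit.  Applied
        per prediction sign: P(benefit | improve) = p_correct and
        P(benefit | no-improve) = 1 - p_correct.
    intent_prediction_correlation : float, optional
        Reserved.  Only 0 (independence) is accepted in this version.
    """

    cohort_size: float
    p_intent: float
    p_positive: float
    adherence: Adherence
    p_correct: float
    intent_prediction_correlation: float = 0.0

    def __post_init__(self) -> None:
        try:
            size = float(self.cohort_size)
        except (TypeError, ValueError):
            raise ValidationError(
                f"cohort_size must be a number, got {self.cohort_size!r}"
            ) from None
        if not size > 0 or math.isinf(size) or math.isnan(size):
            raise ValidationError(f"cohort_size must be > 0, got {self.cohort_size}")
        object.__setattr__(self, "cohort_size", size)
        for name in ("p_intent", "p_positive", "p_correct"):
            object.__setattr__(self, name, _check_probability(name, getattr(self, name)))
        if not isinstance(self.adherence, Adherence):
            raise ValidationError("adherence must be an Adherence instance")
        if float(self.intent_prediction_correlation) != 0.0:
            raise ValidationError(
                "intent_prediction_correlation is reserved: only 0 (independence "
                "between a priori intent and the prediction) is supported"
            )

    def p_benefit(self, prediction: bool) -> float:
        """P(would-benefit | prediction sign)."""
        return self.p_correct if prediction else 1.0 - self.p_correct

    def leaf_probability(self, leaf: OutcomeLeaf) -> float:
        """Path probability of one leaf under the tool-influenced world."""
        p_i = self.p_intent if leaf.intent else 1.0 - self.p_intent
        p_p = self.p_positive if leaf.prediction else 1.0 - self.p_positive
        p_t = self.adherence.probability(leaf.intent, leaf.prediction)
        if not leaf.participation:
            p_t = 1.0 - p_t
        p_o = self.p_benefit(leaf.prediction)
        if not leaf.outcome:
            p_o = 1.0 - p_o
        return p_i * p_p * p_t * p_o


@dataclass(frozen=True)
class LeafAllocation:
    """Expected patient count per leaf; conserves the cohort size.

    ``counts[i - 1]`` holds n_i for canonical leaf index i.  Indexing the
    object with a 1-based leaf index returns that count.
    """

    counts: np.ndarray
    cohort_size: float
    leaves: tuple[OutcomeLeaf, ...] = field(default_factory=build_tree)

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (N_LEAVES,):
            raise ValidationError(f"counts must have shape (16,), got {counts.shape}")
        if np.any(counts < -_REL_TOL * self.cohort_size) or np.any(np.isnan(counts)):
            raise ValidationError("leaf counts must be non-negative")
        total = float(counts.sum())
        if abs(total - self.cohort_size) > _REL_TOL * max(1.0, abs(self.cohort_size)):
            raise ValidationError(
                f"leaf counts sum to {total}, expected cohort_size {self.cohort_size}"
            )
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    def __getitem__(self, index: int) -> float:
        if not 1 <= index <= N_LEAVES:
            raise KeyError(index)
        return float(self.counts[index - 1])

    def as_series(self) -> pd.Series:
        """Counts as a pandas Series indexed by canonical leaf index."""
        return pd.Series(self.counts, index=range(1, N_LEAVES + 1), name="n")

    def as_frame(self) -> pd.DataFrame:
        """Counts with the four leaf attributes, one row per leaf."""
        rows = []
        for leaf, n in zip(self.leaves, self.counts):
            rows.append(
                {
                    "leaf": leaf.index,
                    "intent": INTENT_LABELS[leaf.intent],
                    "prediction": PREDICTION_LABELS[leaf.prediction],
                    "participation": PARTICIPATION_LABELS[leaf.participation],
                    "outcome": OUTCOME_LABELS[leaf.outcome],
                    "n": float(n),
                }
            )
        return pd.DataFrame(rows).set_index("leaf")


def _round_half_away(x: float) -> int:
    # Excel-style ROUND(x, 0) for non-negative x; tiny epsilon guards the
    # float representation of exact halves like 362.5.
    return int(math.floor(x + 0.5 + 1e-9))


def _whole_counts(assumptions: BranchingAssumptions) -> np.ndarray:
    """Spreadsheet-style allocation in whole patients.

    At each binary split the first branch (willing / improve / treated /
    would-benefit) is rounded half away from zero and the second branch
    receives the remainder, so every level — and hence the total — adds
    up exactly.
    """
    counts = np.zeros(N_LEAVES)
    total = _round_half_away(assumptions.cohort_size)
    n_intent = {True: _round_half_away(total * assumptions.p_intent)}
    n_intent[False] = total - n_intent[True]
    pos = 0
    for intent in (True, False):
        n_pred = {True: _round_half_away(n_intent[intent] * assumptions.p_positive)}
        n_pred[False] = n_intent[intent] - n_pred[True]
        for prediction in (True, False):
            p_t = assumptions.adherence.probability(intent, prediction)
            n_part = {True: _round_half_away(n_pred[prediction] * p_t)}
            n_part[False] = n_pred[prediction] - n_part[True]
            for participation in (True, False):
                p_b = assumptions.p_benefit(prediction)
                n_ben = _round_half_away(n_part[participation] * p_b)
                counts[pos] = n_ben
                counts[pos + 1] = n_part[participation] - n_ben
                pos += 2
    return counts


def allocate(
    assumptions: BranchingAssumptions,
    tree: tuple[OutcomeLeaf, ...] | None = None,
    *,
    whole_patients: bool = False,
) -> LeafAllocation:
    """Allocate the cohort across the 16 leaves of the tool-influenced world.

    Parameters
    ----------
    assumptions : BranchingAssumptions
        Validated branching probabilities.
    tree : tuple of OutcomeLeaf, optional
        The canonical tree; built if omitted.
    whole_patients : bool
        If True, emulate a spreadsheet filled with whole patients (round
        half away from zero at every split, remainder to the sibling).
        Default is exact fractional expected counts.

    Returns
    -------
    LeafAllocation
        Counts in canonical leaf order; their sum equals the cohort size
        (exactly in whole-patient mode, to 1e-9 relative otherwise).
    """
    leaves = tree if tree is not None else build_tree()
    if whole_patients:
        counts = _whole_counts(assumptions)
        return LeafAllocation(counts, float(counts.sum()), tuple(leaves))
    counts = np.array([
        assumptions.cohort_size * assumptions.leaf_probability(leaf) for leaf in leaves
    ])
    return LeafAllocation(counts, assumptions.cohort_size, tuple(leaves))


def baseline_allocation(
    assumptions: BranchingAssumptions,
    tree: tuple[OutcomeLeaf, ...] | None = None,
) -> LeafAllocation:
    """Allocation of the no-tool comparator world.

    Without the tool every patient follows their a priori intent, so
    participation equals intent with probability one; the prediction
    margin is kept so the same 16 leaves can be compared, but it has no
    behavioural effect.  Used as a reporting reference only — the effect
    weights already encode changes relative to this world.
    """
    baseline = BranchingAssumptions(
        cohort_size=assumptions.cohort_size,
        p_intent=assumptions.p_intent,
        p_positive=assumptions.p_positive,
        adherence=Adherence.follow_intent(),
        p_correct=assumptions.p_correct,
    )
    return allocate(baseline, tree)
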