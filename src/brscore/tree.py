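"""The 16-possibility outcome tree for a personalized prognostic tool.

When a personalized outcome-prediction tool is introduced on top of a
one-size-fits-all treatment recommendation, what happens to a patient is
determined by four binary attributes:

``intent``
    whether the patient was a priori willing to follow the recommended
    treatment (before seeing any personalized prediction),
``prediction``
    whether the tool predicts an outcome improvement for this patient,
``participation``
    whether the patient actually receives the treatment after seeing the
    prediction, and
``outcome``
    whether the patient *would benefit* from the treatment.  This is a
    counterfactual would-benefit status, so it is defined for participants
    and non-participants alike; a prediction is "correct" exactly when it
    matches this status.

The cross product yields 16 terminal possibilities ("leaves").  Leaves are
indexed 1..16 in canonical lexicographic order over
(intent: yes < no, prediction: improve < no-improve,
participation: yes < no, outcome: benefit < no-benefit), so leaf 1 is the
fully positive path and leaf 16 the fully negative one.

Each leaf carries derived classification flags (see
:class:`LeafClassification`): whether the tool flipped the treatment
decision, whether a placebo or nocebo effect can act, whether the leaf is
the harm pattern (treatment forgone that would have helped) or the
top-benefit pattern (a converted decliner who benefits), and whether the
leaf is behaviourally unlikely (the patient contradicts their own intent
despite a recommendation that agreed with it).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

from .errors import ValidationError

N_LEAVES = 16

#: Human-readable attribute levels used in exported tables.
INTENT_LABELS = {True: "willing", False: "decliner"}
PREDICTION_LABELS = {True: "improve", False: "no-improve"}
PARTICIPATION_LABELS = {True: "treated", False: "untreated"}
OUTCOME_LABELS = {True: "benefit", False: "no-benefit"}


def _attributes(index: int) -> tuple[bool, bool, bool, bool]:
    """Canonical attributes for a 1-based leaf index."""
    b = index - 1
    return (b & 8 == 0, b & 4 == 0, b & 2 == 0, b & 1 == 0)


def leaf_index(intent: bool, prediction: bool, participation: bool, outcome: bool) -> int:
    """Canonical 1-based index of the leaf with the given attributes."""
    return 1 + (
        (0 if intent else 8)
        | (0 if prediction else 4)
        | (0 if participation else 2)
        | (0 if outcome else 1)
    )


@dataclass(frozen=True)
class OutcomeLeaf:
    """One of the 16 terminal possibilities of the outcome tree.

    Attributes
    ----------
    index : int
        Canonical 1-based position (1..16).
    intent : bool
        A priori willing to follow the recommended treatment.
    prediction : bool
        The tool predicts an outcome improvement.
    participation : bool
        The patient receives the treatment.
    outcome : bool
        The patient would benefit from the treatment (counterfactual).
    """

    index: int
    intent: bool
    prediction: bool
    participation: bool
    outcome: bool

    def __post_init__(self) -> None:
        if not 1 <= self.index <= N_LEAVES:
            raise ValidationError(f"leaf index must be in 1..16, got {self.index}")
        for name in ("intent", "prediction", "participation", "outcome"):
            if not isinstance(getattr(self, name), bool):
                raise ValidationError(f"leaf attribute {name!r} must be a bool")
        if _attributes(self.index) != (
            self.intent,
            self.prediction,
            self.participation,
            self.outcome,
        ):
            raise ValidationError(
                f"leaf attributes do not match canonical index {self.index}"
            )

    @classmethod
    def from_attributes(
        cls, intent: bool, prediction: bool, participation: bool, outcome: bool
    ) -> "OutcomeLeaf":
        return cls(
            leaf_index(intent, prediction, participation, outcome),
            intent,
            prediction,
            participation,
            outcome,
        )

    @classmethod
    def from_index(cls, index: int) -> "OutcomeLeaf":
        return cls(index, *_attributes(index))


@dataclass(frozen=True)
class LeafClassification:
    """Derived flags of a leaf; pure functions of its four attributes.

    ``aligned`` and ``flipped`` are mutually exclusive and exhaustive:
    the tool either left the patient's treatment decision where their a
    priori intent had it, or it flipped it.
    """

    aligned: bool
    flipped: bool
    placebo_affected: bool
    nocebo_affected: bool
    harm_leaf: bool
    top_benefit_leaf: bool
    unlikely: bool


def build_tree() -> tuple[OutcomeLeaf, ...]:
    """Enumerate the 16 leaves in canonical order.

    Returns
    -------
    tuple of OutcomeLeaf
        Exactly 16 leaves; every combination of the four binary
        attributes appears once, at its canonical index.
    """
    return tuple(OutcomeLeaf.from_index(i) for i in range(1, N_LEAVES + 1))


def classify_leaf(leaf: OutcomeLeaf) -> LeafClassification:
    """Classify a leaf of the canonical tree.

    Rules
    -----
    - ``flipped``: participation differs from a priori intent — the tool
      changed the decision.
    - ``placebo_affected``: the patient is treated under an improvement
      prediction, so positive expectations can boost the outcome.
    - ``nocebo_affected``: the patient is treated despite a no-improvement
      prediction, so negative expectations can dampen the outcome.
    - ``harm_leaf``: the tool flipped the patient out of a treatment they
      would actually have benefited from (the severe-harm pattern).
    - ``top_benefit_leaf``: an a priori decliner converted to treatment by
      an improvement prediction who then benefits — the best case the
      tool can produce.
    - ``unlikely``: the decision contradicts both the patient's intent and
      a recommendation aligned with that intent (e.g. a willing patient
      who declines after a favourable prediction).
    """
    if not isinstance(leaf, OutcomeLeaf):
        raise ValidationError("classify_leaf expects an OutcomeLeaf")
    flipped = leaf.participation != leaf.intent
    unlikely = flipped and (leaf.prediction == leaf.intent)
    return LeafClassification(
        aligned=not flipped,
        flipped=flipped,
        placebo_affected=leaf.participation and leaf.prediction,
        nocebo_affected=leaf.participation and not leaf.prediction,
        harm_leaf=flipped and not leaf.participation and leaf.outcome,
        top_benefit_leaf=(
            flipped and leaf.participation and leaf.outcome and not unlikely
        ),
        unlikely=unlikely,
    )


def node_path(leaf: OutcomeLeaf) -> tuple[str, str, str]:
    """Best-effort mapping from a leaf to the figure-style node labels.

    The tree is conventionally drawn with a B-level split on a priori
    intent (B1 willing / B2 decliner), D-level nodes for
    intent x prediction x participation (D1..D8, lexicographic), and
    E-level leaves with the would-benefit child first (E1..E16).  Under
    this layout every node named in the accompanying narrative lands
    consistently: the nocebo leaf is E5, the severe-harm leaf E7, the
    top-benefit leaf E9 and its no-benefit sibling E10, and the E-number
    coincides with the canonical leaf index.  The labels are an
    annotation for cross-referencing figures, not part of the index
    contract.
    """
    b = 1 if leaf.intent else 2
    d = 1 + (
        (0 if leaf.intent else 4)
        + (0 if leaf.prediction else 2)
        + (0 if leaf.participation else 1)
    )
    return (f"B{b}", f"D{d}", f"E{leaf.index}")


def iter_classified(
    tree: tuple[OutcomeLeaf, ...] | None = None,
) -> Iterator[tuple[OutcomeLeaf, LeafClassification]]:
    """Iterate ``(leaf, classification)`` pairs over the canonical tree."""
    for leaf in tree if tree is not None else build_tree():
        yield leaf, classify_leaf(leaf)
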