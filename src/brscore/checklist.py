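"""Pre-calculation checklist and the combined report.

Before trusting any benefit-risk calculation, the assumptions feeding it
should be made explicit.  The checklist walks through eleven questions —
how many patients the prediction tool could help or hurt, side effects,
expectation (placebo/nocebo) effects, whether all effects sit on one
coherent scale, further health outcomes, the option of a gatekeeper
rollout, and barriers/facilitators at four levels.  Entries can carry
optional numeric answers that prefill scenario parameters (keyed by the
same names :mod:`brscore.scenario` uses).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import yaml

from .errors import ScenarioParseError, ValidationError
from .scenario import Scenario, with_parameter
from .scoring import IMPLEMENT

#: The eleven checklist items: (id, question).
CHECKLIST_QUESTIONS: tuple[tuple[str, str], ...] = (
    (
        "benefit_count",
        "How many patients could the personalized prediction help, by steering "
        "them toward a treatment that helps them or away from one that harms them?",
    ),
    (
        "harm_count",
        "How many patients could the personalized prediction hurt, by steering "
        "them toward a treatment that harms them or away from one they need?",
    ),
    (
        "side_effect_counts",
        "How many patients would experience positive side effects of the "
        "treatment, and how many negative ones?",
    ),
    (
        "placebo_nocebo_influence",
        "How would placebo and nocebo effects — expectations raised or lowered "
        "by the communicated prediction — shift the outcomes?",
    ),
    (
        "uniform_scale_weights",
        "On one uniform scale, how heavily do the benefits, harms, "
        "placebo/nocebo effects and side effects each weigh?",
    ),
    (
        "additional_outcomes",
        "Are there further health outcomes to take into account (possibly as "
        "side effects)?",
    ),
    (
        "partial_implementation",
        "Could the harm to some patients be limited by a partial rollout, e.g. "
        "giving only clinicians access to the tool?",
    ),
    (
        "barriers_tool",
        "Which barriers and facilitators exist at the level of the tool or "
        "intervention itself?",
    ),
    (
        "barriers_personal",
        "Which barriers and facilitators exist at the personal level of "
        "patients and professionals?",
    ),
    (
        "barriers_institutional",
        "Which barriers and facilitators exist at the institutional or "
        "organizational level?",
    ),
    (
        "barriers_external",
        "Which barriers and facilitators exist in the external context, such "
        "as regulation?",
    ),
)

_IDS = tuple(i for i, _ in CHECKLIST_QUESTIONS)


@dataclass(frozen=True)
class ChecklistEntry:
    id: str
    question: str
    answer: str | None = None
    numbers: dict = field(default_factory=dict)

    @property
    def answered(self) -> bool:
        return self.answer is not None and self.answer.strip() != ""


@dataclass(frozen=True)
class Checklist:
    """The eleven-entry checklist; entries keyed by their fixed ids."""

    entries: tuple[ChecklistEntry, ...]

    def __post_init__(self) -> None:
        if tuple(e.id for e in self.entries) != _IDS:
            raise ValidationError(
                "checklist must contain exactly the eleven canonical entries in order"
            )

    @classmethod
    def blank(cls) -> "Checklist":
        return cls(tuple(ChecklistEntry(i, q) for i, q in CHECKLIST_QUESTIONS))

    def answer(self, entry_id: str, text: str, **numbers: float) -> "Checklist":
        """Copy of the checklist with one entry answered."""
        if entry_id not in _IDS:
            raise ValidationError(f"unknown checklist entry {entry_id!r}")
        entries = tuple(
            replace(e, answer=text, numbers=dict(numbers)) if e.id == entry_id else e
            for e in self.entries
        )
        return Checklist(entries)

    def __getitem__(self, entry_id: str) -> ChecklistEntry:
        for e in self.entries:
            if e.id == entry_id:
                return e
        raise KeyError(entry_id)

    @property
    def open_items(self) -> tuple[str, ...]:
        return tuple(e.id for e in self.entries if not e.answered)

    @property
    def complete(self) -> bool:
        return not self.open_items


def prefill_scenario(checklist: Checklist, scenario: Scenario) -> Scenario:
    """Apply the checklist's numeric answers to a scenario.

    Numeric fields are keyed by the parameter names of
    :mod:`brscore.scenario` (e.g. ``p_intent``, ``benefit[7]``).
    """
    for entry in checklist.entries:
        for name, value in entry.numbers.items():
            scenario = with_parameter(scenario, name, value)
    return scenario


def load_checklist(path) -> Checklist:
    """Load checklist answers from a YAML mapping of id -> answer or
    ``{answer: ..., numbers: {...}}``."""
    try:
        data = yaml.safe_load(open(path).read()) or {}
    except yaml.YAMLError as exc:
        raise ScenarioParseError(f"could not parse checklist {path}: {exc}") from exc
    checklist = Checklist.blank()
    for key, value in data.items():
        if isinstance(value, dict):
            checklist = checklist.answer(
                key, str(value.get("answer", "")), **(value.get("numbers") or {})
            )
        else:
            checklist = checklist.answer(key, str(value))
    return checklist


def checklist_report(checklist: Checklist, scenario: Scenario | None = None) -> str:
    """Markdown report of checklist status, optionally with the BRS summary.

    With a scenario attached the report runs the score and closes with a
    recommendation sentence keyed to the implement/refrain rule.
    """
    lines = ["# Benefit-risk checklist", ""]
    n_open = len(checklist.open_items)
    lines.append(
        f"{len(checklist.entries) - n_open} of {len(checklist.entries)} items "
        f"answered ({n_open} open)."
    )
    lines.append("")
    for k, entry in enumerate(checklist.entries, start=1):
        status = "answered" if entry.answered else "OPEN"
        lines.append(f"{k}. [{status}] {entry.question}")
        if entry.answered:
            lines.append(f"   Answer: {entry.answer}")
        if entry.numbers:
            pairs = ", ".join(f"{k2} = {v}" for k2, v in entry.numbers.items())
            lines.append(f"   Numbers: {pairs}")
    if scenario is not None:
        result = scenario.run()
        lines += [
            "",
            "## Benefit-Risk Score",
            "",
            f"Scenario: {scenario.name} "
            f"({'whole-patient' if scenario.whole_patients else 'expected'} counts)",
            f"Total effect-points: {_fmt(result.total_points)}",
            f"Per patient: {result.per_capita:.4g} "
            f"(cohort of {_fmt(result.cohort_size)})",
            f"Harmed patients (treatment forgone that would have helped): "
            f"{result.harmed_rounded} (expected {result.harmed_count:.1f})",
            f"Decision: {result.decision}",
            "",
            (
                "Recommendation: the score is positive, so creating and "
                "implementing the tool is favoured at the population level — "
                "provided the open checklist items are resolved."
                if result.decision == IMPLEMENT
                else "Recommendation: the score is not positive, so refraining "
                "from implementation (or a partial, gatekeeper-mediated rollout) "
                "is favoured."
            ),
        ]
    return "\n".join(lines) + "\n"


def _fmt(x: float) -> str:
    # integers render without trailing .0; counts keep one decimal
    if abs(x - round(x)) < 1e-9:
        return str(int(round(x)))
    return f"{x:.1f}"
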