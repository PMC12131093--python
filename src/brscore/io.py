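"""Scenario configs (YAML) and the calculation table (CSV / XLSX).

Scenario files are a small YAML dialect; probabilities may be written as
numbers or as exact fraction strings like ``"29/30"``.  The calculation
table is a diff-able CSV with exactly 16 data rows (one per leaf), the
scenario's defining numbers as ``#``-prefixed header comments and the
totals as ``#``-prefixed footer comments, so the file both documents a
run and reconstructs it: :func:`import_table` rebuilds the scenario and
result bit-identically (floats are written with full ``repr`` precision).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path

import numpy as np
import yaml

from .cohort import Adherence, BranchingAssumptions, LeafAllocation
from .errors import ScenarioParseError, ValidationError
from .scenario import Scenario
from .scoring import BRSResult, EffectWeights, compute_brs
from .tree import (
    INTENT_LABELS,
    N_LEAVES,
    OUTCOME_LABELS,
    PARTICIPATION_LABELS,
    PREDICTION_LABELS,
    build_tree,
    node_path,
)

_ADHERENCE_CELLS = (
    "willing_positive",
    "willing_negative",
    "decliner_positive",
    "decliner_negative",
)
_TABLE_COLUMNS = (
    "leaf",
    "node",
    "intent",
    "prediction",
    "participation",
    "outcome",
    "n",
    "benefit",
    "placebo_nocebo",
    "side_effect",
    "catastrophic",
    "points",
)


def parse_number(value, field: str) -> float:
    """Parse a YAML scalar that may be a number or an ``"a/b"`` fraction."""
    if isinstance(value, bool) or value is None:
        raise ScenarioParseError(f"field {field!r} must be a number, got {value!r}")
    if isinstance(value, (int, float)):
        return float(value)
    if isinstance(value, str):
        try:
            return float(Fraction(value))
        except (ValueError, ZeroDivisionError):
            raise ScenarioParseError(
                f"field {field!r} must be a number or a fraction string, got {value!r}"
            ) from None
    raise ScenarioParseError(f"field {field!r} must be a number, got {value!r}")


def _require(mapping: dict, field: str, context: str):
    if not isinstance(mapping, dict) or field not in mapping:
        raise ScenarioParseError(f"missing required field {context}{field!r}")
    return mapping[field]


def scenario_from_dict(data: dict, *, name: str | None = None) -> Scenario:
    """Build and validate a Scenario from a parsed config mapping."""
    if not isinstance(data, dict):
        raise ScenarioParseError("scenario config must be a mapping")
    probs = _require(data, "probabilities", "")
    adh_map = _require(probs, "adherence", "probabilities.")
    adherence = Adherence(
        **{
            cell: parse_number(
                _require(adh_map, cell, "probabilities.adherence."),
                f"probabilities.adherence.{cell}",
            )
            for cell in _ADHERENCE_CELLS
        }
    )
    try:
        assumptions = BranchingAssumptions(
            cohort_size=parse_number(_require(data, "cohort_size", ""), "cohort_size"),
            p_intent=parse_number(_require(probs, "intent", "probabilities."), "intent"),
            p_positive=parse_number(
                _require(probs, "positive_prediction", "probabilities."),
                "positive_prediction",
            ),
            adherence=adherence,
            p_correct=parse_number(
                _require(probs, "correct_prediction", "probabilities."),
                "correct_prediction",
            ),
            intent_prediction_correlation=parse_number(
                probs.get("intent_prediction_correlation", 0.0),
                "intent_prediction_correlation",
            ),
        )
    except ValidationError as exc:
        raise ScenarioParseError(str(exc)) from exc

    rows = _require(data, "weights", "")
    if not isinstance(rows, list) or len(rows) != N_LEAVES:
        raise ScenarioParseError("weights must list exactly 16 per-leaf entries")
    benefit = np.zeros(N_LEAVES)
    pne = np.zeros(N_LEAVES)
    side = np.zeros(N_LEAVES)
    cat = np.zeros(N_LEAVES, dtype=bool)
    seen = set()
    for row in rows:
        idx = _require(row, "leaf", "weights.")
        if not isinstance(idx, int) or not 1 <= idx <= N_LEAVES or idx in seen:
            raise ScenarioParseError(f"weights.leaf must be a unique index 1..16, got {idx!r}")
        seen.add(idx)
        benefit[idx - 1] = parse_number(
            _require(row, "benefit", f"weights[{idx}]."), f"weights[{idx}].benefit"
        )
        pne[idx - 1] = parse_number(
            _require(row, "placebo_nocebo", f"weights[{idx}]."),
            f"weights[{idx}].placebo_nocebo",
        )
        side[idx - 1] = parse_number(
            _require(row, "side_effect", f"weights[{idx}]."),
            f"weights[{idx}].side_effect",
        )
        cat[idx - 1] = bool(row.get("catastrophic", False))
    weights = EffectWeights(benefit, pne, side, cat)

    return Scenario(
        name=str(data.get("name", name or "scenario")),
        assumptions=assumptions,
        weights=weights,
        whole_patients=bool(data.get("whole_patients", False)),
        description=str(data.get("description", "")),
        metadata=dict(data.get("metadata", {})),
    )


def load_scenario(path) -> Scenario:
    """Load and validate a scenario YAML file."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ScenarioParseError(f"could not parse {path}: {exc}") from exc
    return scenario_from_dict(data, name=path.stem)


def scenario_to_dict(scenario: Scenario) -> dict:
    a = scenario.assumptions
    return {
        "name": scenario.name,
        "description": scenario.description,
        "cohort_size": a.cohort_size,
        "whole_patients": scenario.whole_patients,
        "probabilities": {
            "intent": a.p_intent,
            "positive_prediction": a.p_positive,
            "correct_prediction": a.p_correct,
            "adherence": {
                cell: getattr(a.adherence, cell) for cell in _ADHERENCE_CELLS
            },
        },
        "weights": [
            {
                "leaf": i,
                "benefit": float(scenario.weights.benefit[i - 1]),
                "placebo_nocebo": float(scenario.weights.placebo_nocebo[i - 1]),
                "side_effect": float(scenario.weights.side_effect[i - 1]),
                **(
                    {"catastrophic": True}
                    if bool(scenario.weights.catastrophic[i - 1])
                    else {}
                ),
            }
            for i in range(1, N_LEAVES + 1)
        ],
        "metadata": dict(scenario.metadata),
    }


def save_scenario(scenario: Scenario, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(scenario_to_dict(scenario), sort_keys=False)
    )


def _table_rows(scenario: Scenario, allocation: LeafAllocation) -> list[list]:
    rows = []
    for leaf in allocation.leaves:
        i = leaf.index
        b, p, s = scenario.weights.triplet(i)
        n = allocation[i]
        rows.append(
            [
                i,
                node_path(leaf)[2],
                INTENT_LABELS[leaf.intent],
                PREDICTION_LABELS[leaf.prediction],
                PARTICIPATION_LABELS[leaf.participation],
                OUTCOME_LABELS[leaf.outcome],
                repr(n),
                repr(b),
                repr(p),
                repr(s),
                int(scenario.weights.catastrophic[i - 1]),
                repr(n * (b + p + s)),
            ]
        )
    return rows


def _metadata_lines(scenario: Scenario) -> list[str]:
    a = scenario.assumptions
    lines = [
        "# brscore calculation table",
        f"# name: {scenario.name}",
        f"# whole_patients: {scenario.whole_patients}",
        f"# cohort_size: {a.cohort_size!r}",
        f"# p_intent: {a.p_intent!r}",
        f"# p_positive: {a.p_positive!r}",
        f"# p_correct: {a.p_correct!r}",
    ]
    lines += [
        f"# adherence.{cell}: {getattr(a.adherence, cell)!r}" for cell in _ADHERENCE_CELLS
    ]
    return lines


def _footer_lines(result: BRSResult) -> list[str]:
    return [
        f"# total_points: {result.total_points!r}",
        f"# per_capita: {result.per_capita!r}",
        f"# decision: {result.decision}",
        f"# harmed_count: {result.harmed_count!r}",
        f"# harmed_rounded: {result.harmed_rounded}",
    ]


def export_table(
    scenario: Scenario,
    path,
    *,
    allocation: LeafAllocation | None = None,
    result: BRSResult | None = None,
    fmt: str = "csv",
) -> None:
    """Write the per-leaf calculation table.

    One data row per leaf (index, figure node, the four attributes, n_i,
    the weight triplet, the catastrophic flag, and the row product
    n_i * (B_i + PNE_i + SE_i)), with the scenario's defining numbers as
    header comments and the totals as footer comments.  ``fmt`` is
    ``"csv"`` (default, lossless re-import) or ``"xlsx"``.
    """
    if allocation is None:
        allocation = scenario.allocation()
    if result is None:
        result = compute_brs(allocation, scenario.weights)
    rows = _table_rows(scenario, allocation)
    if fmt == "csv":
        path = Path(path)
        with path.open("w", newline="") as fh:
            for line in _metadata_lines(scenario):
                fh.write(line + "\n")
            writer = csv.writer(fh)
            writer.writerow(_TABLE_COLUMNS)
            writer.writerows(rows)
            for line in _footer_lines(result):
                fh.write(line + "\n")
    elif fmt == "xlsx":
        from openpyxl import Workbook

        wb = Workbook()
        ws = wb.active
        ws.title = "calculation"
        for line in _metadata_lines(scenario):
            ws.append([line.lstrip("# ")])
        ws.append(list(_TABLE_COLUMNS))
        for row in rows:
            ws.append(
                [float(v) if isinstance(v, str) and _is_float(v) else v for v in row]
            )
        for line in _footer_lines(result):
            ws.append([line.lstrip("# ")])
        wb.save(Path(path))
    else:
        raise ValidationError(f"unknown table format {fmt!r} (use 'csv' or 'xlsx')")


def _is_float(text: str) -> bool:
    try:
        float(text)
        return True
    except ValueError:
        return False


@dataclass(frozen=True)
class TableImport:
    """Re-imported calculation table: scenario, allocation, recorded result."""

    scenario: Scenario
    allocation: LeafAllocation
    result: BRSResult


def import_table(path) -> TableImport:
    """Rebuild scenario, allocation and recorded totals from an exported CSV."""
    path = Path(path)
    meta: dict[str, str] = {}
    data_rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in path.read_text().splitlines():
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, value = stripped.split(":", 1)
                meta[key.strip()] = value.strip()
            continue
        cells = next(csv.reader([line]))
        if header is None:
            header = cells
            if tuple(header) != _TABLE_COLUMNS:
                raise ScenarioParseError(f"unexpected table columns in {path}")
        else:
            data_rows.append(dict(zip(header, cells)))
    if header is None or len(data_rows) != N_LEAVES:
        raise ScenarioParseError(
            f"calculation table must contain exactly {N_LEAVES} data rows"
        )

    def meta_float(key: str) -> float:
        if key not in meta:
            raise ScenarioParseError(f"missing metadata line {key!r} in {path}")
        return float(meta[key])

    assumptions = BranchingAssumptions(
        cohort_size=meta_float("cohort_size"),
        p_intent=meta_float("p_intent"),
        p_positive=meta_float("p_positive"),
        adherence=Adherence(
            **{cell: meta_float(f"adherence.{cell}") for cell in _ADHERENCE_CELLS}
        ),
        p_correct=meta_float("p_correct"),
    )
    benefit = np.zeros(N_LEAVES)
    pne = np.zeros(N_LEAVES)
    side = np.zeros(N_LEAVES)
    cat = np.zeros(N_LEAVES, dtype=bool)
    counts = np.zeros(N_LEAVES)
    for row in data_rows:
        i = int(row["leaf"]) - 1
        counts[i] = float(row["n"])
        benefit[i] = float(row["benefit"])
        pne[i] = float(row["placebo_nocebo"])
        side[i] = float(row["side_effect"])
        cat[i] = bool(int(row["catastrophic"]))
    scenario = Scenario(
        name=meta.get("name", path.stem),
        assumptions=assumptions,
        weights=EffectWeights(benefit, pne, side, cat),
        whole_patients=meta.get("whole_patients", "False") == "True",
    )
    allocation = LeafAllocation(counts, float(counts.sum()), build_tree())
    result = BRSResult(
        total_points=meta_float("total_points"),
        per_capita=meta_float("per_capita"),
        decision=meta.get("decision", ""),
        harmed_count=meta_float("harmed_count"),
        cohort_size=allocation.cohort_size,
    )
    return TableImport(scenario=scenario, allocation=allocation, result=result)
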