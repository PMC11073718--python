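"""JSON and CSV serialization of PHF data and decision problems.

Formats:

* PHFElement — JSON array of ``{"m": <membership>, "p": <probability>}``.
* PHFSet — JSON array of such arrays (one per universe item).
* PHFSet CSV — one row per universe item; cells ``m|p`` joined by ``;``.
* DecisionProblem — a JSON object::

      {"alternatives": [...],
       "criteria": [{"name": ..., "direction": "benefit"|"cost"}],
       "experts": [{"name": ..., "weight": ...}],
       "matrices": {expert: [[term, ...], ...]},       # criteria x alternatives
       "importance": {expert: [term, ...]}             # or "weights": [...]
      }
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any

from .elements import PHFElement, PHFSet, PHFValidationError
from .mcgdm import Criterion, DecisionProblem, Expert

__all__ = [
    "element_to_obj",
    "element_from_obj",
    "phfs_to_obj",
    "phfs_from_obj",
    "phfs_to_json",
    "phfs_from_json",
    "phfs_to_csv",
    "phfs_from_csv",
    "problem_to_obj",
    "problem_from_obj",
    "load_phfs",
    "load_problem",
]


def element_to_obj(element: PHFElement) -> list[dict[str, float]]:
    return [{"m": g, "p": p} for g, p in element.entries]


def element_from_obj(obj: Any) -> PHFElement:
    try:
        return PHFElement((item["m"], item["p"]) for item in obj)
    except (TypeError, KeyError) as exc:
        raise PHFValidationError(f"malformed PHF element object: {obj!r}") from exc


def phfs_to_obj(phfs: PHFSet) -> list[list[dict[str, float]]]:
    return [element_to_obj(e) for e in phfs]


def phfs_from_obj(obj: Any) -> PHFSet:
    return PHFSet(element_from_obj(item) for item in obj)


def phfs_to_json(phfs: PHFSet, path: str | Path | None = None) -> str:
    text = json.dumps(phfs_to_obj(phfs), indent=2)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def phfs_from_json(text: str) -> PHFSet:
    return phfs_from_obj(json.loads(text))


def phfs_to_csv(phfs: PHFSet) -> str:
    lines = [";".join(f"{g:.17g}|{p:.17g}" for g, p in e) for e in phfs]
    return "\n".join(lines) + "\n"


def phfs_from_csv(text: str) -> PHFSet:
    elements = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        pairs = []
        for cell in line.split(";"):
            try:
                m, p = cell.split("|")
                pairs.append((float(m), float(p)))
            except ValueError as exc:
                raise PHFValidationError(f"malformed CSV cell {cell!r}") from exc
        elements.append(PHFElement(pairs))
    if not elements:
        raise PHFValidationError("empty CSV input")
    return PHFSet(elements)


def problem_to_obj(problem: DecisionProblem) -> dict[str, Any]:
    obj: dict[str, Any] = {
        "alternatives": list(problem.alternatives),
        "criteria": [
            {"name": c.name, "direction": c.direction} for c in problem.criteria
        ],
        "experts": [{"name": e.name, "weight": e.weight} for e in problem.experts],
        "matrices": {k: [list(r) for r in v] for k, v in problem.matrices.items()},
    }
    if problem.importance is not None:
        obj["importance"] = {k: list(v) for k, v in problem.importance.items()}
    if problem.weights is not None:
        obj["weights"] = list(problem.weights)
    return obj


def problem_from_obj(obj: Any) -> DecisionProblem:
    try:
        criteria = tuple(
            Criterion(c["name"], c["direction"]) for c in obj["criteria"]
        )
        experts = tuple(Expert(e["name"], float(e["weight"])) for e in obj["experts"])
        matrices = {
            k: tuple(tuple(row) for row in grid)
            for k, grid in obj["matrices"].items()
        }
        importance = None
        if "importance" in obj:
            importance = {k: tuple(v) for k, v in obj["importance"].items()}
        weights = tuple(obj["weights"]) if "weights" in obj else None
        return DecisionProblem(
            alternatives=tuple(obj["alternatives"]),
            criteria=criteria,
            experts=experts,
            matrices=matrices,
            importance=importance,
            weights=weights,
        )
    except (TypeError, KeyError) as exc:
        raise PHFValidationError(f"malformed decision problem object: {exc}") from exc


def load_phfs(path: str | Path) -> PHFSet:
    """Load a PHFSet from a .json or .csv file by extension."""
    p = Path(path)
    text = p.read_text()
    if p.suffix.lower() == ".csv":
        return phfs_from_csv(text)
    return phfs_from_json(text)


def load_problem(path: str | Path) -> DecisionProblem:
    return problem_from_obj(json.loads(Path(path).read_text()))
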