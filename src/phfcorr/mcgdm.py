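"""Correlation-based multi-criteria group decision making.

The pipeline turns linguistic expert evaluations into a ranking of
alternatives:

1.  Each expert scores every alternative under every criterion with one of
    nine linguistic terms (VL … VH), mapped to Saaty's 1–9 scale.
2.  Criteria weights are elicited the same way: each expert rates every
    criterion's importance; the expert-weighted Saaty values are summed
    per criterion and normalized to a weight vector.
3.  Each expert's term grid becomes a numeric grid (Saaty value × expert
    weight); the per-expert grids are merged cell-wise into a hesitant
    fuzzy group matrix holding the k expert values per cell.
4.  Columns are normalized into (0, 1]: benefit criteria divide by the
    column maximum, cost criteria divide the column minimum by each value.
5.  Equal values within a cell are merged with probability equal to their
    frequency, giving a probabilistic hesitant fuzzy group matrix.
6.  The ideal alternative takes, per criterion, the cell with the highest
    score (ties: lowest deviation, then lowest alternative index);
    alternatives are ranked by their weighted information-energy
    correlation ρ3 with the ideal.

Two rounding modes are supported.  ``precise`` carries full floating-point
precision end to end.  ``paper`` rounds the normalized matrix to two
decimals (half-up) before the probabilistic merge — the convention under
which published worked tables of this pipeline are stated — and is the
mode the shipped fixtures reproduce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

from .correlation import rho3, validate_weights
from .elements import PHFElement, PHFSet, PHFValidationError, compare, deviation, score

__all__ = [
    "SAATY_SCALE",
    "LINGUISTIC_TERMS",
    "Criterion",
    "Expert",
    "DecisionProblem",
    "GroupHFMatrix",
    "GroupPHFMatrix",
    "RankingResult",
    "EvaluationResult",
    "saaty_value",
    "criteria_weights",
    "weighted_numeric_matrices",
    "group_matrix",
    "normalize",
    "to_phf_matrix",
    "ideal_alternative",
    "rank",
    "evaluate",
]

#: Nine-term linguistic vocabulary mapped onto Saaty's 1–9 scale.
SAATY_SCALE: dict[str, int] = {
    "VL": 1,   # very low
    "VLL": 2,  # very low to low
    "L": 3,    # low
    "ML": 4,   # medium low
    "M": 5,    # medium
    "MH": 6,   # medium high
    "H": 7,    # high
    "HVH": 8,  # high to very high
    "VH": 9,   # very high
}

LINGUISTIC_TERMS = tuple(SAATY_SCALE)

#: Merge tolerance for equal normalized values in precise mode.
MERGE_TOL = 1e-9


def saaty_value(term: str) -> int:
    """Map a linguistic term (VL … VH) to its Saaty 1–9 value."""
    try:
        return SAATY_SCALE[term]
    except KeyError:
        raise PHFValidationError(
            f"unknown linguistic term {term!r}; expected one of {LINGUISTIC_TERMS}"
        ) from None


@dataclass(frozen=True)
class Criterion:
    name: str
    direction: str  # "benefit" or "cost"

    def __post_init__(self) -> None:
        if self.direction not in ("benefit", "cost"):
            raise PHFValidationError(
                f"criterion {self.name!r}: direction must be 'benefit' or 'cost', "
                f"got {self.direction!r}"
            )


@dataclass(frozen=True)
class Expert:
    name: str
    weight: float


@dataclass(frozen=True)
class DecisionProblem:
    """A linguistic group decision problem.

    ``matrices[expert]`` is a criteria × alternatives grid of linguistic
    terms (one row per criterion, matching how elicitation tables are laid
    out).  Criteria weights come either from ``importance`` (one term per
    criterion per expert) or directly from ``weights``.
    """

    alternatives: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    experts: tuple[Expert, ...]
    matrices: Mapping[str, tuple[tuple[str, ...], ...]]
    importance: Mapping[str, tuple[str, ...]] | None = None
    weights: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.alternatives or not self.criteria or not self.experts:
            raise PHFValidationError("alternatives, criteria and experts must be non-empty")
        total = math.fsum(e.weight for e in self.experts)
        if any(e.weight < 0 for e in self.experts) or abs(total - 1.0) > 1e-9:
            raise PHFValidationError(
                f"expert weights must be non-negative and sum to 1 (got {total!r})"
            )
        for e in self.experts:
            grid = self.matrices.get(e.name)
            if grid is None:
                raise PHFValidationError(f"missing decision matrix for expert {e.name!r}")
            if len(grid) != len(self.criteria):
                raise PHFValidationError(
                    f"expert {e.name!r}: expected {len(self.criteria)} criterion rows, "
                    f"got {len(grid)}"
                )
            for ci, row in enumerate(grid):
                if len(row) != len(self.alternatives):
                    raise PHFValidationError(
                        f"expert {e.name!r}, criterion {self.criteria[ci].name!r}: "
                        f"expected {len(self.alternatives)} cells, got {len(row)}"
                    )
                for term in row:
                    saaty_value(term)
        if self.importance is None and self.weights is None:
            raise PHFValidationError("either criterion importance or weights must be given")
        if self.importance is not None:
            for e in self.experts:
                row = self.importance.get(e.name)
                if row is None or len(row) != len(self.criteria):
                    raise PHFValidationError(
                        f"expert {e.name!r}: importance row missing or wrong length"
                    )
                for term in row:
                    saaty_value(term)
        if self.weights is not None:
            validate_weights(self.weights, len(self.criteria))


@dataclass(frozen=True)
class GroupHFMatrix:
    """Alternatives × criteria grid of hesitant (multi-valued) cells."""

    alternatives: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    cells: tuple[tuple[tuple[float, ...], ...], ...]  # [alt][crit] -> k values

    def column(self, j: int) -> list[float]:
        """All values of criterion column j, across alternatives."""
        return [v for row in self.cells for v in row[j]]


@dataclass(frozen=True)
class GroupPHFMatrix:
    """Alternatives × criteria grid of probabilistic hesitant fuzzy cells."""

    alternatives: tuple[str, ...]
    criteria: tuple[Criterion, ...]
    cells: tuple[tuple[PHFElement, ...], ...]  # [alt][crit]

    def row(self, i: int) -> PHFSet:
        """Alternative i's evaluation as a PHFS over the criteria."""
        return PHFSet(self.cells[i])


@dataclass(frozen=True)
class RankingResult:
    """Per-alternative correlation with the ideal and the induced order."""

    alternatives: tuple[str, ...]
    coefficients: tuple[float, ...]
    order: tuple[str, ...]  # descending coefficient; ties keep input order
    ties: tuple[tuple[str, ...], ...] = ()

    @property
    def best(self) -> str:
        return self.order[0]

    @property
    def worst(self) -> str:
        return self.order[-1]

    def __str__(self) -> str:
        return " > ".join(self.order)


@dataclass(frozen=True)
class EvaluationResult:
    """Every artifact of an end-to-end pipeline run, for auditability."""

    problem: DecisionProblem
    integrated_weights: tuple[float, ...] | None
    criteria_weights: tuple[float, ...]
    numeric_matrices: dict[str, tuple[tuple[float, ...], ...]]
    group: GroupHFMatrix
    normalized: GroupHFMatrix
    phf: GroupPHFMatrix
    ideal: PHFSet
    ranking: RankingResult


def criteria_weights(
    importance: Mapping[str, Sequence[str]] | Sequence[Sequence[str]],
    expert_weights: Sequence[float],
    expert_names: Sequence[str] | None = None,
) -> tuple[tuple[float, ...], tuple[float, ...]]:
    """Integrate per-expert criterion importance into criteria weights.

    Returns ``(integrated, normalized)`` where ``integrated[j]`` is the
    expert-weighted sum of Saaty values for criterion j and ``normalized``
    divides by the total so the weights sum to 1.
    """
    if isinstance(importance, Mapping):
        names = list(expert_names) if expert_names is not None else list(importance)
        rows = [importance[name] for name in names]
    else:
        rows = list(importance)
    if len(rows) != len(expert_weights):
        raise PHFValidationError(
            f"{len(rows)} importance rows but {len(expert_weights)} expert weights"
        )
    m = len(rows[0])
    if any(len(r) != m for r in rows):
        raise PHFValidationError("importance rows have unequal lengths")
    integrated = tuple(
        math.fsum(w * saaty_value(row[j]) for w, row in zip(expert_weights, rows))
        for j in range(m)
    )
    total = math.fsum(integrated)
    if total <= 0:
        raise PHFValidationError("all integrated criterion weights are zero")
    return integrated, tuple(v / total for v in integrated)


def weighted_numeric_matrices(
    problem: DecisionProblem,
) -> dict[str, tuple[tuple[float, ...], ...]]:
    """Per expert: Saaty value of each term times the expert's weight."""
    out = {}
    for e in problem.experts:
        grid = problem.matrices[e.name]
        out[e.name] = tuple(
            tuple(saaty_value(t) * e.weight for t in row) for row in grid
        )
    return out


def group_matrix(
    numeric: Mapping[str, Sequence[Sequence[float]]],
    alternatives: Sequence[str],
    criteria: Sequence[Criterion],
) -> GroupHFMatrix:
    """Merge per-expert numeric grids: cell (i, j) collects the k expert
    values for alternative i under criterion j, sorted ascending."""
    grids = list(numeric.values())
    shape = (len(grids[0]), len(grids[0][0]))
    for g in grids:
        if (len(g), len(g[0])) != shape:
            raise PHFValidationError("expert grids have mismatched shapes")
    cells = tuple(
        tuple(
            tuple(sorted(g[j][i] for g in grids)) for j in range(len(criteria))
        )
        for i in range(len(alternatives))
    )
    return GroupHFMatrix(tuple(alternatives), tuple(criteria), cells)


def _round2(value: float) -> float:
    """Two-decimal round-half-up, as published worked tables use."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def normalize(matrix: GroupHFMatrix, rounding: str = "precise") -> GroupHFMatrix:
    """Map every column into (0, 1]: benefit columns divide by the column
    maximum, cost columns divide the column minimum by each value.

    In ``paper`` rounding mode every normalized value is rounded to two
    decimals (half-up) immediately, so downstream merging and correlation
    reproduce two-decimal published tables.
    """
    if rounding not in ("precise", "paper"):
        raise PHFValidationError(f"unknown rounding mode {rounding!r}")
    post = _round2 if rounding == "paper" else (lambda v: v)
    new_rows = []
    for row in matrix.cells:
        new_rows.append(list(row))
    for j, crit in enumerate(matrix.criteria):
        col = matrix.column(j)
        if crit.direction == "benefit":
            denom = max(col)
            if denom <= 0:
                raise ZeroDivisionError(
                    f"benefit criterion {crit.name!r} has non-positive column maximum"
                )
            f = lambda v: post(v / denom)
        else:
            numer = min(col)
            if numer <= 0 or any(v <= 0 for v in col):
                raise ZeroDivisionError(
                    f"cost criterion {crit.name!r} requires positive entries"
                )
            f = lambda v: post(numer / v)
        for i in range(len(matrix.alternatives)):
            new_rows[i][j] = tuple(f(v) for v in matrix.cells[i][j])
    cells = tuple(tuple(r) for r in new_rows)
    return GroupHFMatrix(matrix.alternatives, matrix.criteria, cells)


def to_phf_matrix(matrix: GroupHFMatrix, merge_tol: float = MERGE_TOL) -> GroupPHFMatrix:
    """Merge equal values within each cell; probability = frequency / k."""
    rows = []
    for row in matrix.cells:
        cells = []
        for values in row:
            k = len(values)
            merged: list[list[float]] = []  # [value, count]
            for v in sorted(values):
                if merged and abs(v - merged[-1][0]) <= merge_tol:
                    merged[-1][1] += 1
                else:
                    merged.append([v, 1])
            cells.append(PHFElement((v, c / k) for v, c in merged))
        rows.append(tuple(cells))
    return GroupPHFMatrix(matrix.alternatives, matrix.criteria, tuple(rows))


def ideal_alternative(matrix: GroupPHFMatrix) -> PHFSet:
    """Per criterion, the cell with maximal score; ties broken by minimal
    deviation, remaining ties by lowest alternative index.

    Scores within 1e-9 count as tied, so that exact ties survive
    floating-point evaluation order.
    """
    chosen = []
    for j in range(len(matrix.criteria)):
        best = matrix.cells[0][j]
        for i in range(1, len(matrix.alternatives)):
            cand = matrix.cells[i][j]
            sc, sb = score(cand), score(best)
            if sc > sb + 1e-9:
                best = cand
            elif abs(sc - sb) <= 1e-9 and deviation(cand) < deviation(best):
                best = cand
        chosen.append(best)
    return PHFSet(chosen)


def rank(
    matrix: GroupPHFMatrix,
    weights: Sequence[float],
    ideal: PHFSet | None = None,
) -> RankingResult:
    """Rank alternatives by ρ3 with the ideal alternative, descending.

    Equal coefficients are kept in input order and reported as ties.
    """
    w = validate_weights(weights, len(matrix.criteria))
    if ideal is None:
        ideal = ideal_alternative(matrix)
    coeffs = tuple(
        rho3(matrix.row(i), ideal, w) for i in range(len(matrix.alternatives))
    )
    idx = sorted(range(len(coeffs)), key=lambda i: (-coeffs[i], i))
    order = tuple(matrix.alternatives[i] for i in idx)
    ties = []
    group: list[int] = []
    for a, b in zip(idx, idx[1:]):
        if coeffs[a] == coeffs[b]:
            if not group:
                group = [a]
            group.append(b)
        elif group:
            ties.append(tuple(matrix.alternatives[i] for i in group))
            group = []
    if group:
        ties.append(tuple(matrix.alternatives[i] for i in group))
    return RankingResult(matrix.alternatives, coeffs, order, tuple(ties))


def evaluate(problem: DecisionProblem, rounding: str = "precise") -> EvaluationResult:
    """Run the full pipeline and return every intermediate artifact.

    Criteria weights come from ``problem.weights`` when supplied,
    otherwise from integrating ``problem.importance``.
    """
    expert_weights = [e.weight for e in problem.experts]
    integrated = None
    if problem.weights is not None:
        w = tuple(problem.weights)
    else:
        integrated, w = criteria_weights(
            problem.importance, expert_weights, [e.name for e in problem.experts]
        )
    numeric = weighted_numeric_matrices(problem)
    group = group_matrix(numeric, problem.alternatives, problem.criteria)
    normalized = normalize(group, rounding)
    phf = to_phf_matrix(normalized)
    ideal = ideal_alternative(phf)
    ranking = rank(phf, w, ideal)
    return EvaluationResult(
        problem=problem,
        integrated_weights=integrated,
        criteria_weights=w,
        numeric_matrices=numeric,
        group=group,
        normalized=normalized,
        phf=phf,
        ideal=ideal,
        ranking=ranking,
    )
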