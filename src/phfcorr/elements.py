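"""Probabilistic hesitant fuzzy elements and sets.

A probabilistic hesitant fuzzy element (PHFE) models one expert panel's
hesitation about a single membership judgement: a small set of candidate
membership degrees ``γ`` in [0, 1], each tagged with the probability ``p``
of that candidate being the panel's view.  Probabilities within an element
sum to one.  A probabilistic hesitant fuzzy set (PHFS) assigns one PHFE to
every item of a finite universe.

This module provides the element/set containers, their validation, the
score and deviation functions used to compare elements, and the canonical
ordering + length-alignment machinery (sort ascending by ``F = γ·p``, then
pessimistically pad the shorter element) that every pairwise correlation
computation relies on.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

__all__ = [
    "PROB_SUM_TOL",
    "PHFValidationError",
    "MembershipRangeError",
    "ProbabilityRangeError",
    "ProbabilitySumError",
    "PHFElement",
    "CanonicalPHFElement",
    "PHFSet",
    "HFElement",
    "Ordering",
    "Padding",
    "validate",
    "score",
    "deviation",
    "compare",
    "canonical_sort",
    "pad_pessimistic",
    "align",
    "align_hf",
]

#: Tolerance on |Σ p_i − 1| accepted by validation.
PROB_SUM_TOL = 1e-9


class PHFValidationError(ValueError):
    """Base class for invalid probabilistic hesitant fuzzy data."""


class MembershipRangeError(PHFValidationError):
    """A membership degree lies outside [0, 1]."""


class ProbabilityRangeError(PHFValidationError):
    """A probability lies outside [0, 1]."""


class ProbabilitySumError(PHFValidationError):
    """Probabilities of an element do not sum to 1 within tolerance."""


@dataclass(frozen=True)
class PHFElement:
    """One probabilistic hesitant fuzzy element: ``{γ1|p1, …, γl|pl}``.

    ``entries`` is an ordered tuple of ``(membership, probability)`` pairs.
    Zero-probability entries are legal; they arise from pessimistic padding
    and carry no weight in any score or correlation.

    Construction does *not* validate; call :func:`validate` (or
    :meth:`validated`) to enforce the invariants, so that deliberately
    malformed inputs can be built and rejected with a named error.
    """

    entries: tuple[tuple[float, float], ...]

    def __init__(self, entries: Iterable[Sequence[float]]):
        object.__setattr__(
            self, "entries", tuple((float(g), float(p)) for g, p in entries)
        )

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[tuple[float, float]]:
        return iter(self.entries)

    @property
    def memberships(self) -> tuple[float, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def probabilities(self) -> tuple[float, ...]:
        return tuple(p for _, p in self.entries)

    def validated(self) -> "PHFElement":
        return validate(self)

    def score(self) -> float:
        return score(self)

    def deviation(self) -> float:
        return deviation(self)

    def __str__(self) -> str:
        body = ", ".join(f"{g:g}|{p:g}" for g, p in self.entries)
        return "{" + body + "}"

    # Equality is on the entry tuples, across the canonical subclass too,
    # so that a sorted element compares equal to its canonical form.
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PHFElement):
            return NotImplemented
        return self.entries == other.entries

    def __hash__(self) -> int:
        return hash(self.entries)


class CanonicalPHFElement(PHFElement):
    """A PHFE whose entries are ascending in ``F = γ·p``.

    Produced by :func:`canonical_sort`; the invariant ``F_j ≤ F_{j+1}``
    makes pairwise position-by-position products well defined.
    """

    def __init__(self, entries: Iterable[Sequence[float]]):
        super().__init__(entries)
        fs = [g * p for g, p in self.entries]
        if any(a > b + 1e-15 for a, b in zip(fs, fs[1:])):
            raise ValueError("entries are not ascending in F = membership*probability")


@dataclass(frozen=True)
class PHFSet:
    """A probabilistic hesitant fuzzy set: one PHFE per universe item."""

    elements: tuple[PHFElement, ...]

    def __init__(self, elements: Iterable[PHFElement | Iterable[Sequence[float]]]):
        elems = tuple(
            e if isinstance(e, PHFElement) else PHFElement(e) for e in elements
        )
        if not elems:
            raise PHFValidationError("a PHFSet needs at least one element")
        object.__setattr__(self, "elements", elems)

    @property
    def n(self) -> int:
        return len(self.elements)

    def __len__(self) -> int:
        return len(self.elements)

    def __iter__(self) -> Iterator[PHFElement]:
        return iter(self.elements)

    def __getitem__(self, i: int) -> PHFElement:
        return self.elements[i]

    def validated(self) -> "PHFSet":
        for e in self.elements:
            validate(e)
        return self


@dataclass(frozen=True)
class HFElement:
    """A plain hesitant fuzzy element: membership degrees only."""

    values: tuple[float, ...]

    def __init__(self, values: Iterable[float]):
        vals = tuple(float(v) for v in values)
        if not vals:
            raise PHFValidationError("an HFElement needs at least one value")
        for v in vals:
            if not 0.0 <= v <= 1.0:
                raise MembershipRangeError(f"membership {v!r} outside [0, 1]")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self) -> Iterator[float]:
        return iter(self.values)


class Ordering(enum.Enum):
    """Outcome of comparing two PHFEs by score, then deviation."""

    LESS = -1
    EQUAL = 0
    GREATER = 1


class Padding(enum.Enum):
    """Length-equalization convention for elements of unequal length.

    PESSIMISTIC extends the shorter element with its worst (minimum-F)
    membership; OPTIMISTIC with its best (maximum-F) membership.  Padded
    entries carry probability 0 in the probabilistic setting.
    """

    PESSIMISTIC = "pessimistic"
    OPTIMISTIC = "optimistic"


def validate(element: PHFElement) -> PHFElement:
    """Check the PHFE invariants and return the element unchanged.

    Raises :class:`MembershipRangeError`, :class:`ProbabilityRangeError`
    or :class:`ProbabilitySumError` on the first violation found.
    """
    if not element.entries:
        raise PHFValidationError("a PHFElement needs at least one entry")
    for g, p in element.entries:
        if not (0.0 <= g <= 1.0) or math.isnan(g):
            raise MembershipRangeError(f"membership {g!r} outside [0, 1]")
        if not (0.0 <= p <= 1.0) or math.isnan(p):
            raise ProbabilityRangeError(f"probability {p!r} outside [0, 1]")
    total = math.fsum(element.probabilities)
    if abs(total - 1.0) > PROB_SUM_TOL:
        raise ProbabilitySumError(
            f"probabilities sum to {total!r}, expected 1 within {PROB_SUM_TOL}"
        )
    return element


def score(element: PHFElement) -> float:
    """Probability-weighted mean membership ``s(h) = Σ γ_i p_i``."""
    return math.fsum(g * p for g, p in element.entries)


def deviation(element: PHFElement) -> float:
    """Probability-weighted squared dispersion ``δ(h) = Σ (γ_i − s)² p_i``."""
    s = score(element)
    return math.fsum((g - s) ** 2 * p for g, p in element.entries)


def compare(a: PHFElement, b: PHFElement) -> Ordering:
    """Compare two PHFEs: higher score wins; at equal score, lower deviation wins."""
    sa, sb = score(a), score(b)
    if sa > sb:
        return Ordering.GREATER
    if sa < sb:
        return Ordering.LESS
    da, db = deviation(a), deviation(b)
    if da < db:
        return Ordering.GREATER
    if da > db:
        return Ordering.LESS
    return Ordering.EQUAL


def canonical_sort(element: PHFElement) -> CanonicalPHFElement:
    """Sort entries ascending by ``F = γ·p``, ties by (γ, p) ascending."""
    ordered = sorted(element.entries, key=lambda e: (e[0] * e[1], e[0], e[1]))
    return CanonicalPHFElement(ordered)


def pad_pessimistic(
    element: CanonicalPHFElement,
    target_len: int,
    padding: Padding = Padding.PESSIMISTIC,
) -> CanonicalPHFElement:
    """Extend a canonical element to ``target_len`` with probability-0 entries.

    Under the pessimistic criterion the padding membership is that of the
    current minimum-F entry (the element's worst candidate — note: the
    entry lowest in F-order, not the smallest membership); under the
    optimistic criterion it is the maximum-F entry's membership.  Padded
    entries have F = 0 and therefore sort first, so the result stays
    canonical with an unchanged probability sum and score.
    """
    if target_len < len(element):
        raise ValueError(
            f"target length {target_len} < element length {len(element)}"
        )
    if target_len == len(element):
        return element
    src = element.entries[0] if padding is Padding.PESSIMISTIC else element.entries[-1]
    pad = [(src[0], 0.0)] * (target_len - len(element))
    return CanonicalPHFElement(pad + list(element.entries))


def align(
    a: PHFElement, b: PHFElement, padding: Padding = Padding.PESSIMISTIC
) -> tuple[CanonicalPHFElement, CanonicalPHFElement, int]:
    """Canonical-sort both elements and pad the shorter to the common length.

    Returns the two aligned elements and ``l = max(len(a), len(b))``.
    """
    ca, cb = canonical_sort(a), canonical_sort(b)
    l = max(len(ca), len(cb))
    return pad_pessimistic(ca, l, padding), pad_pessimistic(cb, l, padding), l


def align_hf(
    a: HFElement, b: HFElement, padding: Padding = Padding.PESSIMISTIC
) -> tuple[tuple[float, ...], tuple[float, ...], int]:
    """Align two plain hesitant fuzzy elements by sorting ascending and
    padding the shorter with its minimum (pessimistic) or maximum
    (optimistic) value."""
    sa, sb = sorted(a.values), sorted(b.values)
    l = max(len(sa), len(sb))

    def _pad(vals: list[float]) -> tuple[float, ...]:
        if len(vals) == l:
            return tuple(vals)
        fill = vals[0] if padding is Padding.PESSIMISTIC else vals[-1]
        return tuple([fill] * (l - len(vals)) + vals)

    return _pad(sa), _pad(sb), l
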