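"""Correlation coefficients for (probabilistic) hesitant fuzzy sets.

The core coefficients ρ1–ρ4 measure the association between two PHFSs
through their *information energy*

    ψ(A) = Σ_i (1/l_i) Σ_j (γ_ij · p_ij)²

(the self-inner-product of the membership×probability products, with each
element normalized by its own number of entries) and the cross term

    C1(A, B) = Σ_i (1/l_i) Σ_j γ_Aij γ_Bij p_Aij p_Bij

computed position-by-position after canonical F-sorting and pessimistic
padding, with l_i the common (max) length of the aligned pair.

    ρ1 = C1(A,B) / (ψ(A)^½ ψ(B)^½)          geometric-mean normalization
    ρ2 = C1(A,B) / max(ψ(A), ψ(B))          max normalization (ρ2 ≤ ρ1)
    ρ3, ρ4 = weighted analogues with per-item weights w_i applied to both
             the cross and the energy terms; with uniform weights they
             degenerate to ρ1 and ρ2 exactly.

A key convention, pinned by the worked arithmetic these formulas must
reproduce: the cross term uses the *aligned* (max) lengths, while the
energies in every denominator use each set's *own unpadded* lengths.
Padded entries carry probability 0, so they contribute nothing to either.

Two baseline families are provided for comparison experiments: the
Pearson-style mean/variance coefficient over per-element mean vectors
(which degenerates to 1 whenever the mean vectors coincide — the flaw the
information-energy coefficients repair), and the classical hesitant fuzzy
set coefficient that ignores probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from .elements import (
    PROB_SUM_TOL,
    HFElement,
    Padding,
    PHFSet,
    PHFValidationError,
    align,
    align_hf,
    score,
)

__all__ = [
    "ZeroEnergyError",
    "WeightError",
    "CorrelationReport",
    "validate_weights",
    "information_energy",
    "correlation_c1",
    "rho1",
    "rho2",
    "rho3",
    "rho4",
    "baseline_mean_variance_rho",
    "baseline_mean_variance_rho_weighted",
    "baseline_hfs_rho",
]


class ZeroEnergyError(ZeroDivisionError):
    """A correlation denominator vanished (zero information energy or variance)."""


class WeightError(PHFValidationError):
    """An item-weight vector is invalid (negative entries or sum ≠ 1)."""


@dataclass(frozen=True)
class CorrelationReport:
    """Intermediates of one coefficient evaluation: the two self energies,
    the cross term, the resulting coefficient and a method tag."""

    method: str
    energy_a: float
    energy_b: float
    cross: float
    coefficient: float

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "energy_a": self.energy_a,
            "energy_b": self.energy_b,
            "cross": self.cross,
            "coefficient": self.coefficient,
        }


def validate_weights(weights: Sequence[float], n: int) -> tuple[float, ...]:
    """Check an item-weight vector: length n, non-negative, sums to 1."""
    w = tuple(float(x) for x in weights)
    if len(w) != n:
        raise WeightError(f"expected {n} weights, got {len(w)}")
    if any(x < 0 for x in w):
        raise WeightError("weights must be non-negative")
    if abs(math.fsum(w) - 1.0) > PROB_SUM_TOL:
        raise WeightError(f"weights sum to {math.fsum(w)!r}, expected 1")
    return w


def _check_universe(a: PHFSet, b: PHFSet) -> None:
    if a.n != b.n:
        raise PHFValidationError(
            f"sets live on different universes: n = {a.n} vs {b.n}"
        )


def _energy_terms(a: PHFSet) -> list[float]:
    """Per-item energy (1/l_i) Σ_j (γ p)², with each element's own length."""
    return [
        math.fsum((g * p) ** 2 for g, p in e) / len(e) for e in a.elements
    ]


def _cross_terms(
    a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC
) -> list[float]:
    """Per-item aligned cross products (1/l_i) Σ_j γ_a γ_b p_a p_b."""
    out = []
    for ea, eb in zip(a.elements, b.elements):
        ca, cb, l = align(ea, eb, padding)
        out.append(
            math.fsum(
                ga * gb * pa * pb for (ga, pa), (gb, pb) in zip(ca, cb)
            )
            / l
        )
    return out


def information_energy(a: PHFSet) -> float:
    """Information energy ψ(A) = Σ_i (1/l_i) Σ_j (γ_ij p_ij)²."""
    return math.fsum(_energy_terms(a))


def correlation_c1(
    a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC
) -> float:
    """Cross-correlation C1(A, B) over aligned elements; symmetric."""
    _check_universe(a, b)
    return math.fsum(_cross_terms(a, b, padding))


def _report(method, ea, eb, cross, denom) -> CorrelationReport:
    if denom <= 0.0:
        raise ZeroEnergyError(
            f"{method}: zero information energy (ψ_a={ea!r}, ψ_b={eb!r})"
        )
    return CorrelationReport(method, ea, eb, cross, cross / denom)


def rho1_report(
    a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC
) -> CorrelationReport:
    _check_universe(a, b)
    ea, eb = information_energy(a), information_energy(b)
    cross = correlation_c1(a, b, padding)
    return _report("rho1", ea, eb, cross, math.sqrt(ea) * math.sqrt(eb))


def rho1(a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC) -> float:
    """Geometric-mean-normalized information-energy coefficient; in [0, 1]."""
    return rho1_report(a, b, padding).coefficient


def rho2_report(
    a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC
) -> CorrelationReport:
    _check_universe(a, b)
    ea, eb = information_energy(a), information_energy(b)
    cross = correlation_c1(a, b, padding)
    return _report("rho2", ea, eb, cross, max(ea, eb))


def rho2(a: PHFSet, b: PHFSet, padding: Padding = Padding.PESSIMISTIC) -> float:
    """Max-normalized information-energy coefficient; ρ2 ≤ ρ1."""
    return rho2_report(a, b, padding).coefficient


def _weighted_parts(
    a: PHFSet,
    b: PHFSet,
    weights: Sequence[float],
    padding: Padding,
) -> tuple[float, float, float]:
    _check_universe(a, b)
    w = validate_weights(weights, a.n)
    ea = math.fsum(wi * t for wi, t in zip(w, _energy_terms(a)))
    eb = math.fsum(wi * t for wi, t in zip(w, _energy_terms(b)))
    cross = math.fsum(wi * t for wi, t in zip(w, _cross_terms(a, b, padding)))
    return ea, eb, cross


def rho3_report(
    a: PHFSet,
    b: PHFSet,
    weights: Sequence[float],
    padding: Padding = Padding.PESSIMISTIC,
) -> CorrelationReport:
    ea, eb, cross = _weighted_parts(a, b, weights, padding)
    return _report("rho3", ea, eb, cross, math.sqrt(ea) * math.sqrt(eb))


def rho3(
    a: PHFSet,
    b: PHFSet,
    weights: Sequence[float],
    padding: Padding = Padding.PESSIMISTIC,
) -> float:
    """Weighted geometric-mean coefficient; uniform weights give ρ1."""
    return rho3_report(a, b, weights, padding).coefficient


def rho4_report(
    a: PHFSet,
    b: PHFSet,
    weights: Sequence[float],
    padding: Padding = Padding.PESSIMISTIC,
) -> CorrelationReport:
    ea, eb, cross = _weighted_parts(a, b, weights, padding)
    return _report("rho4", ea, eb, cross, max(ea, eb))


def rho4(
    a: PHFSet,
    b: PHFSet,
    weights: Sequence[float],
    padding: Padding = Padding.PESSIMISTIC,
) -> float:
    """Weighted max-normalized coefficient; uniform weights give ρ2."""
    return rho4_report(a, b, weights, padding).coefficient


# ---------------------------------------------------------------------------
# Mean/variance baseline (Pearson-style over per-element mean vectors)
# ---------------------------------------------------------------------------


def _element_means(a: PHFSet) -> list[float]:
    return [score(e) for e in a.elements]


def _covariance(x: Sequence[float], y: Sequence[float]) -> float:
    n = len(x)
    mx = math.fsum(x) / n
    my = math.fsum(y) / n
    return math.fsum((xi - mx) * (yi - my) for xi, yi in zip(x, y)) / n


def baseline_mean_variance_rho(a: PHFSet, b: PHFSet) -> float:
    """Pearson-style coefficient of the two per-element mean vectors.

    Degenerate by construction: any two sets with identical mean vectors
    correlate at exactly 1, however different their inner structure.
    In [−1, 1].
    """
    _check_universe(a, b)
    if a.n < 2:
        raise PHFValidationError("mean/variance baseline needs n >= 2")
    ma, mb = _element_means(a), _element_means(b)
    va, vb = _covariance(ma, ma), _covariance(mb, mb)
    if va <= 0.0 or vb <= 0.0:
        raise ZeroEnergyError("zero variance of a per-element mean vector")
    return _covariance(ma, mb) / (math.sqrt(va) * math.sqrt(vb))


def baseline_mean_variance_rho_weighted(
    a: PHFSet, b: PHFSet, weights: Sequence[float]
) -> float:
    """Weighted mean/variance baseline: item weights applied inside the
    means and covariances; uniform weights reduce to the unweighted form."""
    _check_universe(a, b)
    if a.n < 2:
        raise PHFValidationError("mean/variance baseline needs n >= 2")
    w = validate_weights(weights, a.n)
    ma = [wi * m for wi, m in zip(w, _element_means(a))]
    mb = [wi * m for wi, m in zip(w, _element_means(b))]
    va, vb = _covariance(ma, ma), _covariance(mb, mb)
    if va <= 0.0 or vb <= 0.0:
        raise ZeroEnergyError("zero weighted variance of a mean vector")
    return _covariance(ma, mb) / (math.sqrt(va) * math.sqrt(vb))


# ---------------------------------------------------------------------------
# Classical hesitant fuzzy set baseline (no probabilities)
# ---------------------------------------------------------------------------


def _hfs_cross(
    a: Sequence[HFElement],
    b: Sequence[HFElement],
    weights: Sequence[float] | None,
    padding: Padding,
) -> float:
    terms = []
    for ea, eb in zip(a, b):
        va, vb, l = align_hf(ea, eb, padding)
        terms.append(math.fsum(x * y for x, y in zip(va, vb)) / l)
    if weights is None:
        return math.fsum(terms)
    return math.fsum(wi * t for wi, t in zip(weights, terms))


def _hfs_self(
    a: Sequence[HFElement], weights: Sequence[float] | None
) -> float:
    terms = [math.fsum(v * v for v in e) / len(e) for e in a]
    if weights is None:
        return math.fsum(terms)
    return math.fsum(wi * t for wi, t in zip(weights, terms))


def baseline_hfs_rho(
    a: Sequence[HFElement],
    b: Sequence[HFElement],
    weights: Sequence[float] | None = None,
    padding: Padding = Padding.PESSIMISTIC,
) -> float:
    """Classical HFS correlation coefficient (probabilities ignored).

    Elements are aligned by sorting values ascending and padding the
    shorter with its minimum value; the cross term uses the common (max)
    length, the self-correlations each set's own lengths, and the result
    is normalized by the square-rooted self-correlations.  The default is
    unweighted; pass ``weights`` to weight the per-item terms.
    """
    if len(a) != len(b):
        raise PHFValidationError(
            f"sets live on different universes: n = {len(a)} vs {len(b)}"
        )
    w = None if weights is None else validate_weights(weights, len(a))
    saa, sbb = _hfs_self(a, w), _hfs_self(b, w)
    if saa <= 0.0 or sbb <= 0.0:
        raise ZeroEnergyError("zero self-correlation of an HFS")
    return _hfs_cross(a, b, w, padding) / (math.sqrt(saa) * math.sqrt(sbb))
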