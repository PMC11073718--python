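"""Seeded random PHFS generation for property tests and simulations."""

from __future__ import annotations

import random
from dataclasses import dataclass

from .elements import PHFElement, PHFSet, PHFValidationError

__all__ = ["GeneratorConfig", "random_phf_element", "random_phfs"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of the random PHFS generator.

    ``probability_scheme`` is either ``uniform-dirichlet`` (probabilities
    drawn uniformly and normalized to sum 1 — a flat Dirichlet) or
    ``equal`` (all entries of an element equally probable).  A fixed seed
    yields byte-identical output.
    """

    seed: int
    n: int = 3
    max_len: int = 4
    probability_scheme: str = "uniform-dirichlet"

    def __post_init__(self) -> None:
        if self.n < 1 or self.max_len < 1:
            raise PHFValidationError("n and max_len must be positive")
        if self.probability_scheme not in ("uniform-dirichlet", "equal"):
            raise PHFValidationError(
                f"unknown probability scheme {self.probability_scheme!r}"
            )


def _element(rng: random.Random, max_len: int, scheme: str) -> PHFElement:
    l = rng.randint(1, max_len)
    gammas = [rng.random() for _ in range(l)]
    if scheme == "equal":
        probs = [1.0 / l] * l
    else:
        raw = [rng.random() + 1e-12 for _ in range(l)]
        total = sum(raw)
        probs = [r / total for r in raw]
    return PHFElement(zip(gammas, probs))


def random_phf_element(config: GeneratorConfig) -> PHFElement:
    """One random PHFE under the given configuration."""
    rng = random.Random(config.seed)
    return _element(rng, config.max_len, config.probability_scheme)


def random_phfs(config: GeneratorConfig) -> PHFSet:
    """A random PHFS with ``n`` elements of 1..max_len entries each.

    Memberships are uniform on [0, 1]; probabilities follow the configured
    scheme and sum to 1 per element.  Deterministic under a fixed seed.
    """
    rng = random.Random(config.seed)
    return PHFSet(
        _element(rng, config.max_len, config.probability_scheme)
        for _ in range(config.n)
    )
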