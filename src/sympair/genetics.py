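"""Genotype representation and real-valued variation operators.

A genotype is a pair of 2-vectors: ``x`` (the independent variables — displayed
traits in males, preferences in females) and ``sigma`` (per-coordinate mutation
standard deviations that self-adapt by a log-normal update).

Operators:

* intermediate recombination — each child coordinate is a convex combination of
  the parents' coordinates with a fresh uniform weight per coordinate, applied
  independently to ``x`` and ``sigma``;
* two-stage self-adaptive mutation — ``sigma`` is updated first,
  ``sigma_i' = sigma_i * exp(tau0 * N + tau * N_i)`` with one normal draw shared
  by all coordinates plus one per coordinate, then ``x`` is perturbed with the
  *new* sigma: ``x_i' = x_i + sigma_i' * N_i``.

The random draws are taken from a caller-supplied generator in a documented
order (recombination: uniforms for x, then uniforms for sigma; mutation: shared
normal, per-coordinate normals, x normals), so identical inputs and seed give
identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DomainError, StructuralError

__all__ = ["Genotype", "VariationParams", "default_taus", "recombine", "mutate"]


@dataclass(frozen=True)
class Genotype:
    """Real-coded genotype: independent variables and mutation step sizes."""

    x: tuple[float, ...]
    sigma: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", tuple(float(v) for v in self.x))
        object.__setattr__(self, "sigma", tuple(float(v) for v in self.sigma))
        if len(self.x) != len(self.sigma):
            raise StructuralError(f"x has length {len(self.x)} but sigma has length {len(self.sigma)}")
        if any(s <= 0.0 for s in self.sigma):
            raise StructuralError(f"sigma must be strictly positive, got {self.sigma}")

    @property
    def dimension(self) -> int:
        return len(self.x)


@dataclass(frozen=True)
class VariationParams:
    """Constants of the variation operators.

    tau0 / tau are the global and per-coordinate learning rates of the
    log-normal sigma update; mut_prob / rec_prob are per-offspring event
    probabilities for applying mutation / recombination.
    """

    tau0: float
    tau: float
    mut_prob: float = 0.1
    rec_prob: float = 0.8

    def __post_init__(self) -> None:
        if self.tau0 <= 0.0 or self.tau <= 0.0:
            raise DomainError("tau0 and tau must be positive")
        for name in ("mut_prob", "rec_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must lie in [0, 1], got {p}")

    @classmethod
    def for_dimension(cls, n: int, mut_prob: float = 0.1, rec_prob: float = 0.8) -> "VariationParams":
        tau0, tau = default_taus(n)
        return cls(tau0=tau0, tau=tau, mut_prob=mut_prob, rec_prob=rec_prob)


def default_taus(n: int) -> tuple[float, float]:
    """Recommended learning rates for an ``n``-dimensional genotype.

    tau0 = 1/sqrt(2n) (shared draw), tau = 1/sqrt(2*sqrt(n)) (per-coordinate).
    """
    if n < 1:
        raise DomainError(f"dimension must be >= 1, got {n}")
    return 1.0 / math.sqrt(2.0 * n), 1.0 / math.sqrt(2.0 * math.sqrt(n))


def recombine(parent_a: Genotype, parent_b: Genotype, rng) -> Genotype:
    """Intermediate recombination of two parents into one child.

    Each coordinate of the child is ``xi*a_i + (1-xi)*b_i`` with a fresh
    uniform ``xi`` per coordinate; ``x`` and ``sigma`` get independent draws.
    Children therefore lie inside the per-coordinate interval spanned by the
    parents, for both vectors.
    """
    if parent_a.dimension != parent_b.dimension:
        raise StructuralError(
            f"parents have mismatched dimensions {parent_a.dimension} != {parent_b.dimension}"
        )
    n = parent_a.dimension
    xi_x = rng.random(n)
    xi_s = rng.random(n)
    x = tuple(
        float(xi_x[i]) * parent_a.x[i] + (1.0 - float(xi_x[i])) * parent_b.x[i] for i in range(n)
    )
    sigma = tuple(
        float(xi_s[i]) * parent_a.sigma[i] + (1.0 - float(xi_s[i])) * parent_b.sigma[i]
        for i in range(n)
    )
    return Genotype(x=x, sigma=sigma)


def mutate(g: Genotype, p: VariationParams, rng) -> Genotype:
    """Two-stage self-adaptive mutation (sigma first, then x with the new sigma).

    The result is *not* clamped to any landscape domain; clamping is the
    caller's responsibility.  The exponential update keeps sigma strictly
    positive for any draws.
    """
    n = g.dimension
    shared = float(rng.standard_normal())
    per_coord = rng.standard_normal(n)
    sigma = tuple(
        g.sigma[i] * math.exp(p.tau0 * shared + p.tau * float(per_coord[i])) for i in range(n)
    )
    x_draws = rng.standard_normal(n)
    x = tuple(g.x[i] + sigma[i] * float(x_draws[i]) for i in range(n))
    return Genotype(x=x, sigma=sigma)
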