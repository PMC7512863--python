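"""Multimodal fitness landscapes used as model ecosystems.

Each landscape is a 2-D minimization problem; the neighbourhoods of its local
minima play the role of ecological niches.  Lower values mean better-adapted
agents.  Four classic benchmark surfaces are shipped: Michalewicz, Rastrigin,
Schwefel and Waves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Callable, Mapping, Sequence

from .errors import ConfigurationError, DomainError

__all__ = ["LandscapeSpec", "get_landscape", "landscape_names", "evaluate", "clamp"]


@dataclass(frozen=True)
class LandscapeSpec:
    """A named 2-D fitness landscape together with its domain box."""

    name: str
    lower_bounds: tuple[float, float]
    upper_bounds: tuple[float, float]
    dimension: int = 2
    extra_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.lower_bounds) != self.dimension or len(self.upper_bounds) != self.dimension:
            raise ConfigurationError(f"landscape {self.name!r}: bounds must have length {self.dimension}")
        for lo, hi in zip(self.lower_bounds, self.upper_bounds):
            if not lo < hi:
                raise ConfigurationError(f"landscape {self.name!r}: lower bound {lo} not below upper bound {hi}")
        object.__setattr__(self, "extra_params", MappingProxyType(dict(self.extra_params)))

    @property
    def widths(self) -> tuple[float, ...]:
        return tuple(hi - lo for lo, hi in zip(self.lower_bounds, self.upper_bounds))

    def contains(self, x: Sequence[float]) -> bool:
        return all(lo <= xi <= hi for xi, lo, hi in zip(x, self.lower_bounds, self.upper_bounds))


def _michalewicz(x: Sequence[float], params: Mapping[str, float]) -> float:
    # f1 = -sum_i sin(x_i) * sin(i * x_i^2 / pi)^(2m), i counted from 1
    m = params.get("m", 10.0)
    total = 0.0
    for i, xi in enumerate(x, start=1):
        total += math.sin(xi) * math.sin(i * xi * xi / math.pi) ** (2.0 * m)
    return -total


def _rastrigin(x: Sequence[float], params: Mapping[str, float]) -> float:
    n = len(x)
    return 10.0 * n + sum(xi * xi - 10.0 * math.cos(2.0 * math.pi * xi) for xi in x)


def _schwefel(x: Sequence[float], params: Mapping[str, float]) -> float:
    return sum(-xi * math.sin(math.sqrt(abs(xi))) for xi in x)


def _waves(x: Sequence[float], params: Mapping[str, float]) -> float:
    # The published typesetting of this surface is ambiguous; this is the one
    # parenthesization used throughout the package (see docs/methods.md).
    x1, x2 = x
    return (
        -((0.3 * x1) ** 3)
        - x2 * x2
        - 4.5 * x2 * x2 * x1 * x2
        - 4.7 * math.cos(3.0 * x1 - x2 * x2 * (2.0 + x1)) * math.sin(2.5 * math.pi * x1)
    )


_FUNCTIONS: dict[str, Callable[[Sequence[float], Mapping[str, float]], float]] = {
    "michalewicz": _michalewicz,
    "rastrigin": _rastrigin,
    "schwefel": _schwefel,
    "waves": _waves,
}

_REGISTRY: dict[str, LandscapeSpec] = {
    "michalewicz": LandscapeSpec("michalewicz", (0.0, 0.0), (math.pi, math.pi), extra_params={"m": 10.0}),
    "rastrigin": LandscapeSpec("rastrigin", (-2.5, -2.5), (2.5, 2.5)),
    "schwefel": LandscapeSpec("schwefel", (-500.0, -500.0), (500.0, 500.0)),
    "waves": LandscapeSpec("waves", (-0.9, -1.2), (1.2, 1.2)),
}


def landscape_names() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def get_landscape(name: str) -> LandscapeSpec:
    """Look up one of the shipped landscapes by name."""
    try:
        return _REGISTRY[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown landscape {name!r}; available: {', '.join(landscape_names())}"
        ) from None


def evaluate(spec: LandscapeSpec, x: Sequence[float]) -> float:
    """Evaluate the landscape at ``x`` (must lie inside the domain box).

    Deterministic and pure; lower is fitter.
    """
    if spec.name not in _FUNCTIONS:
        raise ConfigurationError(f"unknown landscape {spec.name!r}")
    if len(x) != spec.dimension:
        raise DomainError(f"expected a {spec.dimension}-vector, got length {len(x)}")
    if not spec.contains(x):
        raise DomainError(f"point {tuple(x)} outside the domain box of {spec.name!r}")
    return _FUNCTIONS[spec.name](x, spec.extra_params)


_RANGE_CACHE: dict[str, tuple[float, float]] = {}


def value_bounds(spec: LandscapeSpec, grid: int = 201) -> tuple[float, float]:
    """Approximate (min, max) of the landscape over its box, by dense grid scan.

    Used to express fitness differences on the landscape's own scale (e.g. by
    the resource-dispensing weights).  Cached per landscape name.
    """
    if spec.name not in _RANGE_CACHE:
        lo_v = math.inf
        hi_v = -math.inf
        f = _FUNCTIONS[spec.name]
        xs = [spec.lower_bounds[0] + i * spec.widths[0] / (grid - 1) for i in range(grid)]
        ys = [spec.lower_bounds[1] + j * spec.widths[1] / (grid - 1) for j in range(grid)]
        for x in xs:
            for y in ys:
                v = f((x, y), spec.extra_params)
                if v < lo_v:
                    lo_v = v
                if v > hi_v:
                    hi_v = v
        _RANGE_CACHE[spec.name] = (lo_v, hi_v)
    return _RANGE_CACHE[spec.name]


def value_range(spec: LandscapeSpec) -> float:
    """Spread between the landscape's (approximate) worst and best values."""
    lo_v, hi_v = value_bounds(spec)
    return hi_v - lo_v


def domain_diagonal(spec: LandscapeSpec) -> float:
    """Euclidean length of the domain box diagonal (the genetic-space scale)."""
    return math.hypot(*spec.widths)


def clamp(spec: LandscapeSpec, x: Sequence[float]) -> tuple[float, ...]:
    """Clip each coordinate to the landscape's domain box (idempotent)."""
    return tuple(
        min(max(xi, lo), hi)
        for xi, lo, hi in zip(x, spec.lower_bounds, spec.upper_bounds)
    )
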