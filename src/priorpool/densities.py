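"""Normal and normal-mixture densities used to represent prior evidence.

Priors on standardized regression coefficients are represented analytically:
a single study (after power-prior variance inflation) is a normal density,
and a linear opinion pool of several studies is a finite normal mixture.
Mixtures keep their component list; they are never discretized.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = ["NormalDensity", "MixtureDensity", "density_from_dict"]

_WEIGHT_TOL = 1e-12


@dataclass(frozen=True)
class NormalDensity:
    """A normal density N(mean, sd) on a standardized (unitless) effect."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if not (self.sd > 0 and math.isfinite(self.sd)):
            raise ValueError(f"sd must be positive and finite, got {self.sd}")
        if not math.isfinite(self.mean):
            raise ValueError(f"mean must be finite, got {self.mean}")

    @property
    def variance(self) -> float:
        return self.sd**2

    def pdf(self, x):
        return stats.norm.pdf(x, loc=self.mean, scale=self.sd)

    def rvs(self, size: int, rng: np.random.Generator):
        return rng.normal(self.mean, self.sd, size=size)

    def to_dict(self) -> dict:
        return {"family": "normal", "mean": self.mean, "sd": self.sd}


@dataclass(frozen=True)
class MixtureDensity:
    """A finite mixture of normals, e.g. the linear pool of study priors.

    Weights default to equal (1/k) and must sum to one.
    """

    components: tuple[NormalDensity, ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if len(comps) < 1:
            raise ValueError("mixture needs at least one component")
        object.__setattr__(self, "components", comps)
        w = tuple(self.weights) if self.weights else tuple([1.0 / len(comps)] * len(comps))
        if len(w) != len(comps):
            raise ValueError("weights and components length mismatch")
        if any(wi <= 0 for wi in w):
            raise ValueError("all mixture weights must be > 0")
        if abs(sum(w) - 1.0) > _WEIGHT_TOL:
            raise ValueError(f"mixture weights must sum to 1, got {sum(w)!r}")
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return len(self.components)

    @property
    def mean(self) -> float:
        return float(sum(w * c.mean for w, c in zip(self.weights, self.components)))

    @property
    def variance(self) -> float:
        m = self.mean
        second = sum(w * (c.variance + c.mean**2) for w, c in zip(self.weights, self.components))
        return float(second - m**2)

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def pdf(self, x):
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        for w, c in zip(self.weights, self.components):
            out += w * c.pdf(x)
        return out

    def rvs(self, size: int, rng: np.random.Generator):
        idx = rng.choice(self.k, size=size, p=np.asarray(self.weights))
        draws = np.empty(size)
        for j, c in enumerate(self.components):
            sel = idx == j
            n = int(sel.sum())
            if n:
                draws[sel] = c.rvs(n, rng)
        return draws

    def to_dict(self) -> dict:
        return {
            "family": "mixture",
            "components": [c.to_dict() for c in self.components],
            "weights": list(self.weights),
        }


def density_from_dict(d: dict) -> NormalDensity | MixtureDensity:
    """Inverse of ``to_dict`` for JSON round-tripping of priors."""
    fam = d.get("family")
    if fam == "normal":
        return NormalDensity(float(d["mean"]), float(d["sd"]))
    if fam == "mixture":
        comps = tuple(density_from_dict(c) for c in d["components"])
        return MixtureDensity(comps, tuple(float(w) for w in d["weights"]))
    raise ValueError(f"unknown density family: {fam!r}")
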