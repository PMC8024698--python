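"""Aggregation of several study priors on one parameter into a single prior.

Three pooling rules for normal components N(mu_i, sigma_i), weights w_i
(equal by default):

linear pool
    the weighted arithmetic average of densities, an analytic normal
    mixture.  Represents every previous result as-is and can be multimodal
    when studies disagree.

logarithmic (geometric) pool
    the normalized weighted product of densities.  For normals this is
    again normal, with precision tau = sum w_i / sigma_i^2 and mean
    (sum w_i mu_i / sigma_i^2) / tau.  It emphasizes the consensual range
    and is never more dispersed than its most precise component, so a
    hyper-precise study dominates it.

normal fitted to the linear pool
    the single normal best fitting the linear pool.  closed_form mode uses
    the mixture's exact moments (the infinite-sample limit of a maximum
    likelihood fit); sampling mode draws n_per_component samples from each
    component and fits by MLE, mirroring a simulation-based workflow.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .densities import MixtureDensity, NormalDensity, density_from_dict
from .weighting import PowerPrior

__all__ = [
    "PooledPrior",
    "linear_pool",
    "logarithmic_pool",
    "fit_normal_to_pool",
    "pool_power_priors",
    "save_pooled_priors",
    "load_pooled_priors",
]


def _check_components(components: Sequence[NormalDensity]) -> None:
    if len(components) == 0:
        raise ValueError("cannot pool an empty component list")


def _resolve_weights(components: Sequence[NormalDensity], weights) -> tuple[float, ...]:
    if weights is None:
        return tuple([1.0 / len(components)] * len(components))
    w = tuple(float(x) for x in weights)
    if len(w) != len(components):
        raise ValueError("weights length must match components")
    if abs(sum(w) - 1.0) > 1e-9:
        raise ValueError("pooling weights must sum to 1")
    if any(x <= 0 for x in w):
        raise ValueError("pooling weights must be positive")
    return w


def linear_pool(
    components: Sequence[NormalDensity], weights: Sequence[float] | None = None
) -> MixtureDensity:
    """Weighted sum of densities: an analytic normal mixture."""
    _check_components(components)
    w = _resolve_weights(components, weights)
    return MixtureDensity(tuple(components), w)


def logarithmic_pool(
    components: Sequence[NormalDensity], weights: Sequence[float] | None = None
) -> NormalDensity:
    """Normalized weighted product of normal densities (precision pooling)."""
    _check_components(components)
    w = _resolve_weights(components, weights)
    tau = sum(wi / c.variance for wi, c in zip(w, components))
    mean = sum(wi * c.mean / c.variance for wi, c in zip(w, components)) / tau
    return NormalDensity(mean=float(mean), sd=float(1.0 / math.sqrt(tau)))


def fit_normal_to_pool(
    mixture: MixtureDensity,
    mode: str = "closed_form",
    n_per_component: int = 5_000,
    seed: int | None = None,
) -> NormalDensity:
    """Single normal fitted to a linear pool.

    closed_form: N(mixture mean, mixture sd) — exact moment matching, the
    limit of a normal MLE on infinitely many pooled draws; deterministic.
    sampling: draw ``n_per_component`` samples from each component, fit a
    normal by maximum likelihood (sample mean, sample sd); converges to the
    closed form as the draw count grows.
    """
    if mode == "closed_form":
        return NormalDensity(mixture.mean, mixture.sd)
    if mode != "sampling":
        raise ValueError(f"unknown mode {mode!r}; use 'closed_form' or 'sampling'")
    if n_per_component < 1:
        raise ValueError("n_per_component must be >= 1")
    if seed is None:
        raise ValueError("sampling mode requires a seed")
    rng = np.random.default_rng(seed)
    draws = np.concatenate([c.rvs(n_per_component, rng) for c in mixture.components])
    # Normal MLE = sample moments (sd with ddof=0).
    return NormalDensity(float(draws.mean()), float(draws.std(ddof=0)))


@dataclass(frozen=True)
class PooledPrior:
    """One parameter's aggregated prior with its provenance."""

    parameter_id: str
    method: str  # {linear, logarithmic, fitted_normal, default}
    density: NormalDensity | MixtureDensity
    provenance: tuple[dict, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.method == "linear" and not isinstance(self.density, MixtureDensity):
            raise ValueError("linear pooling must yield a mixture density")
        if self.method != "linear" and isinstance(self.density, MixtureDensity):
            raise ValueError(f"method {self.method!r} must yield a single normal")

    def to_dict(self) -> dict:
        return {
            "parameter_id": self.parameter_id,
            "method": self.method,
            "density": self.density.to_dict(),
            "provenance": list(self.provenance),
        }


def pool_power_priors(
    priors_by_parameter: dict[str, list[PowerPrior]],
    method: str,
    weights: Sequence[float] | None = None,
    n_per_component: int = 5_000,
    seed: int | None = None,
) -> dict[str, PooledPrior]:
    """Aggregate each parameter's power priors with the requested method.

    ``method`` is one of "linear", "logarithmic", "fitted_normal".  Pooling
    weights are equal across studies unless given explicitly.
    """
    if method not in ("linear", "logarithmic", "fitted_normal"):
        raise ValueError(f"unknown pooling method {method!r}")
    out: dict[str, PooledPrior] = {}
    for pid, pps in priors_by_parameter.items():
        comps = [pp.density() for pp in pps]
        prov = tuple(
            {"study_id": pp.source, "delta": pp.delta, "dialect": pp.dialect} for pp in pps
        )
        if method == "linear":
            dens: NormalDensity | MixtureDensity = linear_pool(comps, weights)
        elif method == "logarithmic":
            dens = logarithmic_pool(comps, weights)
        else:
            mix = linear_pool(comps, weights)
            if seed is None:
                dens = fit_normal_to_pool(mix, mode="closed_form")
            else:
                dens = fit_normal_to_pool(
                    mix, mode="sampling", n_per_component=n_per_component, seed=seed
                )
        out[pid] = PooledPrior(parameter_id=pid, method=method, density=dens, provenance=prov)
    return out


def save_pooled_priors(pooled: dict[str, PooledPrior], path: str | Path) -> None:
    payload = {pid: pp.to_dict() for pid, pp in sorted(pooled.items())}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def load_pooled_priors(path: str | Path) -> dict[str, PooledPrior]:
    payload = json.loads(Path(path).read_text())
    out = {}
    for pid, d in payload.items():
        out[pid] = PooledPrior(
            parameter_id=pid,
            method=d["method"],
            density=density_from_dict(d["density"]),
            provenance=tuple(d.get("provenance", ())),
        )
    return out
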