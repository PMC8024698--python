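"""Cross-lagged mediation path models and their estimation inputs.

Two half-longitudinal mediation models share one structure: internalizing
symptoms of mother (Mint) and adolescent (Aint) at wave T1 predict observed
interaction behavior at wave T2, which in turn predicts symptoms at wave
T3, with 2-year autoregressive symptom paths.  Model A uses positive
interaction behavior (MP, AP), model B negative (MN, AN):

    behavior_T2 ~ Mint1 + Aint1                 (two equations)
    symptom_T3  ~ behavior_M_T2 + behavior_A_T2 + own symptom_T1

The two T2 behavior equations form a residual-correlation block (their
disturbances get a free 2x2 covariance); T3 residuals are independent.
Coefficients are named "<response>on<predictor>" (MPonMint, AintonAP, ...),
ten per model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .densities import MixtureDensity, NormalDensity

__all__ = [
    "Equation",
    "PathModelSpec",
    "PriorAssignment",
    "MCMCConfig",
    "build_model_spec",
    "standardize",
]


@dataclass(frozen=True)
class Equation:
    """One regression equation: response regressed on ordered predictors.

    ``coef_names`` name the slope coefficients, in predictor order.
    """

    response: str
    predictors: tuple[str, ...]
    coef_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.predictors) != len(self.coef_names):
            raise ValueError(f"{self.response}: predictors/coef_names length mismatch")

    @property
    def intercept_name(self) -> str:
        return f"intercept_{self.response}"


@dataclass(frozen=True)
class PathModelSpec:
    """Equations plus residual-correlation blocks of a path model."""

    label: str
    equations: tuple[Equation, ...]
    residual_blocks: tuple[frozenset[str], ...] = ()
    include_intercepts: bool = True

    @property
    def coefficient_names(self) -> tuple[str, ...]:
        return tuple(n for eq in self.equations for n in eq.coef_names)

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names = []
        for eq in self.equations:
            if self.include_intercepts:
                names.append(eq.intercept_name)
            names.extend(eq.coef_names)
        return tuple(names)

    @property
    def variables(self) -> tuple[str, ...]:
        seen: list[str] = []
        for eq in self.equations:
            for v in (eq.response, *eq.predictors):
                if v not in seen:
                    seen.append(v)
        return tuple(seen)

    def equation_for(self, response: str) -> Equation:
        for eq in self.equations:
            if eq.response == response:
                return eq
        raise KeyError(f"no equation for response {response!r}")


def build_model_spec(label: str) -> PathModelSpec:
    """The mediation model for positive ("A") or negative ("B") behavior."""
    if label == "A":
        mb, ab = "MP2", "AP2"
        mtag, atag = "MP", "AP"
    elif label == "B":
        mb, ab = "MN2", "AN2"
        mtag, atag = "MN", "AN"
    else:
        raise ValueError(f"unknown model label {label!r}; use 'A' or 'B'")
    equations = (
        Equation(mb, ("Mint1", "Aint1"), (f"{mtag}onMint", f"{mtag}onAint")),
        Equation(ab, ("Mint1", "Aint1"), (f"{atag}onMint", f"{atag}onAint")),
        Equation("Mint3", (mb, ab, "Mint1"), (f"Minton{mtag}", f"Minton{atag}", "MintonMint")),
        Equation("Aint3", (mb, ab, "Aint1"), (f"Ainton{mtag}", f"Ainton{atag}", "AintonAint")),
    )
    return PathModelSpec(
        label=label,
        equations=equations,
        residual_blocks=(frozenset({mb, ab}),),
    )


def standardize(dataset: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every column to mean 0, sample sd 1.

    Applied per completed (imputed) dataset before estimation, so that
    coefficients are standardized effects comparable with the priors.
    """
    if dataset.isna().any().any():
        raise ValueError("standardize requires a complete dataset (impute first)")
    out = dataset.copy()
    for col in out.columns:
        sd = out[col].std(ddof=1)
        if not sd > 0:
            raise ValueError(f"column {col!r} is constant; cannot standardize")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


@dataclass(frozen=True)
class PriorAssignment:
    """Priors per named parameter, with a proper low-informative fallback.

    Unlisted parameters (intercepts, residual-block coefficients without
    previous evidence) receive the fallback, N(0, 10) by default.
    """

    priors: Mapping[str, NormalDensity | MixtureDensity] = field(default_factory=dict)
    fallback: NormalDensity = NormalDensity(0.0, 10.0)

    def resolve(self, name: str) -> NormalDensity | MixtureDensity:
        return self.priors.get(name, self.fallback)

    @staticmethod
    def diffuse(coefficient_names: Sequence[str], sd: float = 100.0) -> "PriorAssignment":
        """The emulated default-prior regime: N(0, sd) on every coefficient.

        A proper wide normal stands in for improper flat software defaults
        so that shrinkage s = 1 - post_var / prior_var stays defined.
        """
        return PriorAssignment({name: NormalDensity(0.0, sd) for name in coefficient_names})


@dataclass(frozen=True)
class MCMCConfig:
    """Gibbs run lengths: 3 chains of 8,000 iterations, 3,000 warmup."""

    chains: int = 3
    iterations: int = 8_000
    warmup: int = 3_000

    def __post_init__(self) -> None:
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if not (0 <= self.warmup < self.iterations):
            raise ValueError("need 0 <= warmup < iterations")

    @property
    def kept(self) -> int:
        return self.iterations - self.warmup
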