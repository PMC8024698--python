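"""Synthetic dyadic data with the study's descriptive structure.

The generator emulates the analysis sample: mother-adolescent dyads with
internalizing-symptom composites at waves T1 and T3 and observed positive
and negative interaction behavior at T2.  Dyads are drawn from a
multivariate normal whose means, standard deviations, and correlations are
the published descriptives of those eight composites.  MCAR missingness and
previous-study evidence fixtures are generated alongside, so the whole
pipeline (weighting -> pooling -> imputation -> estimation -> diagnostics)
runs without any external data.

One printed correlation — maternal negative interaction T2 with adolescent
internalizing T1, shown as -0.81 — is implausibly large in context and
renders the full matrix non-positive-definite; the packaged default reads
it as -0.081 (the PSD-feasible reading) and records the cell as uncertain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .weighting import (
    StudyEvidence,
    WeightingScheme,
    default_scheme,
    parameter_class,
)

__all__ = [
    "GeneratorSpec",
    "MissingnessSpec",
    "default_generator_spec",
    "default_missingness_spec",
    "generate_dyads",
    "inject_missingness",
    "generate_evidence_fixtures",
    "VARIABLES",
    "AUX_COLUMN",
]

#: The eight model composites (both model variants share the symptom columns).
VARIABLES = ("Aint1", "Aint3", "Mint1", "Mint3", "MP2", "MN2", "AP2", "AN2")

#: Auxiliary column: the depression-questionnaire component of the T1
#: adolescent internalizing composite, carrying the study's 54% missingness.
AUX_COLUMN = "rads2_T1"

_MEANS = {
    "Aint1": -0.12, "Aint3": -0.02, "Mint1": 0.19, "Mint3": 0.19,
    "MP2": 3.50, "MN2": 1.48, "AP2": 3.30, "AN2": 1.43,
}
_SDS = {
    "Aint1": 0.95, "Aint3": 0.88, "Mint1": 0.17, "Mint3": 0.18,
    "MP2": 0.79, "MN2": 0.72, "AP2": 0.91, "AN2": 0.79,
}
# Lower-triangular published correlations, variable order as in VARIABLES.
# The (MN2, Aint1) cell is the uncertain -0.81/-0.081 entry (see module doc).
_CORR_LOWER = {
    ("Aint3", "Aint1"): 0.601,
    ("Mint1", "Aint1"): 0.195, ("Mint1", "Aint3"): 0.148,
    ("Mint3", "Aint1"): 0.105, ("Mint3", "Aint3"): 0.195, ("Mint3", "Mint1"): 0.669,
    ("MP2", "Aint1"): -0.177, ("MP2", "Aint3"): -0.293,
    ("MP2", "Mint1"): -0.293, ("MP2", "Mint3"): -0.366,
    ("MN2", "Aint1"): -0.081, ("MN2", "Aint3"): 0.082,
    ("MN2", "Mint1"): 0.184, ("MN2", "Mint3"): 0.185, ("MN2", "MP2"): -0.574,
    ("AP2", "Aint1"): -0.185, ("AP2", "Aint3"): -0.309, ("AP2", "Mint1"): -0.232,
    ("AP2", "Mint3"): -0.106, ("AP2", "MP2"): 0.471, ("AP2", "MN2"): -0.260,
    ("AN2", "Aint1"): 0.152, ("AN2", "Aint3"): 0.194, ("AN2", "Mint1"): 0.171,
    ("AN2", "Mint3"): 0.238, ("AN2", "MP2"): -0.279, ("AN2", "MN2"): 0.223,
    ("AN2", "AP2"): -0.735,
}

#: Correlation of the auxiliary depression component with the T1 composite.
_AUX_CORR = 0.85


@dataclass(frozen=True)
class GeneratorSpec:
    """Moments of the multivariate-normal dyad generator."""

    variables: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]
    correlation: np.ndarray
    n: int = 102
    include_aux: bool = False

    def __post_init__(self) -> None:
        p = len(self.variables)
        if not (len(self.means) == len(self.sds) == p):
            raise ValueError("variables, means, sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError("all sds must be > 0")
        R = np.asarray(self.correlation, dtype=float)
        if R.shape != (p, p):
            raise ValueError(f"correlation must be {p}x{p}")
        if not np.allclose(R, R.T, atol=1e-12) or not np.allclose(np.diag(R), 1.0):
            raise ValueError("correlation must be symmetric with unit diagonal")
        object.__setattr__(self, "correlation", R)

    @property
    def covariance(self) -> np.ndarray:
        s = np.asarray(self.sds)
        return self.correlation * np.outer(s, s)


@dataclass(frozen=True)
class MissingnessSpec:
    """Per-variable MCAR missingness rates in [0, 1)."""

    rates: Mapping[str, float]

    def __post_init__(self) -> None:
        for v, r in self.rates.items():
            if not (0.0 <= r < 1.0):
                raise ValueError(f"rate for {v!r} must be in [0, 1), got {r}")


def default_generator_spec(n: int = 102, include_aux: bool = True) -> GeneratorSpec:
    """The packaged generator calibrated to the published descriptives."""
    p = len(VARIABLES)
    R = np.eye(p)
    idx = {v: i for i, v in enumerate(VARIABLES)}
    for (a, b), r in _CORR_LOWER.items():
        R[idx[a], idx[b]] = R[idx[b], idx[a]] = r
    return GeneratorSpec(
        variables=VARIABLES,
        means=tuple(_MEANS[v] for v in VARIABLES),
        sds=tuple(_SDS[v] for v in VARIABLES),
        correlation=R,
        n=n,
        include_aux=include_aux,
    )


def default_missingness_spec(include_aux: bool = True) -> MissingnessSpec:
    """Modest per-variable MCAR rates (2-13%) plus 54% on the auxiliary
    depression component, matching the study's missingness profile."""
    rates = {
        "Aint1": 0.02, "Aint3": 0.08, "Mint1": 0.04, "Mint3": 0.13,
        "MP2": 0.06, "MN2": 0.13, "AP2": 0.06, "AN2": 0.07,
    }
    if include_aux:
        rates[AUX_COLUMN] = 0.54
    return MissingnessSpec(rates)


def _nearest_psd(R: np.ndarray, min_eig_floor: float = -0.05) -> np.ndarray:
    """Clip negative eigenvalues and rescale to unit diagonal.

    Small indefiniteness (min eigenvalue in (min_eig_floor, 0)) is repaired
    with a warning; anything worse is an error — the entered correlations
    are then inconsistent beyond rounding.
    """
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= 0:
        return R
    if vals.min() < min_eig_floor:
        raise ValueError(
            f"correlation matrix is not PSD (min eigenvalue {vals.min():.4f} "
            f"< floor {min_eig_floor}); check the entered correlations"
        )
    warnings.warn(
        f"correlation matrix slightly non-PSD (min eigenvalue {vals.min():.2e}); "
        "repaired by eigenvalue clipping",
        stacklevel=3,
    )
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def _cholesky_factor(spec: GeneratorSpec) -> np.ndarray:
    """The lower-triangular factor L with L L' = covariance (after repair)."""
    R = _nearest_psd(spec.correlation)
    s = np.asarray(spec.sds)
    cov = R * np.outer(s, s)
    # Tiny jitter guards the factorization right at the PSD boundary.
    return np.linalg.cholesky(cov + 1e-12 * np.eye(len(s)))


def generate_dyads(spec: GeneratorSpec, seed: int) -> pd.DataFrame:
    """Draw ``spec.n`` dyads from N(means, covariance).

    With ``include_aux`` a depression-component column is appended,
    correlated at 0.85 with the T1 adolescent internalizing composite.
    """
    rng = np.random.default_rng(seed)
    L = _cholesky_factor(spec)
    z = rng.standard_normal((spec.n, len(spec.variables)))
    X = z @ L.T + np.asarray(spec.means)
    df = pd.DataFrame(X, columns=list(spec.variables))
    if spec.include_aux and "Aint1" in spec.variables:
        i = spec.variables.index("Aint1")
        z_a = (df["Aint1"] - spec.means[i]) / spec.sds[i]
        noise = rng.standard_normal(spec.n)
        aux = _AUX_CORR * z_a + np.sqrt(1 - _AUX_CORR**2) * noise
        # Scale roughly like the composite it feeds.
        df[AUX_COLUMN] = spec.means[i] + spec.sds[i] * aux
    return df


def inject_missingness(
    dataset: pd.DataFrame, missspec: MissingnessSpec, seed: int
) -> pd.DataFrame:
    """Independently blank each cell of variable v with probability rate(v).

    Missingness is MCAR: the mask depends on nothing but the seed.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    for var, rate in missspec.rates.items():
        if var not in out.columns:
            continue
        mask = rng.random(len(out)) < rate
        out.loc[mask, var] = np.nan
    return out


# ------------------------------------------------------- evidence fixtures


def _default_flag_probs(scheme: WeightingScheme) -> dict[str, float]:
    probs = {name: 0.5 for name in scheme.names}
    probs["longitudinal"] = 1.0  # fixtures emulate the longitudinal study list
    probs["meta_analysis"] = 0.3
    return probs


def generate_evidence_fixtures(
    true_effects: Mapping[str, float],
    k_studies: int = 3,
    se_range: tuple[float, float] = (0.05, 0.30),
    flag_distribution: Mapping[str, float] | None = None,
    seed: int = 0,
    hyper_precise: bool = False,
    scheme: WeightingScheme | None = None,
    k_per_parameter: Mapping[str, int] | None = None,
) -> list[StudyEvidence]:
    """Fabricate previous-study evidence for each model parameter.

    Per parameter, ``k_studies`` records are drawn with estimates
    ~ N(true effect, se^2), se ~ Uniform(se_range), and random category
    flags (restricted to categories applicable to the parameter's class).
    ``hyper_precise`` adds one extra study per parameter with
    se = se_range[0] / 50, recreating the situation where a single
    extremely specific previous result dominates the logarithmic pool.
    """
    if not true_effects:
        raise ValueError("true_effects must not be empty")
    if k_studies < 1:
        raise ValueError("k_studies must be >= 1")
    lo, hi = se_range
    if not (0 < lo <= hi):
        raise ValueError("se_range must be positive with lo <= hi")
    scheme = scheme or default_scheme()
    probs = dict(flag_distribution or _default_flag_probs(scheme))
    rng = np.random.default_rng(seed)
    out: list[StudyEvidence] = []
    for pid, true in true_effects.items():
        pclass = parameter_class(pid)
        k = k_per_parameter.get(pid, k_studies) if k_per_parameter else k_studies
        for j in range(k):
            se = float(rng.uniform(lo, hi))
            est = float(rng.normal(true, se))
            flags = {}
            for cat in scheme.categories:
                if pclass not in cat.applicable_to:
                    continue
                flags[cat.name] = bool(rng.random() < probs.get(cat.name, 0.5))
            kind = "meta-analysis" if flags.get("meta_analysis") else "empirical"
            out.append(
                StudyEvidence(
                    study_id=f"{pid}_study{j + 1}",
                    parameter_id=pid,
                    estimate=est,
                    se=se,
                    flags=flags,
                    kind=kind,
                )
            )
        if hyper_precise:
            se = lo / 50.0
            flags = {
                cat.name: True
                for cat in scheme.categories
                if pclass in cat.applicable_to and cat.name != "meta_analysis"
            }
            flags["meta_analysis"] = False
            out.append(
                StudyEvidence(
                    study_id=f"{pid}_hyperprecise",
                    parameter_id=pid,
                    estimate=float(rng.normal(true, se)),
                    se=se,
                    flags=flags,
                    kind="empirical",
                )
            )
    return out
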