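"""Expert weighting of previous-study evidence into power priors.

A previous study reports a standardized effect estimate and its standard
error for one regression parameter of the mediation model.  An expert-built
scoring scheme rates how closely the study's design matches the present
study (longitudinal, observational, age range, ...).  The total score,
divided by the maximum attainable score for that parameter class, yields
the power-prior weight delta in (0, 1]; the study's variance is then
inflated by the weight before the study enters any pooling step:

    variance dialect (default):  sd = se / sqrt(delta)
        the exact identity for raising a normal likelihood to the power delta
    sd dialect:                  sd = se / delta
        an alternative convention in which delta divides the standard
        deviation directly

Both dialects agree at delta = 1 and both inflate uncertainty as delta
decreases; the sd dialect inflates more aggressively.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping

import pandas as pd
import yaml

from .densities import NormalDensity

__all__ = [
    "CategoryDefinition",
    "WeightingScheme",
    "StudyEvidence",
    "PowerPrior",
    "StudyExcludedError",
    "score_study",
    "compute_delta",
    "build_power_prior",
    "default_scheme",
    "load_scheme",
    "load_evidence",
    "parameter_class",
]

logger = logging.getLogger(__name__)

#: Parameter classes distinguished by the scheme.  T1_T2: symptom -> behavior
#: paths; T2_T3: behavior -> symptom paths and autoregressive symptom paths
#: (both condition on symptoms at T1 by construction).
PARAMETER_CLASSES = ("T1_T2", "T2_T3")

# Coefficient naming convention: "<response>on<predictor>".  Responses MP, AP,
# MN, AN are T2 interaction behaviors; responses Mint, Aint are T3 symptoms.
_T2_RESPONSES = ("MP", "AP", "MN", "AN")


def parameter_class(parameter_id: str) -> str:
    """Classify a coefficient name as a T1->T2 or a T2->T3 parameter."""
    head = parameter_id.split("on")[0]
    return "T1_T2" if head in _T2_RESPONSES else "T2_T3"


@dataclass(frozen=True)
class CategoryDefinition:
    name: str
    points: int
    applicable_to: frozenset[str] = frozenset(PARAMETER_CLASSES)
    details: str = ""

    def __post_init__(self) -> None:
        if self.points < 0:
            raise ValueError(f"category {self.name!r}: points must be >= 0")
        unknown = set(self.applicable_to) - set(PARAMETER_CLASSES)
        if unknown:
            raise ValueError(f"category {self.name!r}: unknown parameter classes {unknown}")


@dataclass(frozen=True)
class WeightingScheme:
    """An ordered set of scoring categories with per-class maximum scores."""

    categories: tuple[CategoryDefinition, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.categories]
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique within a scheme")

    def category(self, name: str) -> CategoryDefinition:
        for c in self.categories:
            if c.name == name:
                return c
        raise KeyError(f"unknown category {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.categories)

    def max_score(self, parameter_class: str) -> int:
        if parameter_class not in PARAMETER_CLASSES:
            raise ValueError(f"unknown parameter class {parameter_class!r}")
        return sum(c.points for c in self.categories if parameter_class in c.applicable_to)


@dataclass(frozen=True)
class StudyEvidence:
    """One previous study's standardized estimate for one model parameter."""

    study_id: str
    parameter_id: str
    estimate: float
    se: float
    flags: Mapping[str, bool] = field(default_factory=dict)
    kind: str = "empirical"  # {"meta-analysis", "empirical"}

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValueError(f"{self.study_id}/{self.parameter_id}: se must be > 0")

    @property
    def parameter_class(self) -> str:
        return parameter_class(self.parameter_id)


@dataclass(frozen=True)
class PowerPrior:
    """A study's contribution after variance inflation by its weight delta."""

    mean: float
    sd: float
    delta: float
    dialect: str
    source: str

    def density(self) -> NormalDensity:
        return NormalDensity(self.mean, self.sd)


class StudyExcludedError(ValueError):
    """Raised when a study scores 0: ignore its data completely (delta = 0)."""


def score_study(evidence: StudyEvidence, scheme: WeightingScheme) -> int:
    """Sum the points of every fulfilled, applicable category.

    Raises ``KeyError`` for a flag naming no scheme category and
    ``ValueError`` when a flag is set for a category that does not apply to
    the parameter's class (e.g. controlling for T1 symptoms on a T1->T2 path).
    """
    pclass = evidence.parameter_class
    score = 0
    for name, on in evidence.flags.items():
        cat = scheme.category(name)  # KeyError on unknown flag
        if not on:
            continue
        if pclass not in cat.applicable_to:
            raise ValueError(
                f"{evidence.study_id}: category {name!r} is not applicable to "
                f"{pclass} parameter {evidence.parameter_id!r}"
            )
        score += cat.points
    return score


def linear_delta(score: int, max_score: int) -> float:
    return score / max_score


def compute_delta(
    score: int,
    parameter_class: str,
    scheme: WeightingScheme,
    mapping: Callable[[int, int], float] = linear_delta,
) -> float:
    """Map a study score to its power-prior weight delta in (0, 1].

    The default mapping is linear: delta = score / max_score(class).  A score
    of 0 means the study's data are ignored completely; this is signalled by
    ``StudyExcludedError`` rather than delta = 0 (which would demand an
    infinite prior variance).
    """
    mx = scheme.max_score(parameter_class)
    if score == 0:
        raise StudyExcludedError("score 0: ignore the previous data completely")
    if not (0 < score <= mx):
        raise ValueError(f"score {score} outside (0, {mx}] for class {parameter_class}")
    delta = mapping(score, mx)
    if not (0 < delta <= 1):
        raise ValueError(f"delta mapping returned {delta}, outside (0, 1]")
    return delta


def build_power_prior(
    evidence: StudyEvidence, delta: float, dialect: str = "variance"
) -> PowerPrior:
    """Inflate a study's uncertainty by its weight delta.

    dialect "variance": sd = se / sqrt(delta) — dividing the study variance
    by delta, the exact power-prior identity for normal likelihoods.
    dialect "sd": sd = se / delta — delta divides the standard deviation.
    """
    if not (0 < delta <= 1):
        raise ValueError(f"delta must be in (0, 1], got {delta}")
    if dialect == "variance":
        sd = evidence.se / delta**0.5
    elif dialect == "sd":
        sd = evidence.se / delta
    else:
        raise ValueError(f"unknown dialect {dialect!r}; use 'variance' or 'sd'")
    return PowerPrior(
        mean=evidence.estimate, sd=sd, delta=delta, dialect=dialect, source=evidence.study_id
    )


def weigh_evidence(
    evidence: Iterable[StudyEvidence],
    scheme: WeightingScheme,
    dialect: str = "variance",
    mapping: Callable[[int, int], float] = linear_delta,
) -> dict[str, list[PowerPrior]]:
    """Score, weight, and inflate a batch of evidence, grouped by parameter.

    Studies scoring 0 are dropped with a warning instead of aborting the run.
    """
    out: dict[str, list[PowerPrior]] = {}
    for ev in evidence:
        score = score_study(ev, scheme)
        try:
            delta = compute_delta(score, ev.parameter_class, scheme, mapping)
        except StudyExcludedError:
            warnings.warn(
                f"study {ev.study_id!r} scored 0 for {ev.parameter_id!r}: excluded",
                stacklevel=2,
            )
            continue
        out.setdefault(ev.parameter_id, []).append(build_power_prior(ev, delta, dialect))
    return out


# ---------------------------------------------------------------- I/O helpers


def _scheme_from_mapping(doc: Mapping) -> WeightingScheme:
    cats = []
    for entry in doc["categories"]:
        applicable = entry.get("applicable_to")
        cats.append(
            CategoryDefinition(
                name=str(entry["name"]),
                points=int(entry["points"]),
                applicable_to=(
                    frozenset(applicable) if applicable else frozenset(PARAMETER_CLASSES)
                ),
                details=str(entry.get("details", "")),
            )
        )
    return WeightingScheme(tuple(cats))


def load_scheme(path: str | Path) -> WeightingScheme:
    """Load a weighting scheme from a YAML file (one entry per category)."""
    with open(path) as fh:
        return _scheme_from_mapping(yaml.safe_load(fh))


def default_scheme() -> WeightingScheme:
    """The packaged ten-category expert scheme (max 100 / 80 points)."""
    text = resources.files("priorpool.data").joinpath("weighting_scheme.yaml").read_text()
    return _scheme_from_mapping(yaml.safe_load(text))


def load_evidence(path: str | Path, scheme: WeightingScheme) -> list[StudyEvidence]:
    """Read evidence from CSV: study_id, parameter_id, estimate, se, kind,
    plus one 0/1 column per scheme category."""
    df = pd.read_csv(path)
    return evidence_from_frame(df, scheme)


def evidence_from_frame(df: pd.DataFrame, scheme: WeightingScheme) -> list[StudyEvidence]:
    required = {"study_id", "parameter_id", "estimate", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"evidence table missing columns: {sorted(missing)}")
    flag_cols = [c for c in df.columns if c in scheme.names]
    out = []
    for _, row in df.iterrows():
        flags = {c: bool(int(row[c])) for c in flag_cols if pd.notna(row[c])}
        out.append(
            StudyEvidence(
                study_id=str(row["study_id"]),
                parameter_id=str(row["parameter_id"]),
                estimate=float(row["estimate"]),
                se=float(row["se"]),
                flags=flags,
                kind=str(row.get("kind", "empirical")),
            )
        )
    return out


def evidence_to_frame(evidence: Iterable[StudyEvidence], scheme: WeightingScheme) -> pd.DataFrame:
    rows = []
    for ev in evidence:
        row = {
            "study_id": ev.study_id,
            "parameter_id": ev.parameter_id,
            "estimate": ev.estimate,
            "se": ev.se,
            "kind": ev.kind,
        }
        for name in scheme.names:
            row[name] = int(bool(ev.flags.get(name, False)))
        rows.append(row)
    return pd.DataFrame(rows)
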