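"""Convergence, contraction, and prior predictive diagnostics.

Implements the classic (non-rank-normalized) split-chain potential scale
reduction R-hat, autocorrelation-based effective sample size with Geyer's
initial-positive-sequence truncation, posterior shrinkage
s = 1 - posterior_variance / prior_variance, shortest highest-posterior-
density intervals from draws, Rubin's fraction of missing information, and
prior predictive simulation of the path models.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .densities import MixtureDensity, NormalDensity
from .gibbs import PosteriorDraws
from .pathmodel import PathModelSpec, PriorAssignment

__all__ = [
    "DegenerateDrawsError",
    "psr",
    "ess",
    "shrinkage",
    "hpd",
    "HPDInterval",
    "fmi",
    "prior_predictive",
    "PriorPredictiveSummary",
    "convergence_report",
    "shrinkage_report",
    "summary_table",
]

#: Convergence threshold surfaced in reports (stricter modern recommendation).
PSR_THRESHOLD = 1.01
#: Minimum recommended effective sample size for a stable estimate.
ESS_THRESHOLD = 400


class DegenerateDrawsError(ValueError):
    """Raised when draws carry no information (zero within-chain variance)."""


def _split_chains(chains: np.ndarray) -> np.ndarray:
    """Halve each chain (dropping the middle draw if odd length)."""
    chains = np.atleast_2d(np.asarray(chains, dtype=float))
    m, n = chains.shape
    half = n // 2
    first = chains[:, :half]
    second = chains[:, n - half:]
    return np.concatenate([first, second], axis=0)


def psr(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction R-hat.

    ``chains`` is (n_chains, n_draws); a single chain is split in half and
    treated as two.  R-hat = sqrt(V-hat / W), where W is the mean
    within-half variance and V-hat the weighted between+within estimate.
    """
    halves = _split_chains(chains)
    m, n = halves.shape
    if n < 2:
        raise ValueError("each half-chain needs at least 2 draws")
    W = float(halves.var(axis=1, ddof=1).mean())
    if W <= 0:
        raise DegenerateDrawsError("zero within-chain variance")
    B = n * float(halves.mean(axis=1).var(ddof=1))
    v_hat = (n - 1) / n * W + B / n
    return math.sqrt(v_hat / W)


def ess(draws: np.ndarray) -> float:
    """Effective sample size from multi-chain autocorrelations.

    ``draws`` is 1D (one chain) or (n_chains, n_draws).  Autocorrelations
    are combined across chains via the between/within variance decomposition
    and summed in Geyer pairs until the first non-positive pair (initial
    positive sequence).  The estimate is capped at the total draw count.
    """
    chains = np.atleast_2d(np.asarray(draws, dtype=float))
    m, n = chains.shape
    if m * n < 100:
        raise ValueError("need at least 100 draws for a meaningful ESS")
    W = float(chains.var(axis=1, ddof=1).mean())
    if W <= 0:
        raise DegenerateDrawsError("constant draws: ESS undefined")
    if m > 1:
        B = n * float(chains.mean(axis=1).var(ddof=1))
        var_plus = (n - 1) / n * W + B / n
    else:
        var_plus = float(chains.var(ddof=1))

    # Per-chain autocovariances via FFT.
    centered = chains - chains.mean(axis=1, keepdims=True)
    size = 2 ** int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(centered, n=size, axis=1)
    acov = np.fft.irfft(f * np.conj(f), n=size, axis=1)[:, :n].real / n
    mean_acov = acov.mean(axis=0)

    rho = 1.0 - (W - mean_acov) / var_plus
    rho[0] = 1.0
    # Geyer initial positive sequence over pairs (rho_{2k}, rho_{2k+1}).
    tau = 0.0
    t = 1
    while t + 1 < n:
        pair = rho[t] + rho[t + 1]
        if pair <= 0:
            break
        tau += pair
        t += 2
    total = m * n
    return float(min(total, total / (1.0 + 2.0 * tau)))


def shrinkage(prior_variance: float, posterior_variance: float) -> float:
    """Posterior contraction s = 1 - posterior_variance / prior_variance.

    Near 1 when the data dominate the prior, near 0 when the prior
    dominates; slightly negative values occur when the posterior is a touch
    wider than the prior (e.g. bimodal-prior artifacts).
    """
    if not prior_variance > 0:
        raise ValueError("prior variance must be > 0")
    if posterior_variance < 0:
        raise ValueError("posterior variance must be >= 0")
    return 1.0 - posterior_variance / prior_variance


@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def contains(self, x: float) -> bool:
        return self.lower <= x <= self.upper


def hpd(draws: np.ndarray, mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous interval containing ``mass`` of the draws.

    For unimodal posteriors this is the HPD interval; for multimodal draws
    use :func:`hpd_union`, which returns a union of intervals instead.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n < 100:
        raise ValueError("need at least 100 draws for an HPD interval")
    k = int(math.ceil(mass * n))
    widths = x[k - 1:] - x[: n - k + 1]
    i = int(np.argmin(widths))
    return HPDInterval(lower=float(x[i]), upper=float(x[i + k - 1]), mass=mass)


def hpd_union(draws: np.ndarray, mass: float = 0.95, bins: int = 512) -> list[HPDInterval]:
    """Highest-density region as a union of intervals (multimodal variant).

    Histogram-based: raises the density waterline until exactly ``mass`` of
    the draws sit in bins above it, then merges adjacent kept bins.
    Clearly labelled as an approximation for bimodal posteriors; the
    single-interval :func:`hpd` is the default reported everywhere.
    """
    if not 0 < mass < 1:
        raise ValueError("mass must be in (0, 1)")
    x = np.asarray(draws, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=bins)
    order = np.argsort(counts)[::-1]
    need = mass * len(x)
    got = 0.0
    keep = np.zeros(bins, dtype=bool)
    for b in order:
        keep[b] = True
        got += counts[b]
        if got >= need:
            break
    intervals = []
    start = None
    for b in range(bins):
        if keep[b] and start is None:
            start = b
        elif not keep[b] and start is not None:
            intervals.append(HPDInterval(float(edges[start]), float(edges[b]), mass))
            start = None
    if start is not None:
        intervals.append(HPDInterval(float(edges[start]), float(edges[bins]), mass))
    return intervals


def fmi(per_imputation_estimates: Sequence[tuple[float, float]]) -> float:
    """Rubin's fraction of missing information from m (mean, variance) pairs.

    T = U-bar + (1 + 1/m) B with B the between-imputation variance of the
    means and U-bar the mean within variance; fmi = (1 + 1/m) B / T.
    """
    pairs = list(per_imputation_estimates)
    m = len(pairs)
    if m < 2:
        raise ValueError("fmi needs at least 2 imputations")
    means = np.array([p[0] for p in pairs], dtype=float)
    withins = np.array([p[1] for p in pairs], dtype=float)
    B = float(means.var(ddof=1))
    U = float(withins.mean())
    T = U + (1.0 + 1.0 / m) * B
    if T <= 0:
        return 0.0
    return (1.0 + 1.0 / m) * B / T


# ------------------------------------------------------- prior predictive


@dataclass(frozen=True)
class PriorPredictiveSummary:
    """Per dependent variable: one (mean, sd) pair per prior draw."""

    pairs: Mapping[str, np.ndarray]  # each (n_draws, 2)
    observed: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.pairs.values())).shape[0]


def prior_predictive(
    spec: PathModelSpec,
    priors: PriorAssignment,
    n: int = 102,
    n_draws: int = 1_000,
    seed: int = 0,
    residual_sd: float = 1.0,
    observed: pd.DataFrame | None = None,
) -> PriorPredictiveSummary:
    """Simulate datasets from the prior and record predictive (mean, sd).

    For each of ``n_draws`` prior draws, every coefficient is sampled from
    its prior, a dataset of ``n`` dyads is simulated through the model's
    equations (exogenous T1 predictors standard normal, residual sd fixed
    at ``residual_sd`` on the standardized scale), and each dependent
    variable's sample mean and sd are recorded.  The cloud of pairs is the
    prior predictive distribution to overlay on the observed data.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    rng = np.random.default_rng(seed)
    responses = [eq.response for eq in spec.equations]
    exogenous = [v for v in spec.variables if v not in responses]
    pairs = {r: np.empty((n_draws, 2)) for r in responses}
    for d in range(n_draws):
        sim: dict[str, np.ndarray] = {v: rng.standard_normal(n) for v in exogenous}
        for eq in spec.equations:
            y = np.zeros(n)
            if spec.include_intercepts:
                y += priors.resolve(eq.intercept_name).rvs(1, rng)[0]
            for pred, cname in zip(eq.predictors, eq.coef_names):
                if pred not in sim:
                    raise ValueError(f"equation ordering: {pred} simulated after use")
                beta = priors.resolve(cname).rvs(1, rng)[0]
                y += beta * sim[pred]
            y += residual_sd * rng.standard_normal(n)
            sim[eq.response] = y
            pairs[eq.response][d, 0] = y.mean()
            pairs[eq.response][d, 1] = y.std(ddof=1)
    obs = {}
    if observed is not None:
        for r in responses:
            if r in observed.columns:
                obs[r] = (float(observed[r].mean()), float(observed[r].std(ddof=1)))
    return PriorPredictiveSummary(pairs=pairs, observed=obs)


def plot_prior_predictive(summary: PriorPredictiveSummary, path: str) -> None:
    """Scatter the predictive (mean, sd) clouds, one panel per variable."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(summary.pairs)
    fig, axes = plt.subplots(1, len(names), figsize=(4 * len(names), 3.5), squeeze=False)
    for ax, name in zip(axes[0], names):
        pts = summary.pairs[name]
        ax.scatter(pts[:, 0], pts[:, 1], s=4, alpha=0.4)
        if name in summary.observed:
            om, osd = summary.observed[name]
            ax.scatter([om], [osd], color="darkblue", s=30, zorder=3)
        ax.set_title(name)
        ax.set_xlabel("predicted mean")
        ax.set_ylabel("predicted sd")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# ----------------------------------------------------------------- reports


def convergence_report(
    draws: PosteriorDraws, parameters: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-parameter, per-imputation split-PSR and ESS table.

    PSR/ESS are computed within each imputed-dataset analysis over its
    chains (pooling chains across imputations would conflate
    between-imputation variability with non-convergence).
    """
    params = list(parameters or draws.parameters)
    rows = []
    for name in params:
        for m in range(draws.n_imputations):
            ch = draws.chains_of(name, m)
            rows.append(
                {
                    "parameter": name,
                    "imputation": m,
                    "psr": psr(ch),
                    "ess": ess(ch),
                }
            )
    df = pd.DataFrame(rows)
    df["psr_ok"] = df["psr"] <= PSR_THRESHOLD
    df["ess_ok"] = df["ess"] >= ESS_THRESHOLD
    return df


def shrinkage_report(
    draws: PosteriorDraws,
    priors: PriorAssignment,
    parameters: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-parameter prior variance, pooled posterior variance, and s.

    Mixture priors contribute their analytic mixture variance; such rows
    are flagged multimodal since a variance summary understates what a
    bimodal prior does to the posterior.
    """
    params = list(parameters or draws.parameters)
    rows = []
    for name in params:
        prior = priors.resolve(name)
        pv = prior.variance
        post = float(draws.pooled(name).var(ddof=1))
        rows.append(
            {
                "parameter": name,
                "prior_variance": pv,
                "posterior_variance": post,
                "shrinkage": shrinkage(pv, post),
                "multimodal_prior": isinstance(prior, MixtureDensity),
            }
        )
    return pd.DataFrame(rows)


def summary_table(
    draws: PosteriorDraws, parameters: Sequence[str] | None = None, mass: float = 0.95
) -> pd.DataFrame:
    """Posterior mean and HPD bounds per parameter (pooled over imputations)."""
    params = list(parameters or draws.parameters)
    rows = []
    for name in params:
        x = draws.pooled(name)
        iv = hpd(x, mass)
        rows.append(
            {
                "parameter": name,
                "mean": float(x.mean()),
                "hpd_lower": iv.lower,
                "hpd_upper": iv.upper,
                "excludes_zero": not iv.contains(0.0),
            }
        )
    return pd.DataFrame(rows)
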