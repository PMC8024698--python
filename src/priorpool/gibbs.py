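"""Gibbs estimation of the path models under normal and mixture priors.

Every full conditional in the model is conjugate, so the sampler needs no
tuning:

* each regression coefficient (and intercept), given everything else, has a
  normal likelihood term; combined with a normal prior this gives a normal
  full conditional.  Under a mixture (linear-pool) prior a latent component
  indicator is drawn first from its exact conditional — component weight
  times the marginal likelihood of the coefficient's conditional MLE — and
  the coefficient is then drawn from the selected component's conjugate
  normal.  No relabeling machinery is needed: the components are fixed
  densities, not estimated.
* the 2x2 residual covariance of the T2 behavior block has an
  inverse-Wishart conditional (prior IW(d+1, I)); the sampler draws its
  inverse (the precision) directly by the Bartlett decomposition.
* residual variances of the T3 equations have inverse-gamma conditionals
  (prior IG(0.01, 0.01), essentially flat on the standardized scale).

Equations are updated in declaration order within each sweep; chains are
independent streams spawned from one master seed, so runs are bit
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .densities import MixtureDensity, NormalDensity
from .pathmodel import Equation, MCMCConfig, PathModelSpec, PriorAssignment

__all__ = [
    "PosteriorDraws",
    "IndirectEffect",
    "fit_gibbs",
    "pool_imputations",
    "indirect_effects",
]

_IG_SHAPE = 0.01  # residual-variance prior IG(0.01, 0.01)
_IG_RATE = 0.01


@dataclass(frozen=True)
class PosteriorDraws:
    """Per-parameter draws indexed by (imputation, chain, kept iteration)."""

    draws: Mapping[str, np.ndarray]
    config: MCMCConfig
    spec_label: str = ""

    def __post_init__(self) -> None:
        for name, arr in self.draws.items():
            if arr.ndim != 3:
                raise ValueError(f"{name}: draws must be (imputations, chains, kept)")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name}: non-finite draws")

    @property
    def parameters(self) -> tuple[str, ...]:
        return tuple(self.draws.keys())

    @property
    def n_imputations(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def n_kept(self) -> int:
        return next(iter(self.draws.values())).shape[2]

    def pooled(self, name: str) -> np.ndarray:
        """All draws of one parameter concatenated across imputations/chains."""
        return np.asarray(self.draws[name]).reshape(-1)

    def chains_of(self, name: str, imputation: int) -> np.ndarray:
        """(chains, kept) array for one parameter in one imputation."""
        return np.asarray(self.draws[name][imputation])

    def to_frame(self) -> pd.DataFrame:
        """Long columnar form (parameter, imputation, chain, iteration, value)."""
        frames = []
        for name, arr in self.draws.items():
            m, c, k = arr.shape
            idx = np.indices((m, c, k))
            frames.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "imputation": idx[0].ravel(),
                        "chain": idx[1].ravel(),
                        "iteration": idx[2].ravel(),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @staticmethod
    def from_frame(df: pd.DataFrame, config: MCMCConfig | None = None) -> "PosteriorDraws":
        draws = {}
        for name, g in df.groupby("parameter", sort=False):
            m = int(g["imputation"].max()) + 1
            c = int(g["chain"].max()) + 1
            k = int(g["iteration"].max()) + 1
            arr = np.empty((m, c, k))
            arr[g["imputation"], g["chain"], g["iteration"]] = g["value"]
            draws[name] = arr
        if config is None:
            config = MCMCConfig(chains=max(2, c), iterations=k + 1, warmup=1)
        return PosteriorDraws(draws=draws, config=config)


# ------------------------------------------------------------ sampler core


def _prior_params(prior) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(weights, means, precisions) arrays; a plain normal is a 1-mixture."""
    if isinstance(prior, NormalDensity):
        return np.array([1.0]), np.array([prior.mean]), np.array([1.0 / prior.variance])
    if isinstance(prior, MixtureDensity):
        w = np.asarray(prior.weights)
        mu = np.array([c.mean for c in prior.components])
        tau = np.array([1.0 / c.variance for c in prior.components])
        return w, mu, tau
    raise TypeError(f"unresolved prior of type {type(prior).__name__}")


def _draw_coefficient(eta, lam_lik, w, mu, tau, rng) -> float:
    """Draw from the conjugate conditional of one scalar coefficient.

    The likelihood term is exp(eta*c - lam_lik*c^2/2); the prior is the
    (possibly 1-component) normal mixture (w, mu, 1/tau).
    """
    if len(w) == 1:
        lam = lam_lik + tau[0]
        mean = (eta + tau[0] * mu[0]) / lam
        return mean + rng.standard_normal() / math.sqrt(lam)
    # Latent component indicator: weight_m * N(b_lik; mu_m, 1/lam_lik + 1/tau_m).
    b_lik = eta / lam_lik
    var_m = 1.0 / lam_lik + 1.0 / tau
    logw = np.log(w) - 0.5 * np.log(var_m) - 0.5 * (b_lik - mu) ** 2 / var_m
    logw -= logw.max()
    p = np.exp(logw)
    p /= p.sum()
    m_idx = rng.choice(len(w), p=p)
    lam = lam_lik + tau[m_idx]
    mean = (eta + tau[m_idx] * mu[m_idx]) / lam
    return mean + rng.standard_normal() / math.sqrt(lam)


def _draw_wishart_bartlett(df: float, scale_chol: np.ndarray, rng) -> np.ndarray:
    """W ~ Wishart(df, S) with S = scale_chol @ scale_chol.T."""
    d = scale_chol.shape[0]
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = math.sqrt(rng.chisquare(df - i))
        for j in range(i):
            A[i, j] = rng.standard_normal()
    LA = scale_chol @ A
    return LA @ LA.T


class _EquationState:
    """Design columns and per-coefficient bookkeeping for one equation."""

    def __init__(self, eq: Equation, data: pd.DataFrame, include_intercept: bool):
        self.eq = eq
        n = len(data)
        self.y = data[eq.response].to_numpy(dtype=float)
        names = []
        cols = []
        if include_intercept:
            names.append(eq.intercept_name)
            cols.append(np.ones(n))
        for pred, cname in zip(eq.predictors, eq.coef_names):
            names.append(cname)
            cols.append(data[pred].to_numpy(dtype=float))
        self.names = names
        self.cols = cols
        self.xtx = [float(c @ c) for c in cols]
        self.beta = np.zeros(len(cols))


def _run_chain(
    data: pd.DataFrame,
    spec: PathModelSpec,
    priors: PriorAssignment,
    config: MCMCConfig,
    rng: np.random.Generator,
    fixed_residual_variance: Mapping[str, float] | None,
) -> dict[str, np.ndarray]:
    fixed = dict(fixed_residual_variance or {})
    n = len(data)

    block_responses = set().union(*spec.residual_blocks) if spec.residual_blocks else set()
    if fixed and (set(fixed) & block_responses):
        raise ValueError("cannot fix residual variance inside a correlated block")

    # Correlated blocks keep a joint residual matrix and precision Omega.
    blocks = []
    for blk in spec.residual_blocks:
        eqs = [_EquationState(spec.equation_for(r), data, spec.include_intercepts)
               for r in sorted(blk)]
        d = len(eqs)
        Y = np.column_stack([st.y for st in eqs])
        blocks.append({
            "eqs": eqs,
            "E": Y.copy(),          # residuals at beta = 0
            "omega": np.eye(d),
            "nu0": d + 1.0,
            "S0": np.eye(d),
        })
    singles = []
    for eq in spec.equations:
        if eq.response in block_responses:
            continue
        st = _EquationState(eq, data, spec.include_intercepts)
        singles.append({
            "st": st,
            "e": st.y.copy(),
            "sigma2": fixed.get(eq.response, 1.0),
            "fixed": eq.response in fixed,
        })

    prior_cache: dict[str, tuple] = {}

    def prior_of(name: str):
        if name not in prior_cache:
            prior_cache[name] = _prior_params(priors.resolve(name))
        return prior_cache[name]

    store: dict[str, list[float]] = {}
    for blk in blocks:
        for st in blk["eqs"]:
            for nm in st.names:
                store[nm] = []
        rs = [st.eq.response for st in blk["eqs"]]
        for i, ri in enumerate(rs):
            for j in range(i, len(rs)):
                store[f"resid_cov_{ri}_{rs[j]}"] = []
    for sng in singles:
        for nm in sng["st"].names:
            store[nm] = []
        store[f"resid_var_{sng['st'].eq.response}"] = []

    kept_from = config.warmup
    for it in range(config.iterations):
        for blk in blocks:
            omega = blk["omega"]
            E = blk["E"]
            for k, st in enumerate(blk["eqs"]):
                for j, nm in enumerate(st.names):
                    x = st.cols[j]
                    old = st.beta[j]
                    if old != 0.0:
                        E[:, k] += old * x
                    eta = float(x @ (E @ omega[:, k]))
                    lam_lik = omega[k, k] * st.xtx[j]
                    w, mu, tau = prior_of(nm)
                    new = _draw_coefficient(eta, lam_lik, w, mu, tau, rng)
                    st.beta[j] = new
                    E[:, k] -= new * x
            # Inverse-Wishart conditional: draw precision Omega directly.
            S_post = blk["S0"] + E.T @ E
            scale_chol = np.linalg.cholesky(np.linalg.inv(S_post))
            blk["omega"] = _draw_wishart_bartlett(blk["nu0"] + n, scale_chol, rng)
            if it >= kept_from:
                sigma = np.linalg.inv(blk["omega"])
                rs = [st.eq.response for st in blk["eqs"]]
                for i, ri in enumerate(rs):
                    for j in range(i, len(rs)):
                        store[f"resid_cov_{ri}_{rs[j]}"].append(sigma[i, j])
                for st in blk["eqs"]:
                    for j, nm in enumerate(st.names):
                        store[nm].append(st.beta[j])

        for sng in singles:
            st = sng["st"]
            e = sng["e"]
            inv_s2 = 1.0 / sng["sigma2"]
            for j, nm in enumerate(st.names):
                x = st.cols[j]
                old = st.beta[j]
                if old != 0.0:
                    e += old * x
                eta = inv_s2 * float(x @ e)
                lam_lik = inv_s2 * st.xtx[j]
                w, mu, tau = prior_of(nm)
                new = _draw_coefficient(eta, lam_lik, w, mu, tau, rng)
                st.beta[j] = new
                e -= new * x
            if not sng["fixed"]:
                a_post = _IG_SHAPE + 0.5 * n
                b_post = _IG_RATE + 0.5 * float(e @ e)
                sng["sigma2"] = b_post / rng.gamma(a_post)
            if it >= kept_from:
                for j, nm in enumerate(st.names):
                    store[nm].append(st.beta[j])
                store[f"resid_var_{st.eq.response}"].append(sng["sigma2"])

    return {nm: np.asarray(v) for nm, v in store.items()}


def fit_gibbs(
    datasets: pd.DataFrame | Sequence[pd.DataFrame],
    spec: PathModelSpec,
    priors: PriorAssignment,
    config: MCMCConfig = MCMCConfig(),
    seed: int = 0,
    fixed_residual_variance: Mapping[str, float] | None = None,
) -> PosteriorDraws:
    """Fit the path model on each completed dataset and pool the draws.

    ``datasets`` is one complete standardized DataFrame or a sequence of m
    imputed copies; each is analyzed separately (3 chains by default) and
    the per-imputation draws are concatenated by :func:`pool_imputations`.
    ``fixed_residual_variance`` pins named responses' residual variances
    (useful for conjugate closed-form checks).
    """
    if isinstance(datasets, pd.DataFrame):
        datasets = [datasets]
    datasets = list(datasets)
    if not datasets:
        raise ValueError("need at least one dataset")
    for df in datasets:
        missing_cols = set(spec.variables) - set(df.columns)
        if missing_cols:
            raise ValueError(f"dataset lacks model variables: {sorted(missing_cols)}")
        if df[list(spec.variables)].isna().any().any():
            raise ValueError("datasets must be complete; run imputation first")

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(datasets) * config.chains)
    per_imp: list[PosteriorDraws] = []
    for m, df in enumerate(datasets):
        chain_draws: list[dict[str, np.ndarray]] = []
        for c in range(config.chains):
            rng = np.random.default_rng(children[m * config.chains + c])
            chain_draws.append(
                _run_chain(df, spec, priors, config, rng, fixed_residual_variance)
            )
        stacked = {
            nm: np.stack([cd[nm] for cd in chain_draws])[np.newaxis]
            for nm in chain_draws[0]
        }
        per_imp.append(PosteriorDraws(draws=stacked, config=config, spec_label=spec.label))
    return pool_imputations(per_imp)


def pool_imputations(per_imputation_draws: Sequence[PosteriorDraws]) -> PosteriorDraws:
    """Concatenate per-imputation posterior draws along the imputation axis."""
    per = list(per_imputation_draws)
    if not per:
        raise ValueError("no draws to pool")
    names = set(per[0].parameters)
    for p in per[1:]:
        if set(p.parameters) != names:
            raise ValueError("mismatched parameter sets across imputations")
    draws = {
        nm: np.concatenate([np.asarray(p.draws[nm]) for p in per], axis=0)
        for nm in per[0].parameters
    }
    return PosteriorDraws(draws=draws, config=per[0].config, spec_label=per[0].spec_label)


# --------------------------------------------------------- indirect effects


@dataclass(frozen=True)
class IndirectEffect:
    """A mediated path: product of the T1->T2 and T2->T3 coefficients."""

    name: str
    a_path: str  # T1 predictor -> T2 mediator
    b_path: str  # T2 mediator -> T3 outcome
    draws: np.ndarray = field(repr=False)

    @property
    def mean(self) -> float:
        return float(self.draws.mean())

    def pooled(self) -> np.ndarray:
        return np.asarray(self.draws).reshape(-1)


def indirect_effects(draws: PosteriorDraws, spec: PathModelSpec) -> list[IndirectEffect]:
    """All 2 x 2 x 2 mediated paths of the model, computed draw-by-draw.

    The product is taken within the same (imputation, chain, iteration)
    triple, so each indirect-effect draw is a genuine posterior draw of the
    product.  Names follow the <outcome><mediator><predictor> convention,
    e.g. AintMPMint = MPonMint * AintonMP.
    """
    mediator_eqs = [eq for eq in spec.equations
                    if any(eq.response in blk for blk in spec.residual_blocks)]
    outcome_eqs = [eq for eq in spec.equations if eq not in mediator_eqs]
    if not mediator_eqs or not outcome_eqs:
        raise ValueError("spec has no mediator/outcome structure")

    out: list[IndirectEffect] = []
    for out_eq in outcome_eqs:
        outcome_tag = out_eq.response.rstrip("0123456789")  # Mint3 -> Mint
        for med_eq in mediator_eqs:
            med_tag = med_eq.response.rstrip("0123456789")  # MP2 -> MP
            b_name = f"{outcome_tag}on{med_tag}"
            for pred, a_name in zip(med_eq.predictors, med_eq.coef_names):
                pred_tag = pred.rstrip("0123456789")
                if a_name not in draws.draws:
                    raise KeyError(f"missing component path {a_name!r}")
                if b_name not in draws.draws:
                    raise KeyError(f"missing component path {b_name!r}")
                prod = np.asarray(draws.draws[a_name]) * np.asarray(draws.draws[b_name])
                out.append(
                    IndirectEffect(
                        name=f"{outcome_tag}{med_tag}{pred_tag}",
                        a_path=a_name,
                        b_path=b_name,
                        draws=prod,
                    )
                )
    return out
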