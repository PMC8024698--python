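"""Multiple imputation of dyad data under a joint multivariate normal.

Missing cells are filled by data augmentation: each sweep alternates
(i) drawing the joint mean and covariance from their posterior given the
currently completed data (Jeffreys prior: Sigma ~ IW(n-1, S),
mu | Sigma ~ N(y-bar, Sigma/n)) and (ii) drawing every incomplete row's
missing cells from their conditional normal given that row's observed
cells.  After a burn-in, the completed table is one imputation; the m
imputations come from independent seeded streams, so they are proper —
between-imputation variance reflects genuine uncertainty about the
missing values.

The composite scores are continuous, so a joint normal is an adequate
imputation model; the classic >0.10-correlation predictor-selection rule
is reported by :func:`select_predictors`, while the joint model simply
conditions on all columns (a superset of any such selection).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ImputationConfig", "ImputedDatasets", "impute", "select_predictors"]


@dataclass(frozen=True)
class ImputationConfig:
    m: int = 20
    burn_in: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.burn_in < 1:
            raise ValueError("burn_in must be >= 1")


@dataclass(frozen=True)
class ImputedDatasets:
    """m completed copies of one incomplete dataset."""

    datasets: tuple[pd.DataFrame, ...]
    missing_mask: pd.DataFrame = field(repr=False)
    config: ImputationConfig = ImputationConfig()

    @property
    def m(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets)

    def __getitem__(self, i: int) -> pd.DataFrame:
        return self.datasets[i]


def _draw_mu_sigma(X: np.ndarray, rng: np.random.Generator):
    """Posterior draw of (mu, Sigma) given complete data, Jeffreys prior."""
    n, p = X.shape
    xbar = X.mean(axis=0)
    S = (X - xbar).T @ (X - xbar)
    # Guard against numerically singular S at small n.
    S = S + 1e-8 * np.eye(p)
    sigma = stats.invwishart.rvs(df=n - 1, scale=S, random_state=rng)
    sigma = np.atleast_2d(sigma)
    mu = rng.multivariate_normal(xbar, sigma / n, method="cholesky")
    return mu, sigma


def _draw_missing_rows(
    X: np.ndarray, miss: np.ndarray, mu: np.ndarray, sigma: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Redraw missing cells row-wise from their conditional normals, in place."""
    patterns: dict[bytes, list[int]] = {}
    for i in np.flatnonzero(miss.any(axis=1)):
        patterns.setdefault(miss[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        mvec = np.frombuffer(key, dtype=bool)
        o = ~mvec
        S_oo = sigma[np.ix_(o, o)]
        S_mo = sigma[np.ix_(mvec, o)]
        S_mm = sigma[np.ix_(mvec, mvec)]
        solve = np.linalg.solve(S_oo, S_mo.T)  # (n_obs, n_miss)
        cond_cov = S_mm - S_mo @ solve
        cond_cov = (cond_cov + cond_cov.T) / 2 + 1e-10 * np.eye(int(mvec.sum()))
        L = np.linalg.cholesky(cond_cov)
        for i in rows:
            cond_mean = mu[mvec] + (X[i, o] - mu[o]) @ solve
            X[i, mvec] = cond_mean + L @ rng.standard_normal(int(mvec.sum()))


def impute(dataset: pd.DataFrame, config: ImputationConfig = ImputationConfig()) -> ImputedDatasets:
    """Produce m completed datasets; observed cells are never modified."""
    cols = list(dataset.columns)
    X0 = dataset[cols].to_numpy(dtype=float)
    miss = np.isnan(X0)
    n, p = X0.shape
    if p < 2 and miss.any():
        raise ValueError("need >= 2 columns to impute from a joint model")
    fully_missing = [c for c, bad in zip(cols, miss.all(axis=0)) if bad]
    if fully_missing:
        raise ValueError(f"columns fully missing, not estimable: {fully_missing}")
    if n - 1 <= p and miss.any():
        raise ValueError("too few rows to estimate the joint covariance")

    if not miss.any():
        copies = tuple(dataset.copy() for _ in range(config.m))
        return ImputedDatasets(
            datasets=copies,
            missing_mask=pd.DataFrame(miss, columns=cols, index=dataset.index),
            config=config,
        )

    col_means = np.nanmean(X0, axis=0)
    ss = np.random.SeedSequence(config.seed)
    streams = ss.spawn(config.m)
    completed = []
    for k in range(config.m):
        rng = np.random.default_rng(streams[k])
        X = X0.copy()
        X[miss] = np.take(col_means, np.where(miss)[1])
        for _ in range(config.burn_in):
            mu, sigma = _draw_mu_sigma(X, rng)
            _draw_missing_rows(X, miss, mu, sigma, rng)
        df = pd.DataFrame(X, columns=cols, index=dataset.index)
        completed.append(df)
    return ImputedDatasets(
        datasets=tuple(completed),
        missing_mask=pd.DataFrame(miss, columns=cols, index=dataset.index),
        config=config,
    )


def select_predictors(
    dataset: pd.DataFrame,
    threshold: float = 0.10,
    id_columns: Sequence[str] = (),
) -> dict[str, list[str]]:
    """For each incomplete variable, the others correlating beyond the
    threshold (pairwise-complete), excluding identifier columns.

    This is a selection *report*: the joint imputation model conditions on
    all variables regardless (a superset of any selection).  An empty
    selection is returned as such, with a warning that the imputation will
    fall back to using all variables.
    """
    candidates = [c for c in dataset.columns if c not in set(id_columns)]
    corr = dataset[candidates].corr()  # pairwise complete by default
    out: dict[str, list[str]] = {}
    for col in candidates:
        if not dataset[col].isna().any():
            continue
        others = [c for c in candidates if c != col]
        chosen = [c for c in others if abs(corr.loc[col, c]) > threshold]
        if not chosen:
            warnings.warn(
                f"no predictors beyond |r| > {threshold} for {col!r}; "
                "imputation falls back to all variables",
                stacklevel=2,
            )
        out[col] = chosen
    return out
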