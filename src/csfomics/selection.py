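"""Elastic-net prefiltering of high-dimensional feature blocks.

The +/-1-encoded outcome is regressed on standardized features under
the elastic-net penalty lambda * [(1-alpha)/2 ||b||^2 + alpha ||b||_1]
(squared-error loss).  The mixing parameter alpha and penalty lambda
are tuned jointly by stratified 7-fold cross-validated mean squared
error on the training data alone; the features with nonzero
coefficients at the optimum are returned.  Designed to run inside each
ensemble-validation iteration (training portion only), typically on the
protein block.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import ElasticNet

from .errors import DomainError
from .oplsda import encode_labels

logger = logging.getLogger(__name__)

# alpha=0 (pure ridge) is deliberately excluded: ridge produces no exact
# zeros, so "nonzero coefficient" selection semantics would break down
DEFAULT_ALPHA_GRID = (0.1, 0.3, 0.5, 0.7, 0.9, 1.0)


@dataclass
class ElasticNetConfig:
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-4
    n_folds: int = 7
    seed: int = 0
    max_iter: int = 5000

    def __post_init__(self) -> None:
        if len(self.alpha_grid) == 0:
            raise DomainError("alpha grid must be nonempty")
        if any(not 0.0 < a <= 1.0 for a in self.alpha_grid):
            raise DomainError("alpha values must be in (0, 1]; alpha=0 is excluded")
        if self.n_folds < 2:
            raise DomainError("need at least 2 CV folds")
        if self.n_lambda < 1 or self.lambda_min_ratio <= 0:
            raise DomainError("invalid lambda path parameters")


def _lambda_path(Xs: np.ndarray, yc: np.ndarray, alpha: float, cfg) -> np.ndarray:
    """Log-spaced path from lambda_max (all-zero solution) downward."""
    n = Xs.shape[0]
    lam_max = np.abs(Xs.T @ yc).max() / (n * alpha)
    lam_max = max(lam_max, 1e-12)
    return np.geomspace(lam_max, lam_max * cfg.lambda_min_ratio, cfg.n_lambda)


def _stratified_fold_ids(y01: np.ndarray, n_folds: int, rng) -> np.ndarray:
    fold_of = np.empty(len(y01), dtype=int)
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        fold_of[idx] = np.arange(len(idx)) % n_folds
    return fold_of


def elastic_net_select(
    X_train: pd.DataFrame, y_train, cfg: ElasticNetConfig | None = None
) -> list[str]:
    """Features with nonzero coefficients at the CV-optimal (alpha, lambda).

    Must be called on training data only; the caller is responsible for
    keeping test samples out.  May return an empty list when full
    shrinkage wins the cross-validation.
    """
    cfg = cfg or ElasticNetConfig()
    if isinstance(X_train, pd.DataFrame):
        Xm = X_train.to_numpy(dtype=float)
        feat_ids = list(X_train.columns)
    else:
        Xm = np.asarray(X_train, dtype=float)
        feat_ids = [f"x{j}" for j in range(Xm.shape[1])]
    if not np.isfinite(Xm).all():
        raise DomainError("non-finite values in feature matrix")
    ys = encode_labels(y_train)
    y01 = (ys > 0).astype(int)

    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (Xm - mu) / sd
    yc = ys - ys.mean()

    n_folds = min(cfg.n_folds, int(np.bincount(y01).min()))
    n_folds = max(n_folds, 2)
    rng = np.random.default_rng(cfg.seed)
    fold_of = _stratified_fold_ids(y01, n_folds, rng)

    best = None  # (cv_mse, alpha, lambda)
    for alpha in cfg.alpha_grid:
        lambdas = _lambda_path(Xs, yc, alpha, cfg)
        sse = np.zeros(len(lambdas))
        for f in range(n_folds):
            val = fold_of == f
            est = ElasticNet(
                alpha=1.0, l1_ratio=alpha, fit_intercept=False,
                warm_start=True, max_iter=cfg.max_iter, tol=1e-6,
            )
            for j, lam in enumerate(lambdas):  # warm-started path, high to low
                est.set_params(alpha=lam)
                est.fit(Xs[~val], yc[~val])
                pred = Xs[val] @ est.coef_
                sse[j] += float(((yc[val] - pred) ** 2).sum())
        mse = sse / len(yc)
        j_best = int(np.argmin(mse))
        if best is None or mse[j_best] < best[0]:
            best = (float(mse[j_best]), alpha, float(lambdas[j_best]))

    _, alpha, lam = best
    final = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                       max_iter=cfg.max_iter, tol=1e-6)
    final.fit(Xs, yc)
    selected = [feat_ids[j] for j in np.flatnonzero(final.coef_ != 0.0)]
    logger.debug("elastic net: alpha=%.2f lambda=%.4g -> %d features",
                 alpha, lam, len(selected))
    return selected


def make_selector(cfg: ElasticNetConfig | None = None, block_features=None):
    """Adapt :func:`elastic_net_select` to the ensemble selector hook.

    When ``block_features`` is given, the penalized selection is applied
    to those features only (e.g. the protein block) and every other
    feature passes through unfiltered, preserving input order.
    """
    cfg = cfg or ElasticNetConfig()

    def selector(X_train: pd.DataFrame, y_train, rng) -> list[str]:
        local = ElasticNetConfig(
            alpha_grid=cfg.alpha_grid, n_lambda=cfg.n_lambda,
            lambda_min_ratio=cfg.lambda_min_ratio, n_folds=cfg.n_folds,
            seed=int(rng.integers(2**31)), max_iter=cfg.max_iter,
        )
        if block_features is None:
            return elastic_net_select(X_train, y_train, local)
        penalized = [c for c in X_train.columns if c in set(block_features)]
        keep = set(elastic_net_select(X_train[penalized], y_train, local))
        return [c for c in X_train.columns if c not in set(penalized) or c in keep]

    return selector
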