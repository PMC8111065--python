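"""External validation by repeated resampling and permutation testing.

Small-cohort classifiers can reach high apparent accuracy by chance, so
every model here is judged against an ensemble of label-permuted
controls.  Per iteration: the classes are balanced by random
undersampling of the majority class, the balanced set is split into
stratified 90% training / 10% test portions, an optional feature
selector is applied to the training portion only, an OPLS-DA model is
fit and evaluated on the held-out samples.  Repeating this (1000 times
by default) yields an ensemble of test accuracies that is compared with
the permuted-label ensemble through a two-sided two-sample
Kolmogorov-Smirnov test; the expected permuted accuracy for a two-class
problem is 50%.

Feature importance is reported as the mean decrease in held-out
accuracy when the feature is removed and the model refit on the same
split (a removal importance, distinct from the classical projection VIP
in :mod:`csfomics.oplsda`).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateLabelError, DomainError
from .oplsda import fit_oplsda, predict

logger = logging.getLogger(__name__)

Selector = Callable[[pd.DataFrame, np.ndarray, np.random.Generator], list[str]]


@dataclass
class EnsembleConfig:
    """Parameters of the resampling validation engine."""

    n_iter: int = 1000
    test_fraction: float = 0.10
    n_perm: int = 1000
    selector: Selector | None = None
    seed: int = 0
    alpha_sig: float = 0.05
    n_orth: int = 1
    scale: str = "uv"
    compute_importance: bool = False
    compute_q2: bool = True
    max_skip_fraction: float = 0.05
    mode: str = "resample"  # "resample" (repeated 90/10) or "kfold" (repeated 10-fold)

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 0.5:
            raise DomainError("test_fraction must be in (0, 0.5)")
        if self.n_iter < 1 or self.n_perm < 1:
            raise DomainError("iteration counts must be >= 1")
        if self.mode not in ("resample", "kfold"):
            raise DomainError("mode must be 'resample' or 'kfold'")


@dataclass
class EnsembleResult:
    """Per-iteration metrics, pooled held-out scores and importance table."""

    accuracies: np.ndarray
    sensitivities: np.ndarray
    specificities: np.ndarray
    r2y: np.ndarray
    q2: np.ndarray
    selected_sets: list[tuple[str, ...]]
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    n_skipped: int = 0
    perm_accuracies: np.ndarray | None = None
    ks_d: float = float("nan")
    ks_p: float = float("nan")
    importance: pd.DataFrame | None = None

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())

    def pooled_auc(self) -> float:
        from sklearn.metrics import roc_auc_score

        if len(self.pooled_scores) == 0 or len(set(self.pooled_labels)) < 2:
            return float("nan")
        return float(roc_auc_score(self.pooled_labels, self.pooled_scores))

    def summary(self) -> dict:
        def safe_mean(a):
            return float(np.nanmean(a)) if len(a) else float("nan")

        out = {
            "n_iter": int(len(self.accuracies)),
            "n_skipped": int(self.n_skipped),
            "mean_accuracy": safe_mean(self.accuracies),
            "mean_sensitivity": safe_mean(self.sensitivities),
            "mean_specificity": safe_mean(self.specificities),
            "mean_r2y": safe_mean(self.r2y),
            "mean_q2": safe_mean(self.q2),
            "pooled_auc": self.pooled_auc(),
            "ks_d": self.ks_d,
            "ks_p": self.ks_p,
        }
        if self.perm_accuracies is not None:
            out["mean_perm_accuracy"] = float(self.perm_accuracies.mean())
        return out

    def to_json(self, path) -> None:
        doc = {"summary": self.summary()}
        if self.importance is not None:
            doc["importance"] = self.importance.reset_index().to_dict(orient="records")
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=2, default=float)

    def iterations_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accuracy": self.accuracies,
                "sensitivity": self.sensitivities,
                "specificity": self.specificities,
                "r2y": self.r2y,
                "q2": self.q2,
            }
        )


def balance_classes(X: pd.DataFrame, y, rng_or_seed) -> tuple[pd.DataFrame, np.ndarray]:
    """Randomly undersample the majority class to the minority count."""
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    y = np.asarray(y, dtype=int)
    n1, n0 = int((y == 1).sum()), int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise DegenerateLabelError("both classes must be present")
    if n1 == n0:
        return X, y
    minority = 1 if n1 < n0 else 0
    majority = 1 - minority
    keep_maj = rng.choice(
        np.flatnonzero(y == majority), size=min(n1, n0), replace=False
    )
    keep = np.sort(np.concatenate([np.flatnonzero(y == minority), keep_maj]))
    return X.iloc[keep], y[keep]


def _stratified_split(y: np.ndarray, test_fraction: float, rng):
    """Per-class held-out indices: max(1, round(f * n_class)) samples."""
    test_idx = []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        n_test = max(1, round(test_fraction * len(idx)))
        test_idx.append(rng.choice(idx, size=n_test, replace=False))
    test = np.sort(np.concatenate(test_idx))
    train = np.setdiff1d(np.arange(len(y)), test)
    return train, test


def _evaluate_split(Xb, yb, train, test, cols, cfg, rng):
    """Fit on the training portion, return metrics + held-out scores.

    The orthogonal-component count is clipped to the feature budget: a
    panel of p variables supports at most p-1 orthogonal components
    (a single-variable model is plain PLS-DA).
    """
    model = fit_oplsda(
        Xb.iloc[train][cols],
        yb[train],
        n_orth=min(cfg.n_orth, len(cols) - 1),
        scale=cfg.scale,
        seed=int(rng.integers(2**31)),
        compute_q2=cfg.compute_q2,
    )
    scores, calls = predict(model, Xb.iloc[test][cols])
    truth = yb[test]
    acc = float((calls == truth).mean())
    sens = float((calls[truth == 1] == 1).mean()) if (truth == 1).any() else float("nan")
    spec = float((calls[truth == 0] == 0).mean()) if (truth == 0).any() else float("nan")
    return model, scores, acc, sens, spec


def run_ensemble(
    X: pd.DataFrame, y, cfg: EnsembleConfig, permute: bool = False
) -> EnsembleResult:
    """Repeated balance / split / (select) / fit / test cycle.

    With ``permute=True`` the labels are freshly permuted before each
    iteration, producing the chance-level control ensemble.
    """
    if isinstance(X, pd.DataFrame):
        Xf = X
    else:
        Xf = pd.DataFrame(np.asarray(X, dtype=float))
        Xf.columns = [f"x{j}" for j in range(Xf.shape[1])]
    y = np.asarray(y, dtype=int)
    n_iter = cfg.n_perm if permute else cfg.n_iter
    streams = np.random.SeedSequence(cfg.seed).spawn(n_iter)

    accs, senss, specs, r2s, q2s = [], [], [], [], []
    selected_sets: list[tuple[str, ...]] = []
    pooled_scores, pooled_labels = [], []
    imp_drop: dict[str, list[float]] = {}
    imp_count: dict[str, int] = {}
    n_skipped = 0

    fold_cycle = None
    if cfg.mode == "kfold":
        fold_cycle = max(2, round(1.0 / cfg.test_fraction))

    for i in range(n_iter):
        rng = np.random.default_rng(streams[i])
        yi = rng.permutation(y) if permute else y
        Xb, yb = balance_classes(Xf, yi, rng)
        if cfg.mode == "kfold":
            # repeated k-fold: each iteration consumes one fold of a
            # shuffled partition regenerated every k iterations
            k = i % fold_cycle
            fold_rng = np.random.default_rng(streams[i - k])
            folds = _kfold_partition(yb, fold_cycle, fold_rng)
            test = folds[k]
            train = np.setdiff1d(np.arange(len(yb)), test)
        else:
            train, test = _stratified_split(yb, cfg.test_fraction, rng)

        cols = list(Xb.columns)
        if cfg.selector is not None:
            cols = list(cfg.selector(Xb.iloc[train], yb[train], rng))
            if len(cols) == 0:
                n_skipped += 1
                logger.warning("iteration %d: selector returned no features; skipped", i)
                continue
        try:
            model, scores, acc, sens, spec = _evaluate_split(
                Xb, yb, train, test, cols, cfg, rng
            )
        except DomainError as exc:
            n_skipped += 1
            logger.warning("iteration %d skipped: %s", i, exc)
            continue

        accs.append(acc)
        senss.append(sens)
        specs.append(spec)
        r2s.append(model.r2y)
        q2s.append(model.q2)
        selected_sets.append(tuple(cols))
        pooled_scores.append(scores)
        pooled_labels.append(yb[test])

        if cfg.compute_importance:
            # removal refits only need held-out accuracy, not Q2
            imp_cfg = replace(cfg, compute_q2=False)
            fitted = list(model.feature_ids)
            for feat in fitted:
                imp_count[feat] = imp_count.get(feat, 0) + 1
                if len(fitted) < 2:
                    continue
                reduced = [c for c in fitted if c != feat]
                try:
                    _, _, acc_red, _, _ = _evaluate_split(
                        Xb, yb, train, test, reduced, imp_cfg, rng
                    )
                except DomainError:
                    continue
                imp_drop.setdefault(feat, []).append(acc - acc_red)

    if n_skipped > cfg.max_skip_fraction * n_iter:
        raise RuntimeError(
            f"{n_skipped}/{n_iter} iterations skipped "
            f"(> {cfg.max_skip_fraction:.0%} cap); results would be biased"
        )

    importance = None
    if cfg.compute_importance:
        rows = [
            (
                feat,
                float(np.mean(imp_drop.get(feat, [0.0]))),
                imp_count.get(feat, 0) / max(1, len(accs)),
            )
            for feat in sorted(imp_count)
        ]
        importance = (
            pd.DataFrame(rows, columns=["feature_id", "mean_decrease_accuracy",
                                        "selection_frequency"])
            .set_index("feature_id")
            .sort_values("mean_decrease_accuracy", ascending=False)
        )

    return EnsembleResult(
        accuracies=np.asarray(accs),
        sensitivities=np.asarray(senss),
        specificities=np.asarray(specs),
        r2y=np.asarray(r2s),
        q2=np.asarray(q2s),
        selected_sets=selected_sets,
        pooled_scores=np.concatenate(pooled_scores) if pooled_scores else np.array([]),
        pooled_labels=np.concatenate(pooled_labels) if pooled_labels else np.array([]),
        n_skipped=n_skipped,
        importance=importance,
    )


def _kfold_partition(y: np.ndarray, k: int, rng) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for j, s in enumerate(idx):
            folds[j % k].append(s)
    return [np.array(sorted(f)) for f in folds]


def permutation_null(X, y, cfg: EnsembleConfig) -> np.ndarray:
    """Held-out accuracies of the label-permuted control ensemble."""
    return run_ensemble(X, y, cfg, permute=True).accuracies


def ks_compare(acc_real, acc_perm) -> tuple[float, float]:
    """Two-sided two-sample KS statistic and asymptotic p-value."""
    acc_real = np.asarray(acc_real, dtype=float)
    acc_perm = np.asarray(acc_perm, dtype=float)
    if len(acc_real) == 0 or len(acc_perm) == 0:
        raise DomainError("KS comparison requires nonempty samples")
    res = stats.ks_2samp(acc_real, acc_perm, alternative="two-sided", method="asymp")
    return float(res.statistic), float(min(1.0, res.pvalue))


def validate_model(X, y, cfg: EnsembleConfig) -> EnsembleResult:
    """Full validation: real ensemble, permuted ensemble, KS comparison.

    When a per-iteration selector leaves one of the ensembles without
    surviving iterations (no feature ever selected — no evidence of
    signal), the comparison is vacuous and reported as non-significant.
    """
    result = run_ensemble(X, y, cfg)
    result.perm_accuracies = permutation_null(X, y, cfg)
    if len(result.accuracies) == 0 or len(result.perm_accuracies) == 0:
        logger.warning("no surviving iterations in one ensemble; "
                       "KS comparison is vacuous")
        result.ks_d, result.ks_p = 0.0, 1.0
    else:
        result.ks_d, result.ks_p = ks_compare(result.accuracies,
                                              result.perm_accuracies)
    return result
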