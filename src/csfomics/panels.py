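"""Exhaustive 1-to-6-variable multi-omics panel search.

Every combination of candidate variables (panel sizes ``k_min`` to
``k_max``) is pushed through the ensemble OPLS-DA validator and scored
by the ROC AUC of its pooled held-out scores, then ensemble mean
accuracy, sensitivity, specificity, and finally smaller size.  All
panels share the same resampling seed, so comparisons between panels
are paired.  When the enumeration exceeds the evaluation budget a
greedy beam search takes over (logged prominently).  A stopping rule
reports the smallest panel size beyond which neither AUC nor accuracy
improves by more than a configurable margin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .ensemble import EnsembleConfig, run_ensemble
from .errors import DomainError, SchemaError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PanelResult:
    features: tuple[str, ...]
    auc: float
    accuracy: float
    sensitivity: float
    specificity: float
    n_iter_used: int

    @property
    def size(self) -> int:
        return len(self.features)

    def sort_key(self) -> tuple:
        return (self.auc, self.accuracy, self.sensitivity, self.specificity,
                -self.size)


def _evaluate_panel(X, y, features, cfg: EnsembleConfig) -> PanelResult:
    res = run_ensemble(X[list(features)], y, cfg)
    return PanelResult(
        features=tuple(features),
        auc=res.pooled_auc(),
        accuracy=float(res.accuracies.mean()),
        sensitivity=float(np.nanmean(res.sensitivities)),
        specificity=float(np.nanmean(res.specificities)),
        n_iter_used=len(res.accuracies),
    )


def search_panels(
    X: pd.DataFrame,
    y,
    candidates: list[str],
    k_min: int = 1,
    k_max: int = 6,
    cfg: EnsembleConfig | None = None,
    budget: int = 20000,
    beam_width: int = 10,
) -> list[PanelResult]:
    """Ranked panel evaluations over all 1..k_max variable combinations.

    Exhaustive while the total combination count fits the ``budget``;
    otherwise a beam search of width ``beam_width`` extends the best
    panels of each size.  The returned list is sorted best-first.
    """
    cfg = cfg or EnsembleConfig(n_iter=100, n_perm=1)
    candidates = list(dict.fromkeys(candidates))  # dedupe, keep order
    missing = set(candidates) - set(X.columns)
    if missing:
        raise SchemaError(f"candidates absent from matrix: {sorted(missing)[:5]}")
    if not candidates:
        raise DomainError("no candidate features")
    if k_max > len(candidates):
        logger.warning("k_max=%d clipped to %d candidates", k_max, len(candidates))
        k_max = len(candidates)
    if k_min < 1 or k_min > k_max:
        raise DomainError("need 1 <= k_min <= k_max")
    if budget < len(candidates):
        raise DomainError("budget must cover at least the single-variable panels")

    # candidate order must not influence results: evaluate in sorted order
    ordered = sorted(candidates)
    total = sum(comb(len(ordered), k) for k in range(k_min, k_max + 1))
    exhaustive = total <= budget
    if not exhaustive:
        logger.warning(
            "PANEL SEARCH IN BEAM MODE: %d combinations exceed budget %d; "
            "greedy beam of width %d — ranking is approximate", total, budget,
            beam_width,
        )

    results: list[PanelResult] = []
    if exhaustive:
        for k in range(k_min, k_max + 1):
            for feats in combinations(ordered, k):
                results.append(_evaluate_panel(X, y, feats, cfg))
    else:
        frontier = [
            _evaluate_panel(X, y, (f,), cfg) for f in ordered
        ]
        results.extend(r for r in frontier if r.size >= k_min)
        seen = {frozenset(r.features) for r in frontier}
        for k in range(2, k_max + 1):
            frontier = sorted(frontier, key=PanelResult.sort_key, reverse=True)
            frontier = frontier[:beam_width]
            nxt = []
            for base in frontier:
                for f in ordered:
                    if f in base.features:
                        continue
                    feats = frozenset(base.features) | {f}
                    if feats in seen:
                        continue
                    seen.add(feats)
                    nxt.append(_evaluate_panel(X, y, tuple(sorted(feats)), cfg))
            if not nxt:
                break
            results.extend(r for r in nxt if r.size >= k_min)
            frontier = nxt

    results.sort(key=PanelResult.sort_key, reverse=True)
    return results


def best_by_size(results: list[PanelResult]) -> dict[int, PanelResult]:
    """Best-ranked panel per size."""
    out: dict[int, PanelResult] = {}
    for r in sorted(results, key=PanelResult.sort_key, reverse=True):
        out.setdefault(r.size, r)
    return dict(sorted(out.items()))


def stopping_check(results_by_k: dict[int, PanelResult], margin: float = 0.01) -> int:
    """Smallest size k whose successor improves neither AUC nor accuracy.

    A size k is accepted when the best (k+1)-panel exceeds the best
    k-panel by at most ``margin`` in both AUC and accuracy; if
    improvement persists through every consecutive pair, the largest
    size present is returned.
    """
    sizes = sorted(results_by_k)
    if not sizes:
        raise DomainError("no panel results")
    for k in sizes[:-1]:
        if k + 1 not in results_by_k:
            raise DomainError(f"missing results for consecutive size {k + 1}")
        cur, nxt = results_by_k[k], results_by_k[k + 1]
        if (nxt.auc - cur.auc) <= margin and (nxt.accuracy - cur.accuracy) <= margin:
            return k
    return sizes[-1]


def panels_frame(results: list[PanelResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "features": ["+".join(r.features) for r in results],
            "size": [r.size for r in results],
            "auc": [r.auc for r in results],
            "accuracy": [r.accuracy for r in results],
            "sensitivity": [r.sensitivity for r in results],
            "specificity": [r.specificity for r in results],
            "n_iter_used": [r.n_iter_used for r in results],
        }
    )
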