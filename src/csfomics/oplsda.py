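"""Orthogonal partial least squares discriminant analysis (OPLS-DA).

A NIPALS orthogonal-signal-correction implementation for two-class
problems: the outcome is encoded +/-1, the matrix is centered and (by
default) unit-variance scaled, ``n_orth`` components of class-orthogonal
variation are extracted and removed, and a single predictive component
is fit on the deflated matrix.  Goodness of fit is reported as R2Y on
the training data and goodness of prediction as Q2 = 1 - PRESS/TSS from
an internal stratified 7-fold cross-validation.

Variable importance in projection (VIP) follows the classical
projection definition (mean squared VIP over features equals 1); the
removal-based mean-decrease-in-accuracy importance lives in
:mod:`csfomics.ensemble` and reports label which is which.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateLabelError, DomainError, RankError, SchemaError

logger = logging.getLogger(__name__)

SCALINGS = ("uv", "pareto", "none")


@dataclass
class TrainedModel:
    """A fitted two-class OPLS-DA model.

    Scores are on the +/-1 outcome scale; a sample is called a converter
    when its predicted score is >= ``class_threshold`` (default 0, ties
    assigned to the positive class).
    """

    feature_ids: list[str]
    center: np.ndarray
    scale: np.ndarray
    w: np.ndarray            # predictive weights, unit norm
    p: np.ndarray            # predictive loading
    t: np.ndarray            # training predictive scores
    w_orth: np.ndarray       # (n_orth, p)
    p_orth: np.ndarray       # (n_orth, p)
    t_orth: np.ndarray       # (n_orth, n)
    b: float                 # regression of encoded outcome on t
    y_mean: float
    n_orth: int
    r2y: float
    q2: float = float("nan")
    class_threshold: float = 0.0
    scaling: str = "uv"
    dropped_features: list[str] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        doc = {
            "feature_ids": self.feature_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "t": self.t.tolist(),
            "w_orth": self.w_orth.tolist(),
            "p_orth": self.p_orth.tolist(),
            "t_orth": self.t_orth.tolist(),
            "b": self.b,
            "y_mean": self.y_mean,
            "n_orth": self.n_orth,
            "r2y": self.r2y,
            "q2": self.q2,
            "class_threshold": self.class_threshold,
            "scaling": self.scaling,
            "dropped_features": self.dropped_features,
        }
        text = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "TrainedModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        arrays = {
            k: np.asarray(doc[k], dtype=float)
            for k in ("center", "scale", "w", "p", "t", "w_orth", "p_orth", "t_orth")
        }
        # empty orthogonal blocks lose their 2D shape through JSON
        p = len(doc["feature_ids"])
        for k, width in (("w_orth", p), ("p_orth", p), ("t_orth", len(doc["t"]))):
            if arrays[k].size == 0:
                arrays[k] = arrays[k].reshape(0, width)
        return cls(
            feature_ids=list(doc["feature_ids"]),
            b=float(doc["b"]),
            y_mean=float(doc["y_mean"]),
            n_orth=int(doc["n_orth"]),
            r2y=float(doc["r2y"]),
            q2=float(doc["q2"]),
            class_threshold=float(doc["class_threshold"]),
            scaling=doc["scaling"],
            dropped_features=list(doc["dropped_features"]),
            **arrays,
        )


def encode_labels(y) -> np.ndarray:
    """Map binary labels to +/-1 (1 -> +1, 0 -> -1); pass +/-1 through."""
    y = np.asarray(y, dtype=float)
    vals = set(np.unique(y))
    if vals <= {0.0, 1.0}:
        y = 2.0 * y - 1.0
    elif not vals <= {-1.0, 1.0}:
        raise DomainError(f"labels must be binary, got values {sorted(vals)}")
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("both classes required")
    return y


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), list(X.columns)
    X = np.asarray(X, dtype=float)
    return X, [f"x{j}" for j in range(X.shape[1])]


def _fit_core(Xm, yc, n_orth):
    """NIPALS-OSC: extract n_orth orthogonal components then one predictive."""
    n, p = Xm.shape
    if n_orth >= min(n - 1, p):
        raise RankError(
            f"{n_orth} orthogonal components exceed rank budget of {n}x{p} data"
        )
    Xd = Xm.copy()
    W_o, P_o, T_o = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw < 1e-12:
            raise RankError("y-predictive direction vanished during deflation")
        w /= nw
        t = Xd @ w
        p_load = Xd.T @ t / (t @ t)
        w_o = p_load - (w @ p_load) * w
        n_wo = np.linalg.norm(w_o)
        if n_wo < 1e-12:
            raise RankError("no class-orthogonal variation left to remove")
        w_o /= n_wo
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        W_o.append(w_o)
        P_o.append(p_o)
        T_o.append(t_o)
    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw < 1e-12:
        raise RankError("predictive direction vanished")
    w /= nw
    t = Xd @ w
    p_load = Xd.T @ t / (t @ t)
    b = (t @ yc) / (t @ t)
    shape = (len(W_o), p)
    return (
        w,
        p_load,
        t,
        np.array(W_o).reshape(shape),
        np.array(P_o).reshape(shape),
        np.array(T_o).reshape((len(T_o), n)),
        float(b),
    )


def _stratified_folds(y01: np.ndarray, n_folds: int, rng) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        for i, s in enumerate(idx):
            folds[i % n_folds].append(s)
    return [np.array(sorted(f)) for f in folds]


def fit_oplsda(
    X,
    y,
    n_orth: int = 1,
    scale: str = "uv",
    q2_folds: int = 7,
    seed: int = 0,
    compute_q2: bool = True,
) -> TrainedModel:
    """Fit OPLS-DA on training data.

    Parameters
    ----------
    X : DataFrame or array, samples x features
    y : binary labels (0/1 or -1/+1)
    n_orth : number of class-orthogonal components removed before the
        single predictive component (default 1).
    scale : "uv" (unit variance), "pareto" (sqrt SD) or "none";
        centering always applied.  Constant features are dropped with a
        logged warning under "uv" and "pareto".
    q2_folds : internal stratified CV folds for Q2 (default 7, reduced
        to the minority-class count when necessary).
    """
    if scale not in SCALINGS:
        raise DomainError(f"scale must be one of {SCALINGS}")
    Xm, feat_ids = _as_matrix(X)
    ys = encode_labels(y)
    if min((ys == 1).sum(), (ys == -1).sum()) < 2:
        raise DegenerateLabelError("need at least 2 samples per class")

    sd = Xm.std(axis=0, ddof=1)
    dropped: list[str] = []
    if scale in ("uv", "pareto"):
        const = sd == 0
        if const.any():
            dropped = [feat_ids[j] for j in np.flatnonzero(const)]
            logger.warning("dropping %d constant feature(s): %s",
                           len(dropped), dropped[:5])
            keep = ~const
            Xm = Xm[:, keep]
            feat_ids = [f for f, k in zip(feat_ids, keep) if k]
            sd = sd[keep]
    if Xm.shape[1] == 0:
        raise DomainError("no non-constant features left to fit")

    center = Xm.mean(axis=0)
    if scale == "uv":
        scale_vec = sd.copy()
    elif scale == "pareto":
        scale_vec = np.sqrt(sd)
    else:
        scale_vec = np.ones(Xm.shape[1])
    scale_vec[scale_vec == 0] = 1.0
    Xs = (Xm - center) / scale_vec

    y_mean = float(ys.mean())
    yc = ys - y_mean
    w, p_load, t, W_o, P_o, T_o, b = _fit_core(Xs, yc, n_orth)

    resid = yc - b * t
    r2y = float(1.0 - (resid @ resid) / (yc @ yc))

    model = TrainedModel(
        feature_ids=feat_ids,
        center=center,
        scale=scale_vec,
        w=w,
        p=p_load,
        t=t,
        w_orth=W_o,
        p_orth=P_o,
        t_orth=T_o,
        b=b,
        y_mean=y_mean,
        n_orth=n_orth,
        r2y=r2y,
        scaling=scale,
        dropped_features=dropped,
    )

    if compute_q2:
        y01 = (ys > 0).astype(int)
        n_folds = min(q2_folds, int(np.bincount(y01).min()))
        rng = np.random.default_rng(seed)
        press = 0.0
        Xf = pd.DataFrame(Xm, columns=feat_ids)
        for fold in _stratified_folds(y01, n_folds, rng):
            mask = np.ones(len(ys), dtype=bool)
            mask[fold] = False
            sub = fit_oplsda(
                Xf.iloc[mask], ys[mask], n_orth=n_orth, scale=scale,
                compute_q2=False,
            )
            scores, _ = predict(sub, Xf.iloc[fold])
            press += float(((ys[fold] - scores) ** 2).sum())
        tss = float(((ys - ys.mean()) ** 2).sum())
        model.q2 = 1.0 - press / tss
    return model


def predict(m: TrainedModel, Xnew) -> tuple[np.ndarray, np.ndarray]:
    """Predicted scores (on the +/-1 scale) and 0/1 class calls."""
    t, _ = transform(m, Xnew)
    scores = m.b * t + m.y_mean
    labels = (scores >= m.class_threshold).astype(int)
    return scores, labels


def transform(m: TrainedModel, Xnew) -> tuple[np.ndarray, np.ndarray]:
    """Predictive score t and orthogonal scores for new samples."""
    if isinstance(Xnew, pd.DataFrame):
        missing = set(m.feature_ids) - set(Xnew.columns)
        if missing:
            raise SchemaError(f"prediction input lacks features: {sorted(missing)[:5]}")
        Xm = Xnew[m.feature_ids].to_numpy(dtype=float)
    else:
        Xm = np.asarray(Xnew, dtype=float)
        if Xm.ndim == 1:
            Xm = Xm[None, :]
        if Xm.shape[1] != len(m.feature_ids):
            raise SchemaError(
                f"expected {len(m.feature_ids)} features, got {Xm.shape[1]}"
            )
    Xd = (Xm - m.center) / m.scale
    T_o = np.empty((m.w_orth.shape[0], Xd.shape[0]))
    for k in range(m.w_orth.shape[0]):
        t_o = Xd @ m.w_orth[k]
        Xd = Xd - np.outer(t_o, m.p_orth[k])
        T_o[k] = t_o
    t = Xd @ m.w
    return t, T_o


def vip(m: TrainedModel) -> pd.DataFrame:
    """Classical projection VIP for the single predictive component.

    With unit-norm weights, VIP_j = sqrt(p) * |w_j|, so the mean squared
    VIP over features is exactly 1.
    """
    p = len(m.feature_ids)
    v = np.sqrt(p) * np.abs(m.w)
    return pd.DataFrame({"feature_id": m.feature_ids, "vip": v}).set_index("feature_id")
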