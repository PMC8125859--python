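"""Origin discrimination: scaling, PLS-DA, VIP, Kennard–Stone, LOO-CV, ROC.

The classifier is partial least squares regression on dummy-coded class
membership (−1/+1), fitted by NIPALS with per-component deflation.
Variable importance in projection (VIP) is computed in its standard
weight-normalised square-root form,

    VIP_i = sqrt( I · Σ_c w_ic² · SSY_c / SSY_total ),

with unit-norm weight vectors w_c, SSY_c the Y sum of squares explained
by component c and I the number of features; under this form the mean of
the squared VIP scores over features is exactly 1, so the conventional
cut-off VIP > 1 flags above-average contributors.

Vast (variance-stability) scaling divides the autoscaled column by its
coefficient of variation — (x−μ)/s · (μ/s) — down-weighting features with
large relative spread; this is what lets class structure survive strong
confounding variance on uninformative features.

Everything here is deterministic given the input order; randomness is
confined to the synthetic-data module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScaledMatrix",
    "PLSDAModel",
    "SplitPlan",
    "ROCResult",
    "scale",
    "apply_scaling",
    "plsda_fit",
    "plsda_predict",
    "save_model",
    "load_model",
    "vip",
    "kennard_stone",
    "loo_cv",
    "roc",
]

_SCALERS = ("autoscale", "pareto", "vast")


@dataclass
class ScaledMatrix:
    values: np.ndarray  # samples × kept features
    method: str
    mean: np.ndarray  # per kept feature, pre-scaling
    sd: np.ndarray
    kept: np.ndarray  # indices of retained (non-zero-variance) features
    dropped: np.ndarray  # indices of dropped features


def scale(X: np.ndarray, method: str = "vast") -> ScaledMatrix:
    """Column-wise scaling: autoscale, Pareto, or Vast.

    autoscale: (x−μ)/s; pareto: (x−μ)/√s; vast: (x−μ)/s × (μ/s).
    Zero-variance columns are dropped and recorded.
    """
    if method not in _SCALERS:
        raise ValueError(f"unknown scaling method {method!r}")
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    if dropped.size:
        warnings.warn(f"dropping {dropped.size} zero-variance feature(s)", stacklevel=2)
    mu_k, sd_k = mu[kept], sd[kept]
    centered = X[:, kept] - mu_k
    if method == "autoscale":
        values = centered / sd_k
    elif method == "pareto":
        values = centered / np.sqrt(sd_k)
    else:  # vast
        values = centered / sd_k * (mu_k / sd_k)
    return ScaledMatrix(
        values=values, method=method, mean=mu_k, sd=sd_k, kept=kept, dropped=dropped
    )


def apply_scaling(stats: ScaledMatrix, Xnew: np.ndarray) -> np.ndarray:
    """Scale new samples with the training statistics."""
    Xnew = np.asarray(Xnew, dtype=float)
    centered = Xnew[:, stats.kept] - stats.mean
    if stats.method == "autoscale":
        return centered / stats.sd
    if stats.method == "pareto":
        return centered / np.sqrt(stats.sd)
    return centered / stats.sd * (stats.mean / stats.sd)


@dataclass
class PLSDAModel:
    W: np.ndarray  # features × components, unit-norm columns
    T: np.ndarray  # scores, samples × components
    P: np.ndarray  # X loadings
    q: np.ndarray  # Y loadings per component
    C: int
    ssy: np.ndarray  # explained Y sum of squares per component
    ssy_total: float
    coef: np.ndarray  # regression vector on the (scaled) feature space
    y_mean: float
    classes: tuple = ()  # (coded −1, coded +1)
    n_features: int = 0


def plsda_fit(X: np.ndarray, y, C: int = 2) -> PLSDAModel:
    """NIPALS PLS1 on dummy-coded classes.

    ``X`` must already be scaled (columns centred); the two class labels
    are coded −1/+1 in sorted label order, and the response is centred.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(y)
    classes = tuple(sorted(set(labels.tolist())))
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    counts = [(labels == c).sum() for c in classes]
    if min(counts) < 1:
        raise ValueError("both classes need at least one training sample")
    if C < 1 or C > min(X.shape):
        raise ValueError(f"invalid number of components {C} for shape {X.shape}")
    ycoded = np.where(labels == classes[0], -1.0, 1.0)
    y_mean = float(ycoded.mean())
    Xc = X.copy()
    yc = ycoded - y_mean
    n, I = X.shape
    W = np.zeros((I, C))
    T = np.zeros((n, C))
    P = np.zeros((I, C))
    q = np.zeros(C)
    ssy = np.zeros(C)
    for c in range(C):
        w = Xc.T @ yc
        norm = np.linalg.norm(w)
        if norm == 0:
            # response fully deflated; truncate
            W, T, P, q, ssy = W[:, :c], T[:, :c], P[:, :c], q[:c], ssy[:c]
            C = c
            break
        w /= norm
        t = Xc @ w
        tt = float(t @ t)
        qc = float(t @ yc) / tt
        p = Xc.T @ t / tt
        Xc -= np.outer(t, p)
        yc = yc - qc * t
        W[:, c], T[:, c], P[:, c], q[c] = w, t, p, qc
        ssy[c] = qc**2 * tt
    ssy_total = float(ssy.sum())
    # regression vector: B = W (PᵀW)⁻¹ q
    coef = W @ np.linalg.solve(P.T @ W, q)
    return PLSDAModel(
        W=W,
        T=T,
        P=P,
        q=q,
        C=C,
        ssy=ssy,
        ssy_total=ssy_total,
        coef=coef,
        y_mean=y_mean,
        classes=classes,
        n_features=I,
    )


def plsda_predict(model: PLSDAModel, Xnew: np.ndarray):
    """Predicted labels and continuous scores for pre-scaled samples.

    The decision threshold is 0 on the −1/+1 coding.
    """
    Xnew = np.asarray(Xnew, dtype=float)
    if Xnew.ndim == 1:
        Xnew = Xnew[None, :]
    if Xnew.shape[1] != model.n_features:
        raise ValueError(
            f"feature mismatch: model has {model.n_features}, got {Xnew.shape[1]}"
        )
    scores = Xnew @ model.coef + model.y_mean
    labels = np.where(scores > 0, model.classes[1], model.classes[0])
    return labels, scores


def vip(model: PLSDAModel) -> np.ndarray:
    """Variable importance in projection per feature (mean VIP² = 1)."""
    if model.ssy_total == 0:
        raise ValueError("model explains no Y variance")
    w2 = model.W**2  # columns already unit-norm
    return np.sqrt(model.n_features * (w2 @ model.ssy) / model.ssy_total)


def save_model(model: PLSDAModel, path: str) -> None:
    """Serialise a fitted model (weights, loadings, class coding) as JSON."""
    import json

    payload = {
        "W": model.W.tolist(),
        "P": model.P.tolist(),
        "q": model.q.tolist(),
        "C": model.C,
        "ssy": model.ssy.tolist(),
        "ssy_total": model.ssy_total,
        "coef": model.coef.tolist(),
        "y_mean": model.y_mean,
        "classes": list(model.classes),
        "n_features": model.n_features,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str) -> PLSDAModel:
    import json

    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    return PLSDAModel(
        W=np.asarray(payload["W"]),
        T=np.empty((0, payload["C"])),  # training scores are not persisted
        P=np.asarray(payload["P"]),
        q=np.asarray(payload["q"]),
        C=payload["C"],
        ssy=np.asarray(payload["ssy"]),
        ssy_total=payload["ssy_total"],
        coef=np.asarray(payload["coef"]),
        y_mean=payload["y_mean"],
        classes=tuple(payload["classes"]),
        n_features=payload["n_features"],
    )


@dataclass
class SplitPlan:
    train: np.ndarray  # sample indices
    test: np.ndarray


def kennard_stone(X: np.ndarray, n_test: int) -> SplitPlan:
    """Classical max-min Euclidean selection of a representative subset.

    The first two picks are the pair at maximum distance; each further
    pick maximizes its minimum distance to the already-selected set.
    Ties break on the lowest sample index.  The selected points form the
    test set (the paper's usage), the remainder the training set.
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= n_test < n:
        raise ValueError(f"n_test must be in [1, {n - 1}]")
    diff = X[:, None, :] - X[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    # max-distance pair, lowest indices on ties
    best = np.unravel_index(np.argmax(dist), dist.shape)
    selected = [min(best), max(best)] if n_test >= 2 else [min(best)]
    while len(selected) < n_test:
        remaining = [i for i in range(n) if i not in selected]
        min_d = dist[np.ix_(remaining, selected)].min(axis=1)
        pick = remaining[int(np.argmax(min_d))]  # argmax returns first = lowest index
        selected.append(pick)
    test = np.array(sorted(selected))
    train = np.array([i for i in range(n) if i not in selected])
    return SplitPlan(train=train, test=test)


def loo_cv(
    X: np.ndarray, y, C: int = 2, method: str = "vast"
) -> tuple[float, list]:
    """Leave-one-out misclassification error with per-fold refitting.

    Scaling statistics and the PLS-DA model are re-estimated on each
    fold's training portion; the held-out sample is scaled with the
    training statistics.  When a class has a single member, the fold
    holding it out would leave that class unrepresented and is skipped
    with a warning.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(y)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples for LOO")
    assignments: list = []
    wrong = 0
    total = 0
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        train_labels = labels[mask]
        if len(set(train_labels.tolist())) < 2:
            warnings.warn(f"fold {i} skipped: class with a single member", stacklevel=2)
            assignments.append(None)
            continue
        scaled = scale(X[mask], method)
        model = plsda_fit(scaled.values, train_labels, C)
        pred, _ = plsda_predict(model, apply_scaling(scaled, X[i : i + 1]))
        assignments.append(pred[0])
        total += 1
        if pred[0] != labels[i]:
            wrong += 1
    if total == 0:
        raise ValueError("no usable folds")
    return wrong / total, assignments


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc(scores: np.ndarray, labels, positive=None) -> ROCResult:
    """Threshold sweep over the continuous PLS-DA scores.

    ``positive`` defaults to the larger label in sorted order (the +1
    coding).  AUC is the trapezoid over (1−specificity, sensitivity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError("need both classes present")
    if positive is None:
        positive = classes[1]
    is_pos = labels == positive
    n_pos = int(is_pos.sum())
    n_neg = len(labels) - n_pos
    thresholds = np.concatenate(([np.inf], np.unique(scores)[::-1]))
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for k, thr in enumerate(thresholds):
        called_pos = scores >= thr
        sens[k] = (called_pos & is_pos).sum() / n_pos
        spec[k] = (~called_pos & ~is_pos).sum() / n_neg
    auc = float(np.trapezoid(sens, 1 - spec))
    return ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)
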