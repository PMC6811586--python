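"""Partial least squares discriminant analysis (PLS-DA).

Supervised projection of samples (rows) by gene expression (columns) onto
components that maximize covariance with class membership. X is
mean-centered and unit-variance scaled; Y is the one-hot class indicator,
centered. Components are extracted by the iterative NIPALS scheme for PLS2
(weight w from X'u, score t = Xw, y-loading q from Y't, u = Yq; iterate to
convergence, then deflate X and Y by the component). Classification assigns
the class with the largest predicted indicator score.

Component count is selected by repeated stratified cross-validation with a
one-standard-error parsimony rule: the smallest component count whose mean
accuracy is within one standard error of the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = ["PLSDAModel", "fit_plsda", "cross_validate", "confidence_ellipse"]

_TOL = 1e-10
_MAX_ITER = 500


@dataclass
class PLSDAModel:
    n_components: int
    class_labels: list[str]
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: np.ndarray
    x_weights: np.ndarray   # genes x A
    x_loadings: np.ndarray  # genes x A
    y_loadings: np.ndarray  # classes x A
    x_scores: np.ndarray    # samples x A

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Project new samples onto the component space."""
        Xc = (np.asarray(X, dtype=float) - self.x_mean) / self.x_scale
        T = np.empty((Xc.shape[0], self.n_components))
        for a in range(self.n_components):
            t = Xc @ self.x_weights[:, a]
            T[:, a] = t
            Xc = Xc - np.outer(t, self.x_loadings[:, a])
        return T

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Predicted (centered-removed) one-hot indicator scores."""
        T = self.transform(X)
        return T @ self.y_loadings.T + self.y_mean

    def predict(self, X: np.ndarray) -> list[str]:
        scores = self.predict_scores(X)
        return [self.class_labels[i] for i in np.argmax(scores, axis=1)]


def _one_hot(labels: list[str]) -> tuple[np.ndarray, list[str]]:
    classes = sorted(set(labels))
    Y = np.zeros((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        Y[i, classes.index(lab)] = 1.0
    return Y, classes


def fit_plsda(X: np.ndarray | pd.DataFrame, labels, n_components: int) -> PLSDAModel:
    """Fit a PLS-DA model by NIPALS.

    *X* is samples x genes. Constant (zero-variance) gene columns are
    rejected by name, since unit-variance scaling is undefined for them.
    """
    columns = list(X.columns) if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    if len(set(labels)) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    n, p = X.shape
    if not 1 <= n_components <= min(n - 1, p):
        raise ValueError(f"n_components must be in [1, {min(n - 1, p)}]")

    x_mean = X.mean(axis=0)
    x_scale = X.std(axis=0, ddof=1)
    dead = np.flatnonzero(x_scale == 0)
    if dead.size:
        names = [columns[i] for i in dead] if columns else dead.tolist()
        raise ValueError(f"constant gene columns (zero variance): {names}")
    Xc = (X - x_mean) / x_scale
    Y, classes = _one_hot(labels)
    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean

    W = np.empty((p, n_components))
    P = np.empty((p, n_components))
    Q = np.empty((len(classes), n_components))
    T = np.empty((n, n_components))
    for a in range(n_components):
        u = Yc[:, np.argmax(Yc.var(axis=0))].copy()
        t_old = np.zeros(n)
        for _ in range(_MAX_ITER):
            w = Xc.T @ u
            w /= np.linalg.norm(w)
            t = Xc @ w
            q = Yc.T @ t / (t @ t)
            u = Yc @ q / (q @ q)
            if np.linalg.norm(t - t_old) < _TOL:
                break
            t_old = t
        pvec = Xc.T @ t / (t @ t)
        Xc = Xc - np.outer(t, pvec)
        Yc = Yc - np.outer(t, q)
        W[:, a], P[:, a], Q[:, a], T[:, a] = w, pvec, q, t

    return PLSDAModel(
        n_components=n_components,
        class_labels=classes,
        x_mean=x_mean,
        x_scale=x_scale,
        y_mean=y_mean,
        x_weights=W,
        x_loadings=P,
        y_loadings=Q,
        x_scores=T,
    )


def _stratified_folds(labels: list[str], folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Index arrays of *folds* stratified folds."""
    by_class: dict[str, list[int]] = {}
    for i, lab in enumerate(labels):
        by_class.setdefault(lab, []).append(i)
    assignments = [[] for _ in range(folds)]
    for lab in sorted(by_class):
        idx = np.array(by_class[lab])
        rng.shuffle(idx)
        for j, i in enumerate(idx):
            assignments[j % folds].append(i)
    return [np.array(sorted(a)) for a in assignments]


def cross_validate(
    X: np.ndarray | pd.DataFrame,
    labels,
    folds: int = 5,
    repeats: int = 10,
    max_components: int = 10,
    seed: int = 0,
) -> tuple[pd.DataFrame, int]:
    """Repeated stratified CV accuracy per component count; 1-SE choice.

    Returns (accuracy table indexed by component count with columns
    mean_accuracy / se, chosen component count). The chosen count is the
    smallest whose mean accuracy is within one standard error of the
    maximum. Folds are reduced (with a warning) if the smallest class has
    fewer samples than *folds*.
    """
    X = np.asarray(X, dtype=float)
    labels = list(labels)
    class_sizes = pd.Series(labels).value_counts()
    if class_sizes.min() < folds:
        warnings.warn(
            f"smallest class has {class_sizes.min()} samples; reducing folds "
            f"from {folds} to {class_sizes.min()}",
            stacklevel=2,
        )
        folds = int(class_sizes.min())
    limit = min(len(labels) - int(np.ceil(len(labels) / folds)) - 1, X.shape[1])
    if max_components > limit:
        warnings.warn(f"max_components clipped from {max_components} to {limit}", stacklevel=2)
        max_components = limit

    rng = np.random.default_rng(seed)
    acc = np.zeros((max_components, repeats * folds))
    col = 0
    for _ in range(repeats):
        fold_idx = _stratified_folds(labels, folds, rng)
        for f in range(folds):
            test = fold_idx[f]
            train = np.setdiff1d(np.arange(len(labels)), test)
            y_train = [labels[i] for i in train]
            y_test = [labels[i] for i in test]
            # drop columns constant in the training split
            keep = np.flatnonzero(X[train].std(axis=0, ddof=1) > 0)
            a_max = min(max_components, len(train) - 1, keep.size)
            model = fit_plsda(X[np.ix_(train, keep)], y_train, a_max)
            for a in range(1, max_components + 1):
                sub = PLSDAModel(
                    n_components=min(a, a_max),
                    class_labels=model.class_labels,
                    x_mean=model.x_mean,
                    x_scale=model.x_scale,
                    y_mean=model.y_mean,
                    x_weights=model.x_weights[:, : min(a, a_max)],
                    x_loadings=model.x_loadings[:, : min(a, a_max)],
                    y_loadings=model.y_loadings[:, : min(a, a_max)],
                    x_scores=model.x_scores[:, : min(a, a_max)],
                )
                pred = sub.predict(X[np.ix_(test, keep)])
                acc[a - 1, col] = np.mean([p == t for p, t in zip(pred, y_test)])
            col += 1

    mean_acc = acc.mean(axis=1)
    se = acc.std(axis=1, ddof=1) / np.sqrt(acc.shape[1])
    table = pd.DataFrame(
        {"mean_accuracy": mean_acc, "se": se},
        index=pd.Index(range(1, max_components + 1), name="n_components"),
    )
    best = int(np.argmax(mean_acc))
    threshold = mean_acc[best] - se[best]
    chosen = int(np.flatnonzero(mean_acc >= threshold)[0]) + 1
    return table, chosen


def confidence_ellipse(scores_2d: np.ndarray, level: float = 0.954) -> dict:
    """Per-class confidence ellipse of 2-D component scores.

    Center = mean; semi-axes = sqrt(eigenvalue x chi2(2 df) quantile at
    *level*); rotation = angle of the leading eigenvector. A singular class
    covariance is flagged ``degenerate``.
    """
    scores = np.asarray(scores_2d, dtype=float)
    if scores.ndim != 2 or scores.shape[1] != 2:
        raise ValueError("scores must be n x 2")
    if scores.shape[0] < 3:
        raise ValueError("need >= 3 samples per class for an ellipse")
    if not 0 <= level < 1:
        raise ValueError("level must be in [0, 1)")
    center = scores.mean(axis=0)
    cov = np.cov(scores, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    q = chi2.ppf(level, df=2)
    degenerate = bool(np.min(evals) <= 1e-12 * max(np.max(evals), 1.0))
    semi_axes = np.sqrt(np.clip(evals, 0.0, None) * q)
    rotation = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
    return {
        "center": center,
        "semi_axes": semi_axes,
        "rotation": rotation,
        "degenerate": degenerate,
    }
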