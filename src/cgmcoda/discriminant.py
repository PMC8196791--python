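"""Linear discriminant model on ilr coordinates.

A Gaussian equal-covariance discriminant assigns a 24-h composition,
expressed in ilr coordinates, to one of the fitted day categories.  The
model is trained on the 00:00-24:00 days and then applied to the trailing
24-h composition at any anchor time of day, so a patient can ask at 06:00,
12:00 or 18:00 which kind of day the last 24 hours were.  Accuracy is
estimated by leave-one-out cross-validation.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LDModel:
    """Class means, pooled within-class covariance and priors in ilr space."""

    classes: tuple
    means: np.ndarray      # (k, p)
    covariance: np.ndarray # (p, p), pooled, regularized if near-singular
    priors: np.ndarray     # (k,), sums to 1

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def to_json(self, sbp=None) -> str:
        payload = {
            "classes": list(self.classes),
            "means": self.means.tolist(),
            "covariance": self.covariance.tolist(),
            "priors": self.priors.tolist(),
        }
        if sbp is not None:
            payload["sbp"] = np.asarray(sbp).tolist()
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "LDModel":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            means=np.asarray(d["means"], dtype=float),
            covariance=np.asarray(d["covariance"], dtype=float),
            priors=np.asarray(d["priors"], dtype=float),
        )


def fit_ld(coords, labels, priors: str = "empirical") -> LDModel:
    """Fit the linear discriminant on labelled ilr coordinates.

    The pooled within-class covariance is the weighted average of the
    class covariances; a ridge ``eps * I`` with
    ``eps = 1e-8 * trace / p`` is added when it is near-singular.
    ``priors`` is either ``"empirical"`` (class frequencies) or
    ``"uniform"``.  Every class needs at least 2 rows.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    y = np.asarray(labels)
    if X.shape[0] != y.shape[0]:
        raise ValueError("coords and labels length mismatch")
    classes = sorted(set(y.tolist()))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    means, counts = [], []
    pooled = np.zeros((p, p))
    for c in classes:
        Xi = X[y == c]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {c!r} has fewer than 2 rows")
        mu = Xi.mean(axis=0)
        R = Xi - mu
        pooled += R.T @ R
        means.append(mu)
        counts.append(Xi.shape[0])
    pooled /= n - len(classes)
    if np.linalg.cond(pooled) > 1e10:
        eps = 1e-8 * np.trace(pooled) / p
        pooled = pooled + np.eye(p) * max(eps, 1e-12)
    if priors == "empirical":
        pr = np.asarray(counts, dtype=float) / n
    elif priors == "uniform":
        pr = np.full(len(classes), 1.0 / len(classes))
    else:
        raise ValueError("priors must be 'empirical' or 'uniform'")
    return LDModel(tuple(classes), np.asarray(means), pooled, pr)


def predict_ld(model: LDModel, x):
    """Classify coordinates; returns ``(category, posterior)``.

    Discriminant scores are the log Gaussian densities with the shared
    covariance plus log priors; posteriors are their softmax.  A single
    vector yields a scalar category and a length-k posterior; a matrix
    yields arrays.  Ties break toward the lowest class in sort order.
    """
    X = np.asarray(x, dtype=float)
    single = X.ndim == 1
    X = np.atleast_2d(X)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} coordinates, got {X.shape[1]}"
        )
    Sinv = np.linalg.inv(model.covariance)
    scores = np.empty((X.shape[0], len(model.classes)))
    for j, mu in enumerate(model.means):
        R = X - mu
        maha = np.einsum("ij,jk,ik->i", R, Sinv, R)
        scores[:, j] = -0.5 * maha + np.log(model.priors[j])
    scores -= scores.max(axis=1, keepdims=True)
    post = np.exp(scores)
    post /= post.sum(axis=1, keepdims=True)
    idx = post.argmax(axis=1)  # argmax takes the first maximum: lowest label
    cats = np.asarray([model.classes[i] for i in idx])
    if single:
        return cats[0], post[0]
    return cats, post


def loocv_accuracy(coords, labels, priors: str = "empirical") -> float:
    """Leave-one-out cross-validated accuracy, in percent.

    Each row is held out in turn, the model refit on the remainder and the
    held-out row classified.  Rows whose removal would collapse a class to
    a single member are skipped with a warning and excluded from the
    denominator.
    """
    X = np.atleast_2d(np.asarray(coords, dtype=float))
    y = np.asarray(labels)
    counts = {c: int((y == c).sum()) for c in set(y.tolist())}
    correct = evaluated = skipped = 0
    for i in range(X.shape[0]):
        if counts[y[i].item() if hasattr(y[i], "item") else y[i]] <= 2:
            skipped += 1
            continue
        keep = np.ones(X.shape[0], dtype=bool)
        keep[i] = False
        model = fit_ld(X[keep], y[keep], priors=priors)
        pred, _ = predict_ld(model, X[i])
        evaluated += 1
        if pred == y[i]:
            correct += 1
    if skipped:
        warnings.warn(
            f"LOOCV skipped {skipped} row(s) whose removal would leave a "
            "singleton class", stacklevel=2,
        )
    if evaluated == 0:
        raise ValueError("no rows could be evaluated under LOOCV")
    return 100.0 * correct / evaluated
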