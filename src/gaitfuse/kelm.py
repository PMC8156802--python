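"""Kernel extreme learning machine (KELM): closed-form kernel ridge classifier.

Training solves one regularized linear system.  With an RBF Gram matrix
K_{ij} = exp(-||z_i - z_j||^2 / h) over the training features Z and a
one-vs-rest label matrix C (+1 in the true-class column, -1 elsewhere),
the output weights are

    beta = (K + I/lambda)^{-1} C

and a query frame z scores o = k(z, Z) beta, one real value per class; the
hard decision is the arg-max class.  The system is symmetric positive
definite for any finite lambda, so it is solved by Cholesky factorization
rather than explicit inversion.

Default hyperparameters h = 2**3, lambda = 1e4; the sensible search grids
are h in 2**-9..2**9 and lambda in 1e-9..1e9.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist

DEFAULT_H = 2.0**3
DEFAULT_LAMBDA = 1.0e4


def rbf_gram(A: np.ndarray, B: np.ndarray, h: float) -> np.ndarray:
    """RBF kernel matrix exp(-||a_i - b_j||^2 / h); entries in (0, 1]."""
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("feature dimensions differ")
    return np.exp(-cdist(A, B, "sqeuclidean") / h)


@dataclass
class KELMModel:
    """Fitted KELM: training features, kernel parameters and output weights."""

    Z: np.ndarray
    h: float
    lam: float
    beta: np.ndarray
    classes: list[str]
    C: np.ndarray

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.h <= 0 or self.lam <= 0:
            raise ValueError("h and lambda must be positive")
        if self.beta.shape != (self.Z.shape[0], len(self.classes)):
            raise ValueError("beta shape must be (n_train, n_class)")

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "h": self.h,
                "lambda": self.lam,
                "classes": list(self.classes),
                "Z": self.Z.tolist(),
                "beta": self.beta.tolist(),
                "C": self.C.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "KELMModel":
        obj = json.loads(text)
        return cls(
            Z=np.asarray(obj["Z"]),
            h=obj["h"],
            lam=obj["lambda"],
            beta=np.asarray(obj["beta"]),
            classes=list(obj["classes"]),
            C=np.asarray(obj["C"]),
        )


def label_matrix(labels, classes) -> np.ndarray:
    """One-vs-rest +/-1 label matrix: +1 in the true-class column."""
    index = {c: k for k, c in enumerate(classes)}
    C = -np.ones((len(labels), len(classes)))
    for i, lab in enumerate(labels):
        try:
            C[i, index[lab]] = 1.0
        except KeyError:
            raise ValueError(f"label {lab!r} not in class list") from None
    return C


def train_kelm(
    Z: np.ndarray,
    labels,
    h: float = DEFAULT_H,
    lam: float = DEFAULT_LAMBDA,
    classes=None,
) -> KELMModel:
    """Fit the KELM by the direct Cholesky solve of (K + I/lambda) beta = C."""
    Z = np.asarray(Z, dtype=float)
    labels = list(labels)
    if classes is None:
        seen: dict = {}
        for lab in labels:
            seen.setdefault(lab, None)
        classes = list(seen)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    if Z.shape[0] < len(classes):
        raise ValueError("need at least as many training rows as classes")
    if Z.shape[0] != len(labels):
        raise ValueError("row/label count mismatch")
    C = label_matrix(labels, classes)
    K = rbf_gram(Z, Z, h)
    # duplicate feature rows with conflicting labels make the target
    # unreachable for any classifier — worth a warning, not an error
    dup_i, dup_j = np.where(np.triu(K, k=1) >= 1.0)
    if any(labels[i] != labels[j] for i, j in zip(dup_i, dup_j)):
        warnings.warn("duplicate feature rows carry conflicting labels", stacklevel=2)
    A = K + np.eye(K.shape[0]) / lam
    beta = cho_solve(cho_factor(A, lower=True), C)
    return KELMModel(Z=Z, h=h, lam=lam, beta=beta, classes=list(classes), C=C)


def predict_outputs(model: KELMModel, features: np.ndarray) -> np.ndarray:
    """Real-valued class scores o = k(z, Z) beta, one row per query frame."""
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != model.Z.shape[1]:
        raise ValueError(
            f"query has {X.shape[1]} features, model expects {model.Z.shape[1]}"
        )
    return rbf_gram(X, model.Z, model.h) @ model.beta


def hard_decision(o: np.ndarray, classes) -> str:
    """Arg-max class of one output vector; ties go to the lowest class index."""
    o = np.asarray(o, dtype=float).ravel()
    if o.size == 0 or o.size != len(classes):
        raise ValueError("output length must equal the number of classes")
    return classes[int(np.argmax(o))]


def predict_labels(model: KELMModel, features: np.ndarray) -> list[str]:
    O = predict_outputs(model, features)
    return [model.classes[k] for k in np.argmax(O, axis=1)]
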