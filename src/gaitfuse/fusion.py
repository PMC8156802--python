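"""Fuzzy-decision fusion of per-frame classifier outputs.

A classifier output vector o (one real score per class) is mapped to a
fuzzy membership vector

    mu_i = exp(-(o_i / (mean(o) + gamma * sd(o)))**2),   gamma = 0.5,

with sd the sample (n-1) standard deviation.  Each membership lies in
(0, 1]; larger scores map to larger memberships.  Note the map is even in
its argument, so scores +c and -c receive equal membership — a property of
the transformation itself, kept as-is.

The reliability-weighted-sum (RWS) rule then combines the T per-frame
memberships of one recording:

1. consistency matrix A_{tk} = <mu^t, mu^k> (a Gram matrix, PSD and
   nonnegative, diagonal included);
2. the principal eigenvector w of A (nonnegative orientation, which exists
   by Perron-Frobenius) scores how consistent each frame is with the rest;
3. w is rescaled affinely into [a, a+b] (defaults a=0.6, b=0.4) to give
   per-frame reliabilities r_t;
4. global membership mu_g = (1/T) sum_t r_t mu^t, winner = arg-max class.

Five baseline rules are provided for comparison: sum, product, majority
vote, belief, and reliability-weighted belief (the product-type rules use a
small floor delta, default 1e-3, to tame memberships near 0 or 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

DEFAULT_GAMMA = 0.5
DEFAULT_REL_LOWER = 0.6
DEFAULT_REL_SPAN = 0.4
DEFAULT_DELTA = 1.0e-3

FUSION_RULES = ("rws", "sum", "product", "majority", "belief", "weighted_belief")


def fuzzy_membership(o: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Map one classifier output vector to per-class fuzzy memberships."""
    o = np.asarray(o, dtype=float).ravel()
    if o.size < 2:
        raise ValueError("need at least 2 classes")
    denom = o.mean() + gamma * o.std(ddof=1)
    if denom == 0:
        warnings.warn(
            "degenerate output (mean + gamma*sd = 0); using uniform memberships",
            stacklevel=2,
        )
        return np.full(o.size, np.exp(-1.0))
    return np.exp(-((o / denom) ** 2))


def membership_matrix(outputs: np.ndarray, gamma: float = DEFAULT_GAMMA) -> np.ndarray:
    """Apply :func:`fuzzy_membership` to each row of an output matrix."""
    O = np.atleast_2d(np.asarray(outputs, dtype=float))
    return np.vstack([fuzzy_membership(row, gamma) for row in O])


def consistency_matrix(decisions: np.ndarray) -> np.ndarray:
    """T x T Gram matrix of the membership vectors (diagonal included)."""
    M = np.atleast_2d(np.asarray(decisions, dtype=float))
    if M.shape[0] < 2:
        raise ValueError("need at least 2 fuzzy decisions")
    return M @ M.T


@dataclass
class ReliabilityVector:
    """Principal-eigenvector frame reliabilities, rescaled into [a, a+b]."""

    eigenvector: np.ndarray
    weights: np.ndarray
    lower: float
    span: float


def reliability_weights(
    A: np.ndarray,
    a: float = DEFAULT_REL_LOWER,
    b: float = DEFAULT_REL_SPAN,
) -> ReliabilityVector:
    """Frame reliabilities from the consistency matrix.

    The unit-norm eigenvector of the largest eigenvalue, oriented so its
    entries are nonnegative, is mapped affinely onto [a, a+b].  If all its
    entries coincide (mutually identical frames) every reliability is set
    to a+b: identical frames are maximally mutually consistent.
    """
    A = np.asarray(A, dtype=float)
    if A.size == 0:
        raise ValueError("empty consistency matrix")
    _, vecs = np.linalg.eigh(A)
    w = vecs[:, -1]
    if w.sum() < 0:
        w = -w
    spread = w.max() - w.min()
    if spread < 1e-12 * max(1.0, abs(w.max())):
        r = np.full(w.shape, a + b)
    else:
        r = a + b * (w - w.min()) / spread
    return ReliabilityVector(eigenvector=w, weights=r, lower=a, span=b)


@dataclass
class GlobalDecision:
    """Fused decision: global membership, winning class index, rule used."""

    membership: np.ndarray
    class_index: int
    rule: str
    reliabilities: np.ndarray | None = None

    def label(self, classes) -> str:
        return classes[self.class_index]


def _argmax_lowest(mu: np.ndarray) -> int:
    return int(np.argmax(mu))  # argmax already takes the first (lowest) index


def rws_fuse(
    decisions: np.ndarray,
    a: float = DEFAULT_REL_LOWER,
    b: float = DEFAULT_REL_SPAN,
) -> GlobalDecision:
    """Reliability-weighted-sum fusion: mu_g = (1/T) sum_t r_t mu^t."""
    M = np.atleast_2d(np.asarray(decisions, dtype=float))
    if M.shape[0] == 0:
        raise ValueError("need at least one fuzzy decision")
    if M.shape[0] == 1:
        r = np.array([a + b])
    else:
        r = reliability_weights(consistency_matrix(M), a, b).weights
    mu_g = (r[:, None] * M).mean(axis=0)
    return GlobalDecision(
        membership=mu_g, class_index=_argmax_lowest(mu_g), rule="rws", reliabilities=r
    )


def baseline_fuse(
    decisions: np.ndarray,
    rule: str,
    delta: float = DEFAULT_DELTA,
    reliabilities: np.ndarray | None = None,
    a: float = DEFAULT_REL_LOWER,
    b: float = DEFAULT_REL_SPAN,
    hard_indices: np.ndarray | None = None,
) -> GlobalDecision:
    """Baseline fusion rules: sum, product, majority, belief, weighted_belief.

    ``weighted_belief`` needs per-frame reliabilities; when not supplied they
    are computed exactly as in :func:`rws_fuse`.

    The majority vote counts the classifier's per-frame hard decisions.
    Pass them as ``hard_indices`` (one class index per frame, the arg-max of
    the raw classifier outputs); without them the vote falls back to the
    membership arg-max, which can disagree with the classifier's own hard
    decision because the membership transform is even in its argument.
    """
    M = np.atleast_2d(np.asarray(decisions, dtype=float))
    T = M.shape[0]
    if T == 0:
        raise ValueError("need at least one fuzzy decision")
    if rule == "sum":
        mu_g = M.mean(axis=0)
    elif rule == "product":
        mu_g = np.prod(M + delta, axis=0)
    elif rule == "belief":
        mu_g = np.prod(1.0 / (1.0 - M + delta), axis=0)
    elif rule == "weighted_belief":
        if reliabilities is None:
            if T == 1:
                reliabilities = np.array([a + b])
            else:
                reliabilities = reliability_weights(consistency_matrix(M), a, b).weights
        mu_g = np.prod(1.0 / (1.0 - reliabilities[:, None] * M + delta), axis=0)
    elif rule == "majority":
        if hard_indices is not None:
            hard = np.asarray(hard_indices, dtype=int)
            if hard.shape != (T,):
                raise ValueError("hard_indices must hold one class index per frame")
        else:
            hard = np.argmax(M, axis=1)
        counts = np.bincount(hard, minlength=M.shape[1])
        best = counts.max()
        tied = np.flatnonzero(counts == best)
        if tied.size == 1:
            winner = int(tied[0])
        else:  # tie: the tied class with the larger average membership wins
            mean_mu = M.mean(axis=0)
            winner = int(tied[np.argmax(mean_mu[tied])])
        return GlobalDecision(
            membership=counts / T, class_index=winner, rule="majority"
        )
    else:
        raise ValueError(f"unknown fusion rule {rule!r}; choose from {FUSION_RULES}")
    return GlobalDecision(membership=mu_g, class_index=_argmax_lowest(mu_g), rule=rule)


def fuse(decisions: np.ndarray, rule: str = "rws", **kwargs) -> GlobalDecision:
    """Dispatch to :func:`rws_fuse` or :func:`baseline_fuse` by rule name."""
    if rule == "rws":
        allowed = {k: v for k, v in kwargs.items() if k in ("a", "b")}
        return rws_fuse(decisions, **allowed)
    return baseline_fuse(decisions, rule, **kwargs)
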