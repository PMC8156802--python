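"""Unreliable-feature detection and calibration via kernel density tails.

Optical tracking occasionally produces biased frames (marker occlusion,
reflection artefacts).  Rather than deleting such frames, each feature is
screened against its own training distribution: a Gaussian kernel density
estimate gives a smooth CDF Phi, and any value outside the central
probability band [Phi^{-1}(1-P_th), Phi^{-1}(P_th)] is deemed unreliable.
Unreliable values are calibrated, by default clamped to the offending bound
(an alternative replaces them with the training mean); everything else is
left untouched and no row is ever dropped.

Bandwidths follow Silverman's rule, rho = sigma * (4/(3L))^{1/5}.  Bounds
are fitted once on the pooled training split and then applied unchanged to
test data.  Default P_th = 0.999.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm

DEFAULT_P_TH = 0.999
STRATEGIES = ("clamp", "mean", "off")


class DegenerateDistributionError(ValueError):
    """All values identical: no density to estimate, calibration is skipped."""


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth sigma * (4/(3L))^{1/5}."""
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values to estimate a bandwidth")
    sigma = v.std(ddof=1)
    if sigma == 0:
        raise DegenerateDistributionError("all values identical (sigma = 0)")
    return float(sigma * (4.0 / (3.0 * v.size)) ** 0.2)


def estimate_density_cdf(values: np.ndarray, rho: float):
    """CDF of the Gaussian KDE with bandwidth ``rho``.

    Returns a vectorized callable Phi(z) = mean_i N((z - z_i)/rho); monotone
    nondecreasing with limits 0 and 1.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    if rho <= 0:
        raise ValueError("bandwidth rho must be positive")

    def cdf(z):
        z = np.asarray(z, dtype=float)
        out = norm.cdf((z[..., None] - v) / rho).mean(axis=-1)
        return out if out.ndim else float(out)

    return cdf


def compute_bounds(
    values: np.ndarray, p_th: float = DEFAULT_P_TH, rho: float | None = None
) -> tuple[float, float, float]:
    """Tail quantiles (z_lb, z_ub, rho) of the KDE-smoothed distribution.

    z_ub solves Phi(z) = p_th and z_lb solves Phi(z) = 1 - p_th by bisection
    on a bracket spanning the data range padded by multiples of rho.
    """
    if not 0.5 < p_th < 1.0:
        raise ValueError("p_th must lie in (0.5, 1)")
    v = np.asarray(values, dtype=float).ravel()
    if rho is None:
        rho = silverman_bandwidth(v)
    cdf = estimate_density_cdf(v, rho)
    lo, hi = v.min() - 5.0 * rho, v.max() + 5.0 * rho
    # widen until the bracket is guaranteed (needed only for extreme p_th)
    while cdf(lo) > 1.0 - p_th:
        lo -= 5.0 * rho
    while cdf(hi) < p_th:
        hi += 5.0 * rho
    z_ub = brentq(lambda z: cdf(z) - p_th, lo, hi)
    z_lb = brentq(lambda z: cdf(z) - (1.0 - p_th), lo, hi)
    return float(z_lb), float(z_ub), float(rho)


@dataclass
class FeatureBounds:
    """Per-feature calibration bounds fitted on the training split.

    Degenerate (constant) features carry infinite bounds and ``rho`` NaN,
    which makes calibration a no-op for them.
    """

    lower: np.ndarray
    upper: np.ndarray
    rho: np.ndarray
    p_th: float = DEFAULT_P_TH
    center: np.ndarray | None = None  # training mean, used by the 'mean' strategy
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if not (self.lower.shape == self.upper.shape == self.rho.shape):
            raise ValueError("lower/upper/rho must have equal length")
        if np.any(self.lower > self.upper):
            raise ValueError("lower bounds must not exceed upper bounds")
        if not 0.5 < self.p_th < 1.0:
            raise ValueError("p_th must lie in (0.5, 1)")
        if self.center is not None:
            self.center = np.asarray(self.center, dtype=float)

    @property
    def n_features(self) -> int:
        return self.lower.shape[0]

    def to_json(self) -> str:
        names = self.feature_names or [f"f{i:02d}" for i in range(self.n_features)]
        table = {
            name: {"z_lb": lb, "z_ub": ub, "rho": r}
            for name, lb, ub, r in zip(names, self.lower, self.upper, self.rho)
        }
        return json.dumps(
            {"p_th": self.p_th, "center": list(self.center)
             if self.center is not None else None, "bounds": table},
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureBounds":
        obj = json.loads(text)
        names = list(obj["bounds"])
        lower = [obj["bounds"][n]["z_lb"] for n in names]
        upper = [obj["bounds"][n]["z_ub"] for n in names]
        rho = [obj["bounds"][n]["rho"] for n in names]
        center = obj.get("center")
        return cls(
            lower=lower, upper=upper, rho=rho, p_th=obj["p_th"],
            center=np.asarray(center) if center is not None else None,
            feature_names=names,
        )


def fit_feature_bounds(
    features: np.ndarray,
    p_th: float = DEFAULT_P_TH,
    feature_names: list[str] | None = None,
) -> FeatureBounds:
    """Fit per-column KDE tail bounds on a pooled training feature matrix."""
    X = np.asarray(features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 rows")
    n = X.shape[1]
    lower = np.full(n, -np.inf)
    upper = np.full(n, np.inf)
    rho = np.full(n, np.nan)
    for j in range(n):
        try:
            lb, ub, r = compute_bounds(X[:, j], p_th=p_th)
        except DegenerateDistributionError:
            continue  # constant feature: leave unbounded
        lower[j], upper[j], rho[j] = lb, ub, r
    return FeatureBounds(
        lower=lower, upper=upper, rho=rho, p_th=p_th,
        center=X.mean(axis=0), feature_names=feature_names or [],
    )


def calibrate_features(
    features: np.ndarray, bounds: FeatureBounds, strategy: str = "clamp"
) -> np.ndarray:
    """Calibrate out-of-band values; shape is preserved, no row is deleted.

    strategy:
      * ``clamp`` — replace with the violated bound (default);
      * ``mean``  — replace with the feature's training mean;
      * ``off``   — identity.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    X = np.asarray(features, dtype=float)
    if X.shape[-1] != bounds.n_features:
        raise ValueError(
            f"feature count {X.shape[-1]} does not match bounds ({bounds.n_features})"
        )
    if strategy == "off":
        return X.copy()
    if strategy == "clamp":
        return np.clip(X, bounds.lower, bounds.upper)
    if bounds.center is None:
        raise ValueError("'mean' strategy requires bounds fitted with a center")
    flagged = (X < bounds.lower) | (X > bounds.upper)
    out = X.copy()
    out[flagged] = np.broadcast_to(bounds.center, X.shape)[flagged]
    return out
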