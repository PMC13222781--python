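"""Random-effects meta-analytic pooling of a panel's effect estimates.

Pooling uses inverse-variance weights w_i = 1/(se_i**2 + tau2) with the
between-effect variance tau2 estimated by REML (default; Fisher-scoring
iteration) or DerSimonian-Laird (closed form).  Heterogeneity is reported
through Cochran's Q and I^2, both computed with fixed-effect weights.

The six effects of a panel are computed on overlapping data and are not
independent; they are nevertheless pooled as if independent — a faithful
replication of the scrutiny procedure, not an endorsement of it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .effects import EffectEstimate
from .exceptions import ConvergenceError, ParameterError

_METHODS = ("reml", "dl")


@dataclass(frozen=True)
class PooledEffect:
    """Random-effects summary of k effect estimates."""

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    q: float
    i2: float
    k: int
    method: str

    def __post_init__(self):
        if self.k < 2:
            raise ParameterError("pooling requires k >= 2 effects")
        if self.tau2 < 0:
            raise ParameterError("tau2 must be >= 0")

    @property
    def z(self) -> float:
        return self.estimate / self.se

    @property
    def p_value(self) -> float:
        return 2 * stats.norm.sf(abs(self.z))

    @property
    def significant(self) -> bool:
        return abs(self.z) > stats.norm.ppf(0.975)


def _as_arrays(effects: Iterable) -> tuple[np.ndarray, np.ndarray]:
    y, v = [], []
    for eff in effects:
        if isinstance(eff, EffectEstimate):
            y.append(eff.coefficient)
            v.append(eff.variance)
        else:
            est, se = eff
            y.append(float(est))
            v.append(float(se) ** 2)
    y_arr, v_arr = np.asarray(y, dtype=float), np.asarray(v, dtype=float)
    if len(y_arr) < 2:
        raise ParameterError("pooling requires at least two effects")
    if not (np.all(np.isfinite(y_arr)) and np.all(np.isfinite(v_arr))):
        raise ParameterError("effects and variances must be finite")
    if np.any(v_arr <= 0):
        raise ParameterError("every effect needs a positive sampling variance")
    return y_arr, v_arr


def heterogeneity(effects: Sequence) -> tuple[float, float]:
    """Cochran's Q and I^2 (percent) from fixed-effect weights."""
    y, v = _as_arrays(effects)
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = float(np.sum(w * (y - mu_fe) ** 2))
    k = len(y)
    i2 = max(0.0, 100.0 * (q - (k - 1)) / q) if q > 0 else 0.0
    return q, i2


def tau2_dersimonian_laird(y: np.ndarray, v: np.ndarray) -> float:
    """Closed-form DerSimonian-Laird moment estimator, floored at 0."""
    w = 1.0 / v
    mu_fe = np.sum(w * y) / np.sum(w)
    q = np.sum(w * (y - mu_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (q - (len(y) - 1)) / denom))


def tau2_reml(
    y: np.ndarray,
    v: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> float:
    """REML estimate of tau2 by Fisher-scoring iteration.

    Iterates tau2 <- sum(w^2 ((y-mu)^2 - v)) / sum(w^2) + 1/sum(w) with
    w = 1/(v + tau2), projected onto [0, inf); converged when successive
    values differ by less than ``tol``.
    """
    tau2 = max(tau2_dersimonian_laird(y, v), 0.0)
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        mu = np.sum(w * y) / np.sum(w)
        new = np.sum(w**2 * ((y - mu) ** 2 - v)) / np.sum(w**2) + 1.0 / np.sum(w)
        new = max(0.0, float(new))
        if abs(new - tau2) < tol:
            return new
        tau2 = new
    raise ConvergenceError(
        "REML tau2 iteration did not converge", {"tau2": tau2, "max_iter": max_iter}
    )


def pool_random_effects(
    effects: Sequence, method: str = "reml", tau2: float | None = None
) -> PooledEffect:
    """Pool effect estimates under a random-effects model.

    Parameters
    ----------
    effects : sequence of EffectEstimate or (estimate, se) pairs
    method : {"reml", "dl"}
        Between-effect variance estimator.
    tau2 : float, optional
        Bypass estimation and pool at this fixed between-effect variance
        (tau2 = 0 gives the fixed-effect estimate; a very large value
        approaches the unweighted mean).
    """
    y, v = _as_arrays(effects)
    if tau2 is not None:
        if tau2 < 0:
            raise ParameterError("tau2 must be >= 0")
        method = "fixed-tau2"
    elif method in _METHODS:
        tau2 = tau2_reml(y, v) if method == "reml" else tau2_dersimonian_laird(y, v)
    else:
        raise ParameterError(f"method must be one of {_METHODS}")
    w = 1.0 / (v + tau2)
    estimate = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    half = stats.norm.ppf(0.975) * se
    q, i2 = heterogeneity(list(zip(y, np.sqrt(v))))
    return PooledEffect(
        estimate=estimate,
        se=se,
        ci_low=estimate - half,
        ci_high=estimate + half,
        tau2=tau2,
        q=q,
        i2=i2,
        k=len(y),
        method=method,
    )
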