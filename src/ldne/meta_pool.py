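"""Meta-analytic pooling of per-chromosome decay-model parameters.

Each chromosome contributes an estimate with an asymptotic standard
error; chromosomes are treated as independent studies.  Fixed-effect
pooling uses inverse-variance weights; the DerSimonian-Laird
random-effects method adds a moment estimate of the between-chromosome
variance tau^2 derived from Cochran's Q.  Parameters a and b are pooled
independently; the pooled b is read as the current effective population
size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ldne.decay_fit import DecayFit

logger = logging.getLogger(__name__)

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


@dataclass
class PooledEstimate:
    parameter: str
    estimate: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    k_studies: int
    method: str  # "fixed" or "DL"

    def __str__(self) -> str:
        return f"{self.estimate:.2f} ({self.ci_low:.2f}; {self.ci_high:.2f})"

    def to_row(self) -> dict:
        return {
            "parameter": self.parameter,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "Q": self.Q,
            "k_studies": self.k_studies,
            "method": self.method,
        }


def _validate(estimates, variances) -> tuple[np.ndarray, np.ndarray]:
    theta = np.asarray(estimates, dtype=float)
    v = np.asarray(variances, dtype=float)
    if theta.shape != v.shape or theta.ndim != 1:
        raise ValueError("estimates and variances must be equal-length 1-D arrays")
    if len(theta) < 2:
        raise ValueError("pooling requires at least 2 studies")
    if np.any(v <= 0):
        raise ValueError("all variances must be positive")
    return theta, v


def pool_fixed(estimates, variances, parameter: str = "") -> PooledEstimate:
    """Inverse-variance fixed-effect pooling with a normal 95% CI."""
    theta, v = _validate(estimates, variances)
    w = 1.0 / v
    est = float(np.sum(w * theta) / np.sum(w))
    var = 1.0 / float(np.sum(w))
    Q = float(np.sum(w * (theta - est) ** 2))
    half = Z_95 * np.sqrt(var)
    return PooledEstimate(
        parameter=parameter,
        estimate=est,
        ci_low=est - half,
        ci_high=est + half,
        tau2=0.0,
        Q=Q,
        k_studies=len(theta),
        method="fixed",
    )


def pool_dersimonian_laird(estimates, variances, parameter: str = "") -> PooledEstimate:
    """DerSimonian-Laird random-effects pooling.

    tau^2 = max(0, (Q - (k-1)) / (sum w - sum w^2 / sum w)) with the
    fixed-effect weights w = 1/v; studies are then re-weighted by
    1/(v + tau^2).  Reduces exactly to fixed-effect pooling when
    Q <= k - 1.
    """
    theta, v = _validate(estimates, variances)
    k = len(theta)
    w = 1.0 / v
    sw = float(np.sum(w))
    fixed_est = float(np.sum(w * theta) / sw)
    Q = float(np.sum(w * (theta - fixed_est) ** 2))
    denom = sw - float(np.sum(w**2)) / sw
    tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    est = float(np.sum(w_star * theta) / np.sum(w_star))
    var = 1.0 / float(np.sum(w_star))
    half = Z_95 * np.sqrt(var)
    return PooledEstimate(
        parameter=parameter,
        estimate=est,
        ci_low=est - half,
        ci_high=est + half,
        tau2=tau2,
        Q=Q,
        k_studies=k,
        method="DL",
    )


def pool_parameters(
    fits: list[DecayFit], method: str = "DL"
) -> tuple[PooledEstimate, PooledEstimate]:
    """Pool (a, b) across chromosomes; non-converged fits are excluded."""
    if method not in ("DL", "fixed"):
        raise ValueError(f"unknown pooling method {method!r}")
    usable = [f for f in fits if f.converged and np.isfinite(f.se_a) and np.isfinite(f.se_b)]
    dropped = len(fits) - len(usable)
    if dropped:
        logger.warning("pool_parameters: excluded %d non-converged/degenerate fits", dropped)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 converged fits to pool, have {len(usable)}")
    pool = pool_dersimonian_laird if method == "DL" else pool_fixed
    pooled_a = pool([f.a_hat for f in usable], [f.se_a**2 for f in usable], parameter="a")
    pooled_b = pool([f.b_hat for f in usable], [f.se_b**2 for f in usable], parameter="b")
    logger.info("pooled a = %s, b (current Ne) = %s", pooled_a, pooled_b)
    return pooled_a, pooled_b
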