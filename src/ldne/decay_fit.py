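"""Non-linear least-squares fit of the LD decay model per chromosome.

The expected decline of r^2 with genetic distance d (morgans) in an
isolated randomly mating population is E(r^2) = 1/(1 + 4*N*d) (Sved).
The mutation-adjusted form replaces the constant with a free intercept
parameter:

    y_i = 1/(a + 4*b*d_i) + e_i

where y_i is the r^2 of SNP pair i.  Parameter b estimates the current
effective population size Ne; a absorbs mutation and sampling effects
(a = 1 recovers Sved's curve exactly).

The fit is unweighted least squares on pair-level r^2 values via damped
Gauss-Newton iteration with b optimized on the log scale (positivity),
started from a = 2 and a method-of-moments b.  Asymptotic standard
errors come from the residual-variance-scaled inverse Jacobian
cross-product and feed the meta-analytic pooling stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_INIT_A = 2.0
MAX_ITER = 200
REL_TOL = 1e-10


class FitError(ValueError):
    """The decay model cannot be fit to the given pairs."""


@dataclass
class DecayFit:
    chromosome: str
    a_hat: float
    b_hat: float
    se_a: float
    se_b: float
    cov_ab: float
    n_pairs_used: int
    converged: bool
    sse: float

    def to_row(self) -> dict:
        return {
            "chromosome": self.chromosome,
            "a_hat": self.a_hat,
            "b_hat": self.b_hat,
            "se_a": self.se_a,
            "se_b": self.se_b,
            "cov_ab": self.cov_ab,
            "n_pairs_used": self.n_pairs_used,
            "converged": self.converged,
            "sse": self.sse,
        }


def predict_r2(a: float, b: float, d_morgans) -> np.ndarray | float:
    """Model prediction 1/(a + 4*b*d); strictly decreasing in d for b > 0."""
    d = np.asarray(d_morgans, dtype=float)
    denom = a + 4.0 * b * d
    if np.any(denom <= 0):
        raise ValueError("a + 4*b*d must be positive over the requested distances")
    out = 1.0 / denom
    return float(out) if np.isscalar(d_morgans) else out


def _moment_init_b(d: np.ndarray, y: np.ndarray, init_a: float) -> float:
    """Solve 1/(init_a + 4*b*dbar) = ybar at the median distance (scale-aware start)."""
    dbar = float(np.median(d))
    ybar = float(np.mean(y))
    if ybar <= 0 or dbar <= 0:
        return 100.0
    b = (1.0 / ybar - init_a) / (4.0 * dbar)
    return b if b > 0 else 100.0


def _sse(a: float, b: float, d: np.ndarray, y: np.ndarray) -> float:
    return float(np.sum((y - 1.0 / (a + 4.0 * b * d)) ** 2))


def fit_decay(
    d_morgans: np.ndarray,
    r2: np.ndarray,
    chromosome: str = "",
    init_a: float = DEFAULT_INIT_A,
    init_b: float | None = None,
) -> DecayFit:
    """Fit (a, b) by damped Gauss-Newton on pair-level r^2 values.

    Requires at least 10 pairs with positive genetic distance spanning at
    least 2 distinct distances.  Iterates from (init_a, init_b) — by
    default a = 2 and a method-of-moments b — halving the step until the
    objective decreases, until the relative parameter change falls below
    1e-10 or 200 iterations (then ``converged`` is False).
    """
    d = np.asarray(d_morgans, dtype=float)
    y = np.asarray(r2, dtype=float)
    keep = d > 0
    d, y = d[keep], y[keep]
    if len(d) < 10:
        raise FitError(f"need >= 10 pairs with positive distance, got {len(d)}")
    if len(np.unique(d)) < 2:
        raise FitError("degenerate distances: at least 2 distinct values required")

    a = float(init_a)
    logb = np.log(_moment_init_b(d, y, init_a) if init_b is None else float(init_b))
    sse = _sse(a, np.exp(logb), d, y)
    converged = False
    for _ in range(MAX_ITER):
        b = np.exp(logb)
        f = 1.0 / (a + 4.0 * b * d)
        resid = y - f
        # Jacobian of f wrt (a, log b)
        f2 = f * f
        J = np.column_stack([-f2, -4.0 * b * d * f2])
        JtJ = J.T @ J
        Jtr = J.T @ resid
        try:
            step = np.linalg.solve(JtJ, Jtr)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(JtJ, Jtr, rcond=None)[0]
        # damping: halve until the objective does not increase
        lam = 1.0
        for _ in range(60):
            a_new = a + lam * step[0]
            logb_new = logb + lam * step[1]
            sse_new = _sse(a_new, np.exp(logb_new), d, y)
            if np.isfinite(sse_new) and sse_new <= sse:
                break
            lam *= 0.5
        else:
            break  # no acceptable step: stop at current point
        rel_change = max(
            abs(a_new - a) / max(abs(a), 1e-12), abs(logb_new - logb)
        )
        a, logb, sse = a_new, logb_new, sse_new
        if rel_change < REL_TOL:
            converged = True
            break

    b = float(np.exp(logb))
    f = 1.0 / (a + 4.0 * b * d)
    resid = y - f
    f2 = f * f
    # Jacobian wrt (a, b) for reporting-scale standard errors
    J = np.column_stack([-f2, -4.0 * d * f2])
    dof = len(d) - 2
    s2 = float(resid @ resid) / max(dof, 1)
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se_a, se_b = float(np.sqrt(cov[0, 0])), float(np.sqrt(cov[1, 1]))
        cov_ab = float(cov[0, 1])
    except np.linalg.LinAlgError:
        se_a = se_b = cov_ab = float("nan")
    if not converged:
        logger.warning("fit_decay(%s): not converged after %d iterations", chromosome, MAX_ITER)
    return DecayFit(
        chromosome=chromosome,
        a_hat=float(a),
        b_hat=b,
        se_a=se_a,
        se_b=se_b,
        cov_ab=cov_ab,
        n_pairs_used=len(d),
        converged=converged,
        sse=float(sse),
    )


def fit_all_chromosomes(
    table: pd.DataFrame,
    value_col: str = "r2",
    init_a: float = DEFAULT_INIT_A,
    bin_means: bool = False,
) -> list[DecayFit]:
    """One decay fit per chromosome of an LD pair table.

    Fits pair-level r^2 by default; ``bin_means=True`` fits the 50-bin
    class-B means instead (display-style sensitivity analysis).
    Chromosome-level failures are logged and skipped, not fatal.
    """
    from ldne.ld_engine import bin_pairs

    fits: list[DecayFit] = []
    for chrom, sub in table.groupby("chromosome", sort=False):
        try:
            if bin_means:
                bins = bin_pairs(sub, "B", value_col=value_col)
                bins = bins.dropna(subset=["mean_r2"])
                rate = sub["dist_morgans"].sum() / max(sub["dist_bp"].sum(), 1)
                fit = fit_decay(
                    bins["median_of_range"].to_numpy() * 1e6 * rate,
                    bins["mean_r2"].to_numpy(),
                    chromosome=str(chrom),
                    init_a=init_a,
                )
            else:
                fit = fit_decay(
                    sub["dist_morgans"].to_numpy(),
                    sub[value_col].to_numpy(),
                    chromosome=str(chrom),
                    init_a=init_a,
                )
            fits.append(fit)
        except FitError as exc:
            logger.warning("chromosome %s: decay fit failed (%s)", chrom, exc)
    return fits


def fits_to_frame(fits: list[DecayFit]) -> pd.DataFrame:
    return pd.DataFrame([f.to_row() for f in fits])
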