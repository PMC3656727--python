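"""LD-decay curve fitting and threshold-crossing distances.

Two decay models are fitted to the observed (distance, LD) scatter of all
informative-site pairs:

* the drift-recombination expectation of r^2 for a sample of n sequences
  (Hill-Weir), parameterized by the population recombination rate per base
  pair, rho_bp = 4*Ne*r per bp, through C = rho_bp * distance;
* an exponential-in-generations model for D', D'(t) = (1 - r)^t, where the
  recombination fraction r between two sites comes from physical distance
  via an assumed map scale (default 1 cM = 1 Mb) and t - the number of
  generations since D' = 1 - is the fitted parameter.

Both fits are unweighted least squares over all pairs (no distance
binning), with a deterministic log-spaced multi-start so results are
reproducible bit for bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import minimize_scalar

from .ldcore import LDPairSet

logger = logging.getLogger(__name__)

__all__ = [
    "DecayFit",
    "expected_r2",
    "fit_hill_weir",
    "crossing_distance",
    "fit_dprime_decay",
    "recombination_fraction",
]

NEVER_REACHED = "never_reached"
BELOW_AT_ORIGIN = "below_at_origin"

_MAX_SEARCH_BP = 10**9


@dataclass
class DecayFit:
    model: Literal["hill_weir_r2", "dprime_generations"]
    fitted_param: float  # rho per bp, or t in generations
    n_used: float
    map_scale_cm_per_mb: float = 1.0
    residual_ss: float = float("nan")
    n_pairs: int = 0
    grid_residuals: list[tuple[float, float]] = field(default_factory=list)

    def predict(self, distance_bp: np.ndarray | float) -> np.ndarray | float:
        d = np.asarray(distance_bp, dtype=float)
        if self.model == "hill_weir_r2":
            out = expected_r2(self.fitted_param * d, self.n_used)
        else:
            r = recombination_fraction(d, self.map_scale_cm_per_mb)
            out = (1.0 - r) ** self.fitted_param
        return out if np.ndim(distance_bp) else float(out)

    def crossing_bp(self, threshold: float = 0.2) -> int | str:
        return crossing_distance(self, threshold)


def expected_r2(C: np.ndarray | float, n: float) -> np.ndarray | float:
    """Sample-size-adjusted drift expectation of r^2 at scaled recombination C.

    E[r^2] = (10+C)/((2+C)(11+C)) * [1 + (3+C)(12+12C+C^2) / (n(2+C)(11+C))].
    At C=0 and large n this tends to 10/22; as C grows it decays toward 1/n.
    """
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be >= 0")
    if n < 2:
        raise ValueError("n must be >= 2")
    base = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    adj = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (
        n * (2.0 + C) * (11.0 + C)
    )
    out = base * adj
    return out if out.ndim else float(out)


def recombination_fraction(
    distance_bp: np.ndarray | float, map_scale_cm_per_mb: float = 1.0
) -> np.ndarray | float:
    """Recombination fraction from physical distance, capped at 0.5.

    Linear map: r = 0.01 * (cM per Mb) * (distance in Mb).
    """
    d = np.asarray(distance_bp, dtype=float)
    r = np.minimum(0.5, 0.01 * map_scale_cm_per_mb * d / 1e6)
    return r if r.ndim else float(r)


def _multistart_minimize(objective, starts: np.ndarray) -> tuple[float, float, list]:
    """Deterministic multi-start 1-D bounded minimization on a log grid."""
    grid = [(float(s), float(objective(s))) for s in starts]
    best_param, best_val = min(grid, key=lambda t: t[1])
    for s in starts:
        res = minimize_scalar(
            objective,
            bounds=(0.0, max(10.0 * s, 1e-12)),
            method="bounded",
            options={"xatol": 1e-12},
        )
        if res.fun < best_val:
            best_param, best_val = float(res.x), float(res.fun)
    return best_param, best_val, grid


def fit_hill_weir(pairs: LDPairSet, n: float) -> DecayFit:
    """Least-squares fit of the expected-r^2 decay curve to observed pairs.

    Minimizes sum over pairs of (r2_obs - E[r^2](rho_bp * d, n))^2 for
    rho_bp >= 0.  ``n`` is the haplotype sample size entering the
    expectation (for pooled fits across loci of unequal n, pass the mean).
    """
    d = np.array([p.distance_bp for p in pairs.pairs], dtype=float)
    r2 = np.array([p.r2 for p in pairs.pairs], dtype=float)
    if len(d) < 5:
        raise ValueError("need >= 5 pairs with positive distances to fit decay")
    if np.ptp(d) == 0:
        logger.warning("all pair distances equal: decay fit is ill-conditioned")

    def objective(rho_bp: float) -> float:
        return float(np.sum((r2 - expected_r2(rho_bp * d, n)) ** 2))

    starts = np.concatenate([[0.0], np.logspace(-8, 1, 19)])
    param, val, grid = _multistart_minimize(objective, starts)
    return DecayFit(
        model="hill_weir_r2",
        fitted_param=param,
        n_used=float(n),
        residual_ss=val,
        n_pairs=len(d),
        grid_residuals=grid,
    )


def fit_dprime_decay(
    pairs: LDPairSet, map_scale_cm_per_mb: float = 1.0
) -> DecayFit:
    """Least-squares fit of D'(t) = (1 - r(d))^t over observed pairs.

    ``t`` is the number of generations since complete disequilibrium.  When
    every observed D' equals 1 the optimum is t = 0 (no decay observed).
    """
    d = np.array([p.distance_bp for p in pairs.pairs], dtype=float)
    dp = np.array([p.dprime for p in pairs.pairs], dtype=float)
    if len(d) < 5:
        raise ValueError("need >= 5 pairs to fit decay")
    r = recombination_fraction(d, map_scale_cm_per_mb)

    def objective(t: float) -> float:
        return float(np.sum((dp - (1.0 - r) ** t) ** 2))

    if np.allclose(dp, 1.0):
        return DecayFit(
            model="dprime_generations",
            fitted_param=0.0,
            n_used=float("nan"),
            map_scale_cm_per_mb=map_scale_cm_per_mb,
            residual_ss=objective(0.0),
            n_pairs=len(d),
        )
    starts = np.concatenate([[0.0], np.logspace(0, 7, 15)])
    param, val, grid = _multistart_minimize(objective, starts)
    return DecayFit(
        model="dprime_generations",
        fitted_param=param,
        n_used=float("nan"),
        map_scale_cm_per_mb=map_scale_cm_per_mb,
        residual_ss=val,
        n_pairs=len(d),
        grid_residuals=grid,
    )


def crossing_distance(fit: DecayFit, threshold: float = 0.2) -> int | str:
    """Smallest integer distance where the fitted curve falls below a threshold.

    Returns 0 when the curve is already below the threshold at d = 1 (the
    convention used for loci whose fitted curve starts under the cutoff),
    and the ``never_reached`` sentinel when it stays above the threshold
    over the whole search range (decay curves here are monotone
    non-increasing in distance).
    """
    if fit.predict(1) < threshold:
        return 0
    if fit.predict(_MAX_SEARCH_BP) >= threshold:
        return NEVER_REACHED
    lo, hi = 1, _MAX_SEARCH_BP  # predict(lo) >= threshold > predict(hi)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fit.predict(mid) < threshold:
            hi = mid
        else:
            lo = mid
    return hi
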