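"""Small-world indices, summary averages, degree-distribution fit, hubs.

The small-world character of a network is quantified against its
degree-matched nulls by ``gamma = Cp / Cp_rand`` (clustering ratio),
``lambda = Lp / Lp_rand`` (path-length ratio) and their quotient
``sigma = gamma / lambda``; ``sigma > 1`` marks small-world
organization.  Threshold sweeps are summarized by geometric means.  The
degree distribution is fitted as a power law ``p(k) ~ c k^-gamma`` —
note the field reuses the symbol gamma for this decay exponent, a
different quantity from the clustering ratio — and hub nodes are those
whose degree exceeds the mean by more than one standard deviation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SmallWorldIndices",
    "DegreeFit",
    "small_world_indices",
    "geometric_mean",
    "degree_distribution",
    "fit_power_law",
    "hub_mask",
]


@dataclass(frozen=True)
class SmallWorldIndices:
    gamma: float
    lam: float
    sigma: float


@dataclass
class DegreeFit:
    """Power-law fit p(k) = c * k^-exponent of a degree distribution."""

    exponent: float
    prefactor: float
    k_values: np.ndarray
    pk: np.ndarray
    method: str = "ols"


def small_world_indices(cp: float, cp_rand: float, lp: float, lp_rand: float
                        ) -> SmallWorldIndices:
    """Exact ratios gamma = Cp/Cp_rand, lambda = Lp/Lp_rand, sigma = gamma/lambda."""
    for name, v in (("Cp", cp), ("Cp_rand", cp_rand), ("Lp", lp), ("Lp_rand", lp_rand)):
        if not v > 0:
            raise ValueError(f"{name} must be positive, got {v}")
    gamma = cp / cp_rand
    lam = lp / lp_rand
    return SmallWorldIndices(gamma=gamma, lam=lam, sigma=gamma / lam)


def geometric_mean(values) -> float:
    """exp(mean(ln v)) of strictly positive values."""
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("need at least one value")
    if np.any(v <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    return float(np.exp(np.mean(np.log(v))))


def degree_distribution(degrees):
    """Empirical pdf of node degree over observed degrees k >= 1.

    Returns ``(k_support, p)`` with ``p[k]`` the fraction of **all**
    nodes having that degree; isolated nodes contribute to the
    denominator but not to the support, so ``sum(p)`` equals the
    fraction of non-isolated nodes.
    """
    degrees = np.asarray(degrees, dtype=np.int64)
    if degrees.size == 0:
        raise ValueError("need at least one node")
    ks, counts = np.unique(degrees[degrees >= 1], return_counts=True)
    if ks.size == 0:
        warnings.warn("all nodes are isolated; degree distribution is empty",
                      RuntimeWarning, stacklevel=2)
    return ks, counts / degrees.size


def fit_power_law(k_values, pk, method: str = "ols") -> DegreeFit:
    """Fit ``p(k) = c k^-exponent`` to a binned degree pdf.

    The default fits by ordinary least squares of log10 p(k) on log10 k
    over the k >= 1 support with zero-count bins dropped — the
    log-log-plot convention.  ``method="mle"`` instead maximizes the
    discrete (zeta-normalized) power-law likelihood, which is the
    statistically preferred estimator; both are exposed because binned
    OLS is known to bias the exponent.  The exponent is reported as the
    positive decay rate.
    """
    k = np.asarray(k_values, dtype=np.float64)
    p = np.asarray(pk, dtype=np.float64)
    keep = (k >= 1) & (p > 0)
    k, p = k[keep], p[keep]
    if k.size < 3:
        raise ValueError("need at least 3 nonzero support points to fit")
    if method == "ols":
        slope, intercept = np.polyfit(np.log10(k), np.log10(p), 1)
        return DegreeFit(exponent=float(-slope), prefactor=float(10.0 ** intercept),
                         k_values=k, pk=p, method="ols")
    if method == "mle":
        from scipy.optimize import minimize_scalar
        from scipy.special import zeta

        # weights = node fractions; discrete power law on k >= kmin = min support
        kmin = k.min()
        w = p / p.sum()
        mean_log = float((w * np.log(k)).sum())

        def nll(alpha):
            if alpha <= 1.0:
                return np.inf
            return alpha * mean_log + math.log(zeta(alpha, kmin))

        res = minimize_scalar(nll, bounds=(1.0 + 1e-6, 20.0), method="bounded")
        alpha = float(res.x)
        return DegreeFit(exponent=alpha, prefactor=float(1.0 / zeta(alpha, kmin)),
                         k_values=k, pk=p, method="mle")
    raise ValueError(f"unknown fitting method {method!r}")


def hub_mask(degrees) -> np.ndarray:
    """Flag nodes whose degree exceeds mean(k) + sd(k) (sample sd)."""
    degrees = np.asarray(degrees, dtype=np.float64)
    if degrees.size < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    threshold = degrees.mean() + degrees.std(ddof=1)
    return degrees > threshold
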