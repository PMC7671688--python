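"""Shared statistical kernels.

Pure, deterministic helpers used across the pipeline: adjusted R²,
Fisher transforms, partial correlation, and the Meng–Rosenthal–Rubin test
for comparing two dependent correlations that share one variable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "adjusted_r2",
    "fisher_z",
    "inverse_fisher_z",
    "partial_correlation",
    "compare_dependent_correlations",
    "CorrelationComparison",
]


def adjusted_r2(r2, n: int, p_params: int):
    """Adjusted coefficient of determination.

    ``1 - (1 - R^2) * (n - 1) / (n - p_params - 1)`` where ``p_params`` is
    the number of model parameters excluding the intercept.
    """
    r2 = np.asarray(r2, dtype=float)
    if n <= p_params + 1:
        raise ValueError(
            f"adjusted R^2 requires n > p_params + 1 (got n={n}, p_params={p_params})"
        )
    out = 1.0 - (1.0 - r2) * (n - 1) / (n - p_params - 1)
    return float(out) if out.ndim == 0 else out


def fisher_z(r):
    """Fisher r-to-z transform, arctanh(r)."""
    return np.arctanh(r)


def inverse_fisher_z(z):
    return np.tanh(z)


def partial_correlation(x, y, covariates=None) -> float:
    """Correlation of ``x`` and ``y`` after removing ``covariates`` from both.

    Covariates are removed by ordinary least squares (with intercept); the
    residuals are then correlated. With no covariates this reduces to the
    plain product-moment correlation.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    n = x.size
    if y.size != n:
        raise ValueError("x and y must have equal length")
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return float(np.corrcoef(x, y)[0, 1])
    c = np.asarray(covariates, dtype=float)
    if c.ndim == 1:
        c = c[:, None]
    if c.shape[0] != n:
        raise ValueError("covariates must have one row per observation")
    if n <= c.shape[1] + 2:
        raise ValueError("too few observations for the number of covariates")
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    beta, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ beta
    sd = resid.std(axis=0)
    raw_sd = np.column_stack([x, y]).std(axis=0)
    if np.any(sd <= 1e-10 * np.maximum(raw_sd, 1e-30)):
        raise ValueError("zero residual variance; partial correlation undefined")
    return float(np.corrcoef(resid[:, 0], resid[:, 1])[0, 1])


@dataclass
class CorrelationComparison:
    """Result of comparing two correlations sharing one variable."""

    r_common_a: float
    r_common_b: float
    r_ab: float
    n: int
    z: float
    p: float


def compare_dependent_correlations(
    r_common_a: float,
    r_common_b: float,
    r_ab: float,
    n: int,
    alternative: str = "two-sided",
) -> CorrelationComparison:
    """Meng–Rosenthal–Rubin z-test for two overlapping correlations.

    ``r_common_a`` and ``r_common_b`` are the correlations of variables a
    and b with one shared variable; ``r_ab`` is the correlation between a
    and b. The statistic is antisymmetric in (a, b).
    """
    for name, r in (("r_common_a", r_common_a), ("r_common_b", r_common_b),
                    ("r_ab", r_ab)):
        if not np.isfinite(r) or abs(r) > 1:
            raise ValueError(f"{name} must be a finite correlation in [-1, 1]")
    if abs(r_common_a) == 1 or abs(r_common_b) == 1:
        raise ValueError("|r| = 1 input; Fisher transform diverges")
    if n < 10:
        raise ValueError("n must be at least 10")
    z_a = fisher_z(r_common_a)
    z_b = fisher_z(r_common_b)
    r2_bar = (r_common_a**2 + r_common_b**2) / 2.0
    f = (1.0 - r_ab) / (2.0 * (1.0 - r2_bar))
    f = min(f, 1.0)
    h = (1.0 - f * r2_bar) / (1.0 - r2_bar)
    z = (z_a - z_b) * np.sqrt((n - 3) / (2.0 * (1.0 - r_ab) * h))
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "greater":
        p = float(sps.norm.sf(z))
    elif alternative == "less":
        p = float(sps.norm.cdf(z))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(float(p), 1.0)
    return CorrelationComparison(
        r_common_a=float(r_common_a),
        r_common_b=float(r_common_b),
        r_ab=float(r_ab),
        n=int(n),
        z=float(z),
        p=p,
    )
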