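"""Cytoarchitectural gradient extraction and axis modelling.

Microstructure profile covariance (partial correlation of depth profiles
controlling for the dataset-mean profile), diffusion map embedding of the
resulting affinity, polynomial model selection against the geometric axis,
and per-coronal-slice goodness-of-fit tables.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .stats import adjusted_r2

__all__ = [
    "AffinityMatrix",
    "Embedding",
    "mpc_matrix",
    "diffusion_embedding",
    "select_polynomial",
    "PolynomialSelection",
    "per_slice_fits",
]


@dataclass
class AffinityMatrix:
    matrix: np.ndarray
    method: str
    sparsity: float | None = None


@dataclass
class Embedding:
    """Diffusion-map eigenvectors with their eigenvalues.

    ``variance_explained[i] = eigenvalue_i / sum(eigenvalues)`` over the
    retained non-trivial spectrum. ``aligned`` records whether eigenvector
    signs were flipped to correlate positively with a reference axis.
    """

    vectors: np.ndarray
    eigenvalues: np.ndarray
    variance_explained: np.ndarray
    aligned: bool = False

    def align_to(self, reference: np.ndarray) -> "Embedding":
        ref = np.asarray(reference, dtype=float)
        for j in range(self.vectors.shape[1]):
            if np.corrcoef(self.vectors[:, j], ref)[0, 1] < 0:
                self.vectors[:, j] *= -1
        self.aligned = True
        return self


def mpc_matrix(profiles, mode: str = "partial") -> AffinityMatrix:
    """Microstructure profile covariance between all vertices.

    ``partial`` (default): pairwise partial correlation of depth profiles
    controlling for the dataset-mean profile, Fisher r-to-z transformed,
    negatives set to zero, zero diagonal. ``covariance``: plain profile
    covariance, negatives zeroed.
    """
    intens = profiles.intensities if hasattr(profiles, "intensities") \
        else np.asarray(profiles, dtype=float)
    n_vert, n_depth = intens.shape
    if n_vert < 3:
        raise ValueError("need at least 3 vertices")
    if n_depth < 4:
        raise ValueError("need at least 4 depths")
    sd = intens.std(axis=1)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(
            f"constant profiles make correlations undefined; rows "
            f"{constant[:10].tolist()}"
        )
    if mode == "covariance":
        m = np.cov(intens)
        np.fill_diagonal(m, 0.0)
        m[m < 0] = 0.0
        return AffinityMatrix(matrix=m, method="covariance")
    if mode != "partial":
        raise ValueError(f"unknown MPC mode {mode!r}")
    mean_profile = intens.mean(axis=0)
    stack = np.vstack([intens, mean_profile])
    r = np.corrcoef(stack)
    rij = r[:n_vert, :n_vert]
    rim = r[:n_vert, n_vert]
    denom = np.sqrt(np.maximum(1.0 - rim**2, 1e-15))
    partial = (rij - np.outer(rim, rim)) / np.outer(denom, denom)
    np.fill_diagonal(partial, 0.0)
    partial = np.clip(partial, -1 + 1e-12, 1 - 1e-12)
    z = np.arctanh(partial)
    z[z < 0] = 0.0
    z = 0.5 * (z + z.T)
    np.fill_diagonal(z, 0.0)
    return AffinityMatrix(matrix=z, method="partial-correlation r-to-z")


def _row_sparsify(matrix: np.ndarray, sparsity: float) -> np.ndarray:
    """Keep the top (1 - sparsity) entries per row, then re-symmetrize."""
    if not 0.0 <= sparsity < 1.0:
        raise ValueError("sparsity must lie in [0, 1)")
    n = matrix.shape[0]
    keep = max(1, int(np.ceil((1.0 - sparsity) * (n - 1))))
    out = np.zeros_like(matrix)
    order = np.argsort(matrix, axis=1)
    for i in range(n):
        top = order[i, -keep:]
        out[i, top] = matrix[i, top]
    return 0.5 * (out + out.T)


def diffusion_embedding(
    affinity,
    n_components: int = 10,
    alpha: float = 0.5,
    sparsity: float = 0.9,
    diffusion_time: float = 0.0,
) -> Embedding:
    """Diffusion map embedding of a symmetric non-negative affinity.

    Applies row-wise sparsification, anisotropic normalization with
    parameter ``alpha``, and eigendecomposition of the diffusion operator;
    the trivial constant eigenvector is dropped.
    """
    w = affinity.matrix if isinstance(affinity, AffinityMatrix) else \
        np.asarray(affinity, dtype=float)
    if w.shape[0] != w.shape[1]:
        raise ValueError("affinity must be square")
    if np.max(np.abs(w - w.T)) > 1e-10:
        raise ValueError("affinity must be symmetric")
    if np.min(w) < 0:
        raise ValueError("affinity must be non-negative")
    n = w.shape[0]
    if sparsity > 0:
        w = _row_sparsify(w, sparsity)
    n_comp_graph, _ = connected_components(csr_matrix(w > 0), directed=False)
    if n_comp_graph > 1:
        raise ValueError(
            f"affinity graph is disconnected after sparsification "
            f"({n_comp_graph} components); lower the sparsity"
        )
    d = w.sum(axis=1)
    d_alpha = np.power(d, -alpha)
    w1 = w * np.outer(d_alpha, d_alpha)
    d1 = w1.sum(axis=1)
    d1_inv_sqrt = 1.0 / np.sqrt(d1)
    m = w1 * np.outer(d1_inv_sqrt, d1_inv_sqrt)
    m = 0.5 * (m + m.T)
    k = min(n_components + 1, n - 1)
    eigval, eigvec = np.linalg.eigh(m)
    order = np.argsort(eigval)[::-1][:k + 1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    psi = eigvec * d1_inv_sqrt[:, None]
    # drop the trivial (constant) leading eigenvector
    lambdas = eigval[1:k]
    vectors = psi[:, 1:k]
    if diffusion_time > 0:
        vectors = vectors * np.power(lambdas, diffusion_time)[None, :]
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            scale = lambdas / (1.0 - lambdas)
        vectors = vectors * scale[None, :]
    norms = np.linalg.norm(vectors, axis=0)
    lam_pos = np.maximum(lambdas, 0.0)
    variance = lam_pos / lam_pos.sum() if lam_pos.sum() > 0 else lam_pos
    vectors = vectors / np.where(norms > 0, norms, 1.0)[None, :]
    take = min(n_components, vectors.shape[1])
    return Embedding(
        vectors=vectors[:, :take],
        eigenvalues=lambdas[:take],
        variance_explained=variance[:take],
    )


@dataclass
class PolynomialSelection:
    degree: int
    adjusted_r2: dict[int, float]
    residuals: np.ndarray
    coefficients: np.ndarray


def _poly_adjusted_r2(x: np.ndarray, y: np.ndarray, degree: int):
    coeffs = np.polynomial.polynomial.polyfit(x, y, degree)
    fit = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(np.sum((y - fit) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return adjusted_r2(r2, len(x), degree), coeffs, y - fit


def select_polynomial(x, y, degrees=range(1, 6),
                      tol: float = 1e-9) -> PolynomialSelection:
    """Fit polynomials of increasing degree and pick the elbow.

    The selected degree is the lowest degree whose adjusted R² is within
    ``tol`` of the best, unless gains keep accruing: formally, if the
    lowest degree d with adj R²(d) >= max - tol is the smallest candidate
    it is returned directly (parsimony); otherwise the degree with the
    maximum backward second difference of the adjusted-R² sequence is
    selected (ties to the lowest degree).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in input")
    degrees = sorted(int(d) for d in degrees)
    if x.size < degrees[-1] + 2:
        raise ValueError(
            f"need at least degree+2 = {degrees[-1] + 2} points, got {x.size}"
        )
    table: dict[int, float] = {}
    fits: dict[int, tuple] = {}
    for d in degrees:
        a, coeffs, resid = _poly_adjusted_r2(x, y, d)
        table[d] = a
        fits[d] = (coeffs, resid)
    values = np.array([table[d] for d in degrees])
    best = values.max()
    near = [d for d, v in zip(degrees, values) if v >= best - tol]
    if near and near[0] <= degrees[0]:
        chosen = near[0]
    else:
        # backward second difference a(d) - 2 a(d-1) + a(d-2)
        scores = {}
        for i, d in enumerate(degrees):
            if i >= 2:
                scores[d] = values[i] - 2 * values[i - 1] + values[i - 2]
        chosen = max(scores, key=lambda d: (scores[d], -d)) if scores else degrees[0]
    coeffs, resid = fits[chosen]
    return PolynomialSelection(
        degree=chosen,
        adjusted_r2=table,
        residuals=resid,
        coefficients=coeffs,
    )


def per_slice_fits(features: pd.DataFrame, axis_mm, ap_mm,
                   slice_width_mm: float = 1.0, degree: int = 3):
    """Adjusted R² of a per-slice polynomial fit of each feature vs axis.

    The anterior-posterior extent is divided into consecutive slices of
    ``slice_width_mm``; slices with fewer than degree+2 vertices are
    skipped with a warning. Returns (per-slice table, per-feature summary).
    """
    axis_mm = np.asarray(axis_mm, dtype=float)
    ap_mm = np.asarray(ap_mm, dtype=float)
    if isinstance(features, pd.Series):
        features = features.to_frame()
    if not isinstance(features, pd.DataFrame):
        features = pd.DataFrame(np.asarray(features))
    edges = np.arange(ap_mm.min(), ap_mm.max() + slice_width_mm, slice_width_mm)
    if len(edges) < 2:
        edges = np.array([ap_mm.min(), ap_mm.min() + slice_width_mm])
    rows = []
    skipped = 0
    for s in range(len(edges) - 1):
        lo, hi = edges[s], edges[s + 1]
        last = s == len(edges) - 2
        mask = (ap_mm >= lo) & ((ap_mm <= hi) if last else (ap_mm < hi))
        if int(mask.sum()) < degree + 2:
            skipped += 1
            continue
        for col in features.columns:
            a, _, _ = _poly_adjusted_r2(axis_mm[mask],
                                        features[col].to_numpy(float)[mask],
                                        degree)
            rows.append({"slice": s, "ap_lo": lo, "ap_hi": hi,
                         "n_vertices": int(mask.sum()),
                         "feature": col, "adjusted_r2": a})
    if skipped:
        warnings.warn(f"skipped {skipped} slices with fewer than {degree + 2} vertices")
    if not rows:
        raise ValueError("no slice had enough vertices for the fit")
    table = pd.DataFrame(rows)
    summary = table.groupby("feature")["adjusted_r2"].agg(["mean", "std", "count"])
    return table, summary
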