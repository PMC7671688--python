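"""MTL axes versus macroscale functional organisation.

Voxelwise connectivity r-maps along an MTL axis, normalized-angle
functional gradient decomposition of a parcel connectome, spin-permutation
inference on spherical parcel centroids, specificity contrasts, and SNR /
temporal-lobe sensitivity analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation
from scipy.stats import spearmanr

from .cytoarch import Embedding, diffusion_embedding
from .stats import compare_dependent_correlations, partial_correlation

__all__ = [
    "ParcelConnectome",
    "AxisCorrelationMap",
    "axis_fc_map",
    "functional_gradients",
    "normalized_angle",
    "spin_permutation",
    "map_gradient_correspondence",
    "CorrespondenceResult",
    "snr_controls",
    "exclude_temporal_lobe",
    "group_connectome",
]


@dataclass
class ParcelConnectome:
    """Parcel-parcel correlation matrix with spherical centroids."""

    matrix: np.ndarray
    centroids: np.ndarray | None = None
    community: np.ndarray | None = None
    temporal_lobe: np.ndarray | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape[0] != m.shape[1]:
            raise ValueError("connectome must be square")
        if np.max(np.abs(m - m.T)) > 1e-8:
            raise ValueError("connectome must be symmetric")
        self.matrix = m
        if self.centroids is not None:
            c = np.asarray(self.centroids, dtype=float)
            norms = np.linalg.norm(c, axis=1, keepdims=True)
            self.centroids = c / norms


@dataclass
class AxisCorrelationMap:
    """Per-parcel correlation of MTL voxel connectivity with an axis.

    Positive values reflect higher connectivity towards the allocortical
    (high-axis) end.
    """

    r: np.ndarray
    axis_name: str = "iso-to-allocortical"
    extra: dict = field(default_factory=dict)


def group_connectome(subject_matrices) -> np.ndarray:
    """Fisher-z mean of subject correlation matrices, unit diagonal."""
    z = [np.arctanh(np.clip(m, -0.999999, 0.999999)) for m in subject_matrices]
    out = np.tanh(np.mean(z, axis=0))
    np.fill_diagonal(out, 1.0)
    return out


def _columnwise_corr(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """corr(a[:, j], b) for every column j; returns one r per column."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean()
    asd = a0.std(axis=0)
    bsd = b0.std()
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a0 * b0[:, None]).mean(axis=0) / (asd * bsd)
    return r


def axis_fc_map(voxel_ts: np.ndarray, voxel_axis: np.ndarray,
                parcel_ts: np.ndarray,
                axis_name: str = "iso-to-allocortical",
                covariates: np.ndarray | None = None) -> AxisCorrelationMap:
    """Correlate voxel-to-parcel connectivity with voxel axis position.

    For every parcel, the connectivity of each MTL voxel to that parcel is
    correlated (across voxels) with the voxel's axis value; with
    ``covariates`` (n_voxels x k) a partial correlation is used instead.
    """
    voxel_ts = np.asarray(voxel_ts, dtype=float)
    parcel_ts = np.asarray(parcel_ts, dtype=float)
    voxel_axis = np.asarray(voxel_axis, dtype=float).ravel()
    if voxel_ts.shape[1] < 10:
        raise ValueError("need at least 10 MTL voxels")
    if voxel_ts.shape[0] != parcel_ts.shape[0]:
        raise ValueError("voxel and parcel timeseries must share the time axis")
    if voxel_ts.shape[1] != voxel_axis.size:
        raise ValueError("one axis value per voxel required")
    # voxel -> parcel connectivity (n_voxels x n_parcels)
    vz = voxel_ts - voxel_ts.mean(axis=0)
    pz = parcel_ts - parcel_ts.mean(axis=0)
    vs = vz.std(axis=0)
    ps = pz.std(axis=0)
    vs[vs == 0] = np.nan
    ps[ps == 0] = np.nan
    fc = (vz / vs).T @ (pz / ps) / voxel_ts.shape[0]
    if np.ptp(voxel_axis) == 0:
        warnings.warn("constant axis; r map undefined")
        return AxisCorrelationMap(r=np.full(parcel_ts.shape[1], np.nan),
                                 axis_name=axis_name)
    if covariates is None:
        r = _columnwise_corr(fc, voxel_axis)
    else:
        r = np.empty(fc.shape[1])
        for p in range(fc.shape[1]):
            col = fc[:, p]
            if not np.all(np.isfinite(col)) or np.ptp(col) == 0:
                r[p] = np.nan
                continue
            r[p] = partial_correlation(col, voxel_axis, covariates)
    bad = ~np.isfinite(r)
    if np.any(bad) and covariates is None:
        warnings.warn(f"{int(bad.sum())} parcels with undefined r (sentinel NaN)")
    return AxisCorrelationMap(r=r, axis_name=axis_name, extra={"fc": fc})


def normalized_angle(r_matrix: np.ndarray) -> np.ndarray:
    """Affinity a_ij = 1 - arccos(r_ij) / pi. Requires r in [-1, 1]."""
    r = np.asarray(r_matrix, dtype=float)
    if np.any(r > 1 + 1e-12) or np.any(r < -1 - 1e-12):
        raise ValueError("correlations outside [-1, 1]")
    return 1.0 - np.arccos(np.clip(r, -1.0, 1.0)) / np.pi


def functional_gradients(connectome: ParcelConnectome, k: int = 3,
                         alpha: float = 0.5, sparsity: float = 0.9) -> Embedding:
    """Diffusion-map gradients of the normalized-angle connectome affinity."""
    angle = normalized_angle(connectome.matrix)
    np.fill_diagonal(angle, 0.0)
    emb = diffusion_embedding(angle, n_components=k, alpha=alpha,
                              sparsity=sparsity)
    return emb


def spin_permutation(centroids: np.ndarray, values: np.ndarray,
                     n_spins: int, seed: int = 0) -> np.ndarray:
    """Null maps from uniform random rotations of spherical centroids.

    Each spin rotates the centroid cloud and reassigns every parcel the
    value of its nearest rotated centroid; returns (n_spins, n_parcels).
    """
    c = np.asarray(centroids, dtype=float)
    values = np.asarray(values, dtype=float)
    if c.ndim != 2 or c.shape[1] != 3:
        raise ValueError("centroids must be (n, 3)")
    norms = np.linalg.norm(c, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise ValueError("zero-length centroid")
    c = c / norms
    if np.linalg.matrix_rank(c - c.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) centroids; spins are meaningless")
    rng = np.random.default_rng(seed)
    out = np.empty((n_spins, c.shape[0]))
    for s in range(n_spins):
        rot = Rotation.random(rng=rng).as_matrix()
        rotated = c @ rot.T
        # parcel p inherits the value of the nearest rotated centroid
        _, idx = cKDTree(rotated).query(c)
        out[s] = values[idx]
    return out


@dataclass
class CorrespondenceResult:
    rho: np.ndarray                  # observed Spearman rho per gradient
    p_spin: np.ndarray
    null_rho: np.ndarray             # (n_spins, n_gradients)
    specificity: pd.DataFrame        # pairwise dependent-correlation contrasts


def map_gradient_correspondence(cmap: AxisCorrelationMap,
                                gradients: np.ndarray,
                                centroids: np.ndarray,
                                n_spins: int = 1000,
                                seed: int = 0,
                                two_sided: bool = True) -> CorrespondenceResult:
    """Spearman correspondence of an r map with functional gradients.

    Significance comes from spin permutations of the r map
    (p = (1 + #{|rho_null| >= |rho_obs|}) / (n_spins + 1)); specificity
    from pairwise dependent-correlation z-tests between gradients.
    """
    if centroids is None:
        raise ValueError("parcel centroids are required for spin tests")
    if n_spins < 100:
        warnings.warn(f"n_spins={n_spins} is low; p-values will be coarse")
    g = np.asarray(gradients, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    values = np.asarray(cmap.r, dtype=float)
    finite = np.isfinite(values)
    if not np.all(finite):
        warnings.warn("dropping parcels with undefined r from correspondence")
    rho = np.array([
        spearmanr(values[finite], g[finite, j]).statistic
        for j in range(g.shape[1])
    ])
    nulls = spin_permutation(np.asarray(centroids)[finite], values[finite],
                             n_spins, seed=seed)
    from scipy.stats import rankdata

    ranks_g = rankdata(g[finite], axis=0).astype(float)
    ranks_n = rankdata(nulls, axis=1).astype(float)
    rg = ranks_g - ranks_g.mean(axis=0)
    rn = ranks_n - ranks_n.mean(axis=1, keepdims=True)
    denom = np.sqrt((rn**2).sum(axis=1))[:, None] * np.sqrt((rg**2).sum(axis=0))[None, :]
    null_rho = (rn @ rg) / denom
    if two_sided:
        exceed = np.abs(null_rho) >= np.abs(rho)[None, :]
    else:
        exceed = null_rho >= rho[None, :]
    p_spin = (1.0 + exceed.sum(axis=0)) / (n_spins + 1.0)
    rows = []
    n_eff = int(finite.sum())
    for a in range(g.shape[1]):
        for b in range(a + 1, g.shape[1]):
            r_ab = spearmanr(g[finite, a], g[finite, b]).statistic
            clip = 1.0 - 1e-12
            comp = compare_dependent_correlations(
                float(np.clip(rho[a], -clip, clip)),
                float(np.clip(rho[b], -clip, clip)),
                float(np.clip(r_ab, -clip, clip)), n_eff)
            rows.append({"gradient_a": a + 1, "gradient_b": b + 1,
                         "z": comp.z, "p": comp.p})
    return CorrespondenceResult(
        rho=rho, p_spin=p_spin, null_rho=null_rho,
        specificity=pd.DataFrame(rows),
    )


def snr_maps(voxel_ts_raw: np.ndarray,
             grey_matter_ts: np.ndarray | None = None):
    """Spatial and temporal SNR per voxel from non-demeaned series.

    Spatial SNR: voxel mean signal divided by the SD of mean signal across
    grey-matter voxels. Temporal SNR: voxel mean divided by that voxel's
    temporal SD (NaN sentinel where the temporal SD is zero).
    """
    x = np.asarray(voxel_ts_raw, dtype=float)
    mean = x.mean(axis=0)
    gm = x if grey_matter_ts is None else np.asarray(grey_matter_ts, float)
    spatial_sd = gm.mean(axis=0).std()
    spatial = mean / spatial_sd if spatial_sd > 0 else np.full_like(mean, np.nan)
    tsd = x.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        temporal = np.where(tsd > 0, mean / tsd, np.nan)
    if np.any(tsd == 0):
        warnings.warn("zero temporal SD voxels: temporal SNR set to NaN")
    return spatial, temporal


def snr_controls(voxel_ts: np.ndarray, voxel_ts_raw: np.ndarray,
                 voxel_axis: np.ndarray, parcel_ts: np.ndarray,
                 grey_matter_ts: np.ndarray | None = None,
                 axis_name: str = "iso-to-allocortical") -> dict:
    """Recompute the axis r map partialling out spatial and temporal SNR.

    Returns the original and the two controlled maps plus the
    product-moment correlation between each controlled map and the
    original.
    """
    spatial, temporal = snr_maps(voxel_ts_raw, grey_matter_ts)
    original = axis_fc_map(voxel_ts, voxel_axis, parcel_ts, axis_name=axis_name)
    out = {"original": original, "spatial_snr": spatial,
           "temporal_snr": temporal}
    for name, snr in (("spatial", spatial), ("temporal", temporal)):
        ok = np.isfinite(snr)
        controlled = axis_fc_map(voxel_ts[:, ok], voxel_axis[ok], parcel_ts,
                                 axis_name=axis_name,
                                 covariates=snr[ok][:, None])
        finite = np.isfinite(original.r) & np.isfinite(controlled.r)
        out[f"controlled_{name}"] = controlled
        out[f"r_original_vs_{name}"] = float(
            np.corrcoef(original.r[finite], controlled.r[finite])[0, 1]
        )
    return out


def exclude_temporal_lobe(cmap: AxisCorrelationMap, gradients: np.ndarray,
                          centroids: np.ndarray, temporal_flags: np.ndarray,
                          n_spins: int = 1000, seed: int = 0):
    """Correspondence statistics recomputed without temporal-lobe parcels."""
    flags = np.asarray(temporal_flags, dtype=bool)
    keep = ~flags
    n_kept = int(keep.sum())
    if n_kept < 50:
        warnings.warn(f"only {n_kept} parcels retained after exclusion")
    sub = AxisCorrelationMap(r=np.asarray(cmap.r)[keep],
                             axis_name=cmap.axis_name)
    g = np.asarray(gradients, dtype=float)
    if g.ndim == 1:
        g = g[:, None]
    result = map_gradient_correspondence(sub, g[keep],
                                         np.asarray(centroids)[keep],
                                         n_spins=n_spins, seed=seed)
    return result, n_kept
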