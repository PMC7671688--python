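"""Equivolumetric intracortical surfaces and depth-wise profile sampling."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .mesh import vertex_onering_areas
from .surfaces import ConfluenceModel

__all__ = [
    "DepthSurfaceSet",
    "ProfileMatrix",
    "equivolumetric_fractions",
    "equivolumetric_surfaces",
    "sample_profiles",
    "central_moments",
    "depth_percent_names",
]


@dataclass
class DepthSurfaceSet:
    """Vertex positions of n_surfaces depth surfaces, inner to outer."""

    coordinates: np.ndarray       # (n_surfaces, n_vertices, 3)
    depth_fractions: np.ndarray   # nominal alpha_k in [0, 1]

    @property
    def n_surfaces(self) -> int:
        return self.coordinates.shape[0]


@dataclass
class ProfileMatrix:
    """Vertex-by-depth intensity table plus vertex metadata."""

    intensities: np.ndarray       # (n_vertices, n_depths)
    axis_mm: np.ndarray
    ap_mm: np.ndarray
    subregion: np.ndarray | None = None

    @property
    def n_vertices(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_depths(self) -> int:
        return self.intensities.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = {f"i{k + 1:02d}": self.intensities[:, k]
                for k in range(self.n_depths)}
        frame = pd.DataFrame({"axis_mm": self.axis_mm, "ap_mm": self.ap_mm, **cols})
        if self.subregion is not None:
            frame.insert(2, "subregion", self.subregion)
        return frame


def equivolumetric_fractions(alpha, area_inner, area_outer) -> np.ndarray:
    """Position fraction rho along inner->outer enclosing volume fraction alpha.

    Uses the tapered-frustum model in which the cross-section scales
    linearly between the local inner and outer surface areas, so the
    enclosed volume between depth surfaces is exactly equal. Degenerate
    (zero or equal) local areas fall back to the equidistant rho = alpha.
    """
    alpha = np.asarray(alpha, dtype=float)
    a = np.sqrt(np.maximum(np.asarray(area_inner, dtype=float), 0.0))
    b = np.sqrt(np.maximum(np.asarray(area_outer, dtype=float), 0.0))
    a, b = np.broadcast_arrays(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.cbrt(a**3 + alpha * (b**3 - a**3)) - a
        rho = num / (b - a)
    degenerate = (a <= 0) | (b <= 0) | np.isclose(a, b, rtol=1e-8)
    rho = np.where(degenerate, alpha, rho)
    return rho


def equivolumetric_surfaces(model: ConfluenceModel,
                            n_surfaces: int = 16) -> DepthSurfaceSet:
    """Depth surfaces between the inner and outer confluent surfaces.

    Surface 1 is exactly the inner surface and surface ``n_surfaces``
    exactly the outer; intermediate surfaces are placed equivolumetrically
    using the one-ring areas of the two bounding surfaces.
    """
    if n_surfaces < 2:
        raise ValueError("need at least the inner and outer surfaces")
    a_in = vertex_onering_areas(model.inner)
    a_out = vertex_onering_areas(model.outer)
    zero = (a_in <= 0) | (a_out <= 0)
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} vertices have a zero one-ring area; using "
            "equidistant depths there"
        )
    alphas = np.linspace(0.0, 1.0, n_surfaces)
    coords = np.empty((n_surfaces, model.n_vertices, 3))
    delta = model.outer.vertices - model.inner.vertices
    for k, alpha in enumerate(alphas):
        rho = equivolumetric_fractions(alpha, a_in, a_out)
        coords[k] = model.inner.vertices + rho[:, None] * delta
    coords[0] = model.inner.vertices
    coords[-1] = model.outer.vertices
    return DepthSurfaceSet(coordinates=coords, depth_fractions=alphas)


def depth_percent_names(n_surfaces: int = 16) -> list[str]:
    """Feature names carrying the nominal initialisation depth percentage."""
    alphas = np.linspace(0.0, 1.0, n_surfaces)
    return [f"depth_{round(100 * a):d}pct" for a in alphas]


def sample_profiles(volume: np.ndarray, affine: np.ndarray,
                    depth_set: DepthSurfaceSet, model: ConfluenceModel,
                    order: int = 1) -> ProfileMatrix:
    """Sample the volume at every depth point of every vertex.

    Interpolation is trilinear by default (``order=1``). Points outside the
    volume raise with the offending vertex and depth index.
    """
    inv = np.linalg.inv(affine)
    n_surf, n_vert, _ = depth_set.coordinates.shape
    pts = depth_set.coordinates.reshape(-1, 3)
    ijk = (pts @ inv[:3, :3].T) + inv[:3, 3]
    shape = np.asarray(volume.shape, dtype=float)
    bad = np.any((ijk < -0.5) | (ijk > shape - 0.5), axis=1)
    if np.any(bad):
        flat = int(np.flatnonzero(bad)[0])
        k, v = divmod(flat, n_vert)
        raise ValueError(
            f"depth point outside volume: vertex {v}, depth index {k}"
        )
    values = map_coordinates(volume, ijk.T, order=order, mode="nearest")
    intensities = values.reshape(n_surf, n_vert).T
    return ProfileMatrix(
        intensities=intensities,
        axis_mm=(model.axis_mm if model.axis_mm is not None
                 else np.full(n_vert, np.nan)),
        ap_mm=model.ap_mm.copy(),
        subregion=None if model.subregion is None else model.subregion.copy(),
    )


def central_moments(profiles, sentinel: float = np.nan):
    """Per-vertex mean, SD, skewness and kurtosis across depths.

    Uses population (biased) standardized moments: skewness is the third
    and kurtosis the fourth standardized moment (not excess). Zero-variance
    profiles get the sentinel for skewness and kurtosis, with a warning.
    """
    intens = profiles.intensities if isinstance(profiles, ProfileMatrix) \
        else np.asarray(profiles, dtype=float)
    if intens.ndim == 1:
        intens = intens[None, :]
    if intens.shape[1] < 4:
        raise ValueError("need at least 4 depth samples to compute 4 moments")
    mean = intens.mean(axis=1)
    dev = intens - mean[:, None]
    m2 = (dev**2).mean(axis=1)
    sd = np.sqrt(m2)
    flat = m2 == 0
    if np.any(flat):
        warnings.warn(
            f"{int(flat.sum())} constant profiles: skewness/kurtosis set to sentinel"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = (dev**3).mean(axis=1) / np.power(m2, 1.5)
        kurt = (dev**4).mean(axis=1) / np.power(m2, 2.0)
    skew = np.where(flat, sentinel, skew)
    kurt = np.where(flat, sentinel, kurt)
    return pd.DataFrame({"mean": mean, "sd": sd, "skewness": skew,
                         "kurtosis": kurt})
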