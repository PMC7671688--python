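"""Synthetic fixtures with analytic ground truth.

Every generator here emits, next to the data, the quantity a downstream
pipeline stage is supposed to recover: the arc-length axis of the toy
confluence, the programmed depth-profile skewness of the intensity volume,
the coupling matrix behind simulated timeseries, and the low-rank loadings
behind parcel connectivity. All generators are seed-deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import interp1d
from scipy.spatial import cKDTree
from scipy.special import sph_harm_y

from .labels import REGION_CODES, SUBFIELD_CODES
from .mesh import SurfaceMesh

__all__ = [
    "ToyConfluenceSpec",
    "ToyConfluence",
    "make_toy_confluence",
    "ProfileModel",
    "make_intensity_volume",
    "LinearDynamicsSpec",
    "simulate_linear_dynamics",
    "simulate_mar",
    "GradientParcelData",
    "make_gradient_parcel_data",
    "fibonacci_sphere",
    "sphere_pattern_basis",
    "smooth_sphere_map",
]

#: smallest in-rolling (radians) that still produces a usable infolding
MIN_CURL_TURNS = 0.5


# --------------------------------------------------------------------------
# toy confluent meshes
# --------------------------------------------------------------------------

@dataclass
class ToyConfluenceSpec:
    """Parameters of the toy iso/allocortical mesh pair.

    The geometry is a 2D coronal profile extruded along the anterior-
    posterior (y) direction: a straight isocortical ramp descends to the
    seam, continues as an overhang that passes above the allocortical
    sheet, which itself curls away from the seam as an Archimedean spiral.
    """

    n_iso_rows: int = 12
    n_allo_rows: int = 12
    n_columns: int = 8
    curl_turns: float = 4.7
    thickness_mm: float = 1.0
    ap_extent_mm: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_iso_rows", "n_allo_rows", "n_columns"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be at least 2")
        if self.thickness_mm <= 0:
            raise ValueError("thickness_mm must be positive")
        if self.ap_extent_mm <= 0:
            raise ValueError("ap_extent_mm must be positive")
        if self.curl_turns < MIN_CURL_TURNS:
            raise ValueError(
                f"curl_turns={self.curl_turns} gives no usable infolding; "
                f"need at least {MIN_CURL_TURNS} rad so the allocortical sheet "
                "actually curls under the isocortex"
            )


@dataclass
class ToyConfluence:
    """Toy meshes plus ground truth emitted by :func:`make_toy_confluence`."""

    spec: ToyConfluenceSpec
    iso_inner: SurfaceMesh
    iso_outer: SurfaceMesh
    allo_inner: SurfaceMesh
    allo_outer: SurfaceMesh
    #: signed arc-length axis per iso vertex (NaN on the overhang section)
    axis_iso: np.ndarray
    #: arc-length axis per allo vertex (0 at the seam row)
    axis_allo: np.ndarray
    #: allo vertex indices of the seam (bridgehead) row, sorted by y
    seam_vertices: np.ndarray
    #: expected matched iso vertex per seam vertex
    expected_matches: np.ndarray
    #: iso vertices that lie on the overhang (skip) section
    overhang_mask: np.ndarray
    #: dense 2D inner-curve samples used for intensity rasterization
    curve_points: np.ndarray = field(repr=False, default=None)
    curve_normals: np.ndarray = field(repr=False, default=None)
    curve_axis: np.ndarray = field(repr=False, default=None)
    axis_range: tuple[float, float] = (0.0, 1.0)

    def normalized_axis(self, axis_mm: np.ndarray) -> np.ndarray:
        lo, hi = self.axis_range
        return (np.asarray(axis_mm, dtype=float) - lo) / (hi - lo)


def _strip_triangles(n_rows: int, n_cols: int) -> np.ndarray:
    tris = []
    for r in range(n_rows - 1):
        for c in range(n_cols - 1):
            a = r * n_cols + c
            b = r * n_cols + c + 1
            d = (r + 1) * n_cols + c
            e = (r + 1) * n_cols + c + 1
            tris.append((a, b, d))
            tris.append((d, b, e))
    return np.asarray(tris, dtype=np.int64)


def _extrude(points2d, normals2d, y_values, offset):
    """Lift 2D (x, z) row positions into 3D row-major vertices."""
    n_rows = len(points2d)
    n_cols = len(y_values)
    verts = np.empty((n_rows * n_cols, 3))
    for r in range(n_rows):
        x = points2d[r, 0] + offset * normals2d[r, 0]
        z = points2d[r, 1] + offset * normals2d[r, 1]
        rows = slice(r * n_cols, (r + 1) * n_cols)
        verts[rows, 0] = x
        verts[rows, 1] = y_values
        verts[rows, 2] = z
    return verts


def _spiral_samples(curl: float, start_radius: float, shrink: float, n: int):
    """Clockwise Archimedean spiral starting at the origin.

    The spiral centre sits at (0, -start_radius); the curve starts at the
    origin heading in +x and winds down around the centre with linearly
    shrinking radius. Returns points, outward radial normals and cumulative
    arc length.
    """
    phi = np.linspace(0.0, curl, n)
    theta = np.pi / 2 - phi
    radius = start_radius * (1.0 - shrink * phi / curl)
    centre = np.array([0.0, -start_radius])
    pts = centre + radius[:, None] * np.column_stack([np.cos(theta), np.sin(theta)])
    normals = (pts - centre) / radius[:, None]
    seglen = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seglen)])
    return pts, normals, arc


def make_toy_confluence(spec: ToyConfluenceSpec) -> ToyConfluence:
    """Build the toy iso/allocortical surface pairs with ground truth.

    The isocortical sheet has a main ramp below the seam and an overhang
    section that lies geometrically above the curled allocortical sheet,
    mimicking the configuration in which a conventional isocortical surface
    passes over the allocortex. The ground-truth axis is signed arc length
    along the sheet: negative on the isocortical side of the seam, zero at
    the seam row, positive along the allocortical spiral. Overhang vertices
    carry NaN axis (they are meant to be removed during stitching).
    """
    spec.validate()
    th = spec.thickness_mm
    start_radius = 4.0 * th
    shrink = 0.45
    gap = 0.4 * th
    ramp_angle = 0.5          # descent of the main iso ramp, radians
    over_angle = 0.35         # climb of the overhang section, radians

    # allocortical spiral rows at equal arc length
    dense_pts, dense_normals, dense_arc = _spiral_samples(
        spec.curl_turns, start_radius, shrink, 4096
    )
    allo_len = dense_arc[-1]
    row_arc = np.linspace(0.0, allo_len, spec.n_allo_rows)
    fx = interp1d(dense_arc, dense_pts, axis=0)
    fn = interp1d(dense_arc, dense_normals, axis=0)
    allo_pts = fx(row_arc)
    allo_normals = fn(row_arc)
    allo_normals /= np.linalg.norm(allo_normals, axis=1, keepdims=True)

    # isocortical rows: main ramp (far end -> seam), then overhang
    n_over = 1 if spec.n_iso_rows >= 3 else 0
    n_main = spec.n_iso_rows - n_over
    main_len = 1.2 * allo_len
    ramp_dir = np.array([-np.cos(ramp_angle), -np.sin(ramp_angle)])
    over_dir = np.array([np.cos(over_angle), np.sin(over_angle)])
    u = np.linspace(gap + main_len, gap, n_main)   # far end first
    main_pts = u[:, None] * ramp_dir[None, :]
    main_norm = np.tile([ramp_dir[1], -ramp_dir[0]], (n_main, 1))
    over_step = 0.8 * start_radius
    w = over_step * np.arange(1, n_over + 1)
    over_pts = main_pts[-1] + w[:, None] * over_dir[None, :]
    over_norm = np.tile([-over_dir[1], over_dir[0]], (max(n_over, 1), 1))[:n_over]
    iso_pts = np.vstack([main_pts, over_pts])
    iso_normals = np.vstack([main_norm, over_norm])

    y_values = np.linspace(0.0, spec.ap_extent_mm, spec.n_columns)
    nc = spec.n_columns

    iso_inner_v = _extrude(iso_pts, iso_normals, y_values, 0.0)
    iso_outer_v = _extrude(iso_pts, iso_normals, y_values, th)
    allo_inner_v = _extrude(allo_pts, allo_normals, y_values, 0.0)
    allo_outer_v = _extrude(allo_pts, allo_normals, y_values, th)

    iso_tris = _strip_triangles(spec.n_iso_rows, nc)
    allo_tris = _strip_triangles(spec.n_allo_rows, nc)

    # per-vertex ground truth and scalar fields
    axis_iso_rows = np.concatenate([-u, np.full(n_over, np.nan)])
    axis_iso = np.repeat(axis_iso_rows, nc)
    axis_allo = np.repeat(row_arc, nc)
    overhang_mask = np.repeat(
        np.concatenate([np.zeros(n_main, bool), np.ones(n_over, bool)]), nc
    )

    # region labels: nearest-to-seam third entorhinal, then parahippocampal,
    # then fusiform; the overhang keeps the entorhinal label
    region_rows = np.empty(spec.n_iso_rows, dtype=np.int32)
    thirds = np.array_split(np.arange(n_main), 3)
    # rows are ordered far -> seam, so the last third is nearest the seam
    region_rows[thirds[0]] = REGION_CODES["fusiform"]
    region_rows[thirds[1]] = REGION_CODES["parahippocampal"]
    region_rows[thirds[2]] = REGION_CODES["entorhinal"]
    region_rows[n_main:] = REGION_CODES["entorhinal"]
    region = np.repeat(region_rows, nc)

    subfield_rows = np.empty(spec.n_allo_rows, dtype=np.int32)
    fifths = np.array_split(np.arange(spec.n_allo_rows), 5)
    for chunk, code in zip(fifths, SUBFIELD_CODES.values()):
        subfield_rows[chunk] = code
    subfield = np.repeat(subfield_rows, nc)

    ap_iso = np.tile(y_values, spec.n_iso_rows)
    ap_allo = np.tile(y_values, spec.n_allo_rows)
    pd_allo = axis_allo.copy()

    iso_scalars = {
        "region": region,
        "ap": ap_iso,
        "gt_axis": axis_iso,
        "overhang": overhang_mask.astype(np.int8),
    }
    allo_scalars = {
        "ap": ap_allo,
        "pd": pd_allo,
        "subfield": subfield,
        "gt_axis": axis_allo,
    }

    iso_inner = SurfaceMesh(iso_inner_v, iso_tris, dict(iso_scalars))
    iso_outer = SurfaceMesh(iso_outer_v, iso_tris, dict(iso_scalars))
    allo_inner = SurfaceMesh(
        allo_inner_v, allo_tris, {**allo_scalars, "io": np.zeros(len(allo_inner_v))}
    )
    allo_outer = SurfaceMesh(
        allo_outer_v, allo_tris, {**allo_scalars, "io": np.ones(len(allo_outer_v))}
    )

    # seam row = allo row 0; expected iso match = nearest sub-seam iso row,
    # i.e. the last main-ramp row at the same anterior-posterior position
    seam_vertices = np.arange(nc, dtype=np.int64)
    near_row = n_main - 1
    expected_matches = near_row * nc + np.arange(nc, dtype=np.int64)

    # dense inner curve (main ramp + spiral) for intensity rasterization
    n_dense_iso = 2048
    du = np.linspace(gap + main_len, gap, n_dense_iso)
    curve_iso = du[:, None] * ramp_dir[None, :]
    curve_iso_n = np.tile([ramp_dir[1], -ramp_dir[0]], (n_dense_iso, 1))
    curve_points = np.vstack([curve_iso, dense_pts])
    curve_normals = np.vstack([curve_iso_n, dense_normals])
    curve_axis_mm = np.concatenate([-du, dense_arc])
    lo, hi = -(gap + main_len), allo_len
    curve_axis = (curve_axis_mm - lo) / (hi - lo)

    return ToyConfluence(
        spec=spec,
        iso_inner=iso_inner,
        iso_outer=iso_outer,
        allo_inner=allo_inner,
        allo_outer=allo_outer,
        axis_iso=axis_iso,
        axis_allo=axis_allo,
        seam_vertices=seam_vertices,
        expected_matches=expected_matches,
        overhang_mask=overhang_mask,
        curve_points=curve_points,
        curve_normals=curve_normals,
        curve_axis=curve_axis,
        axis_range=(lo, hi),
    )


# --------------------------------------------------------------------------
# intensity volume with programmed depth-profile skewness
# --------------------------------------------------------------------------

def _population_skewness(values: np.ndarray, axis: int = -1) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=axis, keepdims=True)
    dev = values - mu
    m2 = (dev**2).mean(axis=axis)
    m3 = (dev**3).mean(axis=axis)
    return m3 / np.power(m2, 1.5)


@dataclass
class ProfileModel:
    """Continuous (axis, depth) intensity field with programmed skewness.

    The depth shape is ``exp(lam * z(depth))`` with
    ``z(d) = cos(2*pi*(d - peak_depth_fraction))``; ``lam`` is solved per
    axis position so the population skewness of the 16 reference depth
    samples equals ``skew_offset + skewness_slope * axis`` (axis normalized
    to [0, 1]). Intensities are strictly positive.
    """

    skewness_slope: float = 1.1
    peak_depth_fraction: float = 0.5
    baseline_intensity: float = 25.0
    noise_sd: float = 0.0
    skew_offset: float = 0.3
    amplitude: float = 6.0
    n_reference_depths: int = 16
    #: axis-independent sinusoidal drift of the peak depth along the
    #: anterior-posterior direction (in depth-fraction units); profile
    #: skewness is nearly invariant to it, single-depth intensities are not
    peak_drift: float = 0.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.peak_depth_fraction <= 1.0:
            raise ValueError("peak_depth_fraction must lie in [0, 1]")
        if self.baseline_intensity <= 0 or self.amplitude <= 0:
            raise ValueError("baseline_intensity and amplitude must be positive")
        self._build_inverse()

    def depth_shape(self, depth_frac, peak: float | None = None) -> np.ndarray:
        if peak is None:
            peak = self.peak_depth_fraction
        return np.cos(2.0 * np.pi * (np.asarray(depth_frac, dtype=float) - peak))

    def _reference_z(self) -> np.ndarray:
        d = np.linspace(0.0, 1.0, self.n_reference_depths)
        return self.depth_shape(d)

    def _build_inverse(self) -> None:
        z = self._reference_z()
        lam_grid = np.linspace(-12.0, 24.0, 3601)
        lam_grid[np.abs(lam_grid) < 1e-9] = 1e-6
        skews = _population_skewness(np.exp(lam_grid[:, None] * z[None, :]))
        # monotone increasing branch through lam ~ 0
        i0 = int(np.argmin(np.abs(lam_grid)))
        hi = i0
        while hi + 1 < len(lam_grid) and skews[hi + 1] > skews[hi]:
            hi += 1
        lo = i0
        while lo - 1 >= 0 and skews[lo - 1] < skews[lo]:
            lo -= 1
        self._lam_branch = lam_grid[lo:hi + 1]
        self._skew_branch = skews[lo:hi + 1]
        self._skew_min = float(self._skew_branch[0])
        self._skew_max = float(self._skew_branch[-1])
        # reference mean/SD of exp(lam * z) for per-axis standardization
        ref = np.exp(self._lam_branch[:, None] * z[None, :])
        self._ref_mean = ref.mean(axis=1)
        self._ref_sd = ref.std(axis=1)

    def achievable_skew_range(self) -> tuple[float, float]:
        return (self._skew_min, self._skew_max)

    def programmed_skewness(self, axis_norm) -> np.ndarray:
        """Target profile skewness at normalized axis position(s)."""
        return self.skew_offset + self.skewness_slope * np.asarray(
            axis_norm, dtype=float
        )

    def _lam_for_skew(self, target) -> np.ndarray:
        target = np.asarray(target, dtype=float)
        pad = 0.02 * (self._skew_max - self._skew_min)
        if np.any(target < self._skew_min + pad) or np.any(
            target > self._skew_max - pad
        ):
            raise ValueError(
                "programmed skewness outside the achievable range "
                f"[{self._skew_min + pad:.3f}, {self._skew_max - pad:.3f}]"
            )
        return np.interp(target, self._skew_branch, self._lam_branch)

    def lam_for_axis(self, axis_norm) -> np.ndarray:
        return self._lam_for_skew(self.programmed_skewness(axis_norm))

    def field(self, axis_norm, depth_frac, peak: float | None = None) -> np.ndarray:
        """Noise-free intensity at normalized axis / depth-fraction coords.

        The depth shape is standardized per axis position using the
        reference-grid mean and SD of ``exp(lam * z)``, so the profile mean
        and SD are axis-independent while skewness follows the programmed
        target (standardization is affine and skewness-invariant).
        """
        lam = np.asarray(self.lam_for_axis(axis_norm), dtype=float)
        z = self.depth_shape(depth_frac, peak=peak)
        val = np.exp(lam * z)
        m = np.interp(lam, self._lam_branch, self._ref_mean)
        s = np.interp(lam, self._lam_branch, self._ref_sd)
        return self.baseline_intensity + self.amplitude * (val - m) / s

    def profile(self, axis_norm: float, depth_fracs,
                peak: float | None = None) -> np.ndarray:
        """Noise-free depth profile at one axis position."""
        d = np.asarray(depth_fracs, dtype=float)
        return self.field(np.full(d.shape, float(axis_norm)), d, peak=peak)

    def peak_at_ap(self, y_mm, ap_extent_mm: float) -> np.ndarray:
        """Peak depth fraction at anterior-posterior position y."""
        y = np.asarray(y_mm, dtype=float)
        return self.peak_depth_fraction + self.peak_drift * np.sin(
            2.0 * np.pi * y / ap_extent_mm)


def make_intensity_volume(
    toy: ToyConfluence,
    model: ProfileModel,
    voxel_mm: float,
    seed: int | None = None,
    pad_mm: float = 2.0,
):
    """Rasterize the profile-model field around the toy meshes.

    Returns ``(volume, affine)`` with a RAS affine. Each voxel is assigned
    an (axis, depth) coordinate by projecting onto the dense inner curve of
    the toy confluence; the noise-free field value there follows the
    profile model, so depth profiles sampled between the inner and outer
    surfaces reproduce the programmed skewness.
    """
    th = toy.spec.thickness_mm
    min_required = th / 8.0
    if voxel_mm > min_required:
        raise ValueError(
            f"voxel_mm={voxel_mm} too coarse: need at least 8 voxels across "
            f"the {th} mm cortical thickness, i.e. voxel_mm <= {min_required}"
        )
    all_v = np.vstack([
        toy.iso_inner.vertices, toy.iso_outer.vertices,
        toy.allo_inner.vertices, toy.allo_outer.vertices,
    ])
    lo = all_v.min(axis=0) - pad_mm
    hi = all_v.max(axis=0) + pad_mm
    xs = np.arange(lo[0], hi[0] + voxel_mm, voxel_mm)
    ys = np.arange(lo[1], hi[1] + voxel_mm, voxel_mm)
    zs = np.arange(lo[2], hi[2] + voxel_mm, voxel_mm)

    tree = cKDTree(toy.curve_points)
    xg, zg = np.meshgrid(xs, zs, indexing="ij")
    q = np.column_stack([xg.ravel(), zg.ravel()])
    _, idx = tree.query(q)
    rel = q - toy.curve_points[idx]
    depth = np.einsum("ij,ij->i", rel, toy.curve_normals[idx]) / th
    lateral = np.abs(
        rel[:, 0] * toy.curve_normals[idx][:, 1]
        - rel[:, 1] * toy.curve_normals[idx][:, 0]
    )
    axis_norm = toy.curve_axis[idx]

    in_band = (depth >= -0.75) & (depth <= 1.75) & (lateral < 1.5 * th)
    if model.peak_drift == 0.0:
        plane = np.full(q.shape[0], model.baseline_intensity)
        if np.any(in_band):
            plane[in_band] = model.field(axis_norm[in_band], depth[in_band])
        plane = plane.reshape(len(xs), len(zs))
        vol = np.repeat(plane[:, None, :].astype(np.float32), len(ys), axis=1)
    else:
        vol = np.full((len(xs), len(ys), len(zs)), model.baseline_intensity,
                      dtype=np.float32)
        a_in = axis_norm[in_band]
        d_in = depth[in_band]
        band_plane = in_band.reshape(len(xs), len(zs))
        for j, y in enumerate(ys):
            peak = float(model.peak_at_ap(y, toy.spec.ap_extent_mm))
            sheet = np.full(q.shape[0], model.baseline_intensity)
            sheet[in_band] = model.field(a_in, d_in, peak=peak)
            vol[:, j, :] = sheet.reshape(len(xs), len(zs)).astype(np.float32)
        del band_plane
    if model.noise_sd > 0:
        rng = np.random.default_rng(toy.spec.seed if seed is None else seed)
        vol = vol + model.noise_sd * rng.standard_normal(
            vol.shape).astype(np.float32)
        vol = np.maximum(vol, np.float32(1e-3))
    affine = np.array([
        [voxel_mm, 0, 0, xs[0]],
        [0, voxel_mm, 0, ys[0]],
        [0, 0, voxel_mm, zs[0]],
        [0, 0, 0, 1.0],
    ])
    return vol, affine


# --------------------------------------------------------------------------
# linear stochastic dynamics
# --------------------------------------------------------------------------

@dataclass
class LinearDynamicsSpec:
    """Stable multivariate Ornstein–Uhlenbeck specification."""

    coupling: np.ndarray
    noise_sd: float = 1.0
    dt: float = 0.1
    n_samples: int = 10000
    seed: int = 0
    burn_in: int = 1000

    def __post_init__(self) -> None:
        self.coupling = np.asarray(self.coupling, dtype=float)
        if self.coupling.ndim != 2 or self.coupling.shape[0] != self.coupling.shape[1]:
            raise ValueError("coupling must be square")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def check_stable(self) -> None:
        eig = np.linalg.eigvals(self.coupling)
        if np.any(eig.real >= 0):
            raise ValueError(
                "coupling matrix is unstable: eigenvalue real parts "
                f"{np.sort(eig.real)[::-1][:3]} must all be negative"
            )


def simulate_linear_dynamics(spec: LinearDynamicsSpec) -> np.ndarray:
    """Euler–Maruyama simulation of ``dx = A x dt + noise_sd dW``.

    Returns an (n_samples, n_nodes) array recorded after burn-in.
    """
    spec.check_stable()
    n = spec.coupling.shape[0]
    rng = np.random.default_rng(spec.seed)
    total = spec.n_samples + spec.burn_in
    noise = spec.noise_sd * np.sqrt(spec.dt) * rng.standard_normal((total, n))
    out = np.empty((total, n))
    x = np.zeros(n)
    step = np.eye(n) + spec.dt * spec.coupling
    for t in range(total):
        x = step @ x + noise[t]
        out[t] = x
    return out[spec.burn_in:]


def simulate_mar(
    coefficients: np.ndarray,
    noise_sd: float,
    n_samples: int,
    seed: int = 0,
    burn_in: int = 500,
) -> np.ndarray:
    """Discrete first-order multivariate autoregression, for cross-checks."""
    B = np.asarray(coefficients, dtype=float)
    if np.any(np.abs(np.linalg.eigvals(B)) >= 1):
        raise ValueError("AR coefficient matrix has spectral radius >= 1")
    n = B.shape[0]
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal((n_samples + burn_in, n))
    out = np.empty((n_samples + burn_in, n))
    x = np.zeros(n)
    for t in range(n_samples + burn_in):
        x = B @ x + noise[t]
        out[t] = x
    return out[burn_in:]


# --------------------------------------------------------------------------
# spherical parcel data with low-rank gradients
# --------------------------------------------------------------------------

def fibonacci_sphere(n: int) -> np.ndarray:
    """n approximately uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n, dtype=float)
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    phi = 2.0 * np.pi * i / golden
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def sphere_pattern_basis(centroids: np.ndarray, k: int) -> np.ndarray:
    """k smooth orthonormal patterns (low-order polynomials on the sphere)."""
    c = np.asarray(centroids, dtype=float)
    x, y, z = c[:, 0], c[:, 1], c[:, 2]
    candidates = [
        x, y, z,
        x * y, x * z, y * z, x * x - y * y, 3 * z * z - 1,
        x * (x * x - 3 * y * y), z * (5 * z * z - 3),
    ]
    if k > len(candidates):
        raise ValueError(f"at most {len(candidates)} patterns available")
    raw = np.column_stack([np.ones(len(c))] + candidates[:k])
    q, _ = np.linalg.qr(raw)
    basis = q[:, 1:k + 1]
    # deterministic sign: make each pattern positively correlated with its raw form
    for j in range(k):
        if basis[:, j] @ raw[:, j + 1] < 0:
            basis[:, j] *= -1
    return basis * np.sqrt(len(c))   # unit variance-ish scaling


def smooth_sphere_map(centroids: np.ndarray, rng: np.random.Generator,
                      lmax: int = 6) -> np.ndarray:
    """Random smooth field on the sphere (spherical-harmonic superposition)."""
    c = np.asarray(centroids, dtype=float)
    theta = np.arccos(np.clip(c[:, 2], -1, 1))
    phi = np.arctan2(c[:, 1], c[:, 0])
    out = np.zeros(len(c))
    for ell in range(1, lmax + 1):
        amp = 1.0 / (1.0 + ell) ** 1.5
        for m in range(0, ell + 1):
            y = sph_harm_y(ell, m, theta, phi)
            a, b = rng.standard_normal(2)
            if m == 0:
                out += amp * a * y.real
            else:
                out += amp * np.sqrt(2) * (a * y.real + b * y.imag)
    return out


@dataclass
class GradientParcelData:
    """Synthetic parcel/voxel timeseries with programmed gradients."""

    parcel_ts: np.ndarray          # (n_time, n_parcels)
    voxel_ts: np.ndarray           # (n_time, n_mtl_voxels)
    centroids: np.ndarray          # (n_parcels, 3), unit norm
    loadings: np.ndarray           # (n_parcels, k) ground-truth patterns
    weights: np.ndarray            # (k,) pattern strengths
    axes: np.ndarray               # (n_axes, n_mtl_voxels) voxel axis values
    axis_couplings: np.ndarray     # (n_axes, k) programmed interactions


def make_gradient_parcel_data(
    n_parcels: int,
    n_mtl_voxels: int,
    loadings,
    seed: int = 0,
    n_time: int = 2000,
    parcel_noise_sd: float = 0.0,
    voxel_noise_sd: float = 0.0,
    axis_couplings=None,
    common_strength: float = 1.0,
) -> GradientParcelData:
    """Parcel + MTL-voxel timeseries embedding low-rank connectivity.

    ``loadings`` are the variances of k orthogonal smooth patterns on the
    sphere; the parcel-parcel correlation matrix then has the programmed
    rank-k structure. ``axis_couplings`` (n_axes, k) injects interactions
    between voxel axis position and each pattern's latent series, so that
    voxel-to-parcel connectivity varies linearly along the axis against the
    chosen pattern.
    """
    if n_parcels < 10:
        raise ValueError("n_parcels must be at least 10")
    weights = np.atleast_1d(np.asarray(loadings, dtype=float))
    if weights.ndim != 1 or weights.size < 1:
        raise ValueError("loadings must be a 1D sequence of pattern strengths")
    k = weights.size
    rng = np.random.default_rng(seed)
    centroids = fibonacci_sphere(n_parcels)
    basis = sphere_pattern_basis(centroids, k)

    latent = rng.standard_normal((n_time, k))
    latent -= latent.mean(axis=0)
    parcel_ts = (latent * np.sqrt(weights)) @ basis.T
    if parcel_noise_sd > 0:
        parcel_ts = parcel_ts + parcel_noise_sd * rng.standard_normal(parcel_ts.shape)

    # two orthogonal deterministic voxel axes (linear and quadratic ramps)
    t = np.linspace(-1.0, 1.0, n_mtl_voxels)
    axis_a = t / t.std()
    axis_b = (3 * t * t - 1.0)
    axis_b = axis_b - axis_b.mean()
    axis_b /= axis_b.std()
    axes = np.vstack([axis_a, axis_b])

    if axis_couplings is None:
        axis_couplings = np.zeros((2, k))
    axis_couplings = np.asarray(axis_couplings, dtype=float)
    if axis_couplings.ndim == 1:
        axis_couplings = axis_couplings[None, :]
    if axis_couplings.shape[1] != k:
        raise ValueError("axis_couplings must have one column per loading")
    n_axes = axis_couplings.shape[0]

    common = rng.standard_normal(n_time)
    common -= common.mean()
    # orthogonalize against the latent series so the common mode cannot
    # leak programmed patterns into voxel-parcel connectivity
    beta, *_ = np.linalg.lstsq(latent, common, rcond=None)
    common = common - latent @ beta
    voxel_ts = common_strength * common[:, None] * np.ones((1, n_mtl_voxels))
    for a in range(n_axes):
        gain = axes[a][None, :] * np.ones((n_time, 1))
        mix = latent @ axis_couplings[a]
        voxel_ts = voxel_ts + mix[:, None] * gain
    if voxel_noise_sd > 0:
        vnoise = rng.standard_normal(voxel_ts.shape)
        # keep voxel noise orthogonal to the latent series so spurious
        # sample covariance cannot imprint the loadings on the r map
        beta_v, *_ = np.linalg.lstsq(latent, vnoise, rcond=None)
        vnoise = vnoise - latent @ beta_v
        voxel_ts = voxel_ts + voxel_noise_sd * vnoise

    return GradientParcelData(
        parcel_ts=parcel_ts,
        voxel_ts=voxel_ts,
        centroids=centroids,
        loadings=basis,
        weights=weights,
        axes=axes[:n_axes] if n_axes <= 2 else axes,
        axis_couplings=axis_couplings,
    )
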