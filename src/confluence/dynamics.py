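"""Axis-binned timeseries and directed-connectivity analyses.

The volumetric iso-to-allocortical axis is divided into discrete bins;
per-bin mean BOLD timeseries feed a continuous-time linear
(Ornstein–Uhlenbeck) inversion that estimates the directed coupling
between bins. Edges are labelled by their deviation from the axis and by
direction (towards isocortex / towards allocortex) for the downstream
correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import logm

from .stats import compare_dependent_correlations

__all__ = [
    "AxisBinAtlas",
    "DirectedConnectivity",
    "make_bin_atlas",
    "choose_n_bins",
    "extract_bin_timeseries",
    "estimate_ec",
    "edge_table",
    "deviation_analysis",
    "DeviationAnalysis",
    "ap_thirds_analysis",
    "functional_homogeneity",
]

N_BINS_RANGE = (4, 14)


@dataclass
class AxisBinAtlas:
    """Voxel label volume: 0 = background, 1..n_bins iso -> allo."""

    labels: np.ndarray
    n_bins: int
    edges: np.ndarray                       # bin interval edges, length n_bins+1
    composition: pd.DataFrame | None = None

    def bin_mask(self, b: int) -> np.ndarray:
        return self.labels == b


@dataclass
class DirectedConnectivity:
    """Signed coupling over axis bins; column = seed, row = target."""

    coupling: np.ndarray
    n_bins: int
    dt: float = 1.0
    extra: dict = field(default_factory=dict)


def make_bin_atlas(axis_volume: np.ndarray, n_bins: int,
                   mask: np.ndarray | None = None,
                   subregion_volume: np.ndarray | None = None,
                   force: bool = False,
                   mode: str = "equal-width") -> AxisBinAtlas:
    """Divide the axis volume into contiguous bins, iso to allo.

    Bin 1 holds the most negative (most isocortical) axis values. Bins are
    equal-width intervals over the axis range by default; ``equal-count``
    uses voxel-count quantiles. Any empty bin raises.
    """
    axis_volume = np.asarray(axis_volume, dtype=float)
    if mask is None:
        mask = np.isfinite(axis_volume)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(axis_volume)
    if not np.any(mask):
        raise ValueError("no finite axis values inside the mask")
    lo, hi = N_BINS_RANGE
    if not force and not lo <= n_bins <= hi:
        raise ValueError(
            f"n_bins={n_bins} outside the supported range {lo}..{hi} "
            "(pass force=True to override)"
        )
    values = axis_volume[mask]
    if mode == "equal-width":
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    elif mode == "equal-count":
        edges = np.quantile(values, np.linspace(0, 1, n_bins + 1))
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    idx = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, n_bins - 1)
    labels = np.zeros(axis_volume.shape, dtype=np.int32)
    labels[mask] = idx + 1
    counts = np.bincount(labels[mask], minlength=n_bins + 1)[1:]
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0) + 1
        raise ValueError(
            f"bins {empty.tolist()} are empty; use fewer bins"
        )
    composition = None
    if subregion_volume is not None:
        sub = np.asarray(subregion_volume)
        rows = []
        for b in range(1, n_bins + 1):
            in_bin = labels == b
            subs, n = np.unique(sub[in_bin], return_counts=True)
            for s, c in zip(subs, n):
                rows.append({"bin": b, "subregion": s,
                             "fraction": c / in_bin.sum()})
        composition = pd.DataFrame(rows)
    return AxisBinAtlas(labels=labels, n_bins=n_bins, edges=edges,
                        composition=composition)


def choose_n_bins(axis_volume: np.ndarray, min_voxels: int = 10,
                  candidates=None, masks=None) -> tuple[int, pd.DataFrame]:
    """Finest bin count whose bins all hold at least ``min_voxels`` voxels.

    ``masks`` is an optional list of per-subject boolean masks that must
    each satisfy the occupancy requirement. Returns the selected count and
    a decision log.
    """
    if candidates is None:
        candidates = range(N_BINS_RANGE[0], N_BINS_RANGE[1] + 1)
    candidates = sorted(int(c) for c in candidates)
    if masks is None:
        masks = [None]
    log = []
    selected = None
    for n_bins in candidates:
        ok = True
        worst = np.inf
        for m in masks:
            try:
                atlas = make_bin_atlas(axis_volume, n_bins, mask=m)
            except ValueError:
                ok = False
                worst = 0
                break
            counts = np.bincount(atlas.labels[atlas.labels > 0],
                                 minlength=n_bins + 1)[1:]
            worst = min(worst, counts.min())
            if counts.min() < min_voxels:
                ok = False
        log.append({"n_bins": n_bins, "min_bin_voxels": int(worst),
                    "feasible": ok})
        if ok:
            selected = n_bins
    if selected is None:
        raise ValueError(
            f"no candidate bin count in {candidates} keeps at least "
            f"{min_voxels} voxels per bin"
        )
    return selected, pd.DataFrame(log)


def extract_bin_timeseries(fmri: np.ndarray, atlas: AxisBinAtlas,
                           demean: bool = True) -> np.ndarray:
    """Per-bin spatial mean timeseries, (n_time, n_bins), demeaned per bin."""
    fmri = np.asarray(fmri, dtype=float)
    if fmri.ndim != 4:
        raise ValueError("fmri must be a 4D (x, y, z, t) array")
    if fmri.shape[:3] != atlas.labels.shape:
        raise ValueError(
            f"grid mismatch: fmri spatial shape {fmri.shape[:3]} vs atlas "
            f"shape {atlas.labels.shape}"
        )
    n_time = fmri.shape[3]
    out = np.empty((n_time, atlas.n_bins))
    for b in range(1, atlas.n_bins + 1):
        m = atlas.bin_mask(b)
        if not np.any(m):
            raise ValueError(f"bin {b} is empty")
        out[:, b - 1] = fmri[m].mean(axis=0)
    if demean:
        out = out - out.mean(axis=0)
    return out


def estimate_ec(timeseries: np.ndarray, dt: float = 1.0,
                lag_steps: int = 1, ridge: float = 1e-6) -> DirectedConnectivity:
    """Directed coupling from a stable linear stochastic model.

    Fits the discrete propagator B with ridge-regularized least squares on
    lagged samples, then recovers the continuous-time coupling as
    ``logm(B) / (lag_steps * dt)``. The estimate must be stable (negative
    real-part eigenvalues) and finite.
    """
    x = np.asarray(timeseries, dtype=float)
    n_time, n_nodes = x.shape
    if n_time < 10 * n_nodes**2:
        raise ValueError(
            f"need at least 10 * n_nodes^2 = {10 * n_nodes**2} samples, "
            f"got {n_time}"
        )
    x = x - x.mean(axis=0)
    x0 = x[:-lag_steps]
    x1 = x[lag_steps:]
    gram = x0.T @ x0 / len(x0)
    gram = gram + ridge * np.trace(gram) / n_nodes * np.eye(n_nodes)
    cross = x1.T @ x0 / len(x0)
    b = cross @ np.linalg.inv(gram)
    eigval = np.linalg.eigvals(b)
    if np.any(np.abs(eigval) >= 1.0) or np.any(np.abs(eigval) <= 0.0):
        raise ValueError(
            f"discrete propagator is unstable or singular "
            f"(|eig| range {np.abs(eigval).min():.3g}..{np.abs(eigval).max():.3g})"
        )
    a = logm(b) / (lag_steps * dt)
    if np.max(np.abs(a.imag)) > 1e-6 * max(np.max(np.abs(a.real)), 1.0):
        warnings.warn("matrix logarithm has a non-trivial imaginary part; "
                      "taking the real part")
    a = a.real
    if not np.all(np.isfinite(a)):
        raise ValueError("non-finite coupling estimate")
    if np.any(np.linalg.eigvals(a).real >= 0):
        warnings.warn("estimated coupling is not strictly stable")
    return DirectedConnectivity(coupling=a, n_bins=n_nodes, dt=dt,
                                extra={"propagator": b, "lag_steps": lag_steps})


def edge_table(ec: DirectedConnectivity) -> pd.DataFrame:
    """Off-diagonal edges labelled by deviation and direction.

    seed/target bins are 1-based; deviation(i -> j) = |i - j| - 1;
    direction is ``to_isocortex`` when the target bin is lower than the
    seed bin, ``to_allocortex`` otherwise.
    """
    n = ec.n_bins
    rows = []
    for seed in range(1, n + 1):
        for target in range(1, n + 1):
            if seed == target:
                continue
            rows.append({
                "seed": seed,
                "target": target,
                "coupling": ec.coupling[target - 1, seed - 1],
                "deviation": abs(seed - target) - 1,
                "direction": ("to_isocortex" if target < seed
                              else "to_allocortex"),
            })
    return pd.DataFrame(rows)


@dataclass
class DeviationAnalysis:
    r_to_iso: float
    r_to_allo: float
    p_to_iso: float
    p_to_allo: float
    z_difference: float
    p_difference: float
    edges: pd.DataFrame


def deviation_analysis(ec: DirectedConnectivity) -> DeviationAnalysis:
    """Correlate edge deviation with coupling, stratified by direction.

    The directional difference uses the dependent-correlation z-test: the
    two correlations share the deviation labels, with the reciprocal edges
    (i -> j vs j -> i) paired.
    """
    from scipy.stats import pearsonr

    if ec.n_bins < 4:
        raise ValueError("need at least 4 bins")
    table = edge_table(ec)
    iso = table[table.direction == "to_isocortex"].sort_values(["seed", "target"])
    allo = table[table.direction == "to_allocortex"].sort_values(["target", "seed"])
    # reciprocal pairing: edge (s -> t) with t < s pairs with (t -> s)
    c_iso = iso.coupling.to_numpy()
    c_allo = allo.coupling.to_numpy()
    dev = iso.deviation.to_numpy(float)
    if np.ptp(c_iso) == 0 or np.ptp(c_allo) == 0:
        raise ValueError("all couplings equal; correlation undefined")
    r_iso, p_iso = pearsonr(dev, c_iso)
    r_allo, p_allo = pearsonr(dev, c_allo)
    r_ab = float(np.corrcoef(c_iso, c_allo)[0, 1])
    comp = compare_dependent_correlations(r_iso, r_allo, r_ab, len(dev))
    return DeviationAnalysis(
        r_to_iso=float(r_iso), r_to_allo=float(r_allo),
        p_to_iso=float(p_iso), p_to_allo=float(p_allo),
        z_difference=comp.z, p_difference=comp.p,
        edges=table,
    )


def ap_thirds_analysis(axis_volume: np.ndarray, ap_volume: np.ndarray,
                       fmri: np.ndarray, n_bins: int, dt: float = 1.0,
                       full_ec: DirectedConnectivity | None = None):
    """Repeat the dynamic model within anterior-posterior thirds.

    Thirds are voxel-count terciles of the anterior-posterior coordinate
    over labelled voxels; the full model's bin intervals are reused so bin
    identity is comparable. Returns a per-third dict with the EC, its
    off-diagonal correlation with the full model, and the per-third
    deviation analysis.
    """
    axis_volume = np.asarray(axis_volume, dtype=float)
    ap_volume = np.asarray(ap_volume, dtype=float)
    mask = np.isfinite(axis_volume)
    if full_ec is None:
        atlas_full = make_bin_atlas(axis_volume, n_bins)
        full_ec = estimate_ec(extract_bin_timeseries(fmri, atlas_full), dt=dt)
    ap_values = ap_volume[mask]
    terciles = np.quantile(ap_values, [0.0, 1 / 3, 2 / 3, 1.0])
    off = ~np.eye(n_bins, dtype=bool)
    results = {}
    for t, name in enumerate(("anterior", "middle", "posterior")):
        lo, hi = terciles[t], terciles[t + 1]
        if t < 2:
            third_mask = mask & (ap_volume >= lo) & (ap_volume < hi)
        else:
            third_mask = mask & (ap_volume >= lo) & (ap_volume <= hi)
        if not np.any(third_mask):
            raise ValueError(f"{name} third contains no voxels")
        atlas = make_bin_atlas(axis_volume, n_bins, mask=third_mask)
        ts = extract_bin_timeseries(fmri, atlas)
        ec = estimate_ec(ts, dt=dt)
        r_full = float(np.corrcoef(ec.coupling[off],
                                   full_ec.coupling[off])[0, 1])
        results[name] = {
            "ec": ec,
            "r_with_full": r_full,
            "deviation": deviation_analysis(ec),
            "n_voxels": int(third_mask.sum()),
        }
    return full_ec, results


def functional_homogeneity(fmri: np.ndarray, atlas: AxisBinAtlas,
                           max_voxels_per_bin: int = 400,
                           seed: int = 0) -> pd.DataFrame:
    """Mean within-bin vs between-bin voxel timeseries correlation.

    Bins with a single voxel are excluded with a warning. Returns a table
    with per-bin within-bin means, the overall between-bin mean and the
    contrast (within - between).
    """
    fmri = np.asarray(fmri, dtype=float)
    if fmri.shape[:3] != atlas.labels.shape:
        raise ValueError("grid mismatch between fmri and atlas")
    rng = np.random.default_rng(seed)
    series = {}
    for b in range(1, atlas.n_bins + 1):
        m = atlas.bin_mask(b)
        n_vox = int(m.sum())
        if n_vox < 2:
            warnings.warn(f"bin {b} has {n_vox} voxel(s); excluded")
            continue
        ts = fmri[m]
        if n_vox > max_voxels_per_bin:
            pick = rng.choice(n_vox, max_voxels_per_bin, replace=False)
            ts = ts[pick]
        sd = ts.std(axis=1)
        ts = ts[sd > 0]
        series[b] = ts
    if len(series) < 2:
        raise ValueError("need at least two usable bins")
    rows = []
    within = {}
    for b, ts in series.items():
        c = np.corrcoef(ts)
        iu = np.triu_indices_from(c, k=1)
        within[b] = float(c[iu].mean())
        rows.append({"bin": b, "kind": "within", "mean_r": within[b]})
    between = []
    bins = sorted(series)
    for i, bi in enumerate(bins):
        for bj in bins[i + 1:]:
            a, b_ts = series[bi], series[bj]
            az = (a - a.mean(axis=1, keepdims=True)) / a.std(axis=1, keepdims=True)
            bz = (b_ts - b_ts.mean(axis=1, keepdims=True)) / b_ts.std(
                axis=1, keepdims=True)
            r = az @ bz.T / a.shape[1]
            between.append(float(r.mean()))
            rows.append({"bin": (bi, bj), "kind": "between",
                         "mean_r": between[-1]})
    table = pd.DataFrame(rows)
    contrast = float(np.mean(list(within.values())) - np.mean(between))
    table.attrs["contrast"] = contrast
    return table
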