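import numpy as np
import pytest

from confluence.dynamics import (
    choose_n_bins,
    deviation_analysis,
    edge_table,
    estimate_ec,
    extract_bin_timeseries,
    functional_homogeneity,
    make_bin_atlas,
    ap_thirds_analysis,
    DirectedConnectivity,
)
from confluence.synthetic import LinearDynamicsSpec, simulate_linear_dynamics


def _uniform_axis_volume(shape=(20, 10, 10), lo=0.0, hi=1.0, seed=0):
    rng = np.random.default_rng(seed)
    vol = np.full(shape, np.nan)
    vol[2:-2, 2:-2, 2:-2] = rng.uniform(lo, hi,
                                        (shape[0] - 4, shape[1] - 4,
                                         shape[2] - 4))
    return vol


def _chain_coupling(n, self_decay=-0.6, fwd=0.25, bwd=0.2):
    a = self_decay * np.eye(n)
    for i in range(n - 1):
        a[i + 1, i] = fwd
        a[i, i + 1] = bwd
    return a


def _paint_fmri(atlas, node_ts):
    """Voxelwise 4D volume carrying each bin's node series."""
    n_time = node_ts.shape[0]
    fmri = np.zeros(atlas.labels.shape + (n_time,))
    for b in range(1, atlas.n_bins + 1):
        fmri[atlas.labels == b] = node_ts[:, b - 1]
    return fmri


class TestMakeBinAtlas:
    def test_interval_arithmetic(self):
        vol = np.linspace(0, 1, 1000).reshape(10, 10, 10)
        atlas = make_bin_atlas(vol, 8)
        # value 0.13 falls in the second of 8 equal-width bins on [0, 1]
        idx = np.unravel_index(np.argmin(np.abs(vol - 0.13)), vol.shape)
        assert atlas.labels[idx] == 2

    def test_deviation_span_in_8_bin_model(self):
        ec = DirectedConnectivity(coupling=np.zeros((8, 8)), n_bins=8)
        table = edge_table(ec)
        assert table["deviation"].min() == 0
        assert table["deviation"].max() == 6

    def test_out_of_range_bins_rejected_unless_forced(self):
        vol = _uniform_axis_volume()
        with pytest.raises(ValueError, match="4..14"):
            make_bin_atlas(vol, 3)
        atlas = make_bin_atlas(vol, 3, force=True)
        assert atlas.n_bins == 3

    def test_empty_bin_rejected(self):
        vol = np.full((6, 6, 6), np.nan)
        vol[0, 0, 0] = 0.0
        vol[0, 0, 1] = 1.0
        with pytest.raises(ValueError, match="empty"):
            make_bin_atlas(vol, 4)

    def test_bins_ordered_iso_to_allo(self):
        vol = _uniform_axis_volume(lo=-5, hi=5)
        atlas = make_bin_atlas(vol, 6)
        mask = atlas.labels > 0
        for b in range(1, 6):
            assert vol[atlas.labels == b].max() <= \
                vol[atlas.labels == b + 1].min() + 1e-9
        assert np.all(np.isfinite(vol[mask]))

    def test_composition_table(self):
        vol = _uniform_axis_volume()
        sub = np.where(np.isfinite(vol) & (vol < 0.5), 11, 12)
        atlas = make_bin_atlas(vol, 4, subregion_volume=sub)
        assert atlas.composition is not None
        total = atlas.composition.groupby("bin")["fraction"].sum()
        np.testing.assert_allclose(total.to_numpy(), 1.0)

    def test_equal_count_mode(self):
        vol = _uniform_axis_volume(seed=3)
        atlas = make_bin_atlas(vol, 5, mode="equal-count")
        counts = np.bincount(atlas.labels[atlas.labels > 0])[1:]
        assert counts.max() - counts.min() <= counts.mean() * 0.1


class TestChooseNBins:
    def test_generous_mask_returns_14(self):
        vol = _uniform_axis_volume(shape=(30, 20, 20))
        n, log = choose_n_bins(vol, min_voxels=10)
        assert n == 14
        assert log.feasible.all()

    def test_constrained_mask_returns_8(self):
        # 8 * 25 voxels, uniform: at 9+ bins some bin holds < 25 voxels
        vol = np.full((4, 10, 10), np.nan)
        values = (np.arange(200) % 8) / 8.0 + 0.01
        vol.ravel()[:200] = values
        n, _ = choose_n_bins(vol, min_voxels=25)
        assert n == 8

    def test_min_voxels_one_returns_14(self):
        vol = _uniform_axis_volume()
        n, _ = choose_n_bins(vol, min_voxels=1)
        assert n == 14

    def test_no_feasible_candidate_raises(self):
        vol = np.full((3, 3, 3), np.nan)
        vol[0, 0, :2] = [0.0, 1.0]
        with pytest.raises(ValueError, match="no candidate"):
            choose_n_bins(vol, min_voxels=5)


class TestExtractBinTimeseries:
    def test_constant_signal_demeans_to_zero(self):
        vol = _uniform_axis_volume()
        atlas = make_bin_atlas(vol, 4)
        fmri = np.ones(vol.shape + (50,)) * 3.3
        ts = extract_bin_timeseries(fmri, atlas)
        np.testing.assert_allclose(ts, 0.0, atol=1e-12)

    def test_two_voxel_mean(self):
        vol = np.full((4, 4, 4), np.nan)
        vol[0, 0, 0] = 0.05
        vol[0, 0, 1] = 0.10
        vol[1, 0, 0] = 0.4
        vol[2, 0, 0] = 0.6
        vol[3, 0, 0] = 0.9
        atlas = make_bin_atlas(vol, 4)
        fmri = np.zeros((4, 4, 4, 3))
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 6.0])
        fmri[0, 0, 0] = a
        fmri[0, 0, 1] = b
        ts = extract_bin_timeseries(fmri, atlas, demean=False)
        np.testing.assert_allclose(ts[:, 0], (a + b) / 2)

    def test_painted_node_series_recovered(self):
        vol = _uniform_axis_volume(seed=5)
        atlas = make_bin_atlas(vol, 5)
        rng = np.random.default_rng(0)
        node_ts = rng.standard_normal((40, 5))
        fmri = _paint_fmri(atlas, node_ts)
        ts = extract_bin_timeseries(fmri, atlas, demean=False)
        np.testing.assert_allclose(ts, node_ts, atol=1e-12)

    def test_grid_mismatch_names_shapes(self):
        vol = _uniform_axis_volume()
        atlas = make_bin_atlas(vol, 4)
        with pytest.raises(ValueError, match="mismatch"):
            extract_bin_timeseries(np.zeros((3, 3, 3, 10)), atlas)


class TestEstimateEc:
    def test_known_coupling_recovered(self):
        a = _chain_coupling(8)
        x = simulate_linear_dynamics(LinearDynamicsSpec(
            coupling=a, noise_sd=1.0, dt=0.1, n_samples=50000, seed=0))
        ec = estimate_ec(x, dt=0.1)
        off = ~np.eye(8, dtype=bool)
        r = np.corrcoef(ec.coupling[off], a[off])[0, 1]
        assert r > 0.8

    def test_white_noise_couplings_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal((20000, 4))
        ec = estimate_ec(x, dt=1.0)
        off = np.abs(ec.coupling[~np.eye(4, dtype=bool)])
        # permutation null: shuffle time per node independently
        null = []
        for _ in range(200):
            xp = np.column_stack([rng.permutation(x[:2000, j])
                                  for j in range(4)])
            ecp = estimate_ec(xp, dt=1.0)
            null.append(np.abs(ecp.coupling[~np.eye(4, dtype=bool)]))
        thresh = np.quantile(np.concatenate(null), 0.975)
        assert np.mean(off <= thresh) >= 0.95

    def test_chain_adjacent_exceed_distant(self):
        a = _chain_coupling(6, fwd=0.3, bwd=0.25)
        x = simulate_linear_dynamics(LinearDynamicsSpec(
            coupling=a, noise_sd=1.0, dt=0.1, n_samples=60000, seed=4))
        ec = estimate_ec(x, dt=0.1)
        table = edge_table(ec)
        adj = table[table.deviation == 0]["coupling"].abs().mean()
        far = table[table.deviation >= 3]["coupling"].abs().mean()
        assert adj > far

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="samples"):
            estimate_ec(np.zeros((100, 5)), dt=1.0)

    def test_consistency_improves_with_length(self):
        a = _chain_coupling(5)
        errs = []
        for n in (4000, 16000, 64000):
            x = simulate_linear_dynamics(LinearDynamicsSpec(
                coupling=a, noise_sd=1.0, dt=0.1, n_samples=n, seed=11))
            ec = estimate_ec(x, dt=0.1)
            errs.append(np.linalg.norm(ec.coupling - a))
        assert errs[2] < errs[0]


class TestDeviationAnalysis:
    def test_perfect_ordering_gives_minus_one(self):
        n = 8
        coupling = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    coupling[i, j] = 1.0 - 0.1 * (abs(i - j) - 1)
        ec = DirectedConnectivity(coupling=coupling, n_bins=n)
        out = deviation_analysis(ec)
        assert out.r_to_iso == pytest.approx(-1.0)
        assert out.r_to_allo == pytest.approx(-1.0)
        assert out.z_difference == pytest.approx(0.0, abs=1e-10)

    def test_direction_partition(self):
        ec = DirectedConnectivity(coupling=np.random.default_rng(0)
                                  .standard_normal((6, 6)), n_bins=6)
        table = edge_table(ec)
        iso = table[table.direction == "to_isocortex"]
        allo = table[table.direction == "to_allocortex"]
        assert len(iso) == len(allo) == 15
        # deviation labelling is symmetric under edge reversal
        dev = {(r.seed, r.target): r.deviation for r in table.itertuples()}
        for (s, t), d in dev.items():
            assert dev[(t, s)] == d

    def test_label_permutation_gives_small_r(self):
        rng = np.random.default_rng(2)
        rs = []
        for _ in range(50):
            coupling = rng.standard_normal((8, 8))
            out = deviation_analysis(
                DirectedConnectivity(coupling=coupling, n_bins=8))
            rs.extend([out.r_to_iso, out.r_to_allo])
        assert abs(np.mean(rs)) < 0.05
        assert np.std(rs) < 0.35

    def test_equal_couplings_rejected(self):
        ec = DirectedConnectivity(coupling=np.ones((5, 5)), n_bins=5)
        with pytest.raises(ValueError, match="equal"):
            deviation_analysis(ec)

    def test_chain_dynamics_negative_both_directions(self):
        a = _chain_coupling(8, fwd=0.3, bwd=0.25)
        x = simulate_linear_dynamics(LinearDynamicsSpec(
            coupling=a, noise_sd=1.0, dt=0.1, n_samples=50000, seed=6))
        ec = estimate_ec(x, dt=0.1)
        out = deviation_analysis(ec)
        assert out.r_to_iso < 0
        assert out.r_to_allo < 0


class TestApThirds:
    def _setup(self, seed=0, n_bins=5):
        axis = _uniform_axis_volume(shape=(24, 12, 12), seed=seed)
        ap = np.tile(np.arange(12.0)[None, :, None], (24, 1, 12))
        ap[~np.isfinite(axis)] = np.nan
        atlas = make_bin_atlas(axis, n_bins)
        a = _chain_coupling(n_bins)
        node_ts = simulate_linear_dynamics(LinearDynamicsSpec(
            coupling=a, noise_sd=1.0, dt=0.1, n_samples=30000, seed=seed))
        fmri = _paint_fmri(atlas, node_ts)
        return axis, ap, fmri, a

    def test_partition_covers_all_voxels(self):
        axis, ap, fmri, _ = self._setup()
        full_ec, thirds = ap_thirds_analysis(axis, ap, fmri, 5, dt=0.1)
        total = sum(t["n_voxels"] for t in thirds.values())
        assert total == int(np.isfinite(axis).sum())

    def test_homogeneous_dynamics_high_correlation(self):
        axis, ap, fmri, a = self._setup(seed=1)
        full_ec, thirds = ap_thirds_analysis(axis, ap, fmri, 5, dt=0.1)
        for name, res in thirds.items():
            assert res["r_with_full"] > 0.8


class TestFunctionalHomogeneity:
    def test_block_structure_detected(self):
        vol = _uniform_axis_volume(seed=7)
        atlas = make_bin_atlas(vol, 4)
        rng = np.random.default_rng(0)
        node_ts = rng.standard_normal((60, 4))
        fmri = _paint_fmri(atlas, node_ts)
        # add tiny voxel noise so correlations are defined
        fmri += 1e-3 * rng.standard_normal(fmri.shape)
        table = functional_homogeneity(fmri, atlas)
        within = table[table.kind == "within"]["mean_r"]
        between = table[table.kind == "between"]["mean_r"]
        assert within.min() > 0.99
        assert np.abs(between).max() < 0.3
        assert table.attrs["contrast"] > 0.9

    def test_globally_identical_series_zero_contrast(self):
        vol = _uniform_axis_volume(seed=8)
        atlas = make_bin_atlas(vol, 4)
        base = np.sin(np.linspace(0, 10, 50))
        fmri = np.zeros(vol.shape + (50,))
        fmri[atlas.labels > 0] = base
        table = functional_homogeneity(fmri, atlas)
        assert table.attrs["contrast"] == pytest.approx(0.0, abs=1e-9)

    def test_contrast_decreases_with_mixing(self):
        vol = _uniform_axis_volume(seed=9)
        atlas = make_bin_atlas(vol, 4)
        rng = np.random.default_rng(3)
        node_ts = rng.standard_normal((80, 4))
        common = rng.standard_normal(80)
        contrasts = []
        for mix in (0.0, 0.5, 1.0):
            blended = (1 - mix) * node_ts + mix * common[:, None]
            fmri = _paint_fmri(atlas, blended)
            fmri = fmri + 0.05 * rng.standard_normal(fmri.shape)
            table = functional_homogeneity(fmri, atlas, seed=0)
            contrasts.append(table.attrs["contrast"])
        assert contrasts[0] > contrasts[1] > contrasts[2]
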