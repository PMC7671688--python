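import numpy as np
import pytest
from scipy.stats import spearmanr

from confluence.macroscale import (
    AxisCorrelationMap,
    ParcelConnectome,
    axis_fc_map,
    exclude_temporal_lobe,
    functional_gradients,
    group_connectome,
    map_gradient_correspondence,
    normalized_angle,
    snr_controls,
    snr_maps,
    spin_permutation,
)
from confluence.synthetic import (
    fibonacci_sphere,
    make_gradient_parcel_data,
    smooth_sphere_map,
)


@pytest.fixture(scope="module")
def parcel_data():
    return make_gradient_parcel_data(
        300, 80, [1.0, 0.6, 0.4], seed=5,
        axis_couplings=[[0.0, 0.0, 0.5], [0.0, 0.0, 0.0]],
        parcel_noise_sd=0.3, voxel_noise_sd=0.3)


class TestAxisFcMap:
    def test_connectivity_equal_to_axis_gives_unit_r(self):
        rng = np.random.default_rng(0)
        n_vox, n_time = 20, 500
        axis = np.linspace(0.05, 0.95, n_vox)
        # mix so that corr(voxel_v, parcel) equals axis_v by construction
        parcel = rng.standard_normal((n_time, 1))
        noise = rng.standard_normal((n_time, n_vox))
        voxels = axis[None, :] * parcel \
            + np.sqrt(1 - axis**2)[None, :] * noise
        out = axis_fc_map(voxels, axis, parcel)
        assert out.r[0] > 0.9

    def test_programmed_interaction_recovered(self, parcel_data):
        out = axis_fc_map(parcel_data.voxel_ts, parcel_data.axes[0],
                          parcel_data.parcel_ts)
        programmed = parcel_data.loadings @ (
            np.sqrt(parcel_data.weights) * parcel_data.axis_couplings[0])
        # the r map is a mildly saturating transform of the programmed
        # combination; rank correlation is the faithful comparison
        rho = spearmanr(out.r, programmed).statistic
        assert abs(rho) > 0.9

    def test_shuffled_axis_centres_map_on_zero(self, parcel_data, rng):
        shuffled = rng.permutation(parcel_data.axes[0])
        out = axis_fc_map(parcel_data.voxel_ts, shuffled,
                          parcel_data.parcel_ts)
        assert abs(np.mean(out.r)) < 0.05

    def test_too_few_voxels_rejected(self):
        with pytest.raises(ValueError, match="10"):
            axis_fc_map(np.zeros((100, 5)), np.arange(5), np.zeros((100, 3)))

    def test_constant_axis_warns_sentinel(self):
        rng = np.random.default_rng(0)
        with pytest.warns(UserWarning, match="constant axis"):
            out = axis_fc_map(rng.standard_normal((50, 12)), np.ones(12),
                              rng.standard_normal((50, 4)))
        assert np.all(np.isnan(out.r))


class TestNormalizedAngle:
    def test_formula_endpoints(self):
        np.testing.assert_allclose(
            normalized_angle(np.array([[1.0, 0.0, -1.0]])).ravel(),
            [1.0, 0.5, 0.0], atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            normalized_angle(np.array([[1.5]]))

    def test_monotone_in_r(self):
        r = np.linspace(-1, 1, 101)
        a = normalized_angle(r[None, :]).ravel()
        assert np.all(np.diff(a) > 0)


class TestFunctionalGradients:
    def test_low_rank_patterns_recovered(self, parcel_data):
        conn = ParcelConnectome(np.corrcoef(parcel_data.parcel_ts.T),
                                centroids=parcel_data.centroids)
        emb = functional_gradients(conn, k=3)
        for j in range(2):
            rho = abs(spearmanr(emb.vectors[:, j],
                                parcel_data.loadings[:, j]).statistic)
            assert rho > 0.95

    def test_parcel_permutation_equivariance(self, parcel_data, rng):
        conn = np.corrcoef(parcel_data.parcel_ts.T)
        perm = rng.permutation(conn.shape[0])
        emb = functional_gradients(
            ParcelConnectome(conn, centroids=parcel_data.centroids), k=2)
        emb_p = functional_gradients(
            ParcelConnectome(conn[np.ix_(perm, perm)],
                             centroids=parcel_data.centroids[perm]), k=2)
        for j in range(2):
            r = abs(np.corrcoef(emb.vectors[perm, j],
                                emb_p.vectors[:, j])[0, 1])
            assert r > 1 - 1e-6

    def test_group_connectome_fisher_mean(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])
        b = np.array([[1.0, 0.1], [0.1, 1.0]])
        g = group_connectome([a, b])
        expected = np.tanh(0.5 * (np.arctanh(0.5) + np.arctanh(0.1)))
        assert g[0, 1] == pytest.approx(expected)
        assert g[0, 0] == 1.0


class TestSpinPermutation:
    def test_preserves_value_multiset_approximately(self, rng):
        cent = fibonacci_sphere(200)
        values = rng.standard_normal(200)
        nulls = spin_permutation(cent, values, 20, seed=0)
        source = set(np.round(values, 12))
        for s in range(20):
            assert set(np.round(nulls[s], 12)) <= source

    def test_seed_reproducible(self, rng):
        cent = fibonacci_sphere(100)
        values = rng.standard_normal(100)
        a = spin_permutation(cent, values, 10, seed=3)
        b = spin_permutation(cent, values, 10, seed=3)
        assert np.array_equal(a, b)

    def test_degenerate_centroids_rejected(self):
        line = np.tile(np.array([[0.0, 0.0, 1.0]]), (30, 1))
        with pytest.raises(ValueError, match="collinear|degenerate"):
            spin_permutation(line, np.arange(30.0), 5)

    def test_spatial_autocorrelation_preserved(self, rng):
        """Moran-style neighbour similarity of null maps stays within 20%
        of the input map's."""
        cent = fibonacci_sphere(400)
        values = smooth_sphere_map(cent, rng)
        from scipy.spatial import cKDTree
        _, nbr = cKDTree(cent).query(cent, k=7)

        def moran_like(v):
            v = (v - v.mean()) / v.std()
            return np.mean(v[:, None] * v[nbr[:, 1:]])

        base = moran_like(values)
        nulls = spin_permutation(cent, values, 50, seed=1)
        null_stats = np.array([moran_like(n) for n in nulls])
        assert abs(null_stats.mean() - base) / abs(base) < 0.2


class TestCorrespondence:
    def test_self_comparison(self, rng):
        cent = fibonacci_sphere(150)
        values = smooth_sphere_map(cent, rng)
        cmap = AxisCorrelationMap(r=values)
        res = map_gradient_correspondence(cmap, values[:, None], cent,
                                          n_spins=199, seed=0)
        assert res.rho[0] == pytest.approx(1.0)
        assert res.p_spin[0] == pytest.approx(1.0 / 200.0)

    def test_double_dissociation_structure(self):
        data = make_gradient_parcel_data(
            400, 100, [1.0, 0.6, 0.4], seed=9,
            axis_couplings=[[0.6, 0.0, 0.0], [0.0, 0.0, 0.6]],
            parcel_noise_sd=0.3, voxel_noise_sd=0.3)
        conn = ParcelConnectome(np.corrcoef(data.parcel_ts.T),
                                centroids=data.centroids)
        emb = functional_gradients(conn, k=3)
        for a, expected in ((0, 0), (1, 2)):
            cmap = axis_fc_map(data.voxel_ts, data.axes[a], data.parcel_ts)
            res = map_gradient_correspondence(cmap, emb.vectors, data.centroids,
                                              n_spins=299, seed=a)
            assert int(np.argmax(np.abs(res.rho))) == expected
            assert res.p_spin[expected] < 0.05

    def test_missing_centroids_rejected(self, rng):
        cmap = AxisCorrelationMap(r=rng.standard_normal(50))
        with pytest.raises(ValueError, match="centroid"):
            map_gradient_correspondence(cmap, rng.standard_normal((50, 2)),
                                        None, n_spins=100)

    def test_few_spins_warn(self, rng):
        cent = fibonacci_sphere(60)
        cmap = AxisCorrelationMap(r=rng.standard_normal(60))
        with pytest.warns(UserWarning, match="low"):
            map_gradient_correspondence(cmap, rng.standard_normal((60, 2)),
                                        cent, n_spins=50, seed=0)


class TestSnr:
    def test_tsnr_arithmetic(self):
        # voxel with mean 10 and temporal SD 2 -> tSNR 5
        t = np.arange(100)
        series = 10.0 + 2.0 * np.sign(np.sin(t + 0.5))
        series = series - series.mean() + 10.0
        sd = series.std()
        series = 10.0 + (series - 10.0) * (2.0 / sd)
        _, temporal = snr_maps(series[:, None])
        assert temporal[0] == pytest.approx(10.0 / 2.0)

    def test_zero_temporal_sd_sentinel(self):
        raw = np.column_stack([np.full(50, 3.0),
                               np.random.default_rng(0).random(50) + 1])
        with pytest.warns(UserWarning, match="zero temporal"):
            _, temporal = snr_maps(raw)
        assert np.isnan(temporal[0])

    def test_independent_snr_leaves_map_unchanged(self, parcel_data, rng):
        offsets = 50.0 + 5.0 * rng.random(80)
        raw = parcel_data.voxel_ts + offsets[None, :]
        out = snr_controls(parcel_data.voxel_ts, raw, parcel_data.axes[0],
                           parcel_data.parcel_ts)
        assert out["r_original_vs_spatial"] > 0.95
        assert out["r_original_vs_temporal"] > 0.95

    def test_axis_dependent_snr_attenuates_map(self, parcel_data, rng):
        # voxel mean signal strongly increasing along the axis
        offsets = 50.0 + 20.0 * parcel_data.axes[0] + 0.5 * rng.random(80)
        raw = parcel_data.voxel_ts + offsets[None, :]
        dep = snr_controls(parcel_data.voxel_ts, raw, parcel_data.axes[0],
                           parcel_data.parcel_ts)
        offsets_i = 50.0 + 5.0 * rng.random(80)
        indep = snr_controls(parcel_data.voxel_ts,
                             parcel_data.voxel_ts + offsets_i[None, :],
                             parcel_data.axes[0], parcel_data.parcel_ts)
        assert dep["r_original_vs_spatial"] < \
            indep["r_original_vs_spatial"] + 1e-9


class TestExcludeTemporalLobe:
    def test_zero_flags_identical(self, parcel_data):
        conn = ParcelConnectome(np.corrcoef(parcel_data.parcel_ts.T),
                                centroids=parcel_data.centroids)
        emb = functional_gradients(conn, k=2)
        cmap = axis_fc_map(parcel_data.voxel_ts, parcel_data.axes[0],
                           parcel_data.parcel_ts)
        base = map_gradient_correspondence(cmap, emb.vectors,
                                           parcel_data.centroids,
                                           n_spins=99, seed=0)
        res, n_kept = exclude_temporal_lobe(
            cmap, emb.vectors, parcel_data.centroids,
            np.zeros(300, dtype=bool), n_spins=99, seed=0)
        assert n_kept == 300
        np.testing.assert_allclose(res.rho, base.rho, atol=1e-12)

    def test_flag_count_arithmetic(self, parcel_data):
        conn = ParcelConnectome(np.corrcoef(parcel_data.parcel_ts.T),
                                centroids=parcel_data.centroids)
        emb = functional_gradients(conn, k=2)
        cmap = axis_fc_map(parcel_data.voxel_ts, parcel_data.axes[0],
                           parcel_data.parcel_ts)
        flags = np.zeros(300, dtype=bool)
        flags[:59] = True   # 59/300 mirrors the 196/1000 bookkeeping
        res, n_kept = exclude_temporal_lobe(cmap, emb.vectors,
                                            parcel_data.centroids, flags,
                                            n_spins=99, seed=0)
        assert n_kept == 241

    def test_uninformative_flags_preserve_rho(self):
        data = make_gradient_parcel_data(
            320, 90, [1.0, 0.5], seed=11,
            axis_couplings=[[0.6, 0.0]], parcel_noise_sd=0.3,
            voxel_noise_sd=0.3)
        conn = ParcelConnectome(np.corrcoef(data.parcel_ts.T),
                                centroids=data.centroids)
        emb = functional_gradients(conn, k=2)
        cmap = axis_fc_map(data.voxel_ts, data.axes[0], data.parcel_ts)
        base = map_gradient_correspondence(cmap, emb.vectors, data.centroids,
                                           n_spins=99, seed=0)
        rng = np.random.default_rng(0)
        flags = np.zeros(320, dtype=bool)
        flags[rng.choice(320, 40, replace=False)] = True
        res, _ = exclude_temporal_lobe(cmap, emb.vectors, data.centroids,
                                       flags, n_spins=99, seed=0)
        assert abs(res.rho[0] - base.rho[0]) < 0.1
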