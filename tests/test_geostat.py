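"""Geostatistics: weights, Moran/LISA, variography, kriging, RBF,
distribution diagnostics — all checked against brute-force oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist, pdist, squareform

from geometab import (BimodalSpec, FieldSpec, Variogram, VariogramModel,
                      build_kernel_weights, distribution_diagnostics,
                      empirical_variogram, fit_exponential_model, local_moran,
                      make_grid, morans_i, ordinary_krige,
                      positions_to_local_meters, rbf_interpolate,
                      sample_positions, simulate_bimodal_field, simulate_grf)


def brute_force_weights(coords, k):
    """Direct O(n²) triangular-kernel evaluation."""
    n = len(coords)
    d = cdist(coords, coords)
    w = np.zeros((n, n))
    for i in range(n):
        h = np.sort(np.delete(d[i], i))[k - 1]
        for j in range(n):
            if i != j:
                w[i, j] = max(0.0, 1.0 - d[i, j] / h)
    return w


def brute_force_moran(values, w):
    z = values - values.mean()
    n = len(z)
    s0 = w.sum()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return n / s0 * num / (z @ z)


def brute_force_local_moran(values, w):
    z = values - values.mean()
    n = len(z)
    m2 = (z @ z) / n
    return np.array([z[i] / m2 * sum(w[i, j] * z[j] for j in range(n))
                     for i in range(n)])


class TestKernelWeights:
    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(2)
        coords = rng.uniform(0, 100, size=(12, 2))
        w = build_kernel_weights(coords, k=7, row_standardize=False)
        assert np.abs(w.matrix - brute_force_weights(coords, 7)).max() < 1e-12

    def test_neighbor_at_half_bandwidth_gets_weight_half(self):
        # site 0: nearest neighbour at distance 1, seven more on a ring of
        # radius 2 -> bandwidth h0 = 2, so w[0, nearest] = 1 - 1/2 = 0.5
        ring = [(2 * np.cos(t), 2 * np.sin(t))
                for t in np.linspace(0, 2 * np.pi, 8)[:-1]]
        coords = np.array([(0.0, 0.0), (1.0, 0.0)] + ring)
        w = build_kernel_weights(coords, k=7, row_standardize=False)
        assert w.matrix[0, 1] == pytest.approx(0.5, abs=1e-12)
        # the k-th neighbour sits exactly at the bandwidth -> weight 0
        assert w.matrix[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_bounds_and_zero_diagonal(self, field_coords):
        w = build_kernel_weights(field_coords, k=7, row_standardize=False)
        assert w.matrix.min() >= 0.0
        assert w.matrix.max() <= 1.0
        assert np.diagonal(w.matrix).max() == 0.0

    def test_row_standardized_rows_sum_to_one(self, field_coords):
        w = build_kernel_weights(field_coords, k=7)
        sums = w.matrix.sum(axis=1)
        assert np.abs(sums[sums > 0] - 1.0).max() < 1e-12

    def test_duplicate_coordinates_rejected(self):
        coords = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0]] +
                          [[i, 5.0] for i in range(8)])
        with pytest.raises(ValueError, match="duplicate"):
            build_kernel_weights(coords, k=3)


class TestMoran:
    @pytest.mark.parametrize("n", [10, 19, 30])
    def test_matches_brute_force_double_loop(self, n):
        rng = np.random.default_rng(n)
        coords = rng.uniform(0, 50, size=(n, 2))
        values = rng.normal(size=n)
        w = build_kernel_weights(coords, k=min(7, n - 2))
        res = morans_i(values, w, n_perm=99, seed=0)
        assert res.I == pytest.approx(brute_force_moran(values, w.matrix),
                                      abs=1e-12)

    def test_null_mean_matches_expectation(self, field_coords):
        """Mean of I over iid fields ≈ −1/(n−1) within 3 standard errors."""
        w = build_kernel_weights(field_coords, k=7)
        rng = np.random.default_rng(10)
        stats = [morans_i(rng.standard_normal(len(field_coords)), w,
                          n_perm=9, seed=1).I for _ in range(500)]
        se = np.std(stats) / np.sqrt(len(stats))
        assert abs(np.mean(stats) - (-1.0 / (len(field_coords) - 1))) < 3 * se

    def test_clustered_field_detected(self):
        spec = FieldSpec(n_sites=60, extent_m=(500.0, 200.0), nugget=0.09,
                         gps_sigma_m=0.0, seed=21)
        xy = positions_to_local_meters(sample_positions(spec), spec.origin_deg)
        values = simulate_bimodal_field(xy, spec,
                                        BimodalSpec(cluster_length_m=120.0))
        w = build_kernel_weights(xy, k=7)
        res = morans_i(values, w, n_perm=999, seed=3)
        assert res.I > 0.0
        assert res.p_perm <= 0.01

    def test_constant_values_rejected(self, field_coords):
        w = build_kernel_weights(field_coords, k=7)
        with pytest.raises(ValueError, match="constant"):
            morans_i(np.ones(len(field_coords)), w)


class TestLocalMoran:
    @pytest.mark.parametrize("n", [10, 24, 30])
    def test_matches_brute_force_per_site(self, n):
        rng = np.random.default_rng(100 + n)
        coords = rng.uniform(0, 50, size=(n, 2))
        values = rng.normal(size=n)
        w = build_kernel_weights(coords, k=min(7, n - 2))
        res = local_moran(values, w, n_perm=99, seed=0)
        assert np.abs(res.I - brute_force_local_moran(values, w.matrix)).max() \
            < 1e-12

    def test_decomposition_consistent_with_global_i(self, field_coords):
        rng = np.random.default_rng(6)
        values = rng.normal(size=len(field_coords))
        w = build_kernel_weights(field_coords, k=7)
        global_i = morans_i(values, w, n_perm=9, seed=0).I
        local = local_moran(values, w, n_perm=9, seed=0)
        assert local.I.sum() == pytest.approx(w.s0 * global_i, rel=1e-10)

    def test_high_center_among_high_neighbors_is_hh(self):
        coords = np.vstack([[0.0, 0.0],
                            [(np.cos(t), np.sin(t))
                             for t in np.linspace(0, 2 * np.pi, 9)[:-1]]])
        values = np.array([5.0] + [4.0] * 8)   # all above the mean of 0-ish?
        values = np.append(values, 0.0)        # one distant low site
        coords = np.vstack([coords, [50.0, 50.0]])
        w = build_kernel_weights(coords, k=7)
        res = local_moran(values, w, n_perm=99, seed=0)
        assert res.quadrant[0] == "HH"


class TestVariogram:
    def test_matches_brute_force_pair_enumeration(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 100, size=(15, 2))
        values = rng.normal(size=15)
        emp = empirical_variogram(coords, values, n_bins=6)
        # oracle: enumerate all pairs, bin by distance
        d = squareform(pdist(coords))
        max_lag = d[np.triu_indices(15, 1)].max() / 2
        edges = np.linspace(0, max_lag, 7)
        for b in range(6):
            pairs = [(0.5 * (values[i] - values[j]) ** 2)
                     for i in range(15) for j in range(i + 1, 15)
                     if (edges[b] <= d[i, j] < edges[b + 1])
                     or (b == 5 and d[i, j] == max_lag)]
            if not pairs:
                continue
            center = 0.5 * (edges[b] + edges[b + 1])
            k = int(np.argmin(np.abs(emp.bin_centers - center)))
            assert emp.gamma[k] == pytest.approx(np.mean(pairs), rel=1e-12)
            assert emp.counts[k] == len(pairs)

    def test_constant_values_give_zero_semivariance(self, field_coords):
        emp = empirical_variogram(field_coords, np.full(len(field_coords), 3.0))
        assert np.all(emp.gamma == 0.0)

    def test_iid_values_give_flat_variogram_at_variance(self, field_coords):
        rng = np.random.default_rng(8)
        draws = [rng.standard_normal(len(field_coords)) for _ in range(40)]
        gammas = np.mean([empirical_variogram(field_coords, v).gamma
                          for v in draws], axis=0)
        assert np.abs(gammas - 1.0).max() < 0.25

    def test_exact_bins_recover_parameters(self):
        h = np.linspace(5, 200, 20)
        from geometab.geostat import EmpiricalVariogram
        emp = EmpiricalVariogram(h, 0.1 + 1.0 * (1 - np.exp(-h / 30.0)),
                                 np.full(20, 50), 200.0)
        fit = fit_exponential_model(emp)
        assert fit.nugget == pytest.approx(0.1, abs=1e-6)
        assert fit.sill == pytest.approx(1.0, abs=1e-6)
        assert fit.corr_length == pytest.approx(30.0, abs=1e-4)
        assert not fit.no_spatial_structure

    def test_flat_variogram_flagged_no_structure(self):
        from geometab.geostat import EmpiricalVariogram
        h = np.linspace(5, 200, 20)
        emp = EmpiricalVariogram(h, np.full(20, 0.8), np.full(20, 50), 200.0)
        with pytest.warns(UserWarning, match="no spatial structure"):
            fit = fit_exponential_model(emp)
        assert fit.no_spatial_structure
        assert fit.corr_length == pytest.approx(10 * h.max())

    def test_simulation_recovery_within_25_percent(self):
        """GRF with ℓ = 30 m: median fitted length over 20 seeds near truth."""
        lengths = []
        for s in range(20):
            spec = FieldSpec(n_sites=150, extent_m=(300.0, 150.0),
                             corr_length_m=30.0, sill=1.0, nugget=0.1,
                             gps_sigma_m=0.0, seed=700 + s)
            xy = positions_to_local_meters(sample_positions(spec),
                                           spec.origin_deg)
            z = simulate_grf(xy, spec)
            try:
                import warnings
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lengths.append(Variogram(xy, z).fit().corr_length)
            except RuntimeError:
                continue
        assert abs(np.median(lengths) - 30.0) / 30.0 < 0.25


class TestOrdinaryKriging:
    @pytest.fixture
    def small_field(self):
        spec = FieldSpec(n_sites=20, extent_m=(100.0, 100.0),
                         corr_length_m=30.0, sill=1.0, nugget=0.0,
                         gps_sigma_m=0.0, seed=5)
        xy = positions_to_local_meters(sample_positions(spec), spec.origin_deg)
        return xy, simulate_grf(xy, spec), VariogramModel(0.0, 1.0, 30.0)

    def test_exact_interpolation_at_data_sites(self, small_field):
        xy, z, model = small_field
        kr = ordinary_krige(xy, z, model, xy)
        assert np.abs(kr.prediction - z).max() < 1e-8
        assert np.abs(kr.variance).max() < 1e-8

    def test_weights_sum_to_one_everywhere(self, small_field):
        xy, z, model = small_field
        _, _, nodes = make_grid(xy, shape=(25, 25))
        kr = ordinary_krige(xy, z, model, nodes)
        assert np.abs(kr.weights.sum(axis=1) - 1.0).max() < 1e-10

    def test_constant_field_predicts_constant(self, small_field):
        xy, _, model = small_field
        _, _, nodes = make_grid(xy, shape=(10, 10))
        kr = ordinary_krige(xy, np.full(len(xy), 2.5), model, nodes)
        assert np.abs(kr.prediction - 2.5).max() < 1e-10

    def test_matches_dense_direct_solve_oracle(self, small_field):
        """Independent per-node assembly and solve of the kriging system."""
        xy, z, model = small_field
        rng = np.random.default_rng(0)
        nodes = rng.uniform(xy.min(), xy.max(), size=(12, 2))
        kr = ordinary_krige(xy, z, model, nodes)
        n = len(xy)
        gam = lambda h: np.where(h == 0, 0.0,
                                 model.nugget + model.sill
                                 * (1 - np.exp(-h / model.corr_length)))
        for m, node in enumerate(nodes):
            a = np.ones((n + 1, n + 1))
            a[:n, :n] = gam(cdist(xy, xy))
            a[n, n] = 0.0
            rhs = np.append(gam(np.linalg.norm(xy - node, axis=1)), 1.0)
            sol = np.linalg.solve(a, rhs)
            assert kr.prediction[m] == pytest.approx(sol[:n] @ z, abs=1e-10)

    def test_duplicate_sites_rejected(self, small_field):
        xy, z, model = small_field
        bad = np.vstack([xy, xy[0]])
        with pytest.raises(ValueError, match="duplicate"):
            ordinary_krige(bad, np.append(z, z[0]), model, xy)


class TestRbfInterpolation:
    def test_reproduces_data_at_sites(self, field_coords):
        rng = np.random.default_rng(1)
        z = rng.normal(size=len(field_coords))
        out = rbf_interpolate(field_coords, z, field_coords)
        assert np.abs(out - z).max() < 1e-8

    def test_reproduces_affine_surface_exactly(self, field_coords):
        z = 0.3 * field_coords[:, 0] - 1.2 * field_coords[:, 1] + 7.0
        _, _, nodes = make_grid(field_coords, shape=(15, 15))
        out = rbf_interpolate(field_coords, z, nodes)
        expected = 0.3 * nodes[:, 0] - 1.2 * nodes[:, 1] + 7.0
        assert np.abs(out - expected).max() < 1e-6 * np.abs(expected).max()

    def test_matches_direct_dense_thin_plate_solve(self):
        """Oracle: assemble and solve the TPS system with the affine tail."""
        rng = np.random.default_rng(9)
        coords = rng.uniform(0, 10, size=(15, 2))
        z = rng.normal(size=15)
        nodes = rng.uniform(0, 10, size=(20, 2))

        def tps(r):
            with np.errstate(divide="ignore", invalid="ignore"):
                return np.where(r > 0, r**2 * np.log(r), 0.0)

        n = len(coords)
        a = np.zeros((n + 3, n + 3))
        a[:n, :n] = tps(cdist(coords, coords))
        p = np.column_stack([np.ones(n), coords])
        a[:n, n:] = p
        a[n:, :n] = p.T
        sol = np.linalg.solve(a, np.append(z, [0.0, 0.0, 0.0]))
        oracle = tps(cdist(nodes, coords)) @ sol[:n] \
            + np.column_stack([np.ones(len(nodes)), nodes]) @ sol[n:]
        got = rbf_interpolate(coords, z, nodes)
        assert np.abs(got - oracle).max() < 1e-8

    def test_collinear_points_rejected(self):
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            rbf_interpolate(coords, np.arange(5.0), coords)


class TestDistributionDiagnostics:
    def test_histogram_counts_sum_to_n(self):
        rng = np.random.default_rng(0)
        diag = distribution_diagnostics(rng.standard_normal(321))
        assert diag.hist_counts.sum() == 321

    def test_normal_sample_qq_near_identity(self):
        rng = np.random.default_rng(1)
        diag = distribution_diagnostics(rng.standard_normal(1000))
        inner = slice(10, -10)    # tail order statistics are noisy
        assert np.abs(diag.qq_sample[inner]
                      - diag.qq_theoretical[inner]).max() < 0.25

    def test_bimodal_field_shows_two_kde_modes(self):
        spec = FieldSpec(n_sites=400, extent_m=(500.0, 500.0), nugget=0.04,
                         gps_sigma_m=0.0, seed=2)
        xy = positions_to_local_meters(sample_positions(spec), spec.origin_deg)
        values = simulate_bimodal_field(xy, spec, BimodalSpec())
        assert distribution_diagnostics(values).kde_mode_count() == 2
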