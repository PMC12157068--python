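import numpy as np
import pytest

from lemnopt import DomainError, SingularSystemError
from lemnopt.light_field import (
    GridSpec,
    KrigedField,
    PARMeasurement,
    RingSpec,
    VariogramModel,
    empirical_variogram,
    fit_spherical_variogram,
    krige,
    read_measurements_csv,
    ring_average,
    write_measurements_csv,
)


def gaussian_process_sample(model: VariogramModel, xy: np.ndarray, rng, mean=100.0):
    """Draw one field realization whose variogram is the given model
    (treating nugget + partial sill as the total variance)."""
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    sill = model.nugget + model.partial_sill
    gamma = model.semivariance(dx, dy)
    np.fill_diagonal(gamma, 0.0)
    cov = sill - gamma
    cov += 1e-8 * sill * np.eye(len(xy))
    chol = np.linalg.cholesky(cov)
    return mean + chol @ rng.standard_normal(len(xy))


def kriging_oracle(measurements, model, x0, y0):
    """Directly assembled and solved ordinary-kriging system at one point."""
    xy = np.array([(m.x, m.y) for m in measurements])
    z = np.array([m.intensity for m in measurements])
    n = len(z)
    a = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            if i != j:
                a[i, j] = model.semivariance(xy[i, 0] - xy[j, 0], xy[i, 1] - xy[j, 1])
    a[n, :n] = 1.0
    a[:n, n] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        if (xy[i, 0], xy[i, 1]) != (x0, y0):
            b[i] = model.semivariance(xy[i, 0] - x0, xy[i, 1] - y0)
    b[n] = 1.0
    lam = np.linalg.solve(a, b)
    return float(lam[:n] @ z)


@pytest.fixture()
def iso_model():
    return VariogramModel(nugget=0.0, partial_sill=25.0, major_range=400.0, minor_range=400.0)


class TestEmpiricalVariogram:
    def test_constant_field_all_zero(self, rng):
        pts = [PARMeasurement(float(x), float(y), 7.0)
               for x, y in rng.uniform(0, 100, (20, 2))]
        emp = empirical_variogram(pts, n_bins=5)
        assert np.nansum(emp.semivariances) == 0.0

    def test_two_points_single_bin(self):
        pts = [PARMeasurement(0.0, 0.0, 10.0), PARMeasurement(3.0, 4.0, 4.0)]
        emp = empirical_variogram(pts, n_bins=1, max_lag=10.0)
        assert emp.semivariances[0, 0] == pytest.approx(0.5 * (10.0 - 4.0) ** 2)
        assert emp.counts[0, 0] == 1

    def test_empty_bins_flagged(self):
        pts = [PARMeasurement(0.0, 0.0, 1.0), PARMeasurement(1.0, 0.0, 2.0),
               PARMeasurement(2.0, 0.0, 3.0)]
        emp = empirical_variogram(pts, n_bins=10, max_lag=100.0)
        assert np.any(emp.counts == 0)
        assert np.all(np.isnan(emp.semivariances[emp.counts == 0]))

    def test_binned_values_near_model_curve(self, iso_model, rng):
        xy = rng.uniform(0, 800, (65, 2))
        z = gaussian_process_sample(iso_model, xy, rng)
        pts = [PARMeasurement(x, y, max(v, 0.0)) for (x, y), v in zip(xy, z)]
        emp = empirical_variogram(pts, n_bins=6)
        mask = emp.counts > 30
        expected = iso_model.semivariance_at_lag(emp.lags[mask])
        got = emp.semivariances[mask]
        # one 65-point realization: generous Monte-Carlo tolerance
        assert np.all(np.abs(got - expected) < 0.8 * (iso_model.partial_sill + 1))

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            empirical_variogram([PARMeasurement(0, 0, 1.0)])


def pooled_empirical_variogram(model, rng, n_real=60, n_pts=250, domain=2000.0,
                               n_bins=14, n_sectors=1, max_lag=None):
    """Empirical variogram averaged over many independent realizations at
    fixed locations; converges to the model curve (single realizations in a
    domain only a few ranges wide do not)."""
    xy = rng.uniform(0, domain, (n_pts, 2))
    dx = xy[:, 0][:, None] - xy[:, 0][None, :]
    dy = xy[:, 1][:, None] - xy[:, 1][None, :]
    sill = model.nugget + model.partial_sill
    gamma = model.semivariance(dx, dy)
    np.fill_diagonal(gamma, 0.0)
    cov = sill - gamma + 1e-8 * sill * np.eye(n_pts)
    chol = np.linalg.cholesky(cov)
    acc = None
    for _ in range(n_real):
        z = 100.0 + chol @ rng.standard_normal(n_pts)
        pts = [PARMeasurement(x, y, v) for (x, y), v in zip(xy, z)]
        emp = empirical_variogram(pts, n_bins=n_bins, n_sectors=n_sectors, max_lag=max_lag)
        if acc is None:
            acc = emp
            total = np.nan_to_num(emp.semivariances) * 1.0
        else:
            total += np.nan_to_num(emp.semivariances)
    mean_gamma = np.where(acc.counts > 0, total / n_real, np.nan)
    from lemnopt.light_field import EmpiricalVariogram

    return EmpiricalVariogram(acc.lags, mean_gamma, acc.counts * n_real, acc.sector_angles_deg)


class TestFitSphericalVariogram:
    def test_recovers_known_isotropic_model(self, iso_model, rng):
        emp = pooled_empirical_variogram(iso_model, rng, max_lag=800.0)
        model = fit_spherical_variogram(emp, anisotropy=False)
        assert model.partial_sill == pytest.approx(iso_model.partial_sill, rel=0.15)
        assert model.major_range == pytest.approx(iso_model.major_range, rel=0.15)
        assert model.nugget < 0.15 * iso_model.partial_sill

    def test_recovers_known_anisotropic_model(self, rng):
        true = VariogramModel(nugget=0.0, partial_sill=25.0, major_range=500.0,
                              minor_range=250.0, angle_deg=30.0)
        emp = pooled_empirical_variogram(true, rng, n_sectors=6, n_bins=10, max_lag=800.0)
        model = fit_spherical_variogram(emp, anisotropy=True)
        assert model.partial_sill == pytest.approx(true.partial_sill, rel=0.15)
        ratio = model.minor_range / model.major_range
        assert ratio == pytest.approx(0.5, abs=0.15)
        assert abs(model.angle_deg - 30.0) < 20.0

    def test_isotropic_data_near_unit_anisotropy(self, iso_model, rng):
        emp = pooled_empirical_variogram(iso_model, rng, n_sectors=4, n_bins=10, max_lag=800.0)
        model = fit_spherical_variogram(emp, anisotropy=True)
        assert model.minor_range / model.major_range > 0.9

    def test_gamma_at_zero_is_nugget(self):
        m = VariogramModel(nugget=3.0, partial_sill=10.0, major_range=100.0, minor_range=100.0)
        assert m.semivariance_at_lag(0.0) == 3.0

    def test_sill_reached_at_range(self):
        m = VariogramModel(nugget=1.0, partial_sill=10.0, major_range=100.0, minor_range=100.0)
        assert m.semivariance_at_lag(100.0) == pytest.approx(11.0)
        assert m.semivariance_at_lag(500.0) == pytest.approx(11.0)

    def test_too_few_bins(self):
        pts = [PARMeasurement(0, 0, 1.0), PARMeasurement(1, 0, 2.0)]
        emp = empirical_variogram(pts, n_bins=1, max_lag=2.0)
        with pytest.raises(DomainError):
            fit_spherical_variogram(emp)


class TestKrige:
    def test_exact_at_data_with_zero_nugget(self, iso_model, rng):
        xy = rng.uniform(0, 500, (65, 2))
        z = gaussian_process_sample(iso_model, xy, rng)
        pts = [PARMeasurement(x, y, v) for (x, y), v in zip(xy, z)]
        grid = GridSpec(0, 500, 0, 500, 40, 40)
        field = krige(pts, iso_model, grid)
        # predict exactly at the measurement coordinates via a 1-node grid
        for m in pts[:10]:
            tiny = GridSpec(m.x, m.x + 1e-9, m.y, m.y + 1e-9, 2, 2)
            f = krige(pts, iso_model, tiny)
            assert f.values[0, 0] == pytest.approx(m.intensity, abs=1e-8)

    def test_constant_measurements_constant_field(self, iso_model):
        pts = [PARMeasurement(float(x), float(y), 55.5)
               for x in (0, 100, 200) for y in (0, 150)]
        field = krige(pts, iso_model, GridSpec(0, 200, 0, 150, 20, 20))
        assert np.allclose(field.values, 55.5, atol=1e-9)

    def test_three_point_linear_solve_oracle(self, iso_model):
        pts = [
            PARMeasurement(0.0, 0.0, 10.0),
            PARMeasurement(100.0, 0.0, 20.0),
            PARMeasurement(0.0, 100.0, 30.0),
        ]
        grid = GridSpec(0, 100, 0, 100, 5, 5)
        field = krige(pts, iso_model, grid)
        gx, gy = grid.nodes()
        for i in range(5):
            for j in range(5):
                want = kriging_oracle(pts, iso_model, gx[i, j], gy[i, j])
                assert field.values[i, j] == pytest.approx(want, abs=1e-10)

    def test_weights_sum_to_one_via_shift_invariance(self, iso_model, rng):
        # adding a constant to all data must shift every prediction by it
        xy = rng.uniform(0, 300, (20, 2))
        z = rng.uniform(10, 50, 20)
        grid = GridSpec(0, 300, 0, 300, 10, 10)
        f1 = krige([PARMeasurement(x, y, v) for (x, y), v in zip(xy, z)], iso_model, grid)
        f2 = krige([PARMeasurement(x, y, v + 100) for (x, y), v in zip(xy, z)], iso_model, grid)
        assert np.allclose(f2.values - f1.values, 100.0, atol=1e-8)

    def test_predictions_within_data_range(self, iso_model, rng):
        xy = rng.uniform(0, 400, (40, 2))
        z = rng.uniform(20, 120, 40)
        pts = [PARMeasurement(x, y, v) for (x, y), v in zip(xy, z)]
        field = krige(pts, iso_model, GridSpec(0, 400, 0, 400, 30, 30))
        # empirical observation on these fixtures, not a theorem
        assert field.values.min() >= z.min() - 5.0
        assert field.values.max() <= z.max() + 5.0

    def test_duplicate_points_reported(self, iso_model):
        pts = [PARMeasurement(0, 0, 1.0), PARMeasurement(0, 0, 2.0), PARMeasurement(1, 1, 3.0)]
        with pytest.raises(SingularSystemError, match="duplicate"):
            krige(pts, iso_model)

    def test_default_grid_is_100_by_100(self, iso_model, rng):
        xy = rng.uniform(0, 200, (10, 2))
        pts = [PARMeasurement(x, y, 10.0 + x / 100) for x, y in xy]
        field = krige(pts, iso_model)
        assert field.values.shape == (100, 100)

    def test_variance_nonnegative_and_zero_at_data(self, iso_model, rng):
        pts = [
            PARMeasurement(0.0, 0.0, 10.0),
            PARMeasurement(100.0, 0.0, 20.0),
            PARMeasurement(0.0, 100.0, 30.0),
        ]
        grid = GridSpec(0, 100, 0, 100, 3, 3)
        field = krige(pts, iso_model, grid, compute_variance=True)
        assert field.variance is not None
        assert np.all(field.variance >= 0)
        assert field.variance[0, 0] == pytest.approx(0.0, abs=1e-9)


class TestRingAverage:
    def _constant_field(self, value=42.0):
        grid = GridSpec(0, 100, 0, 100, 50, 50)
        return KrigedField(grid=grid, values=np.full((50, 50), value))

    def test_constant_field(self):
        mean, sd = ring_average(self._constant_field(), RingSpec(50, 50, 60))
        assert mean == 42.0
        assert sd == 0.0

    def test_full_cover_equals_global_stats(self, rng):
        grid = GridSpec(0, 100, 0, 100, 30, 30)
        vals = rng.uniform(0, 10, (30, 30))
        field = KrigedField(grid=grid, values=vals)
        mean, sd = ring_average(field, RingSpec(50, 50, 1000))
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(vals.std(ddof=1))

    def test_linear_gradient_centered_ring(self):
        grid = GridSpec(0, 100, 0, 100, 101, 101)
        gx, gy = grid.nodes()
        field = KrigedField(grid=grid, values=3.0 * gx + 1.0)
        mean, _ = ring_average(field, RingSpec(50, 50, 60))
        assert mean == pytest.approx(3.0 * 50 + 1.0, abs=3.0 * 1.0)  # one-cell tolerance

    def test_ring_outside_grid_signalled(self):
        with pytest.raises(DomainError):
            ring_average(self._constant_field(), RingSpec(500, 500, 10))

    def test_rotation_invariance_of_ring_means(self, iso_model, rng):
        xy = rng.uniform(-200, 200, (40, 2))
        z = gaussian_process_sample(iso_model, xy, rng)
        theta = np.deg2rad(90.0)
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy_rot = xy @ rot.T
        grid = GridSpec(-250, 250, -250, 250, 100, 100)
        f1 = krige([PARMeasurement(x, y, v) for (x, y), v in zip(xy, z)], iso_model, grid)
        f2 = krige([PARMeasurement(x, y, v) for (x, y), v in zip(xy_rot, z)], iso_model, grid)
        ring = RingSpec(0.0, 0.0, 237.6)
        m1, _ = ring_average(f1, ring)
        m2, _ = ring_average(f2, ring)
        assert m1 == pytest.approx(m2, rel=0.02)


class TestMeasurementIO:
    def test_round_trip(self, tmp_path):
        pts = [PARMeasurement(1.5, 2.5, 100.0), PARMeasurement(3.0, 4.0, 50.0)]
        path = tmp_path / "survey.csv"
        write_measurements_csv(pts, path)
        back = read_measurements_csv(path)
        assert back == pts

    def test_negative_intensity_rejected(self):
        with pytest.raises(DomainError):
            PARMeasurement(0, 0, -1.0)
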