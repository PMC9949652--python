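import numpy as np
import pytest

from cmcdyn.exceptions import ConvergenceRadiusError
from cmcdyn.params import CMCParameters, CouplingFunction
from cmcdyn.reduction import (
    build_potential,
    fast_period,
    mc_spherical_average,
    orbit_average_drift,
    population_drift_exact,
    population_drift_series,
    taylor_coefficients,
    total_drift,
    total_drift_exact,
    PotentialProfile,
)

TANH = CouplingFunction("tanh")


class TestFastPeriod:
    def test_integer_frequencies(self):
        cfg = fast_period([1.0, 2.0, 3.0, 4.0])
        assert cfg.T == pytest.approx(2 * np.pi)
        assert cfg.commensurate

    def test_single_frequency(self):
        cfg = fast_period([5.0, 5.0, 5.0, 5.0])
        assert cfg.T == pytest.approx(2 * np.pi / 5)

    def test_rational_ratio(self):
        # ratios 1 : 1.5 -> common period 2 cycles of the slower band
        cfg = fast_period([2.0, 3.0])
        assert cfg.T == pytest.approx(2 * np.pi)

    def test_incommensurate_capped_and_flagged(self):
        cfg = fast_period([1.0, np.sqrt(2), 2.0, 3.0], tol=1e-3)
        assert not cfg.commensurate
        assert cfg.T <= 200 * 2 * np.pi + 1e-9

    def test_default_band_stack(self):
        cfg = fast_period([2 * np.pi, 4 * np.pi, 6 * np.pi, 8 * np.pi])
        assert cfg.T == pytest.approx(1.0)


class TestTaylorCoefficients:
    def test_identity_coupling(self):
        dm = taylor_coefficients(CouplingFunction("linear"), 4)
        assert np.allclose(dm.coefficients, [1, 0, 0, 0])

    def test_tanh_maclaurin(self):
        dm = taylor_coefficients(TANH, 3)
        assert np.allclose(dm.coefficients, [1.0, -1 / 3, 2 / 15])

    def test_gain_slope_scaling(self):
        g, s = 2.0, 0.5
        base = taylor_coefficients(TANH, 4).coefficients
        scaled = taylor_coefficients(CouplingFunction("tanh", gain=g, slope=s), 4)
        r = np.arange(1, 5)
        assert np.allclose(scaled.coefficients, g * s ** (2 * r - 1) * base)

    def test_tanh_sum_is_weighted_combination(self):
        comps = ((1.5, 2.0), (-0.5, 0.7))
        dm = taylor_coefficients(CouplingFunction("tanh_sum", components=comps), 5)
        base = taylor_coefficients(TANH, 5).coefficients
        r = np.arange(1, 6)
        expect = sum(w * s ** (2.0 * r - 1) * base for w, s in comps)
        assert np.allclose(dm.coefficients, expect)

    def test_matches_numerical_derivative_of_coupling(self):
        """B_1 and B_3 agree with small-argument evaluation of the coupling."""
        cf = CouplingFunction("tanh", gain=1.2, slope=0.8)
        dm = taylor_coefficients(cf, 6)
        x = np.array([1e-3])
        series = sum(
            b * x ** (2 * r - 1) for r, b in enumerate(dm.coefficients, start=1)
        )
        assert np.allclose(series, cf(x), rtol=1e-10)


class TestPopulationDrift:
    def test_zero_self_connection_zero_drift(self):
        p = CMCParameters(G=np.zeros((4, 4)), mu=0.2, P=TANH)
        dm = taylor_coefficients(TANH, 10)
        assert population_drift_series(1.0, 0, p, dm) == 0.0

    def test_linear_coupling_printed_value(self):
        # mu * w1 * g11 * B1 * R/2 with B1=1, mu=.1, w1=2pi, g=1, R=2 -> 0.2*pi
        p = CMCParameters(G=np.diag([1.0, 0, 0, 0]), mu=0.1, P=CouplingFunction("linear"))
        dm = taylor_coefficients(p.P, 5)
        assert population_drift_series(2.0, 0, p, dm) == pytest.approx(0.2 * np.pi)

    def test_zero_amplitude_zero_drift(self):
        p = CMCParameters(G=np.diag([1.0, 0, 0, 0]), mu=0.1, P=TANH)
        dm = taylor_coefficients(TANH, 10)
        assert population_drift_series(0.0, 0, p, dm) == 0.0

    def test_outside_convergence_radius_raises(self):
        p = CMCParameters(G=np.diag([1.0, 0, 0, 0]), mu=0.1, P=CouplingFunction("tanh", slope=2.0))
        dm = taylor_coefficients(p.P, 20)
        with pytest.raises(ConvergenceRadiusError):
            population_drift_series(3.0, 0, p, dm)

    def test_series_matches_exact_quadrature_inside_radius(self):
        p = CMCParameters(G=np.diag([0.7, 0, 0, 0]), mu=0.05, P=TANH)
        dm = taylor_coefficients(TANH, 25)
        for R in [0.2, 0.6, 1.1]:
            assert population_drift_series(R, 0, p, dm) == pytest.approx(
                population_drift_exact(R, 0, p), rel=1e-8
            )


class TestOrbitAverage:
    CFG = fast_period([2 * np.pi, 4 * np.pi, 6 * np.pi, 8 * np.pi])

    def test_unperturbed_drift_vanishes(self):
        p = CMCParameters()
        d = orbit_average_drift(np.array([0.8, 0.6, 0.9, 0.7]), p, self.CFG)
        assert np.max(np.abs(d)) < 1e-10

    def test_first_order_agreement_with_series(self):
        G = np.diag([0.8, -0.5, 0.6, -0.9])
        R = np.array([0.8, 0.6, 0.9, 0.7])
        dm = taylor_coefficients(TANH, 25)
        mu = 1e-3
        p = CMCParameters(G=G, mu=mu, P=TANH)
        flow = orbit_average_drift(R, p, self.CFG)
        ser = np.array([population_drift_series(R[i], i, p, dm) for i in range(4)])
        assert np.max(np.abs(flow - ser)) < 50 * mu**2

    def test_discrepancy_scales_as_mu_squared(self):
        G = np.diag([0.8, -0.5, 0.6, -0.9])
        R = np.array([0.8, 0.6, 0.9, 0.7])
        dm = taylor_coefficients(TANH, 25)
        errs = []
        mus = [1e-2, 1e-3, 1e-4]
        for mu in mus:
            p = CMCParameters(G=G, mu=mu, P=TANH)
            flow = orbit_average_drift(R, p, self.CFG)
            ser = np.array([population_drift_series(R[i], i, p, dm) for i in range(4)])
            errs.append(np.max(np.abs(flow - ser)))
        slope = np.polyfit(np.log(mus), np.log(errs), 1)[0]
        assert slope >= 1.8

    def test_potential_coupling_enters_at_second_order(self):
        """With mu = 0 the averaged radial drift is O(epsilon^2)."""
        rng = np.random.default_rng(3)
        G = rng.uniform(-1, 1, (4, 4))
        np.fill_diagonal(G, 0.0)
        R = np.array([0.8, 0.6, 0.9, 0.7])
        for eps in (0.1, 0.05):
            p = CMCParameters(G=G, mu=0.0, epsilon=eps, S=TANH, P=TANH)
            d = orbit_average_drift(R, p, self.CFG)
            assert np.max(np.abs(d)) <= 5 * eps**2


class TestTotalDrift:
    P_MULTI = CMCParameters(
        G=np.diag([0.8, -0.5, 0.6, -0.9]),
        mu=0.05,
        P=CouplingFunction("tanh", slope=0.5),
        leadfield=np.array([1.2, 0.9, 1.0, 0.8]),
    )

    def test_zero_connectivity_or_amplitude(self):
        dm = taylor_coefficients(TANH, 10)
        p0 = CMCParameters(mu=0.1, P=TANH)
        assert total_drift(1.0, p0, dm) == 0.0
        assert total_drift(0.0, self.P_MULTI, dm) == 0.0

    def test_closed_form_matches_monte_carlo(self):
        dm = taylor_coefficients(self.P_MULTI.P, 30)
        for Rs in [0.3, 0.55, 0.8]:
            cf = total_drift(Rs, self.P_MULTI, dm)
            est, se = mc_spherical_average(Rs, self.P_MULTI, dm, n_samples=100_000, seed=11)
            assert abs(cf - est) < 3 * se

    def test_single_population_reduces_to_per_population_drift(self):
        p = CMCParameters(
            G=np.diag([1.0, 0, 0, 0]), mu=0.05, P=TANH,
            leadfield=np.array([2.0, 0, 0, 0]),
        )
        for Rs in [0.4, 1.0, 2.5]:
            assert total_drift_exact(Rs, p) == pytest.approx(
                population_drift_exact(Rs, 0, p), rel=1e-12
            )

    def test_monte_carlo_error_scaling(self):
        dm = taylor_coefficients(self.P_MULTI.P, 25)
        _, se1 = mc_spherical_average(0.8, self.P_MULTI, dm, n_samples=50_000, seed=2)
        _, se2 = mc_spherical_average(0.8, self.P_MULTI, dm, n_samples=100_000, seed=3)
        assert 0.6 <= se2 / se1 <= 0.85


class TestBuildPotential:
    def test_gradient_identity(self, bistable_params, bistable_profile):
        """U' on the grid equals minus the tabulated drift."""
        grad = np.gradient(bistable_profile.U, bistable_profile.R_grid)
        inner = slice(5, -5)
        assert np.allclose(grad[inner], -bistable_profile.drift[inner], atol=5e-6)

    def test_normalization_and_alternation(self, bistable_profile):
        assert bistable_profile.U[0] == 0.0
        locs = sorted(
            [(e.location, "min") for e in bistable_profile.minima]
            + [(e.location, "max") for e in bistable_profile.maxima]
        )
        kinds = [k for _, k in locs]
        assert kinds == ["min", "max", "min"]

    def test_curvature_signs(self, bistable_profile):
        assert all(e.curvature > 0 for e in bistable_profile.minima)
        assert all(e.curvature < 0 for e in bistable_profile.maxima)

    def test_zero_connectivity_flat_degenerate(self):
        p = CMCParameters(mu=0.1, P=TANH, leadfield=np.array([2.0, 0, 0, 0]))
        prof = build_potential(p, np.linspace(0, 2, 600), method="oracle")
        assert np.allclose(prof.U, 0.0)
        assert prof.minima[0].degenerate

    def test_series_and_oracle_agree_inside_radius(self):
        p = CMCParameters(
            G=np.diag([0.6, 0, 0, 0]), mu=0.05, P=CouplingFunction("tanh", slope=0.6),
            leadfield=np.array([2.0, 0, 0, 0]),
        )
        grid = np.linspace(0, 1.8, 600)
        a = build_potential(p, grid, method="oracle")
        b = build_potential(p, grid, method="series")
        assert np.allclose(a.U, b.U, atol=1e-10)

    def test_coarse_grid_rejected(self, bistable_params):
        with pytest.raises(ValueError, match="500"):
            build_potential(bistable_params, np.linspace(0, 3.5, 100))

    def test_csv_round_trip(self, tmp_path, bistable_profile):
        path = tmp_path / "prof.csv"
        bistable_profile.to_csv(path)
        back = PotentialProfile.from_csv(path)
        assert np.allclose(back.U, bistable_profile.U)
        assert np.allclose(back.drift, bistable_profile.drift)
        assert back.minima[1].location == pytest.approx(
            bistable_profile.minima[1].location
        )
        assert back.maxima[0].curvature == pytest.approx(
            bistable_profile.maxima[0].curvature
        )
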