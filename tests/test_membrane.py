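"""Membrane mechanics: analytic anchors, relaxation, stability, sweeps."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from nanopearl import (
    MembraneParams,
    ShapeState,
    cmc_deviation,
    helfrich_energy,
    osmotic_pressure,
    pearling_stability,
    relax_cylinder,
    relax_shape,
    sweep_parameters,
)

NO_OSMO = MembraneParams(kappa=30.0, sigma=0.0, c_ext_mosm=0.0, n_solute=0.0)


def sphere_state(radius: float, n: int = 4001, clip: float = 1e-3) -> ShapeState:
    z = np.linspace(-radius * (1 - clip), radius * (1 - clip), n)
    return ShapeState(z, np.sqrt(radius**2 - z**2), periodic=False)


class TestHelfrichEnergy:
    @pytest.mark.parametrize("radius", [100.0, 200.0, 500.0])
    def test_sphere_bending_energy_scale_invariant(self, radius):
        """E_bend = 8 pi kappa for any sphere radius (C0 = 0)."""
        eb = helfrich_energy(sphere_state(radius), NO_OSMO)
        assert eb.bending == pytest.approx(8 * np.pi * 30.0, rel=0.01)

    def test_cylinder_bending_energy(self):
        """Cylinder: H = 1/(2r), A = 2 pi r L -> E_bend = pi kappa L / r."""
        length, r0 = 1000.0, 100.0
        z = np.arange(256) * (length / 256)
        eb = helfrich_energy(ShapeState(z, np.full(256, r0)), NO_OSMO)
        assert eb.bending == pytest.approx(np.pi * 30.0 * length / r0, rel=1e-6)
        assert eb.area == pytest.approx(2 * np.pi * r0 * length, rel=1e-6)
        assert eb.volume == pytest.approx(np.pi * r0**2 * length, rel=1e-6)

    def test_flat_limit_vanishing_density(self):
        """Bending energy per unit area -> 0 as the tube fattens."""
        length = 1000.0
        z = np.arange(128) * (length / 128)
        densities = []
        for r0 in (100.0, 1000.0, 10000.0):
            eb = helfrich_energy(ShapeState(z, np.full(128, r0)), NO_OSMO)
            densities.append(eb.bending / eb.area)
        assert densities[0] > densities[1] > densities[2]
        assert densities[2] < 1e-6

    def test_refinement_convergence(self):
        """Halving the grid changes the total by < 0.1% (smooth shape)."""
        params = MembraneParams()
        totals = []
        for n in (96, 192):
            z = np.arange(n) * (1000.0 / n)
            r = 100.0 + 20.0 * np.cos(2 * np.pi * z / 1000.0)
            p = params.with_isotonic_solute(np.pi * 100**2 * 1000.0)
            totals.append(helfrich_energy(ShapeState(z, r), p).total)
        assert abs(totals[1] - totals[0]) / abs(totals[0]) < 1e-3

    def test_nonpositive_radius_rejected(self):
        z = np.arange(64) * 10.0
        r = np.full(64, 50.0)
        r[10] = -1.0
        with pytest.raises(ValueError):
            helfrich_energy(ShapeState(z, r), NO_OSMO)


class TestOsmoticPressure:
    def test_isotonic_balance(self):
        p = MembraneParams(c_ext_mosm=300.0, n_solute=1000.0)
        assert osmotic_pressure(1000.0 / p.c_ext, p) == pytest.approx(0.0, abs=1e-15)

    def test_doubling_external_osmolarity_linear(self):
        p1 = MembraneParams(c_ext_mosm=300.0, n_solute=1000.0)
        p2 = MembraneParams(c_ext_mosm=600.0, n_solute=1000.0)
        v = 1e7
        assert osmotic_pressure(v, p1) - osmotic_pressure(v, p2) == pytest.approx(
            p1.c_ext, rel=1e-12
        )

    def test_large_volume_limit(self):
        p = MembraneParams(c_ext_mosm=300.0, n_solute=1000.0)
        assert osmotic_pressure(1e18, p) == pytest.approx(-p.c_ext, rel=1e-6)

    def test_decreasing_in_volume_and_invalid_volume(self):
        p = MembraneParams(c_ext_mosm=300.0, n_solute=1000.0)
        vs = np.logspace(5, 9, 10)
        dp = [osmotic_pressure(v, p) for v in vs]
        assert np.all(np.diff(dp) < 0)
        with pytest.raises(ValueError):
            osmotic_pressure(0.0, p)


class TestYoungLaplace:
    def test_equilibrium_sphere_pressure_balance(self):
        """Minimizing E(R) over sphere radii: dP = 2 sigma / R within 1%.

        On a sphere the bending term is scale-invariant, so the radius
        that minimizes the total energy balances tension against the
        osmotic pressure difference exactly as Young-Laplace demands.
        """
        params = MembraneParams(kappa=30.0, sigma=0.02, c_ext_mosm=300.0, n_solute=0.0)
        r_iso = 400.0
        params = params.with_isotonic_solute(4 * np.pi / 3 * r_iso**3)

        def total(radius: float) -> float:
            area = 4 * np.pi * radius**2
            vol = 4 * np.pi / 3 * radius**3
            e_bend = 8 * np.pi * params.kappa
            e_osm = params.c_ext * vol - params.n_solute * np.log(
                vol / (params.n_solute / params.c_ext)
            )
            return e_bend + params.sigma * area + e_osm

        res = minimize_scalar(total, bounds=(100.0, 1000.0), method="bounded")
        r_eq = res.x
        dp = osmotic_pressure(4 * np.pi / 3 * r_eq**3, params)
        assert dp == pytest.approx(2 * params.sigma / r_eq, rel=0.01)

    def test_zero_tension_sphere_is_isotonic(self):
        """sigma = 0: the equilibrium sphere sits at dP = 0."""
        params = MembraneParams(kappa=30.0, sigma=0.0, c_ext_mosm=300.0, n_solute=0.0)
        r_iso = 300.0
        params = params.with_isotonic_solute(4 * np.pi / 3 * r_iso**3)

        def total(radius: float) -> float:
            vol = 4 * np.pi / 3 * radius**3
            return 8 * np.pi * params.kappa + params.c_ext * vol - params.n_solute * np.log(
                vol / (params.n_solute / params.c_ext)
            )

        res = minimize_scalar(total, bounds=(100.0, 900.0), method="bounded")
        dp = osmotic_pressure(4 * np.pi / 3 * res.x**3, params)
        assert abs(dp) < 1e-2 * 2 * 0.02 / res.x  # |dP| ~ 0 vs a tension scale


class TestRelaxation:
    def test_energy_monotone_over_accepted_iterations(self):
        state, report = relax_cylinder(
            100.0, MembraneParams(), grid_n=64, max_iter=2000, tol=1e-4,
            seed=2, record_energy=True,
        )
        trace = report.energy_trace
        assert trace is not None and trace.size > 10
        assert np.all(np.diff(trace) <= 1e-9 * np.abs(trace[:-1]) + 1e-9)

    def test_tense_tube_pearls(self):
        """sigma r0^2 / kappa >> 1: relaxed modulation exceeds 5% of r0."""
        params = MembraneParams(kappa=50.0, sigma=0.05)
        assert params.sigma * 100.0**2 / params.kappa > 5
        state, report = relax_cylinder(100.0, params, grid_n=96, max_iter=15000, tol=1e-4, seed=1)
        assert not report.pinched_off
        modulation = (state.r.max() - state.r.min()) / 2.0
        assert modulation > 0.05 * 100.0

    def test_bending_dominated_tube_stays_cylindrical(self):
        """sigma -> 0: the cylinder is linearly stable; modulation < 1%."""
        params = MembraneParams(kappa=50.0, sigma=1e-4)
        _, _, fastest = pearling_stability(100.0, params)
        assert np.isnan(fastest)
        state, _ = relax_cylinder(100.0, params, grid_n=64, max_iter=3000, tol=1e-4, seed=1)
        assert (state.r.max() - state.r.min()) / 2.0 < 0.01 * 100.0

    def test_pinch_off_flagged(self):
        """A very floppy, tense tube pinches: flagged, partial state returned."""
        params = MembraneParams(kappa=5.0, sigma=0.3)
        state, report = relax_cylinder(
            100.0, params, grid_n=96, max_iter=15000, tol=1e-4, seed=1, r_min=20.0
        )
        assert report.pinched_off
        assert not report.converged
        assert state.r.min() < 20.0

    def test_constant_mean_curvature_outside_neck_layer(self):
        """Relaxed pearls are unduloid-like: H constant within 5% outside
        the bending boundary layer at the necks."""
        params = MembraneParams(kappa=50.0, sigma=0.05)
        state, report = relax_cylinder(100.0, params, grid_n=128, max_iter=15000, tol=1e-4, seed=1)
        assert report.converged
        assert cmc_deviation(state, params) < 0.05


class TestStability:
    def test_pearling_band_and_period_scale(self):
        params = MembraneParams(kappa=50.0, sigma=0.05)
        wl, curv, fastest = pearling_stability(100.0, params)
        assert np.any(curv < 0)
        # period of order the circumference, well above the radius
        assert 2 * np.pi * 50.0 < fastest < 2 * np.pi * 300.0

    def test_low_tension_all_modes_stable(self):
        wl, curv, fastest = pearling_stability(100.0, MembraneParams(sigma=1e-4))
        assert np.all(curv > 0) and np.isnan(fastest)


@pytest.fixture(scope="module")
def sweeps():
    kwargs = dict(max_iter=15000, tol=1e-4)
    osm = sweep_parameters(c_ext_mosm=np.array([150.0, 300.0, 600.0]), **kwargs)
    ten = sweep_parameters(sigma=np.array([0.04, 0.06, 0.09, 0.12]), **kwargs)
    rig = sweep_parameters(kappa=np.array([20.0, 40.0, 60.0, 80.0, 100.0]), **kwargs)
    return osm, ten, rig


class TestSweeps:

    def test_osmolarity_shrinks_pearls(self, sweeps):
        osm, _, _ = sweeps
        assert osm.converged.all()
        assert np.all(np.diff(osm.nsv_width_nm.values) < 0)
        assert np.all(np.diff(osm.nsv_length_nm.values) < 0)

    def test_tension_shrinks_pearls_with_smaller_span(self, sweeps):
        osm, ten, _ = sweeps
        assert ten.converged.all()
        assert np.all(np.diff(ten.nsv_width_nm.values) < 0)
        assert np.all(np.diff(ten.nsv_length_nm.values) < 0)
        span = lambda s: (s.max() - s.min()) / np.median(s)
        assert span(ten.nsv_width_nm.values) < span(osm.nsv_width_nm.values)

    def test_rigidity_effect_modest(self, sweeps):
        osm, _, rig = sweeps
        assert rig.converged.all()
        span = lambda s: (s.max() - s.min()) / np.median(s)
        assert span(rig.nsv_width_nm.values) < span(osm.nsv_width_nm.values)

    def test_grid_refinement_changes_width_under_two_percent(self):
        coarse = sweep_parameters(c_ext_mosm=np.array([300.0]), grid_n=96, max_iter=15000, tol=1e-4)
        fine = sweep_parameters(c_ext_mosm=np.array([300.0]), grid_n=192, max_iter=15000, tol=1e-4)
        w0 = coarse.nsv_width_nm.iloc[0]
        w1 = fine.nsv_width_nm.iloc[0]
        assert abs(w1 - w0) / w0 < 0.02

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sweep_parameters()


class TestParamsValidation:
    def test_invalid_params(self):
        with pytest.raises(ValueError):
            MembraneParams(kappa=0.0)
        with pytest.raises(ValueError):
            MembraneParams(c_ext_mosm=-1.0)
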