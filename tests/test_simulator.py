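"""Simulator unit and property tests: mass balance, closed forms, waves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nodalgrad.simulator import (Geometry1D, Geometry2D, Kymograph, RateParams,
                                 Sensor, build_kymograph, detect_wavefront,
                                 sensor_readout, simulate_diffusion_capture_2d,
                                 simulate_receptor_dynamics_1d,
                                 steady_state_length_scale)


class TestRateParams:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_on"):
            RateParams(k_on=-1.0)

    def test_zero_diffusion_rejected(self):
        with pytest.raises(ValueError, match="D"):
            RateParams(D=0.0)

    def test_effective_capture_rate_is_product(self):
        p = RateParams(k_on=0.005, R0=2.0)
        assert p.k1 == pytest.approx(0.01)


class TestLengthScale:
    def test_forty_micron_case(self):
        lam = steady_state_length_scale(RateParams(D=4.0, k_on=0.0025, R0=1.0))
        assert lam == pytest.approx(40.0)

    def test_invariant_under_kon_r0_tradeoff(self):
        a = steady_state_length_scale(RateParams(k_on=0.0025, R0=1.0))
        b = steady_state_length_scale(RateParams(k_on=0.00125, R0=2.0))
        assert a == pytest.approx(b)

    def test_no_capture_raises(self):
        with pytest.raises(ValueError, match="length scale"):
            steady_state_length_scale(RateParams(R0=0.0))


class TestGeometry:
    def test_sensor_outside_domain_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            Geometry2D(sensors=(Sensor(center_x=299.0, center_y=99.0),))

    def test_sensor_overlapping_source_rejected(self):
        with pytest.raises(ValueError, match="source"):
            Geometry2D(sensors=(Sensor(center_x=6.0, center_y=50.0),))

    def test_coarse_mesh_rejected(self):
        with pytest.raises(ValueError, match="resolve"):
            Geometry2D(mesh_spacing=4.0, sensors=(Sensor(center_x=150.0, center_y=50.0),))

    def test_coarse_1d_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_spacing"):
            Geometry1D(grid_spacing=5.0)


class TestMassBalance:
    def test_conservation_without_sinks(self):
        """With no receptors anywhere, total ligand = source rate x time."""
        geom = Geometry2D()
        host = RateParams(k_on=0.0, k_int=0.0, k_phos=0.0)
        series = simulate_diffusion_capture_2d(geom, host, duration=2000.0, n_samples=5)
        dx = geom.mesh_spacing
        mass = series.final().L.sum() * dx * dx
        expected = host.s * geom.source_mask().sum() * dx * dx * 2000.0
        assert mass == pytest.approx(expected, rel=1e-3)

    def test_ligand_budget_with_capture(self, wt_series_1d, wt_params):
        """d/dt integral(L + C) = source influx - k_int integral(C)."""
        geom = Geometry1D()
        dx = geom.grid_spacing
        influx = wt_params.s * geom.source_mask().sum() * dx
        times = wt_series_1d.times
        total = np.array([(s.L + s.C).sum() * dx for s in wt_series_1d])
        sink = np.array([wt_params.k_int * s.C.sum() * dx for s in wt_series_1d])
        lhs = np.gradient(total, times)
        rhs = influx - sink
        # compare away from t=0 where the source switches on
        sel = times > 200
        drift = np.abs(lhs[sel] - rhs[sel]).max() / influx
        assert drift < 5e-3

    def test_nonnegative_fields(self, wt_series_1d, zoep_series_1d):
        for series in (wt_series_1d, zoep_series_1d):
            for state in series:
                for sp in "LRCP":
                    assert state.species(sp).min() >= 0


class TestClosedForms:
    def test_trivial_fixed_point(self):
        """No secretion and R at its steady state: nothing moves."""
        p = RateParams(s=0.0)
        series = simulate_receptor_dynamics_1d(Geometry1D(), p, duration=1000.0)
        f = series.final()
        assert np.allclose(f.L, 0) and np.allclose(f.C, 0) and np.allclose(f.P, 0)
        assert np.allclose(f.R, p.k3 / p.delta_R, rtol=1e-10)

    def test_receptor_relaxation_rate(self):
        """With s=0, R relaxes to k3/delta_R exponentially at rate delta_R."""
        p = RateParams(s=0.0)
        R_ss = p.k3 / p.delta_R
        series = simulate_receptor_dynamics_1d(
            Geometry1D(), p, R_init=0.2 * R_ss, duration=4000.0,
            warn_no_steady_state=False)
        for state in series[::50]:
            expected = R_ss + (0.2 * R_ss - R_ss) * np.exp(-p.delta_R * state.t)
            assert np.allclose(state.R, expected, rtol=2e-3)

    def test_steady_gradient_matches_analytic_lambda(self):
        """Fixed-receptor interior decay matches sqrt(D/k1) closely."""
        p = RateParams()
        series = simulate_receptor_dynamics_1d(
            Geometry1D(), p, R_init=p.R0, duration=9000.0, fixed_receptor=True,
            warn_no_steady_state=False)
        x, L = series.x, series.final().L
        sel = (x > 60) & (x < 180)
        lam_fit = -1.0 / np.polyfit(x[sel], np.log(L[sel]), 1)[0]
        assert lam_fit == pytest.approx(steady_state_length_scale(p), rel=0.02)

    def test_grid_halving_convergence(self):
        """Halving the grid changes the fitted length scale by < 1%."""
        p = RateParams()
        lams = []
        for dx in (1.0, 0.5):
            series = simulate_receptor_dynamics_1d(
                Geometry1D(grid_spacing=dx), p, R_init=p.R0, duration=6000.0,
                fixed_receptor=True, warn_no_steady_state=False)
            x, L = series.x, series.final().L
            sel = (x > 60) & (x < 180)
            lams.append(-1.0 / np.polyfit(x[sel], np.log(L[sel]), 1)[0])
        assert abs(lams[1] - lams[0]) / lams[0] < 0.01

    def test_2d_matches_1d_on_separable_problem(self):
        """y-invariant 2D slab reduces exactly to the fixed-receptor 1D model."""
        host = RateParams()
        s2 = simulate_diffusion_capture_2d(Geometry2D(), host, duration=3000.0, n_samples=4)
        s1 = simulate_receptor_dynamics_1d(
            Geometry1D(grid_spacing=2.0), host, R_init=host.R0, duration=3000.0,
            fixed_receptor=True, warn_no_steady_state=False)
        L2 = s2.final().L.mean(axis=0)
        L1 = s1.final().L
        assert np.abs(L2 - L1).max() / L1.max() < 1e-3

    def test_psmad2_integrates_complex_decay(self):
        """Late-time P(x) inherits the steady-state ligand decay length."""
        p = RateParams()
        series = simulate_receptor_dynamics_1d(
            Geometry1D(), p, R_init=p.R0, duration=9000.0, fixed_receptor=True,
            warn_no_steady_state=False)
        x, P = series.x, series.final().P
        sel = (x > 60) & (x < 180)
        lam_fit = -1.0 / np.polyfit(x[sel], np.log(P[sel]), 1)[0]
        assert lam_fit == pytest.approx(steady_state_length_scale(p), rel=0.05)


class TestSteadyStateWarning:
    def test_warns_when_duration_too_short(self):
        with pytest.warns(RuntimeWarning, match="steady state"):
            simulate_receptor_dynamics_1d(Geometry1D(), RateParams(), duration=600.0)

    def test_silent_at_full_duration(self, recwarn, wt_series_1d):
        assert not [w for w in recwarn if "steady state" in str(w.message)]


class TestKymograph:
    def test_column_count(self, wt_series_1d):
        kym = build_kymograph(wt_series_1d, "L", column_interval=20.0)
        assert kym.matrix.shape[1] == int(9000 / 20) + 1 == 451

    def test_constant_field_columns_identical(self):
        x = np.arange(0.5, 300, 1.0)
        p = RateParams(s=0.0)
        series = simulate_receptor_dynamics_1d(Geometry1D(), p, duration=400.0)
        kym = build_kymograph(series, "R")
        assert np.allclose(kym.matrix, kym.matrix[:, :1])

    def test_unknown_species_rejected(self, wt_series_1d):
        with pytest.raises(KeyError, match="unknown species"):
            build_kymograph(wt_series_1d, "Q")

    def test_undersampled_series_rejected(self, wt_params):
        series = simulate_receptor_dynamics_1d(
            Geometry1D(), wt_params, duration=1000.0, sample_interval=100.0,
            warn_no_steady_state=False)
        with pytest.raises(ValueError, match="coarsely"):
            build_kymograph(series, "L", column_interval=20.0)


class TestWavefront:
    @staticmethod
    def _kym(profiles, times, x):
        return Kymograph(species="f", matrix=np.column_stack(profiles), x=x,
                         times=times)

    def test_stationary_gradient_speed_zero(self):
        x = np.arange(0.5, 300, 1.0)
        times = np.arange(0, 4001, 20.0)
        kym = self._kym([np.exp(-x / 40)] * len(times), times, x)
        _, speed = detect_wavefront(kym)
        assert abs(speed) < 1e-6

    def test_translating_profile_speed_recovered(self):
        v = 0.01
        x = np.arange(0.5, 300, 1.0)
        times = np.arange(0, 9001, 20.0)
        profs = [np.exp(-0.5 * ((x - 30 - v * t) / 12) ** 2) for t in times]
        _, speed = detect_wavefront(self._kym(profs, times, x))
        assert speed == pytest.approx(v, rel=0.10)

    def test_replacement_suppresses_wave(self, wt_series_1d, zoep_series_1d):
        """Receptor replacement keeps the front static; its loss drives a wave."""
        _, v_wt = detect_wavefront(build_kymograph(wt_series_1d, "C"))
        _, v_z = detect_wavefront(build_kymograph(zoep_series_1d, "C"))
        assert abs(v_wt) < 0.1 * abs(v_z)

    def test_wave_peak_displacement(self, zoep_series_1d):
        """Without replacement the signaling maximum travels > 50 um."""
        geom = Geometry1D()
        src = geom.source_mask()
        x = zoep_series_1d.x

        def peak(state):
            return x[~src][np.argmax(state.C[~src])]

        i3 = len(zoep_series_1d) // 3
        positions = [peak(s) for s in zoep_series_1d[i3:]]
        assert np.all(np.diff(positions) >= -1.01)  # non-decreasing up to one cell
        assert peak(zoep_series_1d.final()) - peak(zoep_series_1d[i3]) > 50.0

    def test_converged_peak_with_replacement(self, wt_series_1d):
        """With replacement the position of max C settles (steady gradient)."""
        geom = Geometry1D()
        src = geom.source_mask()
        x = wt_series_1d.x
        i23 = 2 * len(wt_series_1d) // 3
        p_late = x[~src][np.argmax(wt_series_1d[i23].C[~src])]
        p_end = x[~src][np.argmax(wt_series_1d.final().C[~src])]
        assert abs(p_end - p_late) < 5.0

    def test_bad_level_rejected(self, wt_series_1d):
        kym = build_kymograph(wt_series_1d, "C")
        with pytest.raises(ValueError, match="level"):
            detect_wavefront(kym, level=1.5)


class TestSensorReadout:
    def test_no_phosphorylation_means_zero_readout(self):
        p = RateParams(k_phos=0.0)
        geom = Geometry2D(sensors=(Sensor(center_x=50.0, center_y=50.0, params=p),))
        series = simulate_diffusion_capture_2d(geom, p, duration=500.0, n_samples=3)
        tbl = sensor_readout(series, geom)
        assert np.allclose(tbl["meanP"], 0.0)

    def test_y_invariance_of_duplicate_sensors(self):
        wt = RateParams()
        geom = Geometry2D(sensors=(
            Sensor(center_x=80.0, center_y=25.0, params=wt),
            Sensor(center_x=80.0, center_y=75.0, params=wt),
        ))
        series = simulate_diffusion_capture_2d(geom, wt, duration=3000.0, n_samples=4)
        tbl = sensor_readout(series, geom)
        a, b = tbl["meanP"]
        assert abs(a - b) / max(a, b) < 0.02

    def test_no_sensors_rejected(self, wt_params):
        geom = Geometry2D()
        series = simulate_diffusion_capture_2d(geom, wt_params, duration=100.0, n_samples=2)
        with pytest.raises(ValueError, match="no sensors"):
            sensor_readout(series, geom)


@settings(max_examples=8, deadline=None, derandomize=True)
@given(
    k_on=st.floats(0.0, 0.01),
    s=st.floats(0.0, 0.01),
    k3=st.floats(0.0, 1e-3),
    delta_R=st.floats(1e-5, 1e-3),
)
def test_fields_stay_nonnegative(k_on, s, k3, delta_R):
    """Non-negativity holds for arbitrary non-negative rate combinations."""
    p = RateParams(k_on=k_on, s=s, k3=k3, delta_R=delta_R)
    series = simulate_receptor_dynamics_1d(
        Geometry1D(grid_spacing=2.0), p, duration=500.0,
        warn_no_steady_state=False)
    f = series.final()
    for sp in "LRCP":
        assert f.species(sp).min() >= 0
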