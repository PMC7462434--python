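"""Solvers: oracle equivalence, limits, convergence, conservation."""

from dataclasses import replace

import numpy as np
import pytest

from ephapse import (
    FHNParams,
    FieldState,
    GridSpec,
    StimulusEvent,
    StimulusProtocol,
    dense_reference_step,
    impulse_protocol,
    resting_state,
    simulate_continuum,
    simulate_discrete,
    simulate_single_cable,
)
from ephapse.solvers import (
    PropagationError,
    axial_operator_matrix,
    estimate_pulse_speed,
    lateral_operator_continuum,
    lateral_operator_discrete,
)
from ephapse.stimulation import ProtocolError, evaluate_stimulus


def _rest_fields(fhn, shape):
    rest = resting_state(fhn)
    return np.full(shape, rest.v_star), np.full(shape, rest.w_star)


def _dense_trajectory(model, grid, coupling, fhn, protocol, scheme="euler"):
    """Repeated dense-oracle steps, snapshotted like the production solver."""
    if model == "discrete":
        lateral = lateral_operator_discrete(grid.n_lateral, coupling)
    else:
        lateral = lateral_operator_continuum(grid.n_lateral, coupling, grid.dx)
    axial = axial_operator_matrix(grid.n_z, grid.dz)
    v, w = _rest_fields(fhn, (grid.n_lateral, grid.n_z))
    state = FieldState(v=v, w=w, t=0.0)
    snaps = [state.v.copy()]
    history = {} if scheme == "ab2" else None
    for step in range(grid.n_steps):
        stim = evaluate_stimulus(protocol, state.t, grid)
        state = dense_reference_step(state, lateral, axial, fhn, grid.dt,
                                     stim=stim, history=history)
        if (step + 1) % grid.snapshot_stride == 0:
            snaps.append(state.v.copy())
    return np.asarray(snaps)


class TestGridSpec:
    def test_derived_sizes(self):
        grid = GridSpec(z_extent=20.0, t_end=10.0, n_lateral=6)
        assert grid.n_z == 41
        assert grid.n_steps == 200
        assert grid.snapshot_stride == 20

    def test_non_integral_ratios_rejected(self):
        with pytest.raises(ValueError, match="not integral"):
            GridSpec(z_extent=20.3, t_end=10.0)
        with pytest.raises(ValueError, match="not integral"):
            GridSpec(z_extent=20.0, t_end=10.02)

    def test_positive_required(self):
        with pytest.raises(ValueError):
            GridSpec(z_extent=-1.0, t_end=10.0)


class TestRestIsFixedPoint:
    def test_discrete_stays_at_rest(self, fhn_default):
        grid = GridSpec(z_extent=20.0, t_end=100.0, n_lateral=6, dz=0.5)
        result = simulate_discrete(grid, 0.8, fhn_default,
                                   impulse_protocol([]))
        rest = resting_state(fhn_default)
        assert np.max(np.abs(result.v - rest.v_star)) < 1e-6

    def test_dense_step_preserves_rest(self, fhn_default):
        v, w = _rest_fields(fhn_default, (4, 20))
        lateral = lateral_operator_discrete(4, 0.5)
        axial = axial_operator_matrix(20, 0.5)
        out = dense_reference_step(FieldState(v=v, w=w, t=0.0), lateral,
                                   axial, fhn_default, 0.05)
        assert np.max(np.abs(out.v - v)) < 1e-12
        assert np.max(np.abs(out.w - w)) < 1e-12

    def test_dense_step_dt_zero_identity(self, fhn_default):
        rng = np.random.default_rng(0)
        v = rng.standard_normal((4, 20))
        w = rng.standard_normal((4, 20))
        lateral = lateral_operator_discrete(4, 0.5)
        axial = axial_operator_matrix(20, 0.5)
        out = dense_reference_step(FieldState(v=v, w=w, t=0.0), lateral,
                                   axial, fhn_default, 0.0)
        assert out.v == pytest.approx(v, abs=1e-14)
        assert out.w == pytest.approx(w, abs=1e-14)


class TestDenseOracleEquivalence:
    """Production spectral solver equals the brute-force dense CN step."""

    def test_discrete_trajectory(self, fhn_default, small_grid,
                                 small_discrete_run):
        protocol = impulse_protocol([(3, 0.0)])
        oracle = _dense_trajectory("discrete", small_grid, 0.8, fhn_default,
                                   protocol)
        assert np.max(np.abs(oracle - small_discrete_run.v)) < 1e-8

    def test_continuum_trajectory(self, fhn_default):
        grid = GridSpec(z_extent=20.0, t_end=8.0, n_lateral=6, dz=0.5)
        protocol = impulse_protocol([(3, 0.0), (4, 2.0)])
        result = simulate_continuum(grid, 0.15, fhn_default, protocol)
        oracle = _dense_trajectory("continuum", grid, 0.15, fhn_default,
                                   protocol)
        assert np.max(np.abs(oracle - result.v)) < 1e-8

    def test_ab2_scheme_trajectory(self, fhn_default, small_grid):
        protocol = impulse_protocol([(3, 0.0)])
        result = simulate_discrete(small_grid, 0.8, fhn_default, protocol,
                                   scheme="ab2")
        oracle = _dense_trajectory("discrete", small_grid, 0.8, fhn_default,
                                   protocol, scheme="ab2")
        assert np.max(np.abs(oracle - result.v)) < 1e-8
        # the two explicit splits genuinely differ
        euler = simulate_discrete(small_grid, 0.8, fhn_default, protocol)
        assert np.max(np.abs(euler.v - result.v)) > 1e-6

    def test_size_guard(self, fhn_default):
        v, w = _rest_fields(fhn_default, (25, 40))
        with pytest.raises(ValueError, match="limited to"):
            dense_reference_step(FieldState(v=v, w=w, t=0.0),
                                 np.eye(25), axial_operator_matrix(40, 0.5),
                                 fhn_default, 0.05)


class TestUncoupledLimits:
    def test_continuum_k_zero_equals_single_cable(self, fhn_default):
        grid = GridSpec(z_extent=40.0, t_end=30.0, n_lateral=5, dz=0.5)
        result = simulate_continuum(grid, 0.0, fhn_default,
                                    impulse_protocol([(3, 0.0)]))
        single = simulate_single_cable(
            grid, fhn_default,
            StimulusProtocol(events=(StimulusEvent(lateral_index=1, onset=0.0),)))
        assert np.max(np.abs(result.v[:, 2, :] - single.v[:, 0, :])) < 1e-10
        rest = resting_state(fhn_default)
        # unstimulated columns never move
        assert np.max(np.abs(result.v[:, 0, :] - rest.v_star)) < 1e-12

    def test_uniform_lateral_field_reduces_to_single_cable(self, fhn_default):
        # same impulse on every column: lateral term vanishes by symmetry
        grid = GridSpec(z_extent=40.0, t_end=30.0, n_lateral=5, dz=0.5)
        protocol = impulse_protocol([(p, 0.0) for p in range(1, 6)])
        result = simulate_continuum(grid, 0.2, fhn_default, protocol)
        single = simulate_single_cable(
            grid, fhn_default,
            StimulusProtocol(events=(StimulusEvent(lateral_index=1, onset=0.0),)))
        for col in range(5):
            assert np.max(np.abs(result.v[:, col, :] - single.v[:, 0, :])) < 1e-9

    def test_discrete_large_r_approaches_independent_cables(self, fhn_default):
        grid = GridSpec(z_extent=60.0, t_end=40.0, n_lateral=6, dz=0.5)
        protocol = impulse_protocol([(2, 0.0), (5, 10.0)])
        coupled = simulate_discrete(grid, 100.0, fhn_default, protocol)
        independent = np.zeros_like(coupled.v)
        rest = resting_state(fhn_default)
        independent[:] = rest.v_star
        # the uncoupled comparator is the sheet model's own single-axon
        # normalization (self-diffusion 4(R+1)/(4R+2), not exactly 1), so
        # the comparison isolates the residual cross-talk at R=100
        single_grid = replace(grid, n_lateral=1)
        errs = {}
        for R, run in [(100.0, coupled),
                       (1000.0, simulate_discrete(grid, 1000.0, fhn_default,
                                                  protocol))]:
            independent[:] = rest.v_star
            for lateral_index, onset in [(2, 0.0), (5, 10.0)]:
                single = simulate_discrete(
                    single_grid, R, fhn_default,
                    StimulusProtocol(events=(StimulusEvent(lateral_index=1,
                                                           onset=onset),)))
                independent[:, lateral_index - 1, :] = single.v[:, 0, :]
            errs[R] = np.max(np.abs(run.v - independent))
        # the residual is the genuine subthreshold ephaptic response of the
        # neighbours, which decays like 1/R
        assert errs[100.0] < 2e-3
        assert errs[1000.0] < 2e-4
        assert errs[1000.0] < 0.2 * errs[100.0]


class TestNumericalProperties:
    def test_time_step_convergence_order(self, fhn_default):
        """Second-order split (CN + AB2): halving dt shrinks error >= 3x."""
        base = dict(z_extent=40.0, n_lateral=4, dz=0.5, t_end=20.0,
                    snapshot_every=20.0)
        protocol = impulse_protocol([(2, 0.0)])
        finals = {}
        for dt in (0.1, 0.05, 0.025):
            grid = GridSpec(dt=dt, **base)
            finals[dt] = simulate_discrete(grid, 0.8, fhn_default, protocol,
                                           scheme="ab2").v[-1]
        err_coarse = np.max(np.abs(finals[0.1] - finals[0.025]))
        err_fine = np.max(np.abs(finals[0.05] - finals[0.025]))
        assert err_coarse / err_fine >= 3.0

    def test_euler_split_first_order(self, fhn_default):
        """Reference Euler split converges at first order (ratio ~3 against
        a quarter-step reference)."""
        base = dict(z_extent=40.0, n_lateral=4, dz=0.5, t_end=20.0,
                    snapshot_every=20.0)
        protocol = impulse_protocol([(2, 0.0)])
        finals = {}
        for dt in (0.1, 0.05, 0.025):
            grid = GridSpec(dt=dt, **base)
            finals[dt] = simulate_discrete(grid, 0.8, fhn_default,
                                           protocol).v[-1]
        err_coarse = np.max(np.abs(finals[0.1] - finals[0.025]))
        err_fine = np.max(np.abs(finals[0.05] - finals[0.025]))
        assert 2.0 <= err_coarse / err_fine <= 5.0

    def test_axial_step_convergence(self, fhn_default):
        protocol = impulse_protocol([(1, 0.0)])
        speeds = {}
        for dz in (1.0, 0.5):
            grid = GridSpec(z_extent=150.0, t_end=120.0, n_lateral=1, dz=dz)
            speeds[dz] = estimate_pulse_speed(grid=grid, fhn=fhn_default)
        assert abs(speeds[1.0] - speeds[0.5]) / speeds[0.5] < 0.03

    def test_pulse_shape_preserved(self, fhn_default, single_impulse_run):
        """Impulse amplitude drifts < 1% over the final half of the run."""
        result = single_impulse_run
        amps = result.v[:, 2, :].max(axis=1)
        half = len(amps) // 2
        tail = amps[half:]
        assert tail.max() - tail.min() < 0.01 * tail.mean()

    def test_determinism_bit_identical(self, fhn_default, small_grid,
                                       small_discrete_run):
        repeat = simulate_discrete(small_grid, 0.8, fhn_default,
                                   impulse_protocol([(3, 0.0)]), store_w=True)
        assert np.array_equal(repeat.v, small_discrete_run.v)
        assert np.array_equal(repeat.w, small_discrete_run.w)

    def test_zero_flux_conservation_linear(self, fhn_default):
        """Pure coupled diffusion conserves the trapezoidal z-integral of v."""
        grid = GridSpec(z_extent=20.0, t_end=50.0, n_lateral=6, dz=0.5)
        protocol = impulse_protocol([(3, 0.0)])
        result = simulate_discrete(grid, 0.4, fhn_default, protocol,
                                   _linear_only=True)
        weights = np.ones(grid.n_z)
        weights[0] = weights[-1] = 0.5
        totals = np.einsum("tpz,z->t", result.v, weights)
        # compare after the stimulus boxcar has ended (t >= 2)
        assert np.max(np.abs(totals[3:] - totals[3])) < 1e-8

    def test_protocol_outside_domain_rejected(self, fhn_default):
        grid = GridSpec(z_extent=20.0, t_end=10.0, n_lateral=4, dz=0.5)
        with pytest.raises(ProtocolError):
            simulate_discrete(grid, 0.5, fhn_default,
                              impulse_protocol([(9, 0.0)]))
        with pytest.raises(ProtocolError):
            simulate_discrete(grid, 0.5, fhn_default,
                              impulse_protocol([(2, 50.0)]))


class TestPulseSpeed:
    def test_positive_and_steady(self, fhn_default):
        grid = GridSpec(z_extent=150.0, t_end=120.0, n_lateral=1, dz=0.5)
        speed = estimate_pulse_speed(grid=grid, fhn=fhn_default)
        assert speed > 0.5

    def test_translation_symmetry(self, fhn_default):
        """Speed is independent of which interior axon carries the pulse."""
        grid = GridSpec(z_extent=120.0, t_end=100.0, n_lateral=30, dz=0.5)
        speeds = []
        for lateral_index in (10, 21):
            protocol = StimulusProtocol(
                events=(StimulusEvent(lateral_index=lateral_index, onset=0.0),))
            result = simulate_discrete(grid, 0.8, fhn_default, protocol)
            z = grid.z_coords
            fronts, times = [], []
            for t, snap in zip(result.times,
                               result.v[:, lateral_index - 1, :]):
                above = np.nonzero(snap > 0.0)[0]
                if len(above) and z[above[-1]] < 0.9 * grid.z_extent:
                    fronts.append(z[above[-1]])
                    times.append(t)
            half = len(times) // 2
            speeds.append(np.polyfit(times[half:], fronts[half:], 1)[0])
        assert speeds[0] == pytest.approx(speeds[1], abs=1e-6)

    def test_no_propagation_raises(self, fhn_default):
        # run too short for a front to establish itself
        grid = GridSpec(z_extent=100.0, t_end=3.0, n_lateral=1, dz=0.5)
        with pytest.raises(PropagationError):
            estimate_pulse_speed(grid=grid, fhn=fhn_default)
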