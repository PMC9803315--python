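import dataclasses

import numpy as np
import pytest

from fibrocontrol import (
    DensityField,
    SimulationSettings,
    Trajectory,
    build_grid,
    reaction_fibroblast,
    reaction_myofibroblast,
    simulate,
    step_explicit,
    time_to_fraction,
)
from fibrocontrol.discretization import LinearSystem, _neumann5_laplacian
from fibrocontrol.forward_sim import IntegrationError, initial_field


class TestReactionMyofibroblast:
    def test_initial_rate_matches_term_by_term_oracle(self, params):
        myof, _, _ = params
        # independent term-by-term evaluation of the activation/apoptosis balance
        u0 = 2.51e-12 / (1e-10 + 2.51e-12)
        g0 = 0.58e-3 / (1.5e-8 + 0.58e-3)
        oracle = (0.12 * u0 + 0.12 * g0) * 4.75e-3 - 1.66e-2 * 8.5e-3
        rate = reaction_myofibroblast(myof.m0, myof.TGF0, myof)
        assert rate == pytest.approx(oracle, rel=1e-12)
        assert rate == pytest.approx(4.428e-4, rel=1e-3)

    def test_vanishes_without_drivers(self, params):
        myof, _, _ = params
        quiet = dataclasses.replace(myof, G0=0.0)
        assert reaction_myofibroblast(0.0, 0.0, quiet) == 0.0

    def test_hill_saturation_limit(self, params):
        myof, _, _ = params
        m = myof.m0
        limit = (
            myof.lambda_mfT + myof.lambda_mfG * myof.G0 / (myof.K_G + myof.G0)
        ) * myof.f0 - myof.d_m * m
        assert reaction_myofibroblast(m, 1e6, myof) == pytest.approx(limit, rel=1e-9)

    def test_negative_inputs_rejected(self, params):
        myof, _, _ = params
        with pytest.raises(ValueError):
            reaction_myofibroblast(myof.m0, -1e-12, myof)
        with pytest.raises(ValueError):
            reaction_myofibroblast(myof.m0, myof.TGF0, dataclasses.replace(myof, K_TGF=0.0))


class TestReactionFibroblast:
    def test_initial_rate_matches_term_sum_oracle(self, params):
        myof, fib, _ = params
        u0 = 2.51e-12 / (1e-10 + 2.51e-12)
        terms = [
            0.25 * 0.799,                       # AEC-derived source
            5e-4 * u0 * 0.799 / 0.899,          # TGF-beta-driven production
            -1.66e-2 * 4.75e-3,                 # apoptosis
            -0.12 * 0.58e-3 / (0.58e-3 + 1.5e-8) * 4.75e-3,  # to myofibroblast
            -7.5e-3 * 0.799 / 0.899 * 4.75e-3,  # TGF-beta production drain
            -3e-3 * 4.75e-3,                    # ECM deposition
        ]
        rate = reaction_fibroblast(myof.f0, fib.TGFf0, fib, myof)
        assert rate == pytest.approx(sum(terms), rel=1e-12)
        assert rate == pytest.approx(0.19906, abs=1e-5)

    def test_pure_apoptosis_when_rates_vanish(self, params):
        myof, fib, _ = params
        quiet_fib = dataclasses.replace(
            fib, lambda_Ef=1e-300, lambda_fE=1e-300, lambda_rhof=1e-300,
            lambda_TGFf=1e-300,
        )
        quiet_myof = dataclasses.replace(myof, lambda_mfG=1e-300)
        f = 0.01
        assert reaction_fibroblast(f, 0.0, quiet_fib, quiet_myof) == pytest.approx(
            -fib.d_f * f, rel=1e-9
        )

    def test_zero_net_rate_at_linearized_fixed_point(self, params, one_node_systems):
        myof, fib, _ = params
        _, sys_f = one_node_systems
        # with TGFf held at zero the production term drops out and the
        # source/loss balance fixes f* = c / alpha
        f_star = sys_f.c / sys_f.alpha
        assert reaction_fibroblast(f_star, 0.0, fib, myof) == pytest.approx(0.0, abs=1e-15)


class TestStepExplicit:
    def test_zero_system_is_identity(self, grid1):
        sys_ = LinearSystem(
            A=np.zeros((1, 1)), B=np.zeros((1, 1)), b=np.zeros(1),
            r=0.0, theta=0.0, c=0.0, alpha=0.0,
            grid=grid1, scheme="neumann5", species="myofibroblast",
        )
        field = DensityField(values=np.array([0.42]), grid=grid1)
        out = step_explicit(field, sys_, 0.0, 0.5)
        np.testing.assert_array_equal(out.values, field.values)

    def test_scalar_decay_recurrence(self, params, grid1):
        myof, _, _ = params
        sys_ = LinearSystem(
            A=np.array([[-myof.d_m]]), B=np.zeros((1, 1)), b=np.zeros(1),
            r=0.0, theta=0.0, c=0.0, alpha=0.0,
            grid=grid1, scheme="neumann5", species="myofibroblast",
        )
        dt, k = 0.5, 20
        field = DensityField(values=np.array([myof.m0]), grid=grid1)
        for _ in range(k):
            field = step_explicit(field, sys_, 0.0, dt)
        assert field.values[0] == pytest.approx(myof.m0 * (1 - myof.d_m * dt) ** k, rel=1e-12)

    def test_uniform_field_matches_single_node_recurrence(self, params, system36):
        # zero-flux symmetry: the diffusion term is exactly zero on a
        # uniform field, so every node follows the scalar recurrence
        myof, _, _ = params
        dt = 0.1
        field = DensityField(values=np.full(36, myof.m0), grid=system36.grid)
        scalar = myof.m0
        u0 = myof.TGF0 / (myof.K_TGF + myof.TGF0)
        for _ in range(50):
            field = step_explicit(field, system36, u0, dt)
            scalar = scalar + dt * (
                -myof.d_m * scalar + system36.theta * u0 + system36.c
            )
            assert np.allclose(field.values, scalar, rtol=1e-13, atol=0)

    def test_nonfinite_state_names_the_step(self, params, grid1):
        myof, _, _ = params
        sys_ = LinearSystem(
            A=np.array([[1e300]]), B=np.zeros((1, 1)), b=np.zeros(1),
            r=0.0, theta=0.0, c=0.0, alpha=0.0,
            grid=grid1, scheme="neumann5", species="myofibroblast",
        )
        field = DensityField(values=np.array([1e300]), grid=grid1)
        with np.errstate(over="ignore"), pytest.raises(IntegrationError, match="step 7"):
            step_explicit(field, sys_, 0.0, 1.0, step_index=7)


class TestSimulate:
    def test_well_mixed_closed_form(self, params):
        # coarse check at dt = 1e-2; the tight-tolerance version lives in
        # the acceptance suite
        myof, _, homog = params
        settings = SimulationSettings(tf=100.0, dt=1e-2, n_interior_per_side=1)
        traj = simulate("myofibroblast", myof, homog, settings)
        c = (
            myof.lambda_mfT * myof.TGF0 / (myof.K_TGF + myof.TGF0)
            + myof.lambda_mfG * myof.G0 / (myof.K_G + myof.G0)
        ) * myof.f0
        exact = c / myof.d_m + (myof.m0 - c / myof.d_m) * np.exp(-myof.d_m * 100.0)
        assert traj.mean_density[-1] == pytest.approx(exact, rel=1e-4)

    def test_zero_reaction_conserves_total_mass(self, params, grid36):
        _, _, homog = params
        r = 0.11 / homog.gamma * 1.47e-5 * 49
        lap = r * _neumann5_laplacian(grid36)
        sys_ = LinearSystem(
            A=lap, B=np.zeros((36, 36)), b=np.zeros(36),
            r=r, theta=0.0, c=0.0, alpha=0.0,
            grid=grid36, scheme="neumann5", species="myofibroblast",
        )
        rng = np.random.default_rng(7)
        field = DensityField(values=rng.uniform(0.0, 1.0, 36), grid=grid36)
        total0 = field.values.sum()
        for _ in range(500):
            field = step_explicit(field, sys_, 0.0, 0.1)
        assert field.values.sum() == pytest.approx(total0, rel=1e-13)

    def test_fibroblast_rises_monotonically_toward_fixed_point(self, params):
        myof, fib, homog = params
        settings = SimulationSettings(tf=300.0, dt=0.1, n_interior_per_side=2)
        traj = simulate("fibroblast", myof, homog, settings, fib=fib)
        mean = traj.mean_density
        assert np.all(np.diff(mean) >= 0) and mean[-1] > 100 * mean[0]
        # Euler recurrence shares the continuous fixed point (c + theta*U0)/alpha
        u0 = fib.TGFf0 / (myof.K_TGF + fib.TGFf0)
        fixed_point = (0.19975 + 5e-4 * 0.799 / 0.899 * u0) / 0.14626263634277342
        assert mean[-1] == pytest.approx(fixed_point, rel=1e-9)

    def test_positivity_over_default_horizon(self, params):
        myof, _, homog = params
        settings = SimulationSettings()  # dt = 0.1, tf = 300, 36 nodes
        traj = simulate("myofibroblast", myof, homog, settings)
        assert np.all(traj.values >= 0.0)

    def test_first_order_convergence_against_closed_form(self, params):
        myof, _, homog = params
        c = (
            myof.lambda_mfT * myof.TGF0 / (myof.K_TGF + myof.TGF0)
            + myof.lambda_mfG * myof.G0 / (myof.K_G + myof.G0)
        ) * myof.f0
        exact = c / myof.d_m + (myof.m0 - c / myof.d_m) * np.exp(-myof.d_m * 100.0)
        errors = []
        for dt in (0.04, 0.02):
            settings = SimulationSettings(tf=100.0, dt=dt, n_interior_per_side=1)
            traj = simulate("myofibroblast", myof, homog, settings)
            errors.append(abs(traj.mean_density[-1] - exact))
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.1)

    def test_damage_region_elevates_centre_density(self, params):
        myof, _, homog = params
        grid = build_grid(6)
        field = initial_field(grid, myof.m0, damage_extent=0.3)
        assert field.values.max() == pytest.approx(10 * myof.m0)
        assert field.values.min() == pytest.approx(myof.m0)
        assert 0 < (field.values > myof.m0).sum() < grid.n_interior


class TestTimeToFraction:
    def test_pure_decay_hits_one_percent_at_log100_over_d(self, params):
        myof, _, _ = params
        times = np.arange(0.0, 300.0, 0.05)
        values = (myof.m0 * np.exp(-myof.d_m * times))[:, None]
        traj = Trajectory(times=times, values=values, species="myofibroblast",
                          grid=build_grid(1))
        t = time_to_fraction(traj, 0.01)
        assert t == pytest.approx(np.log(100) / myof.d_m, abs=0.06)

    def test_fraction_one_returns_start_time(self, params):
        myof, _, _ = params
        times = np.array([3.0, 4.0, 5.0])
        traj = Trajectory(times=times, values=np.full((3, 1), myof.m0),
                          species="myofibroblast", grid=build_grid(1))
        assert time_to_fraction(traj, 1.0) == 3.0

    def test_monotone_increase_never_vanishes(self):
        times = np.arange(5.0)
        traj = Trajectory(times=times, values=np.arange(1.0, 6.0)[:, None],
                          species="fibroblast", grid=build_grid(1))
        assert time_to_fraction(traj, 0.5) is None

    def test_invalid_fraction_and_empty_trajectory(self):
        times = np.arange(3.0)
        traj = Trajectory(times=times, values=np.ones((3, 1)),
                          species="fibroblast", grid=build_grid(1))
        with pytest.raises(ValueError):
            time_to_fraction(traj, 0.0)
        empty = Trajectory(times=np.array([]), values=np.empty((0, 1)),
                           species="fibroblast", grid=build_grid(1))
        with pytest.raises(ValueError):
            time_to_fraction(empty, 0.5)
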