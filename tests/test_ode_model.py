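"""Unit and property tests for the compartment model and its rate functions."""

import math

import numpy as np
import pytest

from cartmc.ode_model import (
    FixedParams,
    KineticParams,
    IntegrationError,
    Trajectory,
    antigen_saturation_F,
    cytotoxic_saturation_f,
    distributed_closed_form,
    expansion_rate_k,
    model_rhs,
    simulate,
    total_car_t,
)
from conftest import random_kinetics

# comparison tolerances: relative, plus an absolute floor of a tenth of a
# cell (the solver controls local error to atol=1e-2 cells; global error can
# accumulate slightly above it, and fractions of a cell are not physical)
RTOL = 1e-6
ATOL_CELLS = 0.1


class TestRateFunctions:
    def test_expansion_rate_limits(self, init_kinetics):
        # at infusion the power term vanishes; far out it dominates
        assert expansion_rate_k(0.0, init_kinetics) == pytest.approx(
            init_kinetics.r_min + init_kinetics.p1
        )
        far = KineticParams.from_array(
            np.concatenate([[init_kinetics.beta, init_kinetics.eta, 1e-3, 1.75, 0.5], [2.0],
                            init_kinetics.to_array()[6:]])
        )
        assert expansion_rate_k(1e8, far) == pytest.approx(far.r_min, rel=1e-9)

    def test_expansion_rate_at_published_guess(self, init_kinetics):
        # (p2*26)^p3 ~ 1e-700 underflows, so k(26) is still the full rate
        assert expansion_rate_k(26.0, init_kinetics) == pytest.approx(1.751, abs=1e-10)

    def test_expansion_rate_monotone_nonincreasing(self, init_kinetics):
        ts = np.linspace(0, 50, 200)
        ks = [expansion_rate_k(t, init_kinetics) for t in ts]
        assert all(a >= b - 1e-12 for a, b in zip(ks, ks[1:]))
        assert all(init_kinetics.r_min <= k <= init_kinetics.r_min + init_kinetics.p1 + 1e-12 for k in ks)

    def test_p3_nonpositive_rejected(self, init_kinetics):
        vals = init_kinetics.to_array()
        vals[5] = 0.0
        with pytest.raises(ValueError, match="p3"):
            KineticParams.from_array(vals)

    @pytest.mark.parametrize(
        "T,A,expected",
        [(0.0, 50.0, 0.0), (50.0, 50.0, 0.5), (1e7, 50.0, 1e7 / (50 + 1e7))],
    )
    def test_antigen_saturation(self, T, A, expected):
        assert antigen_saturation_F(T, A) == pytest.approx(expected, rel=1e-12)

    def test_antigen_saturation_bounded_monotone(self):
        Ts = np.logspace(-3, 12, 50)
        vals = [antigen_saturation_F(T, 50.0) for T in Ts]
        assert all(0 <= v < 1 for v in vals)
        assert all(a < b for a, b in zip(vals, vals[1:]))

    @pytest.mark.parametrize(
        "CF,T,expected",
        [
            (0.0, 1e7, 0.0),
            (1000.305, 1.0, 0.5),          # CF*T = vartheta + a -> half saturation
            (1e3, 1e3, 1e6 / (1e6 + 1000.305)),
        ],
    )
    def test_cytotoxic_saturation(self, CF, T, expected):
        assert cytotoxic_saturation_f(CF, T, 0.305, 1000.0) == pytest.approx(expected, rel=1e-9)


class TestRHS:
    def test_origin_is_fixed_point(self, fixed, init_kinetics):
        d = model_rhs(1.0, np.zeros(5), fixed, init_kinetics)
        assert np.all(d == 0)

    def test_single_distributed_cell(self, fixed, init_kinetics):
        # only the CD equation is active: outflow -(beta+eta), inflow eta to CT
        d = model_rhs(0.0, [1.0, 0, 0, 0, 0], fixed, init_kinetics)
        assert d[0] == pytest.approx(-(1.051 + 0.054))
        assert d[1] == pytest.approx(0.054)
        assert np.all(d[2:] == 0)

    def test_tumor_carrying_capacity_equilibrium(self, fixed, init_kinetics):
        d = model_rhs(0.0, [0, 0, 0, 0, 1.0 / fixed.b], fixed, init_kinetics)
        assert d[4] == pytest.approx(0.0, abs=1e-6)

    def test_nonfinite_state_rejected(self, fixed, init_kinetics):
        with pytest.raises(IntegrationError):
            model_rhs(0.0, [np.nan, 0, 0, 0, 0], fixed, init_kinetics)


class TestSimulate:
    def test_initial_total_equals_dose(self, fixed, init_kinetics, patient28, dose, t0):
        traj = simulate(init_kinetics, fixed, dose, t0, patient28.days)
        assert traj.C[0] == dose
        assert total_car_t(traj)[0] == dose

    def test_distributed_matches_closed_form_random_draws(self, fixed, t0):
        # the CD equation is autonomous and linear; the solver must track the
        # analytic exponential across 20 random parameter draws
        rng = np.random.default_rng(42)
        times = np.array([0.0, 1.0, 2.0, 5.0, 10.0, 26.0])
        for _ in range(20):
            kin = random_kinetics(rng)
            dose = float(rng.uniform(1e7, 5e8))
            traj = simulate(kin, FixedParams(), dose, t0, times)
            expected = distributed_closed_form(times, dose, kin.beta, kin.eta)
            np.testing.assert_allclose(traj.CD, expected, rtol=RTOL, atol=ATOL_CELLS)

    def test_tumor_logistic_when_cart_inert(self, fixed, t0):
        # with all CAR-T rates zero the tumor follows the logistic closed form
        kin = KineticParams(
            beta=0, eta=0, r_min=0, p1=0, p2=0, p3=1.0, A=50.0,
            xi=0, epsilon=0, lambda_=0, mu=0, delta=0, gamma=0,
        )
        times = np.linspace(0, 60, 13)
        traj = simulate(kin, fixed, 1.0, t0, times)  # dose 1 cell, inert
        r, b = fixed.r, fixed.b
        analytic = t0 / (b * t0 + (1 - b * t0) * np.exp(-r * times))
        np.testing.assert_allclose(traj.T, analytic, rtol=RTOL)

    def test_nonnegativity_and_tumor_bound(self, fixed, t0):
        rng = np.random.default_rng(7)
        times = np.linspace(0, 26, 27)
        for _ in range(10):
            kin = random_kinetics(rng)
            traj = simulate(kin, fixed, 9.23e7, t0, times)
            assert np.all(traj.states >= -ATOL_CELLS)
            assert np.all(traj.T <= (1 / fixed.b) * (1 + 1e-6))

    def test_grid_refinement_consistency(self, fixed, init_kinetics, patient28, dose, t0):
        traj = simulate(init_kinetics, fixed, dose, t0, patient28.days)
        tight = simulate(init_kinetics, fixed, dose, t0, patient28.days, rtol=5e-9, atol=5e-3)
        np.testing.assert_allclose(traj.C, tight.C, rtol=1e-6)

    def test_input_validation(self, fixed, init_kinetics, t0):
        with pytest.raises(ValueError, match="dose"):
            simulate(init_kinetics, fixed, 0.0, t0, [0.0, 1.0])
        with pytest.raises(ValueError, match="start at 0"):
            simulate(init_kinetics, fixed, 1e7, t0, [1.0, 2.0])
        with pytest.raises(ValueError, match="increasing"):
            simulate(init_kinetics, fixed, 1e7, t0, [0.0, 2.0, 1.0])


class TestClosedForm:
    def test_at_zero_and_zero_rate(self):
        assert distributed_closed_form(0.0, 123.0, 1.0, 0.5) == 123.0
        assert distributed_closed_form(10.0, 123.0, 0.0, 0.0) == 123.0

    def test_published_guess_day2(self):
        # 9.23e7 * exp(-2*(1.051+0.054)) ~ 1.012e7
        val = distributed_closed_form(2.0, 9.230e7, 1.051, 5.400e-2)
        assert val == pytest.approx(9.230e7 * math.exp(-2.21), rel=1e-12)
        assert val == pytest.approx(1.012e7, rel=1e-3)


class TestTrajectoryContainer:
    def test_total_is_sum_of_compartments(self):
        states = np.array([[1.0, 2.0, 3.0, 4.0, 99.0], [0.0, 0.0, 0.0, 0.0, 5.0]])
        traj = Trajectory(times=np.array([0.0, 1.0]), states=states)
        np.testing.assert_array_equal(traj.C, [10.0, 0.0])
        np.testing.assert_array_equal(traj.CF, [3.0, 0.0])

    def test_frame_export_columns(self, fixed, init_kinetics, dose, t0):
        traj = simulate(init_kinetics, fixed, dose, t0, [0.0, 1.0, 2.0])
        df = traj.to_frame()
        assert list(df.columns) == ["day", "CD", "CT", "CM", "CE", "T", "C"]
        np.testing.assert_allclose(df["C"], df[["CD", "CT", "CM", "CE"]].sum(axis=1))

    def test_invalid_shapes_rejected(self):
        with pytest.raises(ValueError):
            Trajectory(times=np.array([0.0, 1.0]), states=np.zeros((3, 5)))
        with pytest.raises(ValueError, match="increasing"):
            Trajectory(times=np.array([0.0, 0.0]), states=np.zeros((2, 5)))
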