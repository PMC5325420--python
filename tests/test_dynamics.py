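import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crosstalksim.dynamics import (
    Trajectory,
    drug_factor,
    drug_factors,
    integrated_output,
    rhs,
    simulate,
)
from crosstalksim.model_core import (
    DrugDose,
    DrugRegimen,
    KineticParameters,
    Species,
    StimulusProfile,
    build_module,
    stimulus_library,
)

A, B, C, D, O = Species.A, Species.B, Species.C, Species.D, Species.O
PARAMS = KineticParameters()
S0 = stimulus_library()["S0"]
ZERO_STIM = (
    StimulusProfile("off", "G1", ()),
    StimulusProfile("off", "G2", ()),
)
SUSTAINED = (
    StimulusProfile("on", "G1", ((0.0, 1000.0, 1.0),)),
    StimulusProfile("off", "G2", ()),
)


class TestDrugFactor:
    def test_untreated_gives_unity(self):
        for sp in Species:
            assert drug_factor(sp, DrugRegimen.untreated(), 5.0, PARAMS) == 1.0

    def test_single_dose_inflates_by_dose_over_kd(self):
        reg = DrugRegimen.single(B, 1.0)
        assert drug_factor(B, reg, 0.0, PARAMS) == pytest.approx(11.0)
        assert drug_factor(A, reg, 0.0, PARAMS) == 1.0

    def test_shared_target_doses_sum(self):
        reg = DrugRegimen.combo([B, B], 1.0)
        assert drug_factor(B, reg, 0.0, PARAMS) == pytest.approx(21.0)

    def test_entry_inactive_before_onset(self):
        reg = DrugRegimen((DrugDose(B, 1.0, t_on=50.0),))
        assert drug_factor(B, reg, 49.9, PARAMS) == 1.0
        assert drug_factor(B, reg, 50.0, PARAMS) == pytest.approx(11.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            drug_factor(B, DrugRegimen.untreated(), -1.0, PARAMS)

    def test_vector_agrees_with_scalar(self):
        reg = DrugRegimen.combo([B, D], 1.0)
        g = drug_factors(reg, 0.0, PARAMS)
        assert [g[sp.idx] for sp in Species] == [
            drug_factor(sp, reg, 0.0, PARAMS) for sp in Species
        ]


class TestRhs:
    def test_quiescent_state_is_fixed_point(self):
        dx = rhs(np.zeros(5), 0.0, build_module(0), PARAMS, ZERO_STIM)
        assert np.all(dx == 0.0)

    def test_activation_term_hand_value(self):
        # A half active, everything else off: only A -> B fires,
        # 0.4 * (1 / (0.8 + 1)) * 0.5
        X = np.array([0.5, 0, 0, 0, 0.0])
        dx = rhs(X, 0.0, build_module(0), PARAMS, ZERO_STIM)
        assert dx[B.idx] == pytest.approx(0.4 * (1.0 / 1.8) * 0.5, abs=1e-12)
        assert dx[A.idx] == pytest.approx(-0.2 * 0.5)  # pure degradation

    def test_drug_inflates_michaelis_constant(self):
        # g_B = 11 turns the denominator into 11*0.8 + 1
        X = np.array([0.5, 0, 0, 0, 0.0])
        dx = rhs(X, 0.0, build_module(0), PARAMS, ZERO_STIM,
                 DrugRegimen.single(B, 1.0))
        assert dx[B.idx] == pytest.approx(0.4 * (1.0 / (11 * 0.8 + 1)) * 0.5,
                                          abs=1e-12)

    def test_nonfinite_state_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            rhs(np.array([np.nan, 0, 0, 0, 0]), 0.0, build_module(0),
                PARAMS, ZERO_STIM)

    def test_literal_inhibition_pushes_below_zero(self):
        # the literal saturation form applies (1 - X_i) to inhibiting
        # edges, so an inhibited species at 0 gets a negative derivative
        X = np.array([0, 0, 0, 0.5, 0.0])  # D active, module 8: D -| A
        dx = rhs(X, 0.0, build_module(8), PARAMS, ZERO_STIM,
                 inhibition="literal")
        assert dx[A.idx] < 0
        dx_deact = rhs(X, 0.0, build_module(8), PARAMS, ZERO_STIM)
        assert dx_deact[A.idx] == 0.0


class TestSimulate:
    def test_zero_stimulus_stays_at_zero(self):
        traj = simulate(build_module(0), PARAMS, ZERO_STIM, T=10, h=0.1)
        assert np.all(traj.states == 0.0)

    def test_initial_condition_recorded(self):
        X0 = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        traj = simulate(build_module(0), PARAMS, ZERO_STIM, T=1, h=0.1, X0=X0)
        assert np.array_equal(traj.states[0], X0)
        assert traj.times[0] == 0.0 and traj.times[-1] == pytest.approx(1.0)

    def test_pathway_symmetry_of_module0(self):
        # with symmetric parameters and S0 on both channels, the two
        # cascades are exact mirror images: A==C and B==D
        traj = simulate(build_module(0), PARAMS, S0, T=100, h=0.01)
        assert np.max(np.abs(traj.species(A) - traj.species(C))) < 1e-12
        assert np.max(np.abs(traj.species(B) - traj.species(D))) < 1e-12

    def test_receptor_steady_state_closed_form(self):
        # under a sustained unit G1, A relaxes to V_A/((K_A + 1) d) = 2/3
        traj = simulate(build_module(0), PARAMS, SUSTAINED, T=100, h=0.01)
        assert traj.species(A)[-1] == pytest.approx(2.0 / 3.0, abs=1e-6)

    def test_rk4_fourth_order_convergence(self):
        # single-species relaxation dX/dt = f - d X has the closed form
        # X(t) = (f/d)(1 - exp(-d t)); the global error must shrink ~16x
        # per halving of h
        f_const = PARAMS.V_A * 1.0 / (PARAMS.K_A + 1.0)
        exact = (f_const / PARAMS.d) * (1.0 - np.exp(-PARAMS.d * 20.0))

        def err(h):
            traj = simulate(build_module(0), PARAMS, SUSTAINED, T=20, h=h)
            return abs(traj.species(A)[-1] - exact)

        ratio = err(1.0) / err(0.5)
        assert 10 < ratio < 24

    def test_halving_step_changes_states_below_1e6(self):
        kwargs = dict(topology=build_module(3), params=PARAMS, stimuli=S0,
                      regimen=DrugRegimen.single(B), T=100)
        coarse = simulate(h=0.02, **kwargs)
        fine = simulate(h=0.01, **kwargs)
        assert np.max(np.abs(fine.states[::2] - coarse.states)) < 1e-6

    def test_zero_dose_bit_matches_untreated(self):
        kwargs = dict(topology=build_module(5), params=PARAMS, stimuli=S0,
                      T=50, h=0.05)
        untreated = simulate(regimen=DrugRegimen.untreated(), **kwargs)
        zero_dose = simulate(regimen=DrugRegimen.single(B, 0.0), **kwargs)
        assert np.array_equal(untreated.states, zero_dose.states)

    def test_drug_monotonically_suppresses_its_target(self):
        curves = [
            simulate(build_module(0), PARAMS, S0,
                     DrugRegimen.single(B, dose), T=50, h=0.05).species(B)
            for dose in (0.0, 0.5, 1.0, 2.0)
        ]
        for lo, hi in zip(curves[1:], curves[:-1]):
            assert np.all(lo <= hi + 1e-12)

    def test_crosstalk_scale_continuity(self):
        # module trajectories converge to module 0 as the scale shrinks
        base = simulate(build_module(0), PARAMS, S0, T=50, h=0.05).states
        gaps = []
        for scale in (1.0, 0.3, 0.1, 0.01):
            states = simulate(build_module(5, scale), PARAMS, S0,
                              T=50, h=0.05).states
            gaps.append(np.max(np.abs(states - base)))
        assert all(a > b for a, b in zip(gaps, gaps[1:]))
        assert gaps[-1] < 1e-2

    def test_non_integral_step_count_rejected(self):
        with pytest.raises(ValueError, match="integral"):
            simulate(build_module(0), PARAMS, S0, T=100, h=0.03)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(
        module_id=st.integers(0, 8),
        scale=st.floats(0.1, 10.0),
        stim=st.sampled_from(["S0", "S1", "S2", "S3", "S4", "S5", "S6"]),
        targets=st.sets(st.sampled_from(["A", "B", "C", "D"]), max_size=2),
    )
    def test_states_stay_in_unit_interval(self, module_id, scale, stim,
                                          targets):
        """Nonnegativity + boundedness under the deactivation convention."""
        regimen = (DrugRegimen.combo(sorted(targets)) if targets
                   else DrugRegimen.untreated())
        traj = simulate(build_module(module_id, scale), PARAMS,
                        stimulus_library()[stim], regimen, T=50, h=0.05)
        assert traj.states.min() >= -1e-12
        assert traj.states.max() <= 1.0 + 1e-12


class TestIntegratedOutput:
    def _traj(self, values, T=100.0):
        n = len(values)
        times = np.linspace(0, T, n)
        states = np.zeros((n, 5))
        states[:, O.idx] = values
        return Trajectory(times, states)

    def test_zero_output_integrates_to_zero(self):
        assert integrated_output(self._traj(np.zeros(101))) == 0.0

    def test_constant_output_integrates_to_horizon(self):
        assert integrated_output(self._traj(np.ones(101))) == pytest.approx(100.0)

    def test_linear_ramp_is_trapezoid_exact(self):
        t = np.linspace(0, 100, 101)
        assert integrated_output(self._traj(t / 100.0)) == pytest.approx(50.0)

    def test_short_trajectory_rejected(self):
        with pytest.raises(ValueError, match="integrate"):
            integrated_output(self._traj(np.ones(11), T=10.0), T=100.0)

    def test_tidy_frame_export(self):
        traj = simulate(build_module(1), PARAMS, S0, T=10, h=0.1)
        df = traj.to_frame()
        assert set(df["species"]) == {"A", "B", "C", "D", "O"}
        assert {"time", "value", "module_id", "regimen"} <= set(df.columns)
        assert len(df) == 5 * len(traj.times)
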