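"""Simulator behaviour: analytic identities, oracle agreement, invariants."""

import numpy as np
import pytest

from ebsim import (
    InvalidInputError,
    ModelConfig,
    SimulationDivergedError,
    SolverOptions,
    SubjectBaseline,
    balanced_intake,
    rhs,
    simulate,
    static_prediction,
)
from ebsim.intake import IntakeSchedule

from conftest import euler_end_weight


class TestRhs:
    def test_energy_balance_gives_zero_rate(self, reference_subject, original_config):
        ei = balanced_intake(reference_subject, original_config)
        sched = IntakeSchedule.constant(ei)
        assert rhs(0.0, reference_subject.w0, reference_subject, sched,
                   original_config) == pytest.approx(0.0, abs=1e-12)

    def test_restriction_gives_negative_rate(self, reference_subject, original_config):
        sched = IntakeSchedule.constant(800.0)
        assert rhs(0.0, reference_subject.w0, reference_subject, sched,
                   original_config) < 0

    def test_nonpositive_weight_diverges(self, reference_subject, original_config):
        with pytest.raises(SimulationDivergedError):
            rhs(5.0, 0.0, reference_subject, IntakeSchedule.constant(800.0),
                original_config)


class TestAnalyticLoss:
    def test_constant_1100_deficit_loses_1kg_per_week(self):
        """With AT and DIT off and REE frozen, a constant 1100 kcal/d deficit
        must lose exactly 7700/7700 = 1 kg over 7 days."""
        cfg = ModelConfig(
            at_ceiling=0.0,
            dit_coeff=0.0,
            ffm_shift=0.0,
            cunningham_intercept=1900.0,
            cunningham_slope=0.0,  # REE frozen at 1900 kcal/d
        )
        subj = SubjectBaseline(w0=93.31, pal=1.2)
        ei = 1.2 * 1900.0 - 1100.0  # deficit exactly 1100 kcal/d
        traj = simulate(subj, IntakeSchedule.constant(ei), 1, cfg)
        assert traj.total_loss == pytest.approx(1100.0 * 7 / 7700.0, abs=1e-6)


class TestSimulate:
    def test_zero_deficit_is_flat(self, reference_subject, original_config):
        ei = balanced_intake(reference_subject, original_config)
        traj = simulate(reference_subject, IntakeSchedule.constant(ei), 8,
                        original_config)
        assert traj.end_weight == pytest.approx(reference_subject.w0, abs=1e-6)
        assert np.all(np.abs(traj.weight - reference_subject.w0) < 1e-6)

    def test_grid_is_daily_from_zero(self, reference_subject, original_config):
        traj = simulate(reference_subject, IntakeSchedule.constant(800.0), 8,
                        original_config)
        assert traj.t[0] == 0.0
        assert traj.t[-1] == 56.0
        assert np.all(np.diff(traj.t) > 0)
        assert len(traj.t) == 57

    def test_weight_non_increasing_under_deficit(self, reference_subject,
                                                 original_config, vled_schedule):
        traj = simulate(reference_subject, vled_schedule, 12, original_config)
        assert np.all(traj.deficit > 0)
        assert np.all(np.diff(traj.weight) <= 1e-9)
        for comp in (traj.ree_net, traj.at, traj.paee, traj.dit, traj.ei):
            assert np.all(comp >= 0)

    def test_euler_oracle_agreement(self, reference_subject, original_config):
        """Adaptive RK end-weight within 5 g of an independent fixed-step
        Euler integration (dt = 0.01 d) on an 8-week run."""
        sched = IntakeSchedule.constant(800.0)
        traj = simulate(reference_subject, sched, 8, original_config)
        euler = euler_end_weight(reference_subject, sched, 8, original_config)
        assert abs(traj.end_weight - euler) < 0.005

    def test_solver_tolerance_reproducibility(self, reference_subject,
                                              original_config, vled_schedule):
        """End-weight stable to < 1 g across tolerances spanning two orders
        of magnitude."""
        loose = simulate(reference_subject, vled_schedule, 12, original_config,
                         SolverOptions(rtol=1e-6, atol=1e-6))
        tight = simulate(reference_subject, vled_schedule, 12, original_config,
                         SolverOptions(rtol=1e-10, atol=1e-10))
        assert abs(loose.end_weight - tight.end_weight) < 0.001

    def test_energy_conservation(self, reference_subject, original_config,
                                 vled_schedule):
        traj = simulate(reference_subject, vled_schedule, 12, original_config)
        cum = np.trapezoid(traj.deficit, traj.t)
        stored = original_config.energy_density * traj.total_loss
        assert cum == pytest.approx(stored, rel=1e-3)

    def test_weekly_deceleration(self, reference_subject, original_config):
        """Week-over-week loss is non-increasing after week 1 under constant
        restriction (weight loss decelerates as expenditure falls)."""
        traj = simulate(reference_subject, IntakeSchedule.constant(800.0), 12,
                        original_config)
        weekly = traj.weekly_weights().to_numpy()
        losses = -np.diff(np.concatenate([[reference_subject.w0], weekly]))
        assert np.all(np.diff(losses) <= 1e-9)

    def test_refined_loses_no_more_than_original(self, reference_subject):
        """With identical REE equation, the refined linear FFM% trajectory
        lies below the original before saturation, so its predicted loss
        cannot exceed the original's."""
        orig = ModelConfig(ree_equation="cunningham",
                           ffm_trajectory="exponential_original")
        refi = ModelConfig(ree_equation="cunningham",
                           ffm_trajectory="linear_refined")
        sched = IntakeSchedule.constant(800.0)
        loss_o = simulate(reference_subject, sched, 8, orig).total_loss
        loss_r = simulate(reference_subject, sched, 8, refi).total_loss
        assert loss_r <= loss_o + 1e-6

    def test_variants_coincide_without_ffm_shift(self, reference_subject):
        """Ablation: with ffm_shift = 0 the two FFM trajectories are the same
        constant, so both variants produce the same trajectory."""
        orig = ModelConfig(ffm_shift=0.0, ffm_trajectory="exponential_original")
        refi = ModelConfig(ffm_shift=0.0, ffm_trajectory="linear_refined")
        sched = IntakeSchedule.constant(800.0)
        t1 = simulate(reference_subject, sched, 8, orig)
        t2 = simulate(reference_subject, sched, 8, refi)
        assert np.allclose(t1.weight, t2.weight, atol=1e-7)

    def test_step_schedule_slows_loss_after_switch(self, reference_subject,
                                                   original_config, vled_schedule):
        traj = simulate(reference_subject, vled_schedule, 12, original_config)
        weekly = traj.weekly_weights().to_numpy()
        losses = -np.diff(weekly)
        # weekly loss in week 11 (after the 1200 kcal switch) < week 9
        assert losses[9] < losses[7]

    def test_invalid_duration_rejected(self, reference_subject, original_config):
        with pytest.raises(InvalidInputError):
            simulate(reference_subject, IntakeSchedule.constant(800.0), 0,
                     original_config)

    def test_implausible_ffm_warns(self, original_config):
        subj = SubjectBaseline(w0=62.0, sex="female", pal=2.4, ei0=0.0)
        with pytest.warns(RuntimeWarning, match="lean-reference"):
            simulate(subj, IntakeSchedule.constant(0.0), 12, original_config)


class TestStaticPrediction:
    @pytest.mark.parametrize(
        "deficit,weeks,expected",
        [(500.0, 1, 0.45359237), (0.0, 8, 0.0), (500.0, 10, 4.5359237)],
    )
    def test_pound_rule_values(self, deficit, weeks, expected):
        assert static_prediction(deficit, weeks) == pytest.approx(expected)

    def test_linear_in_both_arguments(self):
        assert static_prediction(1000.0, 3) == pytest.approx(
            2 * static_prediction(500.0, 3)
        )
        assert static_prediction(500.0, 6) == pytest.approx(
            2 * static_prediction(500.0, 3)
        )

    def test_negative_arguments_rejected(self):
        with pytest.raises(InvalidInputError):
            static_prediction(-1.0, 4)
        with pytest.raises(InvalidInputError):
            static_prediction(500.0, -1)


class TestDynamicBelowStatic:
    @pytest.mark.parametrize("w0", [70.0, 100.0, 130.0])
    @pytest.mark.parametrize("deficit", [300.0, 900.0, 1500.0])
    def test_dynamic_loss_below_static_rule(self, w0, deficit, original_config):
        """The falling-expenditure dynamics make every dynamic prediction
        smaller than the static 3500-kcal rule at the baseline deficit."""
        subj = SubjectBaseline(w0=w0, sex="female", pal=1.6)
        ei = balanced_intake(subj, original_config) - deficit
        traj = simulate(subj, IntakeSchedule.constant(ei), 8, original_config)
        assert traj.total_loss < static_prediction(deficit, 8)
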