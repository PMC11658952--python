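"""Weight-trajectory simulation.

The model is a single scalar ODE for body weight,

.. math::

    \\frac{dw}{dt} = \\frac{EI(t) - TEE(w, t)}{\\rho},

with :math:`\\rho` the tissue energy density (7700 kcal/kg) and TEE composed
algebraically from weight via the energetics functions: baseline FFM%
prediction, the saturating FFM% trajectory, the FFM-based REE equation, the
adaptive-thermogenesis reduction, the PAL multiplier and the DIT fraction of
intake.

Integration uses an adaptive Runge-Kutta (scipy ``solve_ivp``, RK45) with
the time axis split at intake-schedule discontinuities, since a step in the
forcing degrades adaptive steppers that integrate across it. Daily outputs
come from the dense solution; weekly weigh-in values are read at days 7,
14, ... (end-of-week convention).

The static "3500-kcal rule" comparator — 1 lb lost per 3500 kcal of
cumulative deficit, energy expenditure assumed constant — is provided for
contrast with the dynamic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .config import ModelConfig, SubjectBaseline
from .energetics import CompositionState, baseline_ffm_fraction, total_ee
from .energetics import ree as ree_fn
from .errors import InvalidInputError, SimulationDivergedError
from .intake import DAYS_PER_WEEK

KCAL_PER_POUND = 3500.0
KG_PER_POUND = 0.45359237

#: Trajectory CSV / DataFrame column order.
TRAJECTORY_COLUMNS = [
    "t",
    "weight",
    "ffm_kg",
    "ree_net",
    "at",
    "paee",
    "dit",
    "ei",
    "deficit",
]


@dataclass(frozen=True)
class SolverOptions:
    """Tolerances for the adaptive integrator."""

    rtol: float = 1e-8
    atol: float = 1e-8
    max_step: float = field(default=np.inf)


@dataclass(frozen=True)
class Trajectory:
    """Daily simulation output.

    All arrays share the daily time grid ``t`` (days, starting at 0).
    ``deficit = total EE - EI``: positive while the subject is in negative
    energy balance, so weight is non-increasing wherever it is positive.
    """

    t: np.ndarray
    weight: np.ndarray
    ffm_kg: np.ndarray
    ree_net: np.ndarray
    at: np.ndarray
    paee: np.ndarray
    dit: np.ndarray
    ei: np.ndarray
    deficit: np.ndarray

    @property
    def end_weight(self) -> float:
        return float(self.weight[-1])

    @property
    def total_loss(self) -> float:
        return float(self.weight[0] - self.weight[-1])

    def weekly_weights(self) -> pd.Series:
        """Weights at the weekly weigh-ins (days 7, 14, ...), indexed by week."""
        weeks = np.arange(1, int(self.t[-1] // DAYS_PER_WEEK) + 1)
        idx = np.searchsorted(self.t, weeks * DAYS_PER_WEEK)
        return pd.Series(self.weight[idx], index=weeks, name="weight")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {name: getattr(self, name) for name in TRAJECTORY_COLUMNS}
        )


def rhs(
    t: float,
    w: float,
    subject: SubjectBaseline,
    schedule,
    config: ModelConfig,
) -> float:
    """Rate of weight change, kg/d, at time ``t`` (days) and weight ``w`` (kg).

    Relative loss is measured against the pre-intervention weight ``w0`` and
    clamped at zero (transient numerical excursions above w0 are treated as
    zero loss; sustained weight gain is outside model scope).
    """
    if w <= 0:
        raise SimulationDivergedError(
            f"weight reached {w:.3f} kg at day {t:.2f}", day=t
        )
    c = baseline_ffm_fraction(subject.w0, subject.sex, config)
    state = CompositionState.from_weight(min(w, subject.w0), subject.w0, c, config)
    ei = schedule.ei_at(t)
    ee = total_ee(state, ei, subject, config)
    return (ei - ee.total) / config.energy_density


def simulate(
    subject: SubjectBaseline,
    schedule,
    duration_weeks: float,
    config: ModelConfig | None = None,
    solver: SolverOptions | None = None,
) -> Trajectory:
    """Integrate the weight ODE over ``duration_weeks`` and return a daily trajectory.

    The integration is segmented at every intake discontinuity inside the
    simulated interval. Raises :class:`SimulationDivergedError` if the
    solver fails or weight leaves (0, inf); emits a warning (not an error)
    if FFM falls below the sex-specific lean-reference FFM.
    """
    if duration_weeks <= 0:
        raise InvalidInputError(f"duration must be positive, got {duration_weeks}")
    config = config or ModelConfig()
    solver = solver or SolverOptions()

    t_end = duration_weeks * DAYS_PER_WEEK
    breaks = sorted(b for b in schedule.breakpoints() if 0.0 < b < t_end)
    edges = [0.0, *breaks, t_end]

    c = baseline_ffm_fraction(subject.w0, subject.sex, config)
    t_grid = np.arange(0.0, np.floor(t_end) + 1.0)
    if t_grid[-1] < t_end:
        t_grid = np.append(t_grid, t_end)
    # sample just before each intake discontinuity so piecewise-constant
    # forcing is represented exactly (keeps trapezoidal energy bookkeeping
    # consistent with the ODE across the step)
    if breaks:
        t_grid = np.unique(np.concatenate([t_grid, np.array(breaks) - 1e-9]))

    weight = np.empty_like(t_grid)
    weight[0] = subject.w0
    w_seg = subject.w0
    for lo, hi in zip(edges[:-1], edges[1:]):
        # clamp RHS evaluation times to just inside the segment so the
        # half-open step convention cannot leak the post-switch intake into
        # the pre-switch segment at the shared endpoint
        hi_in = np.nextafter(hi, lo)
        sol = solve_ivp(
            lambda t, y: [rhs(min(max(t, lo), hi_in), y[0], subject, schedule, config)],
            (lo, hi),
            [w_seg],
            method="RK45",
            dense_output=True,
            rtol=solver.rtol,
            atol=solver.atol,
            max_step=solver.max_step,
        )
        if not sol.success:
            raise SimulationDivergedError(
                f"integration failed in [{lo:.1f}, {hi:.1f}] d: {sol.message}",
                day=lo,
            )
        mask = (t_grid > lo) & (t_grid <= hi)
        weight[mask] = sol.sol(t_grid[mask])[0]
        w_seg = float(sol.y[0, -1])
        if w_seg <= 0:
            raise SimulationDivergedError(
                f"weight reached {w_seg:.3f} kg by day {hi:.1f}", day=hi
            )

    # algebraic components on the daily grid
    n = t_grid.size
    ffm = np.empty(n)
    ree_net = np.empty(n)
    at = np.empty(n)
    paee = np.empty(n)
    dit_arr = np.empty(n)
    ei_arr = np.empty(n)
    for i, (ti, wi) in enumerate(zip(t_grid, weight)):
        state = CompositionState.from_weight(min(wi, subject.w0), subject.w0, c, config)
        ei = schedule.ei_at(ti)
        ee = total_ee(state, ei, subject, config)
        ffm[i] = state.ffm_kg
        at[i] = ree_fn(state.ffm_kg, config) - ee.ree_net
        ree_net[i] = ee.ree_net
        paee[i] = ee.paee
        dit_arr[i] = ee.dit
        ei_arr[i] = ei
    deficit = (ree_net * subject.pal + dit_arr) - ei_arr

    ref_ffm = config.lean_ref_ffm_frac(subject.sex) * config.lean_ref_weight(subject.sex)
    if np.any(ffm < ref_ffm):
        warnings.warn(
            f"simulated FFM fell below the lean-reference FFM "
            f"({ref_ffm:.1f} kg); the trajectory is physiologically implausible",
            RuntimeWarning,
            stacklevel=2,
        )

    return Trajectory(
        t=t_grid,
        weight=weight,
        ffm_kg=ffm,
        ree_net=ree_net,
        at=at,
        paee=paee,
        dit=dit_arr,
        ei=ei_arr,
        deficit=deficit,
    )


def static_prediction(deficit: float, duration_weeks: float) -> float:
    """Weight loss, kg, under the static 3500-kcal rule.

    A constant daily deficit accumulated over the duration, converted at
    3500 kcal per pound: loss = deficit x 7 x weeks / 3500 lb.
    """
    if deficit < 0:
        raise InvalidInputError(f"deficit must be >= 0, got {deficit}")
    if duration_weeks < 0:
        raise InvalidInputError(f"duration must be >= 0, got {duration_weeks}")
    return deficit * DAYS_PER_WEEK * duration_weeks / KCAL_PER_POUND * KG_PER_POUND


def balanced_intake(subject: SubjectBaseline, config: ModelConfig | None = None) -> float:
    """Energy intake that exactly balances baseline expenditure, kcal/d.

    Solves EI = PAL x REE(w0) + dit_coeff x EI for EI, i.e. the intake at
    which the model predicts a flat trajectory. Useful for constructing
    subjects with a prescribed baseline deficit.
    """
    config = config or ModelConfig()
    c = baseline_ffm_fraction(subject.w0, subject.sex, config)
    state = CompositionState.from_weight(subject.w0, subject.w0, c, config)
    ee0 = total_ee(state, 0.0, subject, config)  # EE without the DIT term
    return ee0.total / (1.0 - config.dit_coeff)
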