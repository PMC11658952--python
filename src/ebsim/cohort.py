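"""Synthetic weekly-weigh-in cohort generator.

Emulates the statistical structure of a commercial very-low-energy
total-diet-replacement cohort — all female, baseline weight roughly
Normal(93.31, 19.18) kg, 6-12-week interventions with weekly weigh-ins —
so the full simulate -> evaluate pipeline is testable without proprietary
client data. Two systematic phenomena known to shape real weigh-in series
are layered onto the model-generated latent trajectory:

* an early glycogen-water bolus: rapid depletion of glycogen stores and
  their bound water (roughly 1:3 g) produces 1.5-2.0 kg of extra observed
  loss in the first week or two. It is water, not an energy store, so it
  is modelled as an offset on the observed weight, not as a change to the
  energy model: extra observed loss b * (1 - 2^(-t/halflife)) with b drawn
  per subject.
* late compliance drift: intake creeping above prescription from a chosen
  onset week, modelled by adding a fixed kcal/d to the latent subject's
  intake from that week on; the evaluation arm still predicts from the
  prescribed schedule, so late weeks show over-predicted loss.

Independent Gaussian observation noise is added to each weekly weigh-in.
Generation is fully reproducible from the CohortSpec seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import ModelConfig, SubjectBaseline
from .errors import InvalidSpecError
from .evaluation import COHORT_COLUMNS
from .intake import DAYS_PER_WEEK, IntakeSchedule
from .simulate import SolverOptions, simulate

#: Enrolment-length distribution over 6-12 weeks: mode at 8 weeks, smallest
#: mass at 12, loosely following the reported enrolment pattern.
DEFAULT_LENGTH_WEIGHTS = {
    6: 0.135,
    7: 0.16,
    8: 0.18,
    9: 0.16,
    10: 0.14,
    11: 0.14,
    12: 0.085,
}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the study conditions: n subjects with baseline
    weight from a truncated Normal(93.31, 19.18) kg, intervention lengths
    drawn from ``length_weights``, a per-subject glycogen-water bolus drawn
    uniformly from ``glycogen_bolus_range`` kg with half-life
    ``glycogen_halflife`` days, compliance drift of
    ``compliance_extra_kcal`` kcal/d from ``compliance_onset_week``, and
    weigh-in noise with SD ``obs_noise_sd`` kg.
    """

    n: int = 100
    weight_mean: float = 93.31
    weight_sd: float = 19.18
    weight_min: float = 45.0  # guard against non-physical draws only; far
    # enough below the mean (-2.5 SD) that truncation barely shifts it
    age_mean: float = 47.0
    length_weights: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_WEIGHTS)
    )
    glycogen_bolus_range: tuple[float, float] = (1.5, 2.0)
    glycogen_halflife: float = 5.0
    compliance_onset_week: float = 8.0
    compliance_extra_kcal: float = 200.0
    obs_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise InvalidSpecError(f"cohort size must be >= 1, got {self.n}")
        if self.weight_sd < 0:
            raise InvalidSpecError("weight_sd must be >= 0")
        total = sum(self.length_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(
                f"length_weights must sum to 1, got {total:.6f}"
            )
        if any(w < 0 for w in self.length_weights.values()):
            raise InvalidSpecError("length_weights must be non-negative")
        lo, hi = self.glycogen_bolus_range
        if lo < 0 or hi < lo:
            raise InvalidSpecError("glycogen_bolus_range must satisfy 0 <= lo <= hi")
        if self.glycogen_halflife <= 0:
            raise InvalidSpecError("glycogen_halflife must be positive")
        if self.obs_noise_sd < 0:
            raise InvalidSpecError("obs_noise_sd must be >= 0")
        if self.weight_sd > 0:
            z = (self.weight_min - self.weight_mean) / self.weight_sd
            if stats.norm.sf(z) < 1e-9:
                raise InvalidSpecError(
                    f"weight_min {self.weight_min} leaves no mass above the "
                    f"truncation point"
                )
        elif self.weight_min > self.weight_mean:
            raise InvalidSpecError(
                "degenerate weight distribution lies entirely below weight_min"
            )


class _DriftedSchedule:
    """Prescribed schedule plus a constant intake excess from an onset week.

    Models relaxed dietary compliance; satisfies the simulator's schedule
    protocol (``ei_at`` / ``breakpoints``).
    """

    def __init__(self, base: IntakeSchedule, extra_kcal: float, onset_week: float):
        self.base = base
        self.extra_kcal = extra_kcal
        self.onset_day = onset_week * DAYS_PER_WEEK

    def ei_at(self, t: float) -> float:
        ei = self.base.ei_at(t)
        if t >= self.onset_day:
            ei += self.extra_kcal
        return ei

    def breakpoints(self) -> list[float]:
        pts = set(self.base.breakpoints())
        if self.extra_kcal != 0.0:
            pts.add(self.onset_day)
        return sorted(pts)


def generate_cohort(
    spec: CohortSpec,
    config: ModelConfig | None = None,
    schedule: IntakeSchedule | None = None,
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Generate the observed arm of a synthetic cohort.

    Returns a DataFrame in the cohort-table schema with the
    ``predicted_weight`` column left NaN (fill it with
    :func:`ebsim.evaluation.add_model_predictions`). The latent "true"
    trajectory is the dynamic model itself, simulated under the prescribed
    schedule perturbed by the compliance drift; the observed weekly weights
    add the decaying glycogen-water loss and i.i.d. weigh-in noise.
    """
    config = config or ModelConfig()
    schedule = schedule or IntakeSchedule.vled_default()
    rng = np.random.default_rng(spec.seed)

    if spec.weight_sd > 0:
        a = (spec.weight_min - spec.weight_mean) / spec.weight_sd
        w0s = stats.truncnorm.rvs(
            a, np.inf, loc=spec.weight_mean, scale=spec.weight_sd,
            size=spec.n, random_state=rng,
        )
    else:
        w0s = np.full(spec.n, spec.weight_mean)

    lengths_avail = sorted(spec.length_weights)
    probs = np.array([spec.length_weights[k] for k in lengths_avail], dtype=float)
    probs = probs / probs.sum()
    lengths = rng.choice(lengths_avail, size=spec.n, p=probs)

    lo, hi = spec.glycogen_bolus_range
    boluses = rng.uniform(lo, hi, size=spec.n) if hi > lo else np.full(spec.n, lo)

    rows = []
    for i in range(spec.n):
        w0 = float(w0s[i])
        weeks = int(lengths[i])
        subject = SubjectBaseline(w0=w0, sex="female", pal=1.6)
        latent_schedule = (
            _DriftedSchedule(schedule, spec.compliance_extra_kcal, spec.compliance_onset_week)
            if spec.compliance_extra_kcal != 0.0
            else schedule
        )
        traj = simulate(subject, latent_schedule, weeks, config, solver)
        weekly = traj.weekly_weights()
        for week in range(1, weeks + 1):
            t_days = week * DAYS_PER_WEEK
            water_loss = boluses[i] * -np.expm1(
                -t_days * np.log(2.0) / spec.glycogen_halflife
            )
            noise = rng.normal(0.0, spec.obs_noise_sd) if spec.obs_noise_sd > 0 else 0.0
            observed = float(weekly.loc[week]) - float(water_loss) + float(noise)
            rows.append(
                {
                    "subject_id": f"S{i + 1:04d}",
                    "week": week,
                    "observed_weight": observed,
                    "predicted_weight": np.nan,
                    "w0": w0,
                    "intervention_length": weeks,
                }
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
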