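"""Core energetics: every algebraic quantity of the energy-balance model.

The model tracks a single state variable, body weight ``w(t)``. Everything
else — fat-free mass (FFM), resting energy expenditure (REE), adaptive
thermogenesis (AT), diet-induced thermogenesis (DIT), physical-activity
energy expenditure (PAEE) — is an algebraic function of weight, the
subject's baseline, and the configuration. The functions here are pure and
scalar; the ODE right-hand side in :mod:`ebsim.simulate` composes them.

Saturating trajectories
-----------------------
Both FFM% (original variant) and AT rise exponentially with relative weight
loss ``x = (w0 − w)/w0`` and saturate at a threshold ``x_sat``:

.. math::

    f(x) = f_{sat} \\cdot \\frac{1 - e^{-kx}}{1 - e^{-k x_{sat}}},
    \\qquad k = \\ln(100)/x_{sat},

clamped to :math:`f_{sat}` for :math:`x \\ge x_{sat}`. The shape constant
``k`` puts the raw exponential at 99% of its asymptote at the threshold, so
the curve is continuous there (the normalisation makes the value exact) and
the anchors — 0 at baseline, the ceiling at the threshold — hold exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

from .config import ModelConfig, SubjectBaseline
from .errors import InvalidInputError

__all__ = [
    "CompositionState",
    "EEComponents",
    "baseline_ffm_fraction",
    "ffm_fraction_at",
    "ree",
    "adaptive_thermogenesis",
    "dit",
    "total_ee",
]


def _saturating_rise(x: float, x_sat: float) -> float:
    """Normalised exponential rise: 0 at x=0, exactly 1 for x >= x_sat."""
    if x >= x_sat:
        return 1.0
    k = math.log(100.0) / x_sat
    return -math.expm1(-k * x) / -math.expm1(-k * x_sat)


@dataclass(frozen=True)
class CompositionState:
    """Body composition at a moment of the weight-loss phase.

    ``ffm_kg = ffm_frac * weight`` and ``rel_loss = (w0 - w)/w0`` by
    construction; fat mass is the complement ``weight - ffm_kg``.
    """

    weight: float
    ffm_frac: float
    ffm_kg: float
    rel_loss: float

    def __post_init__(self):
        if not 0 < self.ffm_frac < 1:
            raise InvalidInputError(
                f"ffm_frac must lie in (0, 1), got {self.ffm_frac}"
            )
        if self.rel_loss < 0:
            raise InvalidInputError(
                f"relative loss must be >= 0, got {self.rel_loss}"
            )

    @property
    def fm_kg(self) -> float:
        return self.weight - self.ffm_kg

    @classmethod
    def from_weight(
        cls,
        weight: float,
        w0: float,
        baseline_frac: float,
        config: ModelConfig,
    ) -> "CompositionState":
        """Composition at current ``weight`` for a subject who started at ``w0``."""
        if weight <= 0:
            raise InvalidInputError(f"weight must be positive, got {weight}")
        rel_loss = (w0 - weight) / w0
        frac = ffm_fraction_at(rel_loss, baseline_frac, config)
        return cls(weight=weight, ffm_frac=frac, ffm_kg=frac * weight, rel_loss=rel_loss)


class EEComponents(NamedTuple):
    """Decomposition of total energy expenditure, kcal/d."""

    ree_net: float  # REE after the AT reduction
    paee: float  # (PAL - 1) x net REE
    dit: float  # dit_coeff x EI
    total: float  # PAL x net REE + DIT


def baseline_ffm_fraction(w0: float, sex: str, config: ModelConfig) -> float:
    """Predict baseline FFM as a fraction of starting weight.

    FFM(kg) is assumed linear in starting weight, anchored at a lean
    reference individual: excess weight above the reference carries
    ``excess_ffm_frac`` (default 25%) fat-free mass, the remainder fat.
    The prediction is FFM(kg)/w0, so it decreases with w0 above the anchor.
    """
    if w0 <= 0:
        raise InvalidInputError(f"starting weight must be positive, got {w0}")
    ref_w = config.lean_ref_weight(sex)
    ref_frac = config.lean_ref_ffm_frac(sex)
    ffm_kg = ref_frac * ref_w + config.excess_ffm_frac * (w0 - ref_w)
    frac = ffm_kg / w0
    if not 0 < frac < 1:
        raise InvalidInputError(
            f"predicted baseline FFM fraction {frac:.3f} outside (0, 1) "
            f"for w0={w0} kg; check lean-reference anchors"
        )
    return frac


def ffm_fraction_at(rel_loss: float, c: float, config: ModelConfig) -> float:
    """FFM fraction of body weight after a relative weight loss.

    Starts at the baseline fraction ``c``; rises with relative loss and
    saturates ``ffm_shift`` percentage points above baseline. The original
    variant rises exponentially and saturates at 10% loss, the refined
    variant linearly with saturation at 20% loss. Continuous and
    non-decreasing everywhere.
    """
    if rel_loss < 0:
        raise InvalidInputError(
            f"relative loss must be >= 0 (weight gain is outside model scope), "
            f"got {rel_loss}"
        )
    if not 0 < c < 1:
        raise InvalidInputError(f"baseline FFM fraction must lie in (0, 1), got {c}")
    shift = config.ffm_shift / 100.0
    if config.ffm_trajectory == "exponential_original":
        frac = c + shift * _saturating_rise(rel_loss, config.sat_threshold_original)
    else:  # linear_refined
        frac = c + shift * min(rel_loss / config.sat_threshold_refined, 1.0)
    return frac


def ree(ffm_kg: float, config: ModelConfig) -> float:
    """Resting energy expenditure, kcal/d, from FFM in kg.

    Cunningham: 500 + 22 FFM. Mifflin (FFM-based form): 413 + 19.7 FFM.
    """
    if ffm_kg <= 0:
        raise InvalidInputError(f"FFM must be positive, got {ffm_kg}")
    if config.ree_equation == "cunningham":
        return config.cunningham_intercept + config.cunningham_slope * ffm_kg
    return config.mifflin_intercept + config.mifflin_slope * ffm_kg


def adaptive_thermogenesis(
    rel_loss: float, ree_value: float, config: ModelConfig
) -> float:
    """Adaptive reduction in REE, kcal/d, as a function of relative loss.

    Zero at baseline, rising exponentially and stabilising at
    ``at_ceiling`` (15%) of REE once relative loss reaches the original
    saturation threshold (10%).
    """
    if rel_loss < 0:
        raise InvalidInputError(f"relative loss must be >= 0, got {rel_loss}")
    if ree_value <= 0:
        raise InvalidInputError(f"REE must be positive, got {ree_value}")
    return (
        config.at_ceiling
        * ree_value
        * _saturating_rise(rel_loss, config.sat_threshold_original)
    )


def dit(ei: float, config: ModelConfig) -> float:
    """Diet-induced thermogenesis: a fixed fraction of energy intake."""
    if ei < 0:
        raise InvalidInputError(f"energy intake must be >= 0, got {ei}")
    return config.dit_coeff * ei


def total_ee(
    state: CompositionState,
    ei: float,
    subject: SubjectBaseline,
    config: ModelConfig,
) -> EEComponents:
    """Total daily energy expenditure and its components.

    AT is subtracted from REE first; PAL then multiplies the AT-adjusted
    REE (PAEE = (PAL − 1) × net REE), and DIT is added on top:

        total = PAL × (REE − AT) + dit_coeff × EI
    """
    gross_ree = ree(state.ffm_kg, config)
    at = adaptive_thermogenesis(state.rel_loss, gross_ree, config)
    ree_net = gross_ree - at
    paee = (subject.pal - 1.0) * ree_net
    dit_val = dit(ei, config)
    total = subject.pal * ree_net + dit_val
    return EEComponents(ree_net=ree_net, paee=paee, dit=dit_val, total=total)
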