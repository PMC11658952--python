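"""Model configuration and subject description.

:class:`ModelConfig` collects every constant of the energy-balance model —
tissue energy density, the diet-induced-thermogenesis coefficient, the
adaptive-thermogenesis ceiling, the fat-free-mass (FFM) trajectory shape and
its saturation thresholds, the resting-energy-expenditure (REE) equation and
its coefficients, and the lean-reference anchors used to predict baseline
FFM%. Nothing numerical is hard-coded elsewhere: the simulator and the
energetics functions read every constant from here.

Two presets mirror the two published model variants:

* :meth:`ModelConfig.original` — Cunningham REE on FFM with an exponential
  FFM% rise saturating at 10% relative weight loss.
* :meth:`ModelConfig.refined` — Mifflin REE on FFM with a linear FFM% rise
  saturating at 20% relative weight loss.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError, InvalidInputError

SEXES = ("female", "male")
REE_EQUATIONS = ("cunningham", "mifflin")
FFM_TRAJECTORIES = ("exponential_original", "linear_refined")

#: PAL index range: 1.2 (chair/bed-bound) to 2.4 (strenuous work or highly
#: active leisure).
PAL_MIN, PAL_MAX = 1.2, 2.4


@dataclass(frozen=True)
class SubjectBaseline:
    """Baseline description of one dieting subject.

    Parameters
    ----------
    w0:
        Starting body weight, kg. Must be positive.
    sex:
        ``"female"`` or ``"male"``; selects the lean-reference anchors used
        to predict baseline FFM%.
    pal:
        Physical activity level, the TEE/REE multiplier. Restricted to the
        PAL-index range [1.2, 2.4]; 1.6 represents a moderately active
        lifestyle and is the modelling default.
    ei0:
        Baseline prescribed energy intake, kcal/d (informational; the
        simulator takes intake from a schedule).
    """

    w0: float
    sex: str = "female"
    pal: float = 1.6
    ei0: float = 800.0

    def __post_init__(self):
        if not self.w0 > 0:
            raise InvalidInputError(f"starting weight must be positive, got {self.w0}")
        if self.sex not in SEXES:
            raise InvalidInputError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not (PAL_MIN <= self.pal <= PAL_MAX):
            raise InvalidInputError(
                f"PAL must lie in [{PAL_MIN}, {PAL_MAX}], got {self.pal}"
            )
        if self.ei0 < 0:
            raise InvalidInputError(f"baseline intake must be >= 0, got {self.ei0}")


@dataclass(frozen=True)
class ModelConfig:
    """All constants of the dynamic energy-balance model.

    Attributes
    ----------
    energy_density:
        kcal per kg of tissue used to convert energy deficit to weight
        change; default 7700.
    dit_coeff:
        Diet-induced thermogenesis as a fraction of energy intake; 0.05 for
        an overweight/obese population (0.10 would suit a lean one).
    at_ceiling:
        Adaptive thermogenesis at saturation, as a fraction of REE (0.15:
        AT stabilises at 15% of REE).
    ffm_shift:
        Percentage points added to baseline FFM% at saturation (default 10).
    sat_threshold_original / sat_threshold_refined:
        Relative weight loss (fraction of w0) at which the exponential
        (original) / linear (refined) FFM% trajectory saturates; AT always
        saturates at ``sat_threshold_original``.
    ree_equation:
        ``"cunningham"`` (REE = 500 + 22·FFM) or ``"mifflin"``
        (REE = 413 + 19.7·FFM), both FFM in kg, REE in kcal/d.
    ffm_trajectory:
        ``"exponential_original"`` or ``"linear_refined"``.
    lean_ref_weight_* / lean_ref_ffm_frac_*:
        Literature anchors for a lean reference individual of each sex,
        used by the baseline FFM% predictor.
    excess_ffm_frac:
        Fraction of excess body weight (above the lean reference) assumed
        to be FFM; default 0.25 (the remaining 75% is fat mass).
    """

    energy_density: float = 7700.0
    dit_coeff: float = 0.05
    at_ceiling: float = 0.15
    ffm_shift: float = 10.0
    sat_threshold_original: float = 0.10
    sat_threshold_refined: float = 0.20
    ree_equation: str = "cunningham"
    ffm_trajectory: str = "exponential_original"
    lean_ref_weight_female: float = 60.0
    lean_ref_weight_male: float = 70.0
    lean_ref_ffm_frac_female: float = 0.72
    lean_ref_ffm_frac_male: float = 0.85
    excess_ffm_frac: float = 0.25
    cunningham_intercept: float = 500.0
    cunningham_slope: float = 22.0
    mifflin_intercept: float = 413.0
    mifflin_slope: float = 19.7

    def __post_init__(self):
        if not self.energy_density > 0:
            raise InvalidInputError("energy_density must be positive")
        if not 0 <= self.dit_coeff <= 1:
            raise InvalidInputError("dit_coeff must lie in [0, 1]")
        if not 0 <= self.at_ceiling < 1:
            raise InvalidInputError("at_ceiling must lie in [0, 1)")
        if self.ffm_shift < 0:
            raise InvalidInputError("ffm_shift must be >= 0")
        for name in ("sat_threshold_original", "sat_threshold_refined"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise InvalidInputError(f"{name} must lie in (0, 1)")
        if self.ree_equation not in REE_EQUATIONS:
            raise InvalidInputError(
                f"ree_equation must be one of {REE_EQUATIONS}, got {self.ree_equation!r}"
            )
        if self.ffm_trajectory not in FFM_TRAJECTORIES:
            raise InvalidInputError(
                f"ffm_trajectory must be one of {FFM_TRAJECTORIES}, "
                f"got {self.ffm_trajectory!r}"
            )
        for name in (
            "lean_ref_weight_female",
            "lean_ref_weight_male",
        ):
            if not getattr(self, name) > 0:
                raise InvalidInputError(f"{name} must be positive")
        for name in (
            "lean_ref_ffm_frac_female",
            "lean_ref_ffm_frac_male",
            "excess_ffm_frac",
        ):
            if not 0 < getattr(self, name) < 1:
                raise InvalidInputError(f"{name} must lie in (0, 1)")

    # -- presets ---------------------------------------------------------

    @classmethod
    def original(cls, **overrides) -> "ModelConfig":
        """Original model: Cunningham REE, exponential FFM% trajectory."""
        overrides.setdefault("ree_equation", "cunningham")
        overrides.setdefault("ffm_trajectory", "exponential_original")
        return cls(**overrides)

    @classmethod
    def refined(cls, **overrides) -> "ModelConfig":
        """Refined model: Mifflin REE, linear FFM% trajectory to 20% loss."""
        overrides.setdefault("ree_equation", "mifflin")
        overrides.setdefault("ffm_trajectory", "linear_refined")
        return cls(**overrides)

    # -- sex-specific accessors -----------------------------------------

    def lean_ref_weight(self, sex: str) -> float:
        if sex not in SEXES:
            raise InvalidInputError(f"sex must be one of {SEXES}, got {sex!r}")
        return self.lean_ref_weight_female if sex == "female" else self.lean_ref_weight_male

    def lean_ref_ffm_frac(self, sex: str) -> float:
        if sex not in SEXES:
            raise InvalidInputError(f"sex must be one of {SEXES}, got {sex!r}")
        return (
            self.lean_ref_ffm_frac_female
            if sex == "female"
            else self.lean_ref_ffm_frac_male
        )

    def sat_threshold(self) -> float:
        """Saturation threshold of the configured FFM% trajectory."""
        if self.ffm_trajectory == "exponential_original":
            return self.sat_threshold_original
        return self.sat_threshold_refined

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        if not isinstance(data, dict):
            raise ConfigError(f"model config must be a mapping, got {type(data).__name__}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown model config keys: {sorted(unknown)}")
        try:
            return cls(**data)
        except TypeError as exc:  # pragma: no cover - defensive
            raise ConfigError(str(exc)) from exc

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "ModelConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
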