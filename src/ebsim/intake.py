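"""Energy-intake schedules.

Intake is a (piecewise-constant) function of time in days. Two kinds are
supported: a constant level, and a two-level step — the form used for
very-low-energy total-diet-replacement programmes, where intake rises from
800 to 1200 kcal/d at week 10 to reflect food reintroduction. Week 10 is
internally day 70; the step uses the half-open convention [0, 70) -> level1,
[70, inf) -> level2, so the first reintroduction day already carries the
higher intake.

Any object with ``ei_at(t)`` and ``breakpoints()`` methods can serve as a
schedule for the simulator; the dataclass here is the standard concrete one.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import InvalidInputError

DAYS_PER_WEEK = 7.0


@dataclass(frozen=True)
class IntakeSchedule:
    """Constant or two-level step energy intake.

    Fields
    ------
    kind : {"constant", "step"}
    level1 : kcal/d, the (first) intake level.
    level2 : kcal/d, the post-switch level (step only).
    switch_week : week at which intake switches to level2 (step only);
        the switch happens at day ``7 * switch_week``.
    """

    kind: str = "constant"
    level1: float = 800.0
    level2: float | None = None
    switch_week: float | None = None

    def __post_init__(self):
        if self.kind not in ("constant", "step"):
            raise InvalidInputError(
                f"schedule kind must be 'constant' or 'step', got {self.kind!r}"
            )
        if self.level1 < 0:
            raise InvalidInputError(f"level1 must be >= 0, got {self.level1}")
        if self.kind == "step":
            if self.level2 is None or self.level2 < 0:
                raise InvalidInputError("step schedule needs level2 >= 0")
            if self.switch_week is None or not self.switch_week > 0:
                raise InvalidInputError("step schedule needs switch_week > 0")

    @classmethod
    def constant(cls, level: float) -> "IntakeSchedule":
        return cls(kind="constant", level1=level)

    @classmethod
    def step(cls, level1: float, level2: float, switch_week: float) -> "IntakeSchedule":
        return cls(kind="step", level1=level1, level2=level2, switch_week=switch_week)

    @classmethod
    def vled_default(cls) -> "IntakeSchedule":
        """800 kcal/d before week 10, 1200 kcal/d from week 10 on."""
        return cls.step(800.0, 1200.0, 10.0)

    def ei_at(self, t: float) -> float:
        """Energy intake, kcal/d, at time ``t`` in days."""
        if t < 0:
            raise InvalidInputError(f"time must be >= 0, got {t}")
        if self.kind == "constant":
            return self.level1
        return self.level1 if t < self.switch_week * DAYS_PER_WEEK else self.level2

    def breakpoints(self) -> list[float]:
        """Times (days) at which intake is discontinuous."""
        if self.kind == "step":
            return [self.switch_week * DAYS_PER_WEEK]
        return []

    def to_dict(self) -> dict:
        d = {"kind": self.kind, "level1": self.level1}
        if self.kind == "step":
            d["level2"] = self.level2
            d["switch_week"] = self.switch_week
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "IntakeSchedule":
        from .errors import ConfigError

        known = {"kind", "level1", "level2", "switch_week"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown schedule keys: {sorted(unknown)}")
        return cls(**data)
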