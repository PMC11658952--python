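"""Shared fixtures and the independent fixed-step Euler oracle.

The Euler integrator here is deliberately written as a plain forward loop,
independent of the adaptive solver used by the package, so solver
cross-checks compare two genuinely different integration routes over the
same right-hand side.
"""

import pytest

from ebsim import ModelConfig, SubjectBaseline
from ebsim.intake import IntakeSchedule
from ebsim.simulate import rhs


def euler_end_weight(subject, schedule, duration_weeks, config, dt=0.01):
    """Forward-Euler end weight with fixed step dt (days)."""
    t_end = duration_weeks * 7.0
    n = round(t_end / dt)
    w = subject.w0
    for i in range(n):
        w += dt * rhs(i * dt, w, subject, schedule, config)
    return w


@pytest.fixture
def reference_subject():
    """The cohort-mean subject: 93.31 kg female, PAL 1.6."""
    return SubjectBaseline(w0=93.31, sex="female", pal=1.6)


@pytest.fixture
def original_config():
    return ModelConfig.original()


@pytest.fixture
def refined_config():
    return ModelConfig.refined()


@pytest.fixture
def vled_schedule():
    return IntakeSchedule.vled_default()
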