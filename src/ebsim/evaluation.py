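"""Agreement statistics between observed and predicted weights.

The primary accuracy metric is the mean error

    delta = (actual - predicted end-weight) / actual end-weight x 100  [%]

positive when the model under-predicts end-weight, i.e. over-predicts
weight loss. Cohort summaries report mean and sample SD (n - 1 denominator)
of per-subject delta both in percent and in kg, at the end of each
subject's intervention or at a chosen week; subjects without a weigh-in at
the requested week are excluded (listwise per-week availability, no
imputation).

Bland-Altman agreement on total weight loss uses differences d = actual -
predicted loss: bias = mean(d), limits of agreement = bias +/- 2 SD(d) by
default (+/- 1.96 SD available via ``loa_factor``).

A cohort table is a pandas DataFrame with one row per subject-week and
columns ``subject_id, week, observed_weight, predicted_weight, w0,
intervention_length``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ModelConfig, SubjectBaseline
from .errors import InvalidInputError
from .simulate import SolverOptions, simulate

COHORT_COLUMNS = [
    "subject_id",
    "week",
    "observed_weight",
    "predicted_weight",
    "w0",
    "intervention_length",
]


def mean_error_delta(actual: float, predicted: float) -> float:
    """Mean error delta in percent for one actual/predicted weight pair."""
    if actual <= 0:
        raise InvalidInputError(f"actual weight must be positive, got {actual}")
    return (actual - predicted) / actual * 100.0


@dataclass(frozen=True)
class ErrorSummary:
    """Cohort-level delta summary at one timepoint."""

    n: int
    delta_pct_mean: float
    delta_pct_sd: float
    error_kg_mean: float
    error_kg_sd: float

    def is_empty(self) -> bool:
        return self.n == 0


def _summarise(actual: np.ndarray, predicted: np.ndarray) -> ErrorSummary:
    n = actual.size
    if n == 0:
        return ErrorSummary(0, np.nan, np.nan, np.nan, np.nan)
    delta = (actual - predicted) / actual * 100.0
    err_kg = actual - predicted
    sd_pct = float(np.std(delta, ddof=1)) if n > 1 else np.nan
    sd_kg = float(np.std(err_kg, ddof=1)) if n > 1 else np.nan
    return ErrorSummary(
        n=int(n),
        delta_pct_mean=float(np.mean(delta)),
        delta_pct_sd=sd_pct,
        error_kg_mean=float(np.mean(err_kg)),
        error_kg_sd=sd_kg,
    )


def cohort_error_summary(table: pd.DataFrame, at: int | str = "end") -> ErrorSummary:
    """Delta summary at ``at`` = ``"end"`` (each subject's final week) or week k.

    Subjects lacking the requested week are excluded; an empty selection
    yields an ``ErrorSummary`` with n = 0 and NaN statistics rather than an
    error.
    """
    if table.empty:
        return _summarise(np.array([]), np.array([]))
    if at == "end":
        sel = table[table["week"] == table["intervention_length"]]
    else:
        week = int(at)
        sel = table[table["week"] == week]
    return _summarise(
        sel["observed_weight"].to_numpy(float),
        sel["predicted_weight"].to_numpy(float),
    )


def weekly_error_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Per-week delta summary, one row per week with a declining n.

    Mirrors a weekly mean-error figure: subjects contribute to every week
    up to their own intervention length, so n shrinks with week.
    """
    rows = []
    for week in sorted(table["week"].unique()):
        s = cohort_error_summary(table, at=int(week))
        rows.append(
            {
                "week": int(week),
                "n": s.n,
                "delta_pct_mean": s.delta_pct_mean,
                "delta_pct_sd": s.delta_pct_sd,
                "error_kg_mean": s.error_kg_mean,
                "error_kg_sd": s.error_kg_sd,
            }
        )
    return pd.DataFrame(rows).set_index("week")


@dataclass(frozen=True)
class BlandAltman:
    """Bland-Altman agreement between actual and predicted weight loss."""

    bias: float
    sd: float
    loa_low: float
    loa_high: float
    means: np.ndarray  # per-pair (actual + predicted) / 2, for plotting
    diffs: np.ndarray  # per-pair actual - predicted


def bland_altman(
    actual_losses, predicted_losses, loa_factor: float = 2.0
) -> BlandAltman:
    """Bias and limits of agreement for paired weight losses (kg).

    ``loa_factor`` defaults to 2 (mean +/- 2 SD); pass 1.96 for the normal
    95% convention.
    """
    a = np.asarray(actual_losses, dtype=float)
    p = np.asarray(predicted_losses, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise InvalidInputError(
            f"paired loss lists must be equal-length 1-d, got {a.shape} vs {p.shape}"
        )
    if a.size == 0:
        raise InvalidInputError("paired loss lists must be nonempty")
    d = a - p
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa_low=bias - loa_factor * sd,
        loa_high=bias + loa_factor * sd,
        means=(a + p) / 2.0,
        diffs=d,
    )


def add_model_predictions(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    schedule=None,
    pal: float = 1.6,
    sex: str = "female",
    solver: SolverOptions | None = None,
) -> pd.DataFrame:
    """Fill the ``predicted_weight`` column by simulating each subject.

    Each subject is simulated from their recorded w0 over their
    intervention length under the given intake schedule; predictions are
    the simulated weekly weigh-in weights. Returns a new DataFrame.
    """
    from .intake import IntakeSchedule

    config = config or ModelConfig()
    schedule = schedule or IntakeSchedule.vled_default()
    out = table.copy()
    out["predicted_weight"] = np.nan
    for sid, grp in table.groupby("subject_id", sort=False):
        w0 = float(grp["w0"].iloc[0])
        weeks = int(grp["intervention_length"].iloc[0])
        subject = SubjectBaseline(w0=w0, sex=sex, pal=pal)
        traj = simulate(subject, schedule, weeks, config, solver)
        weekly = traj.weekly_weights()
        out.loc[grp.index, "predicted_weight"] = (
            grp["week"].map(weekly).to_numpy(float)
        )
    return out


def end_losses(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (actual, predicted) total weight loss at intervention end."""
    end = table[table["week"] == table["intervention_length"]]
    actual = end["w0"].to_numpy(float) - end["observed_weight"].to_numpy(float)
    predicted = end["w0"].to_numpy(float) - end["predicted_weight"].to_numpy(float)
    return actual, predicted


def bland_altman_figure(ba: BlandAltman, path) -> None:
    """Save a Bland-Altman scatter with bias and limits of agreement."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.diffs, s=12, alpha=0.6)
    ax.axhline(ba.bias, color="k", label=f"bias {ba.bias:.2f} kg")
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel("average of actual and predicted loss (kg)")
    ax.set_ylabel("actual - predicted loss (kg)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def weekly_error_figure(profile: pd.DataFrame, path) -> None:
    """Save the weekly mean-error profile (mean +/- SEM)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sem = profile["delta_pct_sd"] / np.sqrt(profile["n"].clip(lower=1))
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.errorbar(profile.index, profile["delta_pct_mean"], yerr=sem, fmt="o-")
    ax.axhline(0.0, color="k", linewidth=0.8)
    ax.set_xlabel("week")
    ax.set_ylabel("mean error delta (%)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
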