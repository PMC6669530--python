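"""Interaction Factor analysis for two-agent mixture experiments.

For a factorial design with control mean C, single-agent means G_A and G_B
and mixture mean G_AB, the Interaction Factor is the departure of the
mixture response from additivity of the single-agent effects:

    IF      = G_AB - G_A - G_B + C
    SEM_IF  = sqrt(SEM_AB^2 + SEM_A^2 + SEM_B^2 + SEM_C^2)

The predicted additive effect and its propagated error are

    A       = (G_A - C) + (G_B - C)
    SEM_add = sqrt(SEM_A^2 + SEM_B^2 + SEM_C^2)

(Pythagorean combination of standard errors).  A negative IF indicates
antagonism, zero additivity and a positive IF synergism.  Significance is
decided by non-overlap of two intervals built from the confidence limits
scaled by 1/sqrt(2): the mixture interval IF +/- CL_IF/sqrt(2) against the
additive interval 0 +/- CL_add/sqrt(2), where CL = z_{1-alpha/2} * SEM.
The sqrt(2) scaling makes interval overlap approximate a two-sample test at
level alpha rather than the overly conservative raw-interval comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .errors import ValidationError
from .synthetic import ExposureDesign

__all__ = [
    "GroupStats",
    "InteractionResult",
    "interaction_factor",
    "predicted_additive",
    "classify_interaction",
    "analyze_mixture",
    "interaction_table",
]


@dataclass(frozen=True)
class GroupStats:
    """Mean, SEM and n for one experimental group."""

    mean: float
    sem: float
    n: int | None = None

    def __post_init__(self):
        if not math.isfinite(self.mean) or not math.isfinite(self.sem):
            raise ValidationError("group mean and SEM must be finite")
        if self.sem < 0:
            raise ValidationError("SEM must be >= 0")


@dataclass(frozen=True)
class InteractionResult:
    """One mixture row: IF, propagated errors, intervals and the call."""

    if_value: float
    sem_if: float
    additive_effect: float
    sem_add: float
    halfwidth_if: float
    halfwidth_add: float
    classification: str  # antagonistic | additive | synergistic
    significant: bool
    alpha: float


def _require(name: str, cell) -> GroupStats:
    if cell is None:
        raise ValidationError(f"missing group summary: {name}")
    if isinstance(cell, GroupStats):
        return cell
    try:
        return GroupStats(float(cell[0]), float(cell[1]))
    except Exception as exc:  # pragma: no cover - defensive
        raise ValidationError(f"group '{name}': cannot interpret {cell!r}") from exc


def interaction_factor(control, g_a, g_b, g_ab) -> tuple[float, float]:
    """IF and its propagated SEM from four group summaries.

    Symmetric in the two agents; invariant to adding a constant to all four
    means.
    """
    c = _require("control", control)
    a = _require("A", g_a)
    b = _require("B", g_b)
    ab = _require("mixture", g_ab)
    if_value = ab.mean - a.mean - b.mean + c.mean
    sem_if = math.sqrt(ab.sem**2 + a.sem**2 + b.sem**2 + c.sem**2)
    return if_value, sem_if


def predicted_additive(control, g_a, g_b) -> tuple[float, float]:
    """Predicted additive mean effect A and its propagated SEM."""
    c = _require("control", control)
    a = _require("A", g_a)
    b = _require("B", g_b)
    add = (a.mean - c.mean) + (b.mean - c.mean)
    sem_add = math.sqrt(a.sem**2 + b.sem**2 + c.sem**2)
    return add, sem_add


def classify_interaction(
    if_value: float,
    sem_if: float,
    sem_add: float,
    alpha: float = 0.05,
    additive_effect: float = float("nan"),
) -> InteractionResult:
    """Classify a mixture as antagonistic / additive / synergistic.

    The mixture interval IF +/- z*SEM_IF/sqrt(2) is compared with the
    additive null interval 0 +/- z*SEM_add/sqrt(2); strict non-overlap
    (touching endpoints do not count) flags significance, and the label then
    follows the sign of IF.  z is the standard-normal 1-alpha/2 quantile.
    With all SEMs exactly zero the intervals degenerate to points and
    significance reduces to IF != 0.
    """
    if not 0 < alpha < 1:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if sem_if < 0 or sem_add < 0:
        raise ValidationError("SEMs must be >= 0")
    z = stats.norm.ppf(1 - alpha / 2)
    h_if = z * sem_if / math.sqrt(2)
    h_add = z * sem_add / math.sqrt(2)
    if h_if == 0 and h_add == 0:
        significant = if_value != 0
    else:
        total = h_if + h_add
        # touching endpoints do not count; guard against float round-off
        significant = abs(if_value) > total and not math.isclose(
            abs(if_value), total, rel_tol=1e-9, abs_tol=1e-12
        )
    if not significant:
        label = "additive"
    else:
        label = "antagonistic" if if_value < 0 else "synergistic"
    return InteractionResult(
        if_value=float(if_value),
        sem_if=float(sem_if),
        additive_effect=float(additive_effect),
        sem_add=float(sem_add),
        halfwidth_if=float(h_if),
        halfwidth_add=float(h_add),
        classification=label,
        significant=bool(significant),
        alpha=alpha,
    )


def analyze_mixture(control, g_a, g_b, g_ab, alpha: float = 0.05) -> InteractionResult:
    """Full IF analysis of one mixture from its four group summaries."""
    if_value, sem_if = interaction_factor(control, g_a, g_b, g_ab)
    add, sem_add = predicted_additive(control, g_a, g_b)
    return classify_interaction(if_value, sem_if, sem_add, alpha, additive_effect=add)


def interaction_table(
    summaries: pd.DataFrame,
    design: ExposureDesign,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One IF row per mixture group of the design.

    ``summaries`` is the per-group frame from
    :func:`mixtox.endpoint_stats.summarize_groups` (columns group, mean,
    sem, n).  The output mirrors the conventional report shape: treatment,
    IF, the half confidence interval (CL/sqrt(2)), significance flag and
    classification label.
    """
    by_group = {row["group"]: GroupStats(row["mean"], row["sem"], int(row["n"]))
                for _, row in summaries.iterrows()}
    missing = []
    needed = {design.control_label}
    for mix, a_lab, b_lab in design.mixtures:
        needed |= {mix, a_lab, b_lab}
    missing = sorted(needed - set(by_group))
    if missing:
        raise ValidationError(f"missing group summaries: {missing}")

    rows = []
    control = by_group[design.control_label]
    for mix, a_lab, b_lab in design.mixtures:
        res = analyze_mixture(control, by_group[a_lab], by_group[b_lab], by_group[mix], alpha)
        rows.append(
            {
                "treatment": mix,
                "IF": res.if_value,
                "halfwidth": res.halfwidth_if,
                "sem_if": res.sem_if,
                "additive_effect": res.additive_effect,
                "sem_add": res.sem_add,
                "halfwidth_add": res.halfwidth_add,
                "significant": res.significant,
                "label": res.classification,
            }
        )
    return pd.DataFrame(rows)
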