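"""Recommended contextual-effect estimators.

The contextual effect is the between-group contrast of a placebo arm
against an untreated (no-treatment) control: both arms experience the
same non-specific improvement (natural course, regression to the mean,
measurement error), so the contrast cancels it and what remains is the
improvement attributable to the treatment context.  The three-arm
decomposition extends this bookkeeping to the full additive model

    total = specific + contextual + non_specific

where total is the active arm's improvement, specific the
active-vs-placebo contrast, contextual the placebo-vs-no-treatment
contrast, and non_specific the no-treatment arm's improvement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from .effects import (
    DEFAULT_CI_LEVEL,
    DEFAULT_PRE_POST_CORR,
    ArmSummary,
    EffectEstimate,
    InputError,
    mean_change,
    mean_difference_between,
    smd_between,
)


class RoleMismatchError(InputError):
    """An arm was passed in a role it does not hold."""


def _require_role(arm: ArmSummary, *allowed: str) -> None:
    if arm.role not in allowed:
        raise RoleMismatchError(
            f"expected an arm with role in {allowed}, got {arm.role!r} "
            f"(study {arm.study_id!r})"
        )


def _require_same_study(*arms: ArmSummary) -> None:
    ids = {a.study_id for a in arms}
    if len(ids) > 1:
        raise InputError(f"arms belong to different studies: {sorted(ids)}")


@dataclass(frozen=True)
class Decomposition:
    """Additive decomposition of a three-arm study.

    Point estimates satisfy
    ``specific + contextual + non_specific = total`` (up to floating
    round-off); each component carries its own SE assuming independent
    arms.
    """

    study_id: str
    total: EffectEstimate
    specific: EffectEstimate
    contextual: EffectEstimate
    non_specific: EffectEstimate

    def contextual_proportion(self) -> float:
        """Descriptive ratio contextual/total; defined only when total > 0.

        This is *not* the proportional contextual effect ratio — it is a
        plain share of the additive total, offered as an exploratory
        summary.
        """
        if not self.total.estimate > 0:
            raise InputError(
                "contextual proportion undefined: total improvement is not positive"
            )
        return self.contextual.estimate / self.total.estimate

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "total": self.total.to_dict(),
            "specific": self.specific.to_dict(),
            "contextual": self.contextual.to_dict(),
            "non_specific": self.non_specific.to_dict(),
        }

    def to_tidy(self) -> pd.DataFrame:
        rows = []
        for name in ("total", "specific", "contextual", "non_specific"):
            est: EffectEstimate = getattr(self, name)
            rows.append(
                {
                    "study_id": self.study_id,
                    "component": name,
                    "estimate": est.estimate,
                    "se": est.se,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
        return pd.DataFrame(rows)


def contextual_effect(
    placebo: ArmSummary,
    no_treatment: ArmSummary,
    measure: str = "MD",
    on: str = "change",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Contextual effect as the placebo vs no-treatment contrast.

    Non-specific improvement occurs in both arms and cancels in the
    difference; a positive value means contextual benefit.  ``measure``
    selects a raw mean difference (``MD``) or a standardized one
    (``SMD``); ``on`` contrasts change scores (default) or follow-up
    levels.
    """
    _require_role(placebo, "placebo", "placebo_control")
    _require_role(no_treatment, "no_treatment")
    _require_same_study(placebo, no_treatment)
    if measure == "MD":
        return mean_difference_between(placebo, no_treatment, on, ci_level, default_corr)
    if measure == "SMD":
        return smd_between(
            placebo, no_treatment, on, False, ci_level, default_corr
        )
    raise InputError(f"measure must be 'MD' or 'SMD', got {measure!r}")


def contextual_effect_open_label(
    placebo_active: ArmSummary,
    placebo_control: ArmSummary,
    measure: str = "MD",
    on: str = "change",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Contrast of a blinded placebo arm against an open-label placebo arm.

    The "placebo control" arm is told it receives an inert treatment, so
    this design estimates the contextual increment attributable to the
    belief of being actively treated.  Non-specific effects cancel, but
    whatever contextual effect the open-label arm still experiences is
    also cancelled — the full contextual effect is not isolated and the
    estimate is a lower bound under the additive model.
    """
    _require_role(placebo_active, "placebo")
    _require_role(placebo_control, "placebo_control")
    _require_same_study(placebo_active, placebo_control)
    if measure == "MD":
        return mean_difference_between(
            placebo_active, placebo_control, on, ci_level, default_corr
        )
    if measure == "SMD":
        return smd_between(
            placebo_active, placebo_control, on, False, ci_level, default_corr
        )
    raise InputError(f"measure must be 'MD' or 'SMD', got {measure!r}")


def decompose_three_arm(
    active: ArmSummary,
    placebo: ArmSummary,
    no_treatment: ArmSummary,
    on: str = "change",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> Decomposition:
    """Full additive decomposition of a three-arm study.

    total = active-arm improvement; specific = active - placebo;
    contextual = placebo - no_treatment; non_specific = no-treatment
    improvement.  SEs assume independent randomized arms.
    """
    _require_role(active, "active")
    _require_role(placebo, "placebo", "placebo_control")
    _require_role(no_treatment, "no_treatment")
    _require_same_study(active, placebo, no_treatment)
    total = mean_change(active, ci_level, default_corr)
    non_specific = mean_change(no_treatment, ci_level, default_corr)
    contextual = mean_difference_between(placebo, no_treatment, on, ci_level, default_corr)
    specific = mean_difference_between(active, placebo, on, ci_level, default_corr)
    return Decomposition(
        study_id=active.study_id,
        total=total,
        specific=specific,
        contextual=contextual,
        non_specific=non_specific,
    )


def contextual_proportion_bootstrap(
    subjects: pd.DataFrame,
    n_boot: int = 1000,
    ci_level: float = DEFAULT_CI_LEVEL,
    seed: Optional[int] = None,
) -> Tuple[float, float, float]:
    """Bootstrap CI for the contextual/total share from subject-level data.

    ``subjects`` must have columns ``arm`` (roles active, placebo,
    no_treatment) and ``improvement``.  Subjects are resampled with
    replacement within arms; each replicate recomputes
    (placebo - no_treatment) / active mean improvements.  Returns
    (point, ci_low, ci_high) by the percentile method.  Replicates with
    non-positive total are dropped (the share is undefined there).
    """
    rng = np.random.default_rng(seed)
    groups = {
        role: subjects.loc[subjects["arm"] == role, "improvement"].to_numpy()
        for role in ("active", "placebo", "no_treatment")
    }
    for role, vals in groups.items():
        if len(vals) == 0:
            raise InputError(f"no subjects in {role!r} arm")
    total = groups["active"].mean()
    if not total > 0:
        raise InputError("contextual proportion undefined: total is not positive")
    point = (groups["placebo"].mean() - groups["no_treatment"].mean()) / total
    reps = []
    for _ in range(n_boot):
        means = {
            role: rng.choice(vals, size=len(vals), replace=True).mean()
            for role, vals in groups.items()
        }
        if means["active"] > 0:
            reps.append((means["placebo"] - means["no_treatment"]) / means["active"])
    if not reps:
        raise InputError("all bootstrap replicates had non-positive total")
    alpha = 1.0 - ci_level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(point), float(lo), float(hi)
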