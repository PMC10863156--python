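"""Effect-size algebra on trial arm summaries.

Everything downstream (contextual-effect contrasts, the proportional
contextual effect ratio, meta-analysis inputs) is built from within-arm
improvements and between-arm contrasts computed here.  An *improvement*
is always oriented so that a positive number means the arm got better,
regardless of whether the outcome scale runs "lower is better" (pain)
or "higher is better" (function).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

ROLES = ("active", "placebo", "placebo_control", "no_treatment")
DIRECTIONS = ("lower_is_better", "higher_is_better")

#: Pre/post correlation imputed when neither a change SD nor a
#: correlation is supplied.  The conventional value for patient-reported
#: outcomes; it affects standard errors only, never point estimates.
DEFAULT_PRE_POST_CORR = 0.5

#: Default two-sided confidence level.
DEFAULT_CI_LEVEL = 0.95


class InputError(ValueError):
    """Invalid or inconsistent user input."""


class DegenerateInputError(InputError):
    """A quantity required as a divisor or SD is zero."""


def _zcrit(ci_level: float) -> float:
    if not 0.0 < ci_level < 1.0:
        raise InputError(f"ci_level must be in (0, 1), got {ci_level}")
    return float(stats.norm.ppf(0.5 + ci_level / 2.0))


@dataclass(frozen=True)
class ArmSummary:
    """Aggregate statistics for one arm of a randomized trial.

    Parameters
    ----------
    study_id : str
        Label of the study the arm belongs to.
    role : str
        One of ``active``, ``placebo``, ``placebo_control`` (an
        open-label placebo group told it receives an inert treatment),
        or ``no_treatment`` (untreated / natural-history control).
    n : int
        Number of analyzed participants (>= 2).
    mean_baseline, sd_baseline : float
        Baseline outcome mean and SD (SD > 0).
    mean_followup, sd_followup : float
        Follow-up outcome mean and SD (SD > 0).
    sd_change : float, optional
        SD of the within-subject change score, if reported.
    corr_pre_post : float, optional
        Pre/post correlation in (-1, 1), used to derive ``sd_change``
        when it is not reported.
    direction : str
        ``lower_is_better`` (default; pain-scale convention) or
        ``higher_is_better``.
    """

    study_id: str
    role: str
    n: int
    mean_baseline: float
    sd_baseline: float
    mean_followup: float
    sd_followup: float
    sd_change: Optional[float] = None
    corr_pre_post: Optional[float] = None
    direction: str = "lower_is_better"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InputError(f"unknown arm role {self.role!r}; expected one of {ROLES}")
        if self.direction not in DIRECTIONS:
            raise InputError(f"unknown direction {self.direction!r}")
        if int(self.n) != self.n or self.n < 2:
            raise InputError(f"n must be an integer >= 2, got {self.n}")
        for name in ("sd_baseline", "sd_followup"):
            if not getattr(self, name) > 0:
                raise InputError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.sd_change is not None and not self.sd_change > 0:
            raise InputError(f"sd_change must be > 0, got {self.sd_change}")
        if self.corr_pre_post is not None and not -1.0 < self.corr_pre_post < 1.0:
            raise InputError(
                f"corr_pre_post must be in (-1, 1), got {self.corr_pre_post}"
            )

    def improvement(self) -> float:
        """Signed mean change, positive = improvement."""
        if self.direction == "lower_is_better":
            return self.mean_baseline - self.mean_followup
        return self.mean_followup - self.mean_baseline

    def change_sd(self, default_corr: float = DEFAULT_PRE_POST_CORR) -> float:
        """SD of the change score, derived from pre/post SDs if absent.

        Uses sd_change directly when reported; otherwise
        sqrt(sd_b^2 + sd_f^2 - 2 r sd_b sd_f) with the arm's
        ``corr_pre_post`` or, failing that, ``default_corr``.
        """
        if self.sd_change is not None:
            return self.sd_change
        r = self.corr_pre_post if self.corr_pre_post is not None else default_corr
        var = (
            self.sd_baseline**2
            + self.sd_followup**2
            - 2.0 * r * self.sd_baseline * self.sd_followup
        )
        if var <= 0:
            raise DegenerateInputError(
                f"derived change variance is non-positive ({var}); "
                "check SDs and pre/post correlation"
            )
        return math.sqrt(var)


@dataclass(frozen=True)
class EffectEstimate:
    """A point estimate with SE, normal-theory CI, and scale metadata.

    ``scale`` is one of ``raw_difference``, ``standardized``,
    ``log_ratio``; ``measure`` is a free label such as ``mean_change``,
    ``SMD``, ``MD``, ``lnRR``.
    """

    estimate: float
    se: float
    ci_low: float
    ci_high: float
    scale: str
    measure: str
    ci_level: float = DEFAULT_CI_LEVEL

    def __post_init__(self) -> None:
        if self.se < 0:
            raise InputError(f"se must be >= 0, got {self.se}")
        if not self.ci_low <= self.estimate <= self.ci_high:
            raise InputError("confidence interval must bracket the estimate")

    @classmethod
    def from_normal(
        cls,
        estimate: float,
        se: float,
        scale: str,
        measure: str,
        ci_level: float = DEFAULT_CI_LEVEL,
    ) -> "EffectEstimate":
        z = _zcrit(ci_level)
        return cls(
            estimate=float(estimate),
            se=float(se),
            ci_low=float(estimate - z * se),
            ci_high=float(estimate + z * se),
            scale=scale,
            measure=measure,
            ci_level=ci_level,
        )

    def __neg__(self) -> "EffectEstimate":
        return replace(
            self, estimate=-self.estimate, ci_low=-self.ci_high, ci_high=-self.ci_low
        )

    def to_dict(self) -> dict:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "scale": self.scale,
            "measure": self.measure,
            "ci_level": self.ci_level,
        }


@dataclass(frozen=True)
class ResponderResult:
    """Responder count at a threshold with a Wilson score interval."""

    threshold: float
    n_responders: int
    n_total: int
    proportion: float
    ci_low: float
    ci_high: float


def mean_change(
    arm: ArmSummary,
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Raw within-arm mean change, oriented so improvement is positive.

    SE = sd_change / sqrt(n), with sd_change derived from the pre/post
    SDs and correlation when not reported.
    """
    delta = arm.improvement()
    se = arm.change_sd(default_corr) / math.sqrt(arm.n)
    return EffectEstimate.from_normal(delta, se, "raw_difference", "mean_change", ci_level)


def standardized_mean_change(
    arm: ArmSummary,
    sd_basis: str = "baseline",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Within-arm mean change in SD units (standardized mean change d).

    ``sd_basis`` chooses the standardizer: the baseline SD (default),
    the follow-up SD, or the change-score SD.  The large-sample
    variance is ``2(1-r)/n + d^2/(2n)`` for baseline/follow-up
    standardization and ``1/n + d^2/(2n)`` when standardizing by the
    change SD itself.
    """
    if sd_basis == "baseline":
        sd = arm.sd_baseline
    elif sd_basis == "followup":
        sd = arm.sd_followup
    elif sd_basis == "change":
        sd = arm.change_sd(default_corr)
    else:
        raise InputError(f"sd_basis must be baseline/change/followup, got {sd_basis!r}")
    if sd <= 0:
        raise DegenerateInputError("standardizing SD must be > 0")
    d = arm.improvement() / sd
    n = arm.n
    if sd_basis == "change":
        var = 1.0 / n + d * d / (2.0 * n)
    else:
        r = arm.corr_pre_post if arm.corr_pre_post is not None else default_corr
        var = 2.0 * (1.0 - r) / n + d * d / (2.0 * n)
    return EffectEstimate.from_normal(d, math.sqrt(var), "standardized", "SMC", ci_level)


def _check_compatible(arm_a: ArmSummary, arm_b: ArmSummary) -> None:
    if arm_a.direction != arm_b.direction:
        raise InputError(
            "arms use different direction conventions "
            f"({arm_a.direction!r} vs {arm_b.direction!r})"
        )


def _oriented_followup(arm: ArmSummary) -> float:
    # Follow-up level on the improvement orientation: higher = better.
    if arm.direction == "lower_is_better":
        return -arm.mean_followup
    return arm.mean_followup


def mean_difference_between(
    arm_a: ArmSummary,
    arm_b: ArmSummary,
    on: str = "change",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Mean difference between two independent arms, positive favoring arm_a.

    ``on="change"`` contrasts within-arm improvements (change scores);
    ``on="followup"`` contrasts follow-up levels, oriented so a
    positive value means arm_a ended up better off.
    """
    _check_compatible(arm_a, arm_b)
    if on == "change":
        est = arm_a.improvement() - arm_b.improvement()
        var = (
            arm_a.change_sd(default_corr) ** 2 / arm_a.n
            + arm_b.change_sd(default_corr) ** 2 / arm_b.n
        )
    elif on == "followup":
        est = _oriented_followup(arm_a) - _oriented_followup(arm_b)
        var = arm_a.sd_followup**2 / arm_a.n + arm_b.sd_followup**2 / arm_b.n
    else:
        raise InputError(f"on must be 'change' or 'followup', got {on!r}")
    return EffectEstimate.from_normal(est, math.sqrt(var), "raw_difference", "MD", ci_level)


def hedges_correction(df: int) -> float:
    """Small-sample correction factor J = 1 - 3/(4 df - 1)."""
    if df < 2:
        raise InputError(f"df must be >= 2, got {df}")
    return 1.0 - 3.0 / (4.0 * df - 1.0)


def smd_between(
    arm_a: ArmSummary,
    arm_b: ArmSummary,
    on: str = "change",
    small_sample_correction: bool = False,
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> EffectEstimate:
    """Between-arm standardized mean difference (Cohen's d / Hedges' g).

    The difference in improvements (or follow-up levels) is divided by
    the pooled SD of the chosen scores.  With
    ``small_sample_correction`` the estimate is multiplied by
    J = 1 - 3/(4 df - 1), df = n_a + n_b - 2.  Variance uses the
    standard large-sample formula
    (n_a + n_b)/(n_a n_b) + d^2 / (2 (n_a + n_b)).
    """
    _check_compatible(arm_a, arm_b)
    if on == "change":
        diff = arm_a.improvement() - arm_b.improvement()
        sd_a, sd_b = arm_a.change_sd(default_corr), arm_b.change_sd(default_corr)
    elif on == "followup":
        diff = _oriented_followup(arm_a) - _oriented_followup(arm_b)
        sd_a, sd_b = arm_a.sd_followup, arm_b.sd_followup
    else:
        raise InputError(f"on must be 'change' or 'followup', got {on!r}")
    na, nb = arm_a.n, arm_b.n
    pooled_var = ((na - 1) * sd_a**2 + (nb - 1) * sd_b**2) / (na + nb - 2)
    if pooled_var <= 0:
        raise DegenerateInputError("pooled SD is zero; SMD undefined")
    d = diff / math.sqrt(pooled_var)
    if small_sample_correction:
        d *= hedges_correction(na + nb - 2)
    var = (na + nb) / (na * nb) + d * d / (2.0 * (na + nb))
    return EffectEstimate.from_normal(d, math.sqrt(var), "standardized", "SMD", ci_level)


def reexpress_smd(smd: float, assumed_sd: float) -> float:
    """Re-express a standardized mean difference on the outcome scale.

    Multiplies the SMD by an assumed population SD of the target scale,
    e.g. an SMD of -0.28 with SD 20 on a 0-100 pain scale corresponds
    to about a 5.6-point change.
    """
    if not assumed_sd > 0:
        raise InputError(f"assumed_sd must be > 0, got {assumed_sd}")
    return smd * assumed_sd


def responder_proportion(
    improvements: Sequence[float],
    threshold: float,
    ci_level: float = DEFAULT_CI_LEVEL,
) -> ResponderResult:
    """Dichotomize per-subject improvements at a response threshold.

    A subject whose improvement is >= threshold counts as a responder
    (ties count as response).  The CI is a Wilson score interval.  This
    analysis is provided so its behavior can be studied; within a
    placebo arm the proportion absorbs non-specific improvement and
    does not isolate a contextual effect.
    """
    if len(improvements) == 0:
        raise InputError("improvements must be non-empty")
    if not math.isfinite(threshold):
        raise InputError("threshold must be finite")
    n_total = len(improvements)
    n_resp = sum(1 for x in improvements if x >= threshold)
    lo, hi = proportion_confint(n_resp, n_total, alpha=1 - ci_level, method="wilson")
    return ResponderResult(
        threshold=float(threshold),
        n_responders=int(n_resp),
        n_total=int(n_total),
        proportion=n_resp / n_total,
        ci_low=float(lo),
        ci_high=float(hi),
    )
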