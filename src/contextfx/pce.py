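"""The proportional contextual effect (PCE) pipeline, reproduced as-is.

PCE divides the placebo arm's standardized mean change by the active
arm's (d_placebo / d_active), log-transforms for pooling, attaches a
response-ratio standard error, drops studies where either arm worsened
(the log of a non-positive change is undefined), pools on the log
scale, and exponentiates the summary.

The statistic is reproduced faithfully so its behavior can be audited
against simulated ground truth: because ln(PCE) = ln(d_placebo) -
ln(d_active) is a placebo-vs-active *treatment* contrast on a
multiplicative scale, PCE absorbs non-specific effects and does not
estimate the contextual share of the total treatment effect.  This
module intentionally makes no attempt to repair it (values above 1 are
reported raw and flagged, never truncated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .effects import (
    DEFAULT_CI_LEVEL,
    DEFAULT_PRE_POST_CORR,
    ArmSummary,
    InputError,
    _zcrit,
    standardized_mean_change,
)
from .meta import MetaInput, MetaResult, NoDataError, back_transform_exp, pool_fixed, pool_random


@dataclass(frozen=True)
class PCEStudyResult:
    """Per-study PCE with its log transform and exclusion status.

    When ``excluded`` is set (either arm's mean change <= 0), the
    ratio-scale fields are NaN and ``exclusion_reason`` says why.
    """

    study_id: str
    d_placebo: float
    d_active: float
    pce: float
    log_pce: float
    se_log: float
    ci_low: float
    ci_high: float
    excluded: bool
    exclusion_reason: Optional[str] = None

    @property
    def exceeds_one(self) -> bool:
        """True when the ratio exceeds 1, i.e. the 'proportion' reading
        would exceed 100%."""
        return not self.excluded and self.pce > 1.0

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "d_placebo": self.d_placebo,
            "d_active": self.d_active,
            "pce": self.pce,
            "log_pce": self.log_pce,
            "se_log": self.se_log,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
        }


def pce_log_se(
    placebo: ArmSummary,
    active: ArmSummary,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> float:
    """SE of ln(PCE) via the log response-ratio (ratio-of-means) variance.

    Applied to the two arms' raw mean changes Delta with change SDs s:

        SE^2 = s_p^2 / (n_p Delta_p^2) + s_a^2 / (n_a Delta_a^2)

    The standardizing SDs cancel in the ratio when both arms are
    standardized on the same basis, so the SE is computed from raw
    changes.  Requires strictly positive mean changes in both arms.
    """
    dp, da = placebo.improvement(), active.improvement()
    if dp <= 0 or da <= 0:
        raise InputError(
            "log response-ratio SE undefined: both mean changes must be > 0 "
            f"(placebo {dp}, active {da})"
        )
    sp = placebo.change_sd(default_corr)
    sa = active.change_sd(default_corr)
    var = sp**2 / (placebo.n * dp**2) + sa**2 / (active.n * da**2)
    return math.sqrt(var)


def compute_pce(
    placebo: ArmSummary,
    active: ArmSummary,
    sd_basis: str = "baseline",
    ci_level: float = DEFAULT_CI_LEVEL,
    default_corr: float = DEFAULT_PRE_POST_CORR,
) -> PCEStudyResult:
    """PCE for one study: d_placebo / d_active with log-scale CI.

    Standardized mean changes come from
    :func:`contextfx.effects.standardized_mean_change` with the chosen
    ``sd_basis``.  A study in which either arm worsened (or did not
    change) is returned with ``excluded=True`` rather than raising,
    mirroring the pipeline's exclusion rule.
    """
    if placebo.study_id != active.study_id:
        raise InputError(
            f"arms belong to different studies ({placebo.study_id!r} vs "
            f"{active.study_id!r})"
        )
    d_p = standardized_mean_change(placebo, sd_basis, ci_level, default_corr).estimate
    d_a = standardized_mean_change(active, sd_basis, ci_level, default_corr).estimate
    nan = float("nan")
    if d_p <= 0 or d_a <= 0:
        which = []
        if d_p <= 0:
            which.append("placebo")
        if d_a <= 0:
            which.append("active")
        return PCEStudyResult(
            study_id=placebo.study_id,
            d_placebo=d_p,
            d_active=d_a,
            pce=nan,
            log_pce=nan,
            se_log=nan,
            ci_low=nan,
            ci_high=nan,
            excluded=True,
            exclusion_reason=f"worsening or zero change in {' and '.join(which)} arm",
        )
    log_pce = math.log(d_p) - math.log(d_a)
    se = pce_log_se(placebo, active, default_corr)
    z = _zcrit(ci_level)
    return PCEStudyResult(
        study_id=placebo.study_id,
        d_placebo=d_p,
        d_active=d_a,
        pce=math.exp(log_pce),
        log_pce=log_pce,
        se_log=se,
        ci_low=math.exp(log_pce - z * se),
        ci_high=math.exp(log_pce + z * se),
        excluded=False,
    )


def pce_exclusion_filter(
    studies: Sequence[PCEStudyResult],
) -> Tuple[List[PCEStudyResult], List[PCEStudyResult]]:
    """Partition studies into (retained, excluded), preserving order."""
    retained = [s for s in studies if not s.excluded]
    excluded = [s for s in studies if s.excluded]
    return retained, excluded


def pce_meta(
    studies: Sequence[PCEStudyResult],
    method: str = "random",
    ci_level: float = DEFAULT_CI_LEVEL,
) -> MetaResult:
    """Pool log PCE across retained studies and exponentiate the summary.

    Excluded studies are dropped first (the pipeline's exclusion rule).
    ``method`` is ``"random"`` (DerSimonian-Laird, default) or
    ``"fixed"``.  The returned result carries the pooled log value and
    its exponentiated point/CI in ``back_transformed``.
    """
    retained, _ = pce_exclusion_filter(studies)
    if not retained:
        raise NoDataError("no retained studies: every study was excluded")
    inputs = [
        MetaInput(study_id=s.study_id, y=s.log_pce, v=s.se_log**2) for s in retained
    ]
    if method == "random":
        pooled = pool_random(inputs, ci_level=ci_level)
    elif method == "fixed":
        pooled = pool_fixed(inputs, ci_level=ci_level)
    else:
        raise InputError(f"method must be 'random' or 'fixed', got {method!r}")
    return back_transform_exp(pooled)


def pce_table(studies: Sequence[PCEStudyResult]) -> pd.DataFrame:
    """Flat per-study results table (one row per study)."""
    return pd.DataFrame([s.to_dict() for s in studies])
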