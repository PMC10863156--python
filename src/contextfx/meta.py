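"""Inverse-variance meta-analysis with DerSimonian-Laird heterogeneity.

Fixed-effect and random-effects pooling of generic (effect, variance)
pairs, used both for pooling log proportional-contextual-effect values
and for pooling contextual-effect contrasts across studies.  Kept
deliberately small: one tau^2 estimator (DerSimonian-Laird moments),
normal-theory Wald intervals.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .effects import DEFAULT_CI_LEVEL, InputError, _zcrit

logger = logging.getLogger(__name__)


class NoDataError(InputError):
    """Pooling was requested on an empty set of studies."""


@dataclass(frozen=True)
class MetaInput:
    """One study's contribution: effect ``y`` on the analysis scale and
    its sampling variance ``v``."""

    study_id: str
    y: float
    v: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.y):
            raise InputError(f"effect y must be finite, got {self.y}")
        if not self.v > 0:
            raise InputError(f"variance v must be > 0, got {self.v}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled estimate with heterogeneity statistics.

    ``tau2`` is the between-study variance estimate, ``Q`` Cochran's
    heterogeneity statistic, ``I2`` the percentage of variation
    attributable to heterogeneity.  ``back_transformed`` holds
    (point, ci_low, ci_high) on the exponentiated (ratio) scale when
    pooling was done on a log scale.
    """

    k: int
    pooled: float
    se: float
    ci_low: float
    ci_high: float
    tau2: float
    Q: float
    I2: float
    method: str
    ci_level: float = DEFAULT_CI_LEVEL
    back_transformed: Optional[Tuple[float, float, float]] = None

    def to_dict(self) -> dict:
        d = {
            "k": self.k,
            "pooled": self.pooled,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "tau2": self.tau2,
            "Q": self.Q,
            "I2": self.I2,
            "method": self.method,
            "ci_level": self.ci_level,
        }
        if self.back_transformed is not None:
            point, lo, hi = self.back_transformed
            d["back_transformed"] = {"point": point, "ci_low": lo, "ci_high": hi}
        return d


def _as_arrays(inputs: Sequence[MetaInput]) -> Tuple[np.ndarray, np.ndarray]:
    if len(inputs) == 0:
        raise NoDataError("no studies to pool")
    y = np.array([s.y for s in inputs], dtype=float)
    v = np.array([s.v for s in inputs], dtype=float)
    return y, v


def pool_fixed(
    inputs: Sequence[MetaInput], ci_level: float = DEFAULT_CI_LEVEL
) -> MetaResult:
    """Fixed-effect inverse-variance pooling.

    pooled = sum(y/v) / sum(1/v); se = 1/sqrt(sum(1/v)); Q is computed
    against the fixed pooled value.
    """
    y, v = _as_arrays(inputs)
    w = 1.0 / v
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    Q = float(np.sum(w * (y - pooled) ** 2))
    k = len(inputs)
    I2 = _i_squared(Q, k)
    z = _zcrit(ci_level)
    return MetaResult(
        k=k,
        pooled=pooled,
        se=se,
        ci_low=pooled - z * se,
        ci_high=pooled + z * se,
        tau2=0.0,
        Q=Q,
        I2=I2,
        method="fixed",
        ci_level=ci_level,
    )


def _i_squared(Q: float, k: int) -> float:
    if k <= 1 or Q <= 0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / Q) * 100.0


def tau2_dersimonian_laird(inputs: Sequence[MetaInput]) -> float:
    """DerSimonian-Laird moment estimator of tau^2, truncated at zero."""
    y, v = _as_arrays(inputs)
    k = len(inputs)
    if k < 2:
        return 0.0
    w = 1.0 / v
    pooled = np.sum(w * y) / np.sum(w)
    Q = float(np.sum(w * (y - pooled) ** 2))
    C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    if C <= 0:
        return 0.0
    return max(0.0, (Q - (k - 1)) / C)


def pool_random(
    inputs: Sequence[MetaInput],
    tau2_method: str = "DL",
    ci_level: float = DEFAULT_CI_LEVEL,
) -> MetaResult:
    """Random-effects pooling with DerSimonian-Laird tau^2.

    Weights are 1/(v + tau^2).  With a single study no heterogeneity is
    estimable; the fixed-effect result for that study is returned with
    a logged warning.
    """
    if tau2_method != "DL":
        raise InputError(f"unsupported tau2_method {tau2_method!r}; only 'DL'")
    y, v = _as_arrays(inputs)
    k = len(inputs)
    if k == 1:
        logger.warning(
            "random-effects pooling with k=1 study (%s): tau^2 not estimable, "
            "returning the single-study result",
            inputs[0].study_id,
        )
        fixed = pool_fixed(inputs, ci_level)
        return replace(fixed, method="random_DL")
    tau2 = tau2_dersimonian_laird(inputs)
    # Q and I2 are reported from the fixed-effect weights, as is standard.
    w_fixed = 1.0 / v
    pooled_fixed = np.sum(w_fixed * y) / np.sum(w_fixed)
    Q = float(np.sum(w_fixed * (y - pooled_fixed) ** 2))
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = _zcrit(ci_level)
    return MetaResult(
        k=k,
        pooled=pooled,
        se=se,
        ci_low=pooled - z * se,
        ci_high=pooled + z * se,
        tau2=tau2,
        Q=Q,
        I2=_i_squared(Q, k),
        method="random_DL",
        ci_level=ci_level,
    )


def back_transform_exp(result: MetaResult) -> MetaResult:
    """Exponentiate a log-scale pooled result onto the ratio scale.

    Returns a copy with ``back_transformed = (exp(pooled),
    exp(ci_low), exp(ci_high))``; log-scale fields are untouched.
    """
    return replace(
        result,
        back_transformed=(
            math.exp(result.pooled),
            math.exp(result.ci_low),
            math.exp(result.ci_high),
        ),
    )


def forest_table(inputs: Iterable[MetaInput]) -> pd.DataFrame:
    """Tidy per-study table with fixed- and random-effects weights
    (normalized to sum to 1), ready for forest plotting."""
    inputs = list(inputs)
    y, v = _as_arrays(inputs)
    tau2 = tau2_dersimonian_laird(inputs) if len(inputs) >= 2 else 0.0
    w_f = (1.0 / v) / np.sum(1.0 / v)
    w_r = (1.0 / (v + tau2)) / np.sum(1.0 / (v + tau2))
    return pd.DataFrame(
        {
            "study_id": [s.study_id for s in inputs],
            "y": y,
            "v": v,
            "weight_fixed": w_f,
            "weight_random": w_r,
        }
    )
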