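"""Predictive models embedded in the burn-care outcome thresholds.

Two predictions feed the indicator set:

* the **revised Baux score** — ``age + %TBSA + increment * inhalation`` — mapped
  to a probability of in-hospital death through a logistic model, and
* a **predicted length of stay** (LOS) from a linear predictor on age, %TBSA
  and inhalation injury.

Neither model is re-estimated here: both are configuration.  The shipped
mortality defaults reproduce the commonly reported LD50 revised-Baux score of
about 109.6 (the score at which predicted mortality is 50%); the shipped LOS
defaults encode the classic "about one hospital day per %TBSA" rule plus age
and inhalation terms.  Every report records the coefficients actually used, so
centers can substitute locally fitted values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Union

import numpy as np
from scipy.special import expit

__all__ = [
    "RiskModelConfig",
    "DEFAULT_RISK_MODEL",
    "revised_baux_score",
    "predicted_mortality_risk",
    "predicted_los",
]

ArrayLike = Union[float, int, np.ndarray]


class RiskConfigurationError(ValueError):
    """Raised when required model coefficients are absent or invalid."""


@dataclass(frozen=True)
class RiskModelConfig:
    """Coefficients for the mortality and LOS predictions.

    Parameters
    ----------
    baux_inhalation_increment
        Points added to the revised Baux score for clinically diagnosed
        inhalation injury (default 17).
    mortality_logit_intercept, mortality_logit_slope
        Logistic-regression coefficients mapping the revised Baux score to a
        probability of death: ``p = expit(intercept + slope * score)``.
    los_intercept, los_age, los_tbsa, los_inhalation
        Linear predictor for expected hospital days:
        ``intercept + age*los_age + tbsa*los_tbsa + inhalation*los_inhalation``,
        clamped at zero.
    mortality_risk_cutoff
        Predicted-mortality probability below which a death counts as
        unexpected (default 0.25, i.e. "predicted risk of mortality <= 25%").
    """

    baux_inhalation_increment: float = 17.0
    mortality_logit_intercept: float = -8.33
    mortality_logit_slope: float = 0.076
    los_intercept: float = 0.3
    los_age: float = 0.045
    los_tbsa: float = 1.15
    los_inhalation: float = 4.0
    mortality_risk_cutoff: float = 0.25

    def __post_init__(self) -> None:
        if not (0.0 < self.mortality_risk_cutoff < 1.0):
            raise RiskConfigurationError(
                f"mortality_risk_cutoff must lie in (0,1), got {self.mortality_risk_cutoff}"
            )
        for name in ("mortality_logit_intercept", "mortality_logit_slope"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v):
                raise RiskConfigurationError(f"missing or non-finite coefficient: {name}")

    def to_dict(self) -> dict:
        return asdict(self)


DEFAULT_RISK_MODEL = RiskModelConfig()


def _validate_age_tbsa(age: ArrayLike, tbsa: ArrayLike) -> None:
    age = np.asarray(age, dtype=float)
    tbsa = np.asarray(tbsa, dtype=float)
    if np.any(age < 0) or np.any(~np.isfinite(age)):
        raise ValueError("age must be a finite non-negative number of years")
    if np.any(tbsa < 0) or np.any(tbsa > 100) or np.any(~np.isfinite(tbsa)):
        raise ValueError("TBSA must lie in [0, 100] percent")


def revised_baux_score(
    age: ArrayLike,
    tbsa: ArrayLike,
    inhalation: ArrayLike,
    config: RiskModelConfig = DEFAULT_RISK_MODEL,
) -> ArrayLike:
    """Revised Baux score: ``age + %TBSA + increment * inhalation``.

    Monotone non-decreasing in every argument.  Accepts scalars or arrays.
    """
    _validate_age_tbsa(age, tbsa)
    score = (
        np.asarray(age, dtype=float)
        + np.asarray(tbsa, dtype=float)
        + config.baux_inhalation_increment * np.asarray(inhalation, dtype=float)
    )
    return float(score) if score.ndim == 0 else score


def predicted_mortality_risk(
    score: ArrayLike, config: RiskModelConfig = DEFAULT_RISK_MODEL
) -> ArrayLike:
    """Probability of death for a revised Baux score, via the logistic model."""
    lp = config.mortality_logit_intercept + config.mortality_logit_slope * np.asarray(
        score, dtype=float
    )
    risk = expit(lp)
    return float(risk) if risk.ndim == 0 else risk


def predicted_los(
    age: ArrayLike,
    tbsa: ArrayLike,
    inhalation: ArrayLike,
    config: RiskModelConfig = DEFAULT_RISK_MODEL,
) -> ArrayLike:
    """Predicted hospital days from the linear age/%TBSA/inhalation model.

    The linear predictor is clamped at zero; no rounding is applied (threshold
    comparison against an integer actual LOS is the indicator's concern).
    """
    _validate_age_tbsa(age, tbsa)
    for name in ("los_intercept", "los_age", "los_tbsa", "los_inhalation"):
        v = getattr(config, name)
        if v is None or not np.isfinite(v):
            raise RiskConfigurationError(f"missing or non-finite coefficient: {name}")
    lp = (
        config.los_intercept
        + config.los_age * np.asarray(age, dtype=float)
        + config.los_tbsa * np.asarray(tbsa, dtype=float)
        + config.los_inhalation * np.asarray(inhalation, dtype=float)
    )
    days = np.maximum(lp, 0.0)
    return float(days) if days.ndim == 0 else days
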