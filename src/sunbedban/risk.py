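"""Exposure-adjusted transition inputs.

Registry incidence includes cancers attributable to sunbed use.  To model a
policy that changes exposure, the attributable share is first removed with
Levin's population attributable fraction (PAF), giving a baseline incidence
for the unexposed population mix; arm-specific incidence is then rebuilt as
``b·[(1 − p) + p·RR]`` using the arm's own (lagged) ever-use prevalence p.
When p equals the prevalence used for attribution, the registry value is
recovered exactly — the status-quo arm reproduces observed incidence.

Exposure acts with a lag (published mean 9 years from exposure to diagnosis),
implemented as a deterministic shift of the prevalence curve.  For melanoma
only ever-use accrued before ``age_rr_cutoff`` (35) carries the elevated
risk; for KC ever-use at any age counts.

The module also provides the thick-melanoma excess-mortality schedule (a
declining annual risk for ten years after diagnosis, then a lifetime
constant) and the other-cause mortality adjustment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .parameters import ParameterSet
from .population import PopulationTables

__all__ = [
    "attributable_fraction",
    "baseline_incidence",
    "lagged_exposed_prevalence",
    "exposed_prevalence_curve",
    "arm_incidence",
    "arm_incidence_curve",
    "ExcessMortalitySchedule",
    "excess_thick_mortality",
    "other_cause_mortality",
    "other_cause_curve",
]

logger = logging.getLogger(__name__)


def attributable_fraction(p_exposed, rr):
    """Levin population attributable fraction, p(RR−1)/(1+p(RR−1)).

    Accepts scalars or arrays; p in [0, 1], RR > 0.  Negative values (RR < 1)
    indicate a protective exposure.
    """
    excess = np.asarray(p_exposed, dtype=float) * (rr - 1.0)
    out = excess / (1.0 + excess)
    return float(out) if np.isscalar(p_exposed) else out


def baseline_incidence(registry_incidence, p_exposed, rr):
    """Incidence with the sunbed-attributable share removed: the annual
    probability of diagnosis not attributable to sunbed use."""
    return registry_incidence * (1.0 - attributable_fraction(p_exposed, rr))


def lagged_exposed_prevalence(
    age: float, curve: np.ndarray, lag: float, ages: np.ndarray
) -> float:
    """Ever-use prevalence at (age − lag), floored at the curve's first age.

    Risk elevation therefore begins ``lag`` years after first possible
    exposure; non-integer lags interpolate linearly between tabulated ages.
    """
    if lag < 0:
        raise ValueError("lag must be non-negative")
    lookup = min(max(age - lag, ages[0]), ages[-1])
    return float(np.interp(lookup, ages, curve))


def exposed_prevalence_curve(
    sex: str,
    site: str,
    arm: str,
    tables: PopulationTables,
    params: ParameterSet,
) -> np.ndarray:
    """Lagged, site-eligible exposure prevalence at every model age.

    Melanoma risk eligibility is capped at exposure accrued before
    ``age_rr_cutoff``; KC uses ever-use at any age.
    """
    curve = tables.everuse[(sex, arm)]
    ages = tables.ages
    lookup = ages.astype(float) - params.lag_years
    if site == "melanoma":
        lookup = np.minimum(lookup, params.age_rr_cutoff)
    elif site != "kc":
        raise ValueError(f"unknown site: {site!r}")
    lookup = np.clip(lookup, ages[0], ages[-1])
    return np.interp(lookup, ages, curve)


def arm_incidence_curve(
    sex: str,
    site: str,
    arm: str,
    tables: PopulationTables,
    params: ParameterSet,
) -> np.ndarray:
    """Arm-specific annual cancer incidence at every model age.

    The attributable share is removed with the status-quo exposure mix (that
    is what the registry observed), then the arm's own exposure prevalence is
    applied: b·[(1 − p) + p·RR], clamped to [0, 1].
    """
    if site == "melanoma":
        registry = tables.melanoma_incidence[sex]
        rr = params.rr_melanoma
    else:
        registry = tables.kc_incidence[sex]
        rr = params.rr_kc
    p_attr = exposed_prevalence_curve(sex, site, "status_quo", tables, params)
    base = baseline_incidence(registry, p_attr, rr)
    p_arm = exposed_prevalence_curve(sex, site, arm, tables, params)
    return np.clip(base * (1.0 - p_arm + p_arm * rr), 0.0, 1.0)


def arm_incidence(
    age: float,
    sex: str,
    site: str,
    arm: str,
    tables: PopulationTables,
    params: ParameterSet,
) -> float:
    """Scalar convenience wrapper around :func:`arm_incidence_curve`."""
    return float(arm_incidence_curve(sex, site, arm, tables, params)[tables.age_index(age)])


@dataclass(frozen=True)
class ExcessMortalitySchedule:
    """Melanoma excess-mortality schedule.

    Thick (>1 mm) melanoma carries an annual excess death risk of
    ``year1_risk`` in the year of diagnosis, reduced by ``annual_decrement``
    each year through year 10, then ``post10_excess`` for life.  The yearly
    sequence is floored at zero so that low sensitivity-analysis values of
    the first-year risk remain runnable.  Thin melanoma carries a constant
    lifetime excess of ``thin_excess``.
    """

    year1_risk: float = 0.0555
    annual_decrement: float = 0.0055
    post10_excess: float = 0.0056
    thin_excess: float = 0.0056

    def __post_init__(self):
        for name in ("year1_risk", "annual_decrement", "post10_excess", "thin_excess"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    @classmethod
    def from_params(cls, params: ParameterSet) -> "ExcessMortalitySchedule":
        return cls(
            year1_risk=params.mort_thick_year1,
            annual_decrement=params.mort_annual_decrement,
            post10_excess=params.mort_post10_excess,
            thin_excess=params.mort_thin_excess,
        )

    def scaled(self, factor: float) -> "ExcessMortalitySchedule":
        """Schedule with all excess risks multiplied by ``factor`` (used for
        treatment-effect sensitivity analysis)."""
        return ExcessMortalitySchedule(
            year1_risk=self.year1_risk * factor,
            annual_decrement=self.annual_decrement * factor,
            post10_excess=self.post10_excess * factor,
            thin_excess=self.thin_excess,
        )


def excess_thick_mortality(
    years_since_dx: int, schedule: ExcessMortalitySchedule
) -> float:
    """Annual excess melanoma-death probability by year since thick-melanoma
    diagnosis (year 1 = year of diagnosis)."""
    if years_since_dx < 1:
        raise ValueError("years_since_dx must be >= 1")
    if years_since_dx <= 10:
        return max(
            schedule.year1_risk - (years_since_dx - 1) * schedule.annual_decrement, 0.0
        )
    return schedule.post10_excess


def other_cause_curve(sex: str, tables: PopulationTables) -> np.ndarray:
    """Annual probability of death from causes other than melanoma, at every
    model age: all-cause minus the melanoma-death component, floored at 0."""
    q = tables.all_cause_mortality[sex] - tables.melanoma_mortality[sex]
    if np.any(q < 0):
        logger.warning(
            "other-cause mortality floored at 0 for %d ages (sex=%s)",
            int(np.sum(q < 0)),
            sex,
        )
    return np.clip(q, 0.0, 1.0)


def other_cause_mortality(age: float, sex: str, tables: PopulationTables) -> float:
    return float(other_cause_curve(sex, tables)[tables.age_index(age)])
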