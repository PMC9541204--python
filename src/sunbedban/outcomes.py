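"""Valuation of cohort traces: discounted costs, QALYs and decision metrics.

QALYs accrue as state occupancy × age-specific EQ-5D norm × state utility
multiplier (thin melanoma and KC 0.93, thick melanoma 0.837, death 0;
post-melanoma states carry no decrement).  When a KC coincides with an
incident melanoma in the same cycle only the larger decrement applies.
Per-cycle utility is half-cycle corrected by trapezoidal averaging of
adjacent cycles and discounted at 3.5% per year.

Costs are one-off lump sums at the event cycle (diagnosis, melanoma death,
KC episode), discounted but not half-cycle corrected; the public information
campaign is a single undiscounted payment at cycle 0 in the intervention arm
only.  Event counts are reported undiscounted at national cohort scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .markov import (
    CohortTrace,
    DEATH_MEL,
    N_STATES,
    THICK_TUNNEL_FIRST,
    THIN,
)
from .parameters import ParameterSet
from .population import PopulationTables

__all__ = [
    "ArmResult",
    "IncrementalResult",
    "discount_factor",
    "value_trace",
    "combine_results",
    "incremental",
    "results_table",
]


def discount_factor(cycle, rate: float):
    """Present-value weight (1 + rate)^(−cycle)."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    return (1.0 + rate) ** (-np.asarray(cycle, dtype=float))


@dataclass(frozen=True)
class ArmResult:
    """Totals for one strategy arm: discounted cost and QALYs, and
    undiscounted lifetime event counts, at the stated population scale."""

    total_cost: float
    total_qalys: float
    melanoma_cases: float
    melanoma_deaths: float
    kc_cases: float

    def __post_init__(self):
        if self.total_qalys < 0 or min(
            self.melanoma_cases, self.melanoma_deaths, self.kc_cases
        ) < 0:
            raise ValueError("QALYs and event counts must be non-negative")


def value_trace(
    trace: CohortTrace,
    sex: str,
    tables: PopulationTables,
    params: ParameterSet,
    scale: Optional[float] = None,
    anxiety_decrement: float = 0.0,
    denied_fraction: Optional[np.ndarray] = None,
) -> ArmResult:
    """Value one sex's trace.  ``scale`` defaults to the sex's share of the
    national cohort; the campaign cost is *not* added here (it is a single
    national payment, added once in :func:`combine_results`).

    ``anxiety_decrement`` applies a per-cycle utility decrement to the
    ``denied_fraction`` of the alive cohort (used by the ban-anxiety scenario
    analysis); both default to no effect.
    """
    n = trace.n_cycles
    if scale is None:
        scale = params.cohort_n * params.sex_share(sex)
    norms = tables.eq5d_norm[sex][: n + 1]
    disc = discount_factor(np.arange(n + 1), params.discount_rate)

    mult = np.ones(N_STATES)
    mult[THIN] = params.util_mult_thin
    mult[THICK_TUNNEL_FIRST] = params.util_mult_thick
    mult[DEATH_MEL] = 0.0
    mult[DEATH_MEL + 1] = 0.0
    # per-cycle expected utility per cohort member, with the KC overlay:
    # a fraction kc_rate of each alive state takes min(state mult, KC mult)
    kc_mult = np.minimum(mult, params.util_mult_kc)
    occ = trace.occupancy
    base_u = occ @ mult
    kc_u = occ @ kc_mult
    k = np.append(trace.kc_rate, 0.0)  # no KC draw at the final cycle
    u = norms * ((1.0 - k) * base_u + k * kc_u)

    if anxiety_decrement > 0.0:
        if denied_fraction is None:
            raise ValueError("anxiety decrement requires a denied_fraction curve")
        denied = np.minimum(denied_fraction[: n + 1], trace.alive_mass)
        u = u - anxiety_decrement * denied * norms

    qalys = float(np.sum(0.5 * (u[:-1] * disc[:-1] + u[1:] * disc[1:])))

    event_cost = (
        trace.thin_incidence * params.cost_thin
        + trace.thick_incidence * params.cost_thick
        + trace.kc_incidence * params.cost_kc
        + trace.melanoma_deaths * params.cost_melanoma_death
    )
    cost = float(np.sum(event_cost * disc[:-1]))

    return ArmResult(
        total_cost=cost * scale,
        total_qalys=qalys * scale,
        melanoma_cases=float(
            (trace.thin_incidence.sum() + trace.thick_incidence.sum()) * scale
        ),
        melanoma_deaths=float(trace.melanoma_deaths.sum() * scale),
        kc_cases=float(trace.kc_incidence.sum() * scale),
    )


def combine_results(results: list[ArmResult], campaign_cost: float = 0.0) -> ArmResult:
    """Sum per-sex results and add the one-off campaign cost (undiscounted,
    cycle 0) once."""
    return ArmResult(
        total_cost=sum(r.total_cost for r in results) + campaign_cost,
        total_qalys=sum(r.total_qalys for r in results),
        melanoma_cases=sum(r.melanoma_cases for r in results),
        melanoma_deaths=sum(r.melanoma_deaths for r in results),
        kc_cases=sum(r.kc_cases for r in results),
    )


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental decision metrics for intervention vs comparator at a
    stated willingness-to-pay threshold.

    ``icer`` is None exactly when dominance applies (or ΔQALY = 0);
    ``nmb = threshold × nhb`` by construction.
    """

    delta_cost: float
    delta_qalys: float
    icer: Optional[float]
    dominant: bool
    dominated: bool
    nmb: float
    nhb: float
    threshold_used: float


def incremental(
    intervention: ArmResult, comparator: ArmResult, threshold: float
) -> IncrementalResult:
    """Incremental cost-effectiveness of the intervention vs the comparator.

    The intervention *dominates* when it costs less and yields more QALYs (no
    ICER is reported); it is *dominated* in the mirror case.  The ICER
    ΔC/ΔQ is reported only when both differences carry the same sign.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.total_qalys - comparator.total_qalys
    dominant = dc < 0 and dq > 0
    dominated = dc > 0 and dq < 0
    icer: Optional[float] = None
    if not dominant and not dominated and dq != 0.0:
        icer = dc / dq
    nmb = threshold * dq - dc
    return IncrementalResult(
        delta_cost=dc,
        delta_qalys=dq,
        icer=icer,
        dominant=dominant,
        dominated=dominated,
        nmb=nmb,
        nhb=dq - dc / threshold,
        threshold_used=threshold,
    )


def results_table(
    comparator: ArmResult, intervention: ArmResult, inc: IncrementalResult
) -> pd.DataFrame:
    """Publication-shaped summary table (one row per estimate)."""
    if inc.dominant:
        icer_text = "not applicable (intervention dominant)"
    elif inc.dominated:
        icer_text = "not applicable (intervention dominated)"
    elif inc.icer is None:
        icer_text = "undefined (zero QALY difference)"
    else:
        icer_text = f"{inc.icer:,.0f}"
    rows = [
        ("melanoma_cases", comparator.melanoma_cases, intervention.melanoma_cases,
         intervention.melanoma_cases - comparator.melanoma_cases),
        ("melanoma_deaths", comparator.melanoma_deaths, intervention.melanoma_deaths,
         intervention.melanoma_deaths - comparator.melanoma_deaths),
        ("kc_cases", comparator.kc_cases, intervention.kc_cases,
         intervention.kc_cases - comparator.kc_cases),
        ("total_cost_gbp", comparator.total_cost, intervention.total_cost,
         inc.delta_cost),
        ("total_qalys", comparator.total_qalys, intervention.total_qalys,
         inc.delta_qalys),
        ("icer_gbp_per_qaly", None, icer_text, None),
        ("net_health_benefit_qalys", None, inc.nhb, None),
        ("incremental_net_benefit_gbp", None, inc.nmb, None),
    ]
    return pd.DataFrame(
        rows, columns=["estimate", "current_situation", "intervention", "difference"]
    )
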