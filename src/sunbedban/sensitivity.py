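"""Deterministic and probabilistic sensitivity analyses.

* OWSA: each uncertain parameter in turn is set to its worst- and best-case
  plausible bound and the full model re-run; rows are ordered by worst-case
  incremental net benefit (INB), ascending — the tornado ordering.
* TWSA: a grid over melanoma treatment-cost multipliers (100–200% in 20%
  steps) crossed with thick-melanoma mortality reductions (0–50% in 5%
  steps), reporting INB per cell.
* PSA: joint Monte-Carlo over every parameter with a non-fixed distribution
  (independent draws), yielding the incremental cost/QALY cloud, the
  probability the intervention dominates, and the cost-effectiveness
  acceptability curve (CEAC): the fraction of iterations with positive net
  monetary benefit at each willingness-to-pay threshold.
* Scenario analyses: a ban-anxiety utility decrement with a net-benefit
  cutoff search; a lower melanoma relative risk (1.2) applied to all users
  regardless of age at first use; and closed-form campaign-cost thresholds
  (cost-neutral price and the price at which the ICER reaches the
  threshold), both exact by linearity of the one-off campaign cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .outcomes import incremental, value_trace, combine_results
from .parameters import (
    DistributionSpec,
    ModelConfig,
    OwsaBounds,
    ParameterSet,
    draw_psa_sample,
)
from .pipeline import COMPARATOR, INTERVENTION, DeterministicResult, evaluate, run_arm
from .population import PopulationTables, SEXES, make_population_tables

__all__ = [
    "owsa",
    "twsa",
    "PsaSummary",
    "run_psa",
    "scenario_disutility_threshold",
    "scenario_low_rr",
    "campaign_cost_thresholds",
]

DEFAULT_CEAC_GRID = np.arange(0.0, 50_001.0, 1000.0)


def _icer_text(inc) -> str:
    if inc.dominant:
        return "dominant"
    if inc.dominated:
        return "dominated"
    if inc.icer is None:
        return "undefined"
    return f"{inc.icer:.0f}"


def owsa(
    base: ParameterSet,
    bounds: list[OwsaBounds],
    tables: PopulationTables | None = None,
) -> pd.DataFrame:
    """One-way sensitivity analysis: full deterministic rerun per bound.

    Returns one row per parameter with worst/best INB and ICER (or a
    dominance flag), ordered by worst-case INB ascending.
    """
    if tables is None:
        tables = make_population_tables(base)
    fields = set(ParameterSet.model_fields)
    rows = []
    for bound in bounds:
        if bound.parameter not in fields:
            raise KeyError(f"unknown OWSA parameter: {bound.parameter!r}")
        results = {}
        for case, value in (("worst", bound.worst), ("best", bound.best)):
            params = base.model_copy(update={bound.parameter: value})
            results[case] = evaluate(params, tables).incremental
        rows.append(
            {
                "parameter": bound.parameter,
                "worst_value": bound.worst,
                "best_value": bound.best,
                "inb_worst": results["worst"].nmb,
                "inb_best": results["best"].nmb,
                "icer_worst": _icer_text(results["worst"]),
                "icer_best": _icer_text(results["best"]),
            }
        )
    frame = pd.DataFrame(rows)
    return frame.sort_values("inb_worst", ignore_index=True)


def twsa(
    base: ParameterSet,
    cost_multipliers: np.ndarray | None = None,
    mortality_reductions: np.ndarray | None = None,
    tables: PopulationTables | None = None,
) -> pd.DataFrame:
    """Two-way grid: melanoma treatment costs × thick-melanoma mortality.

    Costs of thin and thick melanoma treatment are scaled together by the
    multiplier; the thick-melanoma excess-mortality schedule (first-year
    risk, annual decrement, lifetime excess) is scaled by (1 − reduction).
    Long-format output with one row per cell and the INB at the base
    threshold.
    """
    if cost_multipliers is None:
        cost_multipliers = np.round(np.arange(1.0, 2.01, 0.2), 10)
    if mortality_reductions is None:
        mortality_reductions = np.round(np.arange(0.0, 0.501, 0.05), 10)
    cost_multipliers = np.asarray(cost_multipliers, dtype=float)
    mortality_reductions = np.asarray(mortality_reductions, dtype=float)
    if cost_multipliers.size == 0 or mortality_reductions.size == 0:
        raise ValueError("grids must be non-empty")
    if tables is None:
        tables = make_population_tables(base)
    rows = []
    for m in cost_multipliers:
        for r in mortality_reductions:
            params = base.model_copy(
                update={
                    "cost_thin": base.cost_thin * m,
                    "cost_thick": base.cost_thick * m,
                    "mort_thick_year1": base.mort_thick_year1 * (1.0 - r),
                    "mort_annual_decrement": base.mort_annual_decrement * (1.0 - r),
                    "mort_post10_excess": base.mort_post10_excess * (1.0 - r),
                }
            )
            inc = evaluate(params, tables).incremental
            rows.append(
                {
                    "cost_multiplier": float(m),
                    "mortality_reduction": float(r),
                    "inb": inc.nmb,
                    "delta_cost": inc.delta_cost,
                    "delta_qalys": inc.delta_qalys,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class PsaSummary:
    """Probabilistic sensitivity analysis output."""

    delta_costs: np.ndarray
    delta_qalys: np.ndarray
    thresholds: np.ndarray
    ceac: np.ndarray
    prob_dominant: float
    mean_delta_cost: float
    mean_delta_qalys: float
    n_iterations: int = field(default=0)

    def prob_cost_effective(self, threshold: float) -> float:
        """Fraction of iterations with NMB > 0 at the given threshold."""
        nmb = threshold * self.delta_qalys - self.delta_costs
        return float(np.mean(nmb > 0))

    def scatter_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"delta_cost": self.delta_costs, "delta_qalys": self.delta_qalys}
        )

    def ceac_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.thresholds, "prob_cost_effective": self.ceac}
        )


def run_psa(
    base: ParameterSet,
    distributions: dict[str, DistributionSpec],
    n_iterations: int | None = None,
    thresholds: np.ndarray | None = None,
    seed: int | None = None,
    tables: PopulationTables | None = None,
) -> PsaSummary:
    """Monte-Carlo PSA: ``n_iterations`` full model evaluations at jointly
    sampled parameter sets.  Reproducible under ``seed`` (defaults to the
    parameter set's master seed)."""
    if n_iterations is None:
        n_iterations = base.psa_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if thresholds is None:
        thresholds = DEFAULT_CEAC_GRID
    thresholds = np.asarray(thresholds, dtype=float)
    if tables is None:
        tables = make_population_tables(base)
    rng = np.random.default_rng(base.rng_seed if seed is None else seed)

    dc = np.empty(n_iterations)
    dq = np.empty(n_iterations)
    for i in range(n_iterations):
        sample = draw_psa_sample(base, distributions, rng)
        inc = evaluate(sample, tables).incremental
        dc[i] = inc.delta_cost
        dq[i] = inc.delta_qalys

    nmb = thresholds[:, None] * dq[None, :] - dc[None, :]
    ceac = (nmb > 0).mean(axis=1)
    return PsaSummary(
        delta_costs=dc,
        delta_qalys=dq,
        thresholds=thresholds,
        ceac=ceac,
        prob_dominant=float(np.mean((dc < 0) & (dq > 0))),
        mean_delta_cost=float(dc.mean()),
        mean_delta_qalys=float(dq.mean()),
        n_iterations=n_iterations,
    )


def _nmb_with_anxiety(
    base: ParameterSet, tables: PopulationTables, decrement: float
) -> float:
    """NMB of the intervention when the fraction of the cohort denied sunbed
    use (status-quo would-be users minus post-ban users) carries a utility
    decrement ``decrement`` every alive cycle in the intervention arm."""
    sq, _ = run_arm(COMPARATOR, tables, base)
    from .markov import run_cohort  # local import to avoid a cycle

    per_sex = []
    for sex in SEXES:
        trace = run_cohort(sex, INTERVENTION, tables, base)
        denied = np.clip(
            tables.everuse[(sex, COMPARATOR)] - tables.everuse[(sex, INTERVENTION)],
            0.0,
            None,
        )
        per_sex.append(
            value_trace(
                trace,
                sex,
                tables,
                base,
                anxiety_decrement=decrement,
                denied_fraction=denied,
            )
        )
    ban = combine_results(per_sex, campaign_cost=base.cost_campaign)
    return incremental(ban, sq, base.threshold).nmb


def scenario_disutility_threshold(
    base: ParameterSet,
    tables: PopulationTables | None = None,
    d_max: float = 0.10,
    tol: float = 1e-6,
) -> float | None:
    """Smallest anxiety utility decrement in [0, d_max] at which the
    intervention's NMB falls to or below £0, found by bisection.

    Returns ``None`` when the NMB stays positive across the whole range
    ("no cutoff in range").
    """
    if tables is None:
        tables = make_population_tables(base)
    else:
        tables = tables.with_prevalence(base)
    lo, hi = 0.0, d_max
    if _nmb_with_anxiety(base, tables, lo) <= 0:
        return 0.0
    if _nmb_with_anxiety(base, tables, hi) > 0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _nmb_with_anxiety(base, tables, mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def scenario_low_rr(
    base: ParameterSet,
    tables: PopulationTables | None = None,
    rr: float = 1.2,
) -> DeterministicResult:
    """Lower melanoma relative risk (default 1.2) applied to all sunbed users
    regardless of age at first use (the age-35 eligibility cap is lifted)."""
    params = base.model_copy(
        update={"rr_melanoma": rr, "age_rr_cutoff": 1e9}
    )
    return evaluate(params, tables)


def campaign_cost_thresholds(
    base: ParameterSet,
    tables: PopulationTables | None = None,
) -> tuple[float, float]:
    """Campaign-cost break-even points, exact by linearity of the one-off
    campaign payment.

    Returns ``(cost_neutral, cost_at_threshold)``: the campaign cost at
    which incremental costs are zero, and the cost at which the ICER equals
    the willingness-to-pay threshold.  Requires the intervention to save
    treatment costs at the base campaign price.
    """
    result = evaluate(base, tables)
    inc = result.incremental
    savings = base.cost_campaign - inc.delta_cost  # treatment costs averted
    if savings <= 0:
        raise ValueError("intervention does not save treatment costs at base case")
    cost_neutral = savings
    cost_at_threshold = base.threshold * inc.delta_qalys + savings
    return float(cost_neutral), float(cost_at_threshold)
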