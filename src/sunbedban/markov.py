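"""Cohort Markov model of melanoma natural history with a KC event overlay.

Sixteen states: no melanoma; incident thin melanoma (Breslow ≤ 1 mm, one
cycle); thick melanoma (> 1 mm) as a ten-year tunnel (the incident state is
tunnel year 1, nine further slots cover years 2–10) encoding the declining
excess death risk after diagnosis; post-thick lifetime; post-thin; and two
absorbing death states (melanoma / other causes).  Keratinocyte cancer (KC)
is not a state: it is an overlay event that any alive state can experience
each cycle, carrying a cost and a one-cycle utility decrement but no
mortality.

Within a cycle, competing risks act on start-of-cycle occupancy: death takes
precedence over incidence (melanoma incidence applies to other-cause
survivors), the melanoma excess risks are additive with other-cause death,
and any negative residual probability is a model error.  Post-melanoma
states cannot re-enter the incident states (no second primaries) and carry
no quality-of-life decrement of their own.

An individual-level microsimulation walking the identical per-cycle
probabilities serves as an independent cross-check of the cohort
expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .parameters import ParameterSet
from .population import PopulationTables
from .risk import (
    ExcessMortalitySchedule,
    arm_incidence_curve,
    excess_thick_mortality,
    other_cause_curve,
)

__all__ = [
    "STATES",
    "NO_MEL",
    "THIN",
    "THICK_TUNNEL_FIRST",
    "POST_THICK",
    "POST_THIN",
    "DEATH_MEL",
    "DEATH_OTHER",
    "N_STATES",
    "CohortTrace",
    "build_cycle_transitions",
    "transition_matrices",
    "run_cohort",
    "microsimulate",
    "MicrosimResult",
]

NO_MEL = 0
THIN = 1
THICK_TUNNEL_FIRST = 2  # tunnel year 1 = incident thick melanoma
POST_THICK = 12  # lifetime state after the 10-year tunnel
POST_THIN = 13
DEATH_MEL = 14
DEATH_OTHER = 15
N_STATES = 16

STATES = (
    ["no_melanoma", "thin_melanoma"]
    + [f"thick_tunnel_year_{k}" for k in range(1, 11)]
    + ["post_thick_lifetime", "post_thin", "death_melanoma", "death_other"]
)

_MASS_TOL = 1e-9


class ModelError(RuntimeError):
    """Raised on an impossible transition structure or invariant breach."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle expectations for one sex under one strategy arm.

    ``occupancy`` has shape (n_cycles + 1, 16); row t is the state
    distribution at the start of cycle t (age 18 + t).  Event arrays have
    length n_cycles; entry t is the expected number of events per cohort
    member during cycle t.  ``kc_rate`` is the per-capita KC probability used
    for the overlay, kept alongside the expected counts because the utility
    adjustment needs the rate, not the count.
    """

    sex: str
    arm: str
    ages: np.ndarray
    occupancy: np.ndarray
    thin_incidence: np.ndarray
    thick_incidence: np.ndarray
    kc_incidence: np.ndarray
    melanoma_deaths: np.ndarray
    kc_rate: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    @property
    def alive_mass(self) -> np.ndarray:
        return self.occupancy[:, :DEATH_MEL].sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """Long-format export: one row per cycle and state, with per-cycle
        expected events repeated on the no-melanoma row set to NaN elsewhere."""
        n = self.n_cycles
        frames = []
        for s, name in enumerate(STATES):
            frames.append(
                pd.DataFrame(
                    {
                        "cycle": np.arange(n + 1),
                        "age": self.ages,
                        "state": name,
                        "mass": self.occupancy[:, s],
                    }
                )
            )
        out = pd.concat(frames, ignore_index=True)
        events = pd.DataFrame(
            {
                "cycle": np.arange(n),
                "incident_thin": self.thin_incidence,
                "incident_thick": self.thick_incidence,
                "incident_kc": self.kc_incidence,
                "melanoma_deaths": self.melanoma_deaths,
            }
        )
        return out.merge(events, on="cycle", how="left")


def _fill_transitions(
    T: np.ndarray,
    q: np.ndarray,
    i_mel: np.ndarray,
    p_thick: float,
    schedule: ExcessMortalitySchedule,
) -> None:
    """Populate transition matrices in place.

    ``T`` has shape (n, 16, 16); ``q`` and ``i_mel`` are the per-cycle
    other-cause death and melanoma incidence probabilities.
    """
    surv = 1.0 - q
    T[:, NO_MEL, DEATH_OTHER] = q
    T[:, NO_MEL, THIN] = surv * i_mel * (1.0 - p_thick)
    T[:, NO_MEL, THICK_TUNNEL_FIRST] = surv * i_mel * p_thick
    T[:, NO_MEL, NO_MEL] = surv * (1.0 - i_mel)

    # melanoma excess risks add to other-cause death, but other-cause death
    # takes precedence: the excess is capped at the surviving probability
    thin_excess = np.minimum(schedule.thin_excess, surv)
    for s in (THIN, POST_THIN):
        T[:, s, DEATH_OTHER] = q
        T[:, s, DEATH_MEL] = thin_excess
        T[:, s, POST_THIN] = 1.0 - q - thin_excess

    for year in range(1, 11):
        s = THICK_TUNNEL_FIRST + year - 1
        excess = np.minimum(excess_thick_mortality(year, schedule), surv)
        dest = s + 1 if year < 10 else POST_THICK
        T[:, s, DEATH_OTHER] = q
        T[:, s, DEATH_MEL] = excess
        T[:, s, dest] = 1.0 - q - excess

    post10 = np.minimum(schedule.post10_excess, surv)
    T[:, POST_THICK, DEATH_OTHER] = q
    T[:, POST_THICK, DEATH_MEL] = post10
    T[:, POST_THICK, POST_THICK] = 1.0 - q - post10

    T[:, DEATH_MEL, DEATH_MEL] = 1.0
    T[:, DEATH_OTHER, DEATH_OTHER] = 1.0

    if np.any(T < -1e-15):
        bad = np.argwhere(T < -1e-15)[0]
        raise ModelError(
            f"negative residual probability in state {STATES[bad[1]]} "
            f"at cycle {bad[0]}"
        )
    np.clip(T, 0.0, 1.0, out=T)


def transition_matrices(
    sex: str, arm: str, tables: PopulationTables, params: ParameterSet
) -> np.ndarray:
    """All per-cycle 16×16 transition matrices, shape (n_cycles, 16, 16)."""
    n = params.n_cycles
    if len(tables.ages) < n + 1:
        raise ModelError("tables do not cover the full model horizon")
    q = other_cause_curve(sex, tables)[:n]
    i_mel = arm_incidence_curve(sex, "melanoma", arm, tables, params)[:n]
    T = np.zeros((n, N_STATES, N_STATES))
    _fill_transitions(T, q, i_mel, params.p_thick, ExcessMortalitySchedule.from_params(params))
    return T


def build_cycle_transitions(
    age: float,
    sex: str,
    arm: str,
    tables: PopulationTables,
    params: ParameterSet,
) -> np.ndarray:
    """Single-cycle 16×16 transition matrix at one age (rows sum to 1)."""
    idx = tables.age_index(age)
    q = other_cause_curve(sex, tables)[idx : idx + 1]
    i_mel = arm_incidence_curve(sex, "melanoma", arm, tables, params)[idx : idx + 1]
    T = np.zeros((1, N_STATES, N_STATES))
    _fill_transitions(T, q, i_mel, params.p_thick, ExcessMortalitySchedule.from_params(params))
    return T[0]


def run_cohort(
    sex: str, arm: str, tables: PopulationTables, params: ParameterSet
) -> CohortTrace:
    """Propagate a unit cohort starting in no-melanoma at age 18 through
    ``n_cycles`` annual cycles, recording occupancy and expected events.

    Mass is conserved at every cycle to 1e-9 or the run aborts with the
    offending cycle index.
    """
    n = params.n_cycles
    T = transition_matrices(sex, arm, tables, params)
    kc_rate = arm_incidence_curve(sex, "kc", arm, tables, params)[:n]

    occupancy = np.zeros((n + 1, N_STATES))
    occupancy[0, NO_MEL] = 1.0
    thin_inc = np.zeros(n)
    thick_inc = np.zeros(n)
    kc_inc = np.zeros(n)
    mel_deaths = np.zeros(n)

    for t in range(n):
        occ = occupancy[t]
        alive = occ[:DEATH_MEL].sum()
        kc_inc[t] = alive * kc_rate[t]
        nxt = occ @ T[t]
        thin_inc[t] = occ @ T[t, :, THIN]
        thick_inc[t] = occ @ T[t, :, THICK_TUNNEL_FIRST]
        mel_deaths[t] = nxt[DEATH_MEL] - occ[DEATH_MEL]
        if abs(nxt.sum() - 1.0) > _MASS_TOL or np.any(nxt < -_MASS_TOL):
            raise ModelError(f"mass conservation violated at cycle {t}")
        occupancy[t + 1] = np.clip(nxt, 0.0, None)

    return CohortTrace(
        sex=sex,
        arm=arm,
        ages=tables.ages[: n + 1],
        occupancy=occupancy,
        thin_incidence=thin_inc,
        thick_incidence=thick_inc,
        kc_incidence=kc_inc,
        melanoma_deaths=mel_deaths,
        kc_rate=kc_rate,
    )


@dataclass(frozen=True)
class MicrosimResult:
    """Per-person means and Monte-Carlo standard errors from the
    individual-level simulation (discounted cost and QALYs; undiscounted
    lifetime event counts)."""

    n_individuals: int
    mean_cost: float
    se_cost: float
    mean_qalys: float
    se_qalys: float
    mean_melanoma_cases: float
    se_melanoma_cases: float
    mean_melanoma_deaths: float
    se_melanoma_deaths: float
    mean_kc_cases: float
    se_kc_cases: float


def _state_multipliers(params: ParameterSet) -> np.ndarray:
    m = np.ones(N_STATES)
    m[THIN] = params.util_mult_thin
    m[THICK_TUNNEL_FIRST] = params.util_mult_thick
    m[DEATH_MEL] = 0.0
    m[DEATH_OTHER] = 0.0
    return m


def microsimulate(
    sex: str,
    arm: str,
    tables: PopulationTables,
    params: ParameterSet,
    n_individuals: int,
    rng: np.random.Generator,
) -> MicrosimResult:
    """Monte-Carlo walk of individuals through the identical per-cycle
    probabilities as :func:`run_cohort`, valuing costs and QALYs with the
    same discounting and half-cycle (trapezoidal) convention.

    KC events are Bernoulli draws each alive cycle; when a KC coincides with
    an incident melanoma cycle only the larger utility decrement applies.
    """
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    n = params.n_cycles
    T = transition_matrices(sex, arm, tables, params)
    cum = np.cumsum(T, axis=2)
    cum[:, :, -1] = 1.0  # guard against rounding in searchsorted
    kc_rate = arm_incidence_curve(sex, "kc", arm, tables, params)[:n]
    norms = tables.eq5d_norm[sex][: n + 1]
    disc = (1.0 + params.discount_rate) ** -np.arange(n + 1)
    mult = _state_multipliers(params)

    state = np.zeros(n_individuals, dtype=np.int64)
    cost = np.zeros(n_individuals)
    qalys = np.zeros(n_individuals)
    mel_cases = np.zeros(n_individuals)
    mel_deaths = np.zeros(n_individuals)
    kc_cases = np.zeros(n_individuals)
    u_prev = np.zeros(n_individuals)

    for t in range(n):
        alive = state < DEATH_MEL
        kc_event = np.zeros(n_individuals, dtype=bool)
        if alive.any():
            kc_event[alive] = rng.random(int(alive.sum())) < kc_rate[t]
        kc_cases += kc_event
        cost += np.where(kc_event, params.cost_kc * disc[t], 0.0)

        u_t = norms[t] * mult[state]
        u_t = np.where(kc_event, norms[t] * np.minimum(mult[state], params.util_mult_kc), u_t)
        if t > 0:
            qalys += 0.5 * (u_prev * disc[t - 1] + u_t * disc[t])
        u_prev = u_t

        draws = rng.random(n_individuals)
        new_state = state.copy()
        for s in np.unique(state):
            sel = state == s
            new_state[sel] = np.searchsorted(cum[t, s], draws[sel], side="right")
        np.clip(new_state, 0, N_STATES - 1, out=new_state)

        incident_thin = new_state == THIN
        incident_thick = (new_state == THICK_TUNNEL_FIRST) & (state == NO_MEL)
        died_mel = (new_state == DEATH_MEL) & (state != DEATH_MEL)
        mel_cases += incident_thin | incident_thick
        mel_deaths += died_mel
        cost += (
            incident_thin * params.cost_thin
            + incident_thick * params.cost_thick
            + died_mel * params.cost_melanoma_death
        ) * disc[t]
        state = new_state

    u_final = norms[n] * mult[state]
    qalys += 0.5 * (u_prev * disc[n - 1] + u_final * disc[n])

    def _summ(x: np.ndarray) -> tuple[float, float]:
        if n_individuals == 1:
            return float(x.mean()), 0.0
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(n_individuals))

    mc, sc = _summ(cost)
    mq, sq = _summ(qalys)
    mm, sm = _summ(mel_cases)
    md, sd = _summ(mel_deaths)
    mk, sk = _summ(kc_cases)
    return MicrosimResult(
        n_individuals=n_individuals,
        mean_cost=mc,
        se_cost=sc,
        mean_qalys=mq,
        se_qalys=sq,
        mean_melanoma_cases=mm,
        se_melanoma_cases=sm,
        mean_melanoma_deaths=md,
        se_melanoma_deaths=sd,
        mean_kc_cases=mk,
        se_kc_cases=sk,
    )
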