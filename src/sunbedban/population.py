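"""Synthetic age/sex-indexed population tables.

The analysis needs five age/sex tables — all-cause mortality, melanoma
incidence, keratinocyte-cancer (KC) incidence, EQ-5D-3L population norms and
sunbed ever-use prevalence (one curve per strategy arm) — over model ages 18
to 101 (cohort entry plus 83 one-year cycles).  This module generates them
synthetically with the statistical structure the analysis assumes:

* mortality follows a Gompertz–Makeham hazard (constant background plus an
  exponentially age-increasing component), with the final modelled age forced
  to probability 1;
* cancer incidence is log-linear in age up to a plateau at 80, anchored
  exactly to the published 18-year-old female values (melanoma 0.00005,
  KC 0.00001) and sex-scaled for males;
* EQ-5D norms decline piecewise-linearly from 0.929 at 18;
* ever-use prevalence accumulates from the age-18 level via a year-on-year
  uptake hazard that declines geometrically with age; under the ban, new
  commercial uptake stops and only a small residual pool (``post_ban_use``)
  keeps accruing first use.

Every curve other than the printed 18-year-old anchors is synthetic: it is
shaped to be epidemiologically plausible for England, not to reproduce any
registry number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .parameters import ParameterSet

__all__ = [
    "SyntheticPopulationConfig",
    "PopulationTables",
    "make_life_table",
    "make_incidence_tables",
    "make_utility_norms",
    "make_prevalence_curves",
    "make_population_tables",
    "life_expectancy",
    "write_tables",
    "read_tables",
]

SEXES = ("female", "male")
ARMS = ("status_quo", "ban")

AGE_MIN = 18
AGE_MAX = 101  # 18 + 83 cycles


class GenerationError(ValueError):
    """Raised when shape parameters yield an impossible table."""


@dataclass(frozen=True)
class SyntheticPopulationConfig:
    """Shape parameters of the synthetic tables.

    Mortality: annual hazard h(a) = makeham + gompertz_b·exp(gompertz_c·a).
    Incidence: i(a) = anchor·sex_ratio·exp(slope·(min(a, plateau_age) − 18)).
    EQ-5D: piecewise-linear decline; ``eq5d_bands`` maps a band-start age to
    the per-year decline applied from that age on.
    """

    makeham_female: float = 1.0e-4
    makeham_male: float = 1.5e-4
    gompertz_b_female: float = 1.6e-5
    gompertz_b_male: float = 3.0e-5
    gompertz_c_female: float = 0.099
    gompertz_c_male: float = 0.095
    melanoma_anchor: float = 5.0e-5  # 18-year-old female
    kc_anchor: float = 1.0e-5  # 18-year-old female
    melanoma_slope: float = 0.05
    kc_slope: float = 0.115
    plateau_age: float = 80.0
    melanoma_sex_ratio: float = 1.1  # male : female
    kc_sex_ratio: float = 1.3
    eq5d_anchor: float = 0.929
    eq5d_bands: tuple[tuple[int, float], ...] = (
        (18, 0.0005),
        (35, 0.002),
        (55, 0.003),
        (75, 0.005),
    )

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, object]) -> "SyntheticPopulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(mapping) - known
        if unknown:
            raise GenerationError(f"unknown population options: {sorted(unknown)}")
        kwargs = dict(mapping)
        if "eq5d_bands" in kwargs:
            kwargs["eq5d_bands"] = tuple(
                (int(a), float(d)) for a, d in kwargs["eq5d_bands"]  # type: ignore[union-attr]
            )
        return cls(**kwargs)  # type: ignore[arg-type]


@dataclass(frozen=True)
class PopulationTables:
    """Age/sex-indexed inputs to the cohort model.

    All columns are aligned to ``ages`` (18..101).  ``all_cause_mortality``
    here is generated net of melanoma deaths (``melanoma_mortality`` defaults
    to zero), so the other-cause adjustment subtracts nothing unless a caller
    supplies an explicit melanoma-death component.
    """

    ages: np.ndarray
    all_cause_mortality: dict[str, np.ndarray]
    melanoma_incidence: dict[str, np.ndarray]
    kc_incidence: dict[str, np.ndarray]
    eq5d_norm: dict[str, np.ndarray]
    everuse: dict[tuple[str, str], np.ndarray]  # (sex, arm) -> curve
    melanoma_mortality: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if not self.melanoma_mortality:
            zeros = {s: np.zeros_like(self.ages, dtype=float) for s in SEXES}
            object.__setattr__(self, "melanoma_mortality", zeros)

    def age_index(self, age: float) -> int:
        idx = int(round(age - self.ages[0]))
        if not 0 <= idx < len(self.ages):
            raise IndexError(f"age {age} outside table range")
        return idx

    def validate(self) -> None:
        """Check the structural invariants of every column."""
        for sex in SEXES:
            q = self.all_cause_mortality[sex]
            if np.any(q < 0) or np.any(q > 1):
                raise GenerationError("mortality outside [0, 1]")
            over40 = self.ages >= 40
            if np.any(np.diff(q[over40]) < -1e-12):
                raise GenerationError("mortality not non-decreasing beyond 40")
            for inc in (self.melanoma_incidence[sex], self.kc_incidence[sex]):
                if np.any(inc < 0) or np.any(inc > 1):
                    raise GenerationError("incidence outside [0, 1]")
            u = self.eq5d_norm[sex]
            if np.any(u > 1) or np.any(np.diff(u) > 1e-12):
                raise GenerationError("EQ-5D norms must be non-increasing and <= 1")
            for arm in ARMS:
                p = self.everuse[(sex, arm)]
                if np.any(p < 0) or np.any(p > 1):
                    raise GenerationError("ever-use prevalence outside [0, 1]")
                if arm == "status_quo" and np.any(np.diff(p) < -1e-12):
                    raise GenerationError("status-quo ever-use must be non-decreasing")

    def with_prevalence(self, params: ParameterSet) -> "PopulationTables":
        """Return a copy whose ever-use curves are rebuilt from ``params``
        (the only columns that depend on the parameter set)."""
        everuse = {
            (sex, arm): make_prevalence_curves(params, sex, arm, self.ages)
            for sex in SEXES
            for arm in ARMS
        }
        return replace(self, everuse=everuse)


def make_life_table(
    sex: str,
    makeham: float | None = None,
    gompertz_b: float | None = None,
    gompertz_c: float | None = None,
    ages: np.ndarray | None = None,
    config: SyntheticPopulationConfig | None = None,
) -> np.ndarray:
    """Gompertz–Makeham annual death probabilities, q(a) = 1 − exp(−h(a)).

    The final modelled age is forced to probability 1 (cohort extinction at
    the model boundary).  Shape parameters that reach q ≥ 1 before age 95 are
    rejected.
    """
    cfg = config or SyntheticPopulationConfig()
    if makeham is None:
        makeham = cfg.makeham_male if sex == "male" else cfg.makeham_female
    if gompertz_b is None:
        gompertz_b = cfg.gompertz_b_male if sex == "male" else cfg.gompertz_b_female
    if gompertz_c is None:
        gompertz_c = cfg.gompertz_c_male if sex == "male" else cfg.gompertz_c_female
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    hazard = makeham + gompertz_b * np.exp(gompertz_c * ages.astype(float))
    q = 1.0 - np.exp(-hazard)
    if np.any(q[ages < 95] >= 1.0):
        raise GenerationError(
            "mortality shape parameters give probability >= 1 before age 95"
        )
    q = np.clip(q, 0.0, 1.0)
    q[-1] = 1.0
    return q


def make_incidence_tables(
    sex: str,
    melanoma_anchor: float | None = None,
    kc_anchor: float | None = None,
    ages: np.ndarray | None = None,
    config: SyntheticPopulationConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Registry-style melanoma and KC incidence columns (including
    sunbed-attributable cases).

    Log-linear in age up to the plateau; the female column passes exactly
    through the 18-year-old anchors, the male column is scaled by the
    configured sex ratio.
    """
    cfg = config or SyntheticPopulationConfig()
    if melanoma_anchor is None:
        melanoma_anchor = cfg.melanoma_anchor
    if kc_anchor is None:
        kc_anchor = cfg.kc_anchor
    if melanoma_anchor <= 0 or kc_anchor <= 0:
        raise GenerationError("incidence anchors must be positive")
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    years = np.minimum(ages.astype(float), cfg.plateau_age) - AGE_MIN
    ratio_mel = cfg.melanoma_sex_ratio if sex == "male" else 1.0
    ratio_kc = cfg.kc_sex_ratio if sex == "male" else 1.0
    melanoma = np.clip(melanoma_anchor * ratio_mel * np.exp(cfg.melanoma_slope * years), 0, 1)
    kc = np.clip(kc_anchor * ratio_kc * np.exp(cfg.kc_slope * years), 0, 1)
    return melanoma, kc


def make_utility_norms(
    anchor: float | None = None,
    ages: np.ndarray | None = None,
    config: SyntheticPopulationConfig | None = None,
) -> np.ndarray:
    """Piecewise-linear, non-increasing EQ-5D-3L population norms by age,
    equal to the anchor (0.929) at age 18."""
    cfg = config or SyntheticPopulationConfig()
    if anchor is None:
        anchor = cfg.eq5d_anchor
    if not 0 < anchor <= 1:
        raise GenerationError("EQ-5D anchor must lie in (0, 1]")
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    bands = sorted(cfg.eq5d_bands)
    declines = np.zeros_like(ages, dtype=float)
    for start, rate in bands:
        declines[ages >= start] = rate
    # utility drops by the band's rate for each year lived past the band start
    steps = np.concatenate([[0.0], declines[:-1]])
    values = anchor - np.cumsum(steps)
    return np.clip(values, 1e-6, 1.0)


def make_prevalence_curves(
    params: ParameterSet,
    sex: str,
    arm: str,
    ages: np.ndarray | None = None,
) -> np.ndarray:
    """Sunbed ever-use prevalence by age for one sex under one strategy arm.

    Status quo: P(a+1) = P(a) + u(a)·(1 − P(a)) with first-use hazard
    u(a) = u0·(1 − decline)^(a−18), starting from the age-18 prevalence.
    ``uptake_rate_initial`` is the male hazard at 18; the female hazard is
    multiplied by ``female_male_ratio``.  ``prevalence_scale`` scales the
    whole exposure propensity (the age-18 level and the uptake hazard), so
    low/high-use sensitivity scenarios move every age consistently.

    Ban: ever-use accrued before the ban is retained, new commercial uptake
    stops, and a residual pool of size ``post_ban_use`` accrues first use
    under the same hazard, so the curve rises from the age-18 level towards
    (age-18 level + post_ban_use).
    """
    if ages is None:
        ages = np.arange(AGE_MIN, AGE_MAX + 1)
    n = len(ages)
    p18 = params.prev_18_female if sex == "female" else params.prev_18_male
    p18 = min(p18 * params.prevalence_scale, 1.0)
    u0 = (
        params.uptake_rate_initial
        * params.prevalence_scale
        * (params.female_male_ratio if sex == "female" else 1.0)
    )
    uptake = np.clip(u0 * (1.0 - params.uptake_decline) ** (ages - ages[0]), 0.0, 1.0)

    curve = np.empty(n)
    if arm == "status_quo":
        curve[0] = p18
        for k in range(n - 1):
            curve[k + 1] = curve[k] + uptake[k] * (1.0 - curve[k])
    elif arm == "ban":
        accrual = np.empty(n)  # fraction of the residual pool exposed by age a
        accrual[0] = 0.0
        for k in range(n - 1):
            accrual[k + 1] = accrual[k] + uptake[k] * (1.0 - accrual[k])
        curve = p18 + params.post_ban_use * accrual
    else:
        raise ValueError(f"unknown arm: {arm!r}")
    return np.clip(curve, 0.0, 1.0)


def make_population_tables(
    params: ParameterSet,
    config: SyntheticPopulationConfig | Mapping[str, object] | None = None,
) -> PopulationTables:
    """Build the complete synthetic table set for both sexes and arms."""
    if config is None:
        cfg = SyntheticPopulationConfig()
    elif isinstance(config, SyntheticPopulationConfig):
        cfg = config
    else:
        cfg = SyntheticPopulationConfig.from_mapping(config)
    ages = np.arange(AGE_MIN, AGE_MIN + params.n_cycles + 1)
    mortality, mel, kc, eq5d = {}, {}, {}, {}
    everuse = {}
    for sex in SEXES:
        mortality[sex] = make_life_table(sex, ages=ages, config=cfg)
        mel[sex], kc[sex] = make_incidence_tables(sex, ages=ages, config=cfg)
        eq5d[sex] = make_utility_norms(ages=ages, config=cfg)
        for arm in ARMS:
            everuse[(sex, arm)] = make_prevalence_curves(params, sex, arm, ages)
    tables = PopulationTables(
        ages=ages,
        all_cause_mortality=mortality,
        melanoma_incidence=mel,
        kc_incidence=kc,
        eq5d_norm=eq5d,
        everuse=everuse,
    )
    tables.validate()
    return tables


def life_expectancy(q: np.ndarray) -> float:
    """Expected years lived from the first tabulated age, counting a year as
    lived if the individual is alive at its start (survival-curve sum)."""
    survival = np.cumprod(1.0 - q)
    return float(1.0 + survival[:-1].sum())


# ---------------------------------------------------------------------------
# Delimited-text I/O (long format: age, sex, quantity, value)

_QUANTITY_GETTERS = {
    "all_cause_mortality": lambda t, s: t.all_cause_mortality[s],
    "melanoma_mortality": lambda t, s: t.melanoma_mortality[s],
    "melanoma_incidence": lambda t, s: t.melanoma_incidence[s],
    "kc_incidence": lambda t, s: t.kc_incidence[s],
    "eq5d_norm": lambda t, s: t.eq5d_norm[s],
    "everuse_status_quo": lambda t, s: t.everuse[(s, "status_quo")],
    "everuse_ban": lambda t, s: t.everuse[(s, "ban")],
}


def tables_to_frame(tables: PopulationTables) -> pd.DataFrame:
    records = []
    for quantity, getter in _QUANTITY_GETTERS.items():
        for sex in SEXES:
            col = getter(tables, sex)
            for age, value in zip(tables.ages, col):
                records.append((int(age), sex, quantity, float(value)))
    return pd.DataFrame(records, columns=["age", "sex", "quantity", "value"])


def write_tables(tables: PopulationTables, directory: str | Path) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = directory / "population_tables.csv"
    tables_to_frame(tables).to_csv(out, index=False, float_format="%.12g")
    return out


def read_tables(source: str | Path) -> PopulationTables:
    """Read a table set written by :func:`write_tables`."""
    path = Path(source)
    if path.is_dir():
        path = path / "population_tables.csv"
    frame = pd.read_csv(path)
    ages = np.array(sorted(frame["age"].unique()))
    cols: dict[str, dict[str, np.ndarray]] = {}
    for quantity in _QUANTITY_GETTERS:
        cols[quantity] = {}
        for sex in SEXES:
            sub = frame[(frame["quantity"] == quantity) & (frame["sex"] == sex)]
            sub = sub.sort_values("age")
            if len(sub) != len(ages):
                raise GenerationError(
                    f"table {quantity}/{sex} does not cover every age"
                )
            cols[quantity][sex] = sub["value"].to_numpy()
    return PopulationTables(
        ages=ages,
        all_cause_mortality=cols["all_cause_mortality"],
        melanoma_incidence=cols["melanoma_incidence"],
        kc_incidence=cols["kc_incidence"],
        eq5d_norm=cols["eq5d_norm"],
        everuse={
            (sex, arm): cols[f"everuse_{arm}"][sex] for sex in SEXES for arm in ARMS
        },
        melanoma_mortality=cols["melanoma_mortality"],
    )
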