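"""Parameter space of the indoor-tanning ban cost-effectiveness model.

The model compares a nationwide ban on commercial indoor tanning (plus a
public information campaign) against the status quo for a national cohort of
18-year-olds, from an NHS perspective in 2019 GBP.  This module defines the
full parameter set — epidemiological inputs (relative risks, incidence
anchors, excess-mortality schedule), exposure-prevalence components, costs,
utility multipliers and design constants (discount rate, cycle count,
willingness-to-pay threshold) — together with per-parameter sampling
distributions for probabilistic sensitivity analysis (PSA) and plausible
bounds for one-way sensitivity analysis (OWSA).

Configuration is a YAML document with sections ``cohort``, ``parameters``,
``distributions``, ``owsa_bounds``, ``scenarios`` and ``population``;
:func:`load_config` validates it into a :class:`ParameterSet`.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Any, Literal, Mapping, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = [
    "DistributionSpec",
    "ParameterSet",
    "OwsaBounds",
    "load_config",
    "distribution_from_mean_ci",
    "draw_psa_sample",
    "default_distributions",
    "default_owsa_bounds",
    "PARAMETER_DOMAINS",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


class ConfigurationError(ValueError):
    """Raised when a configuration document is malformed or incomplete."""


class SamplingError(RuntimeError):
    """Raised when a PSA draw cannot be made legal within bounded retries."""


class DistributionSpec(BaseModel):
    """Sampling distribution for one uncertain parameter.

    ``kind`` selects the family:

    - ``fixed``     — degenerate at ``mean`` (excluded from PSA variation);
    - ``normal``    — Normal(mean, se);
    - ``lognormal`` — exp(Normal(ln mean, se)); ``mean`` is the median on the
      natural scale and ``se`` the log-scale standard deviation;
    - ``beta``      — Beta(alpha, beta) on [0, 1];
    - ``scaled-beta`` — lo + (hi − lo)·Beta(alpha, beta).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    kind: Literal["fixed", "normal", "lognormal", "beta", "scaled-beta"]
    mean: Optional[float] = None
    se: Optional[float] = None
    alpha: Optional[float] = None
    beta: Optional[float] = None
    lo: Optional[float] = None
    hi: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "DistributionSpec":
        if self.kind in ("fixed", "normal", "lognormal"):
            if self.mean is None:
                raise ValueError(f"{self.kind} spec requires a mean")
            if self.kind != "fixed":
                if self.se is None or self.se <= 0:
                    raise ValueError(f"{self.kind} spec requires SE > 0")
        if self.kind in ("beta", "scaled-beta"):
            if self.alpha is None or self.beta is None:
                raise ValueError(f"{self.kind} spec requires alpha and beta")
            if self.alpha <= 0 or self.beta <= 0:
                raise ValueError("beta parameters must be positive")
        if self.kind == "scaled-beta":
            if self.lo is None or self.hi is None or not self.lo < self.hi:
                raise ValueError("scaled-beta requires lo < hi")
        return self

    def sample(self, rng: np.random.Generator, size: int | None = None):
        """Draw from the distribution. A ``fixed`` spec returns its point value."""
        if self.kind == "fixed":
            return self.mean if size is None else np.full(size, self.mean)
        if self.kind == "normal":
            return rng.normal(self.mean, self.se, size)
        if self.kind == "lognormal":
            return np.exp(rng.normal(math.log(self.mean), self.se, size))
        if self.kind == "beta":
            return rng.beta(self.alpha, self.beta, size)
        # scaled-beta
        return self.lo + (self.hi - self.lo) * rng.beta(self.alpha, self.beta, size)

    def expected_value(self) -> float:
        """Analytic mean (for lognormal, the median — by construction the
        published point estimate)."""
        if self.kind in ("fixed", "normal", "lognormal"):
            return float(self.mean)
        m = self.alpha / (self.alpha + self.beta)
        if self.kind == "beta":
            return float(m)
        return float(self.lo + (self.hi - self.lo) * m)


def distribution_from_mean_ci(
    mean: float, ci_low: float, ci_high: float
) -> DistributionSpec:
    """Lognormal spec from a published point estimate and 95% CI.

    The log-scale location is ``ln(mean)`` (median-matched to the point
    estimate) and the log-scale SD is ``(ln ci_high − ln ci_low) / (2·1.96)``,
    so sampling reproduces the published interval as the 2.5/97.5 percentiles.
    """
    if not (0 < ci_low < mean < ci_high):
        raise ValueError(
            f"require 0 < ci_low < mean < ci_high, got ({mean}, {ci_low}, {ci_high})"
        )
    sd = (math.log(ci_high) - math.log(ci_low)) / (2 * _Z95)
    return DistributionSpec(kind="lognormal", mean=mean, se=sd)


class OwsaBounds(BaseModel):
    """One-way sensitivity bounds: worst-case (favouring the status quo) and
    best-case plausible values for one parameter."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    parameter: str
    worst: float
    best: float


class ParameterSet(BaseModel):
    """Every model input: point estimates, design constants and (separately
    attached) distribution specs and OWSA bounds.

    Defaults are the published base case.  Probabilities and proportions live
    in [0, 1], relative risks are positive, utility multipliers in (0, 1].
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # --- relative risks and natural history -------------------------------
    rr_melanoma: float = Field(1.59, gt=0)
    rr_kc: float = Field(1.48, gt=0)
    p_thick: float = Field(0.354, ge=0, le=1)
    mort_thick_year1: float = Field(0.0555, ge=0, le=1)
    mort_annual_decrement: float = Field(0.0055, ge=0, le=1)
    mort_post10_excess: float = Field(0.0056, ge=0, le=1)
    mort_thin_excess: float = Field(0.0056, ge=0, le=1)
    lag_years: float = Field(9.0, ge=0)
    age_rr_cutoff: float = Field(35.0, gt=0)

    # --- exposure-prevalence components -----------------------------------
    prev_18_female: float = Field(0.043, ge=0, le=1)
    prev_18_male: float = Field(0.02, ge=0, le=1)
    female_male_ratio: float = Field(1.76, gt=0)
    uptake_rate_initial: float = Field(0.0125, ge=0, le=1)
    uptake_decline: float = Field(0.12, ge=0, le=1)
    post_ban_use: float = Field(0.02, ge=0, le=1)
    prevalence_scale: float = Field(1.0, gt=0)

    # --- costs (2019 GBP) --------------------------------------------------
    cost_kc: float = Field(1348.0, ge=0)
    cost_thin: float = Field(1338.0, ge=0)
    cost_thick: float = Field(3182.0, ge=0)
    cost_melanoma_death: float = Field(4686.0, ge=0)
    cost_campaign: float = Field(1_000_000.0, ge=0)

    # --- utility multipliers -----------------------------------------------
    util_mult_thin: float = Field(0.93, gt=0, le=1)
    util_mult_kc: float = Field(0.93, gt=0, le=1)
    util_mult_thick: float = Field(0.837, gt=0, le=1)

    # --- design constants ---------------------------------------------------
    discount_rate: float = Field(0.035, ge=0)
    threshold: float = Field(20_000.0, gt=0)
    n_cycles: int = Field(83, ge=1)
    cohort_n: int = Field(618_873, ge=1)
    prop_male: float = Field(0.51, ge=0, le=1)
    psa_iterations: int = Field(5000, ge=1)
    rng_seed: int = Field(2019, ge=0)

    def sex_share(self, sex: str) -> float:
        return self.prop_male if sex == "male" else 1.0 - self.prop_male


# Legal sampling domains per PSA-varied field: (low, high, low_open, high_open)
PARAMETER_DOMAINS: dict[str, tuple[float, float, bool, bool]] = {
    "rr_melanoma": (0.0, math.inf, True, True),
    "rr_kc": (0.0, math.inf, True, True),
    "p_thick": (0.0, 1.0, False, False),
    "mort_thick_year1": (0.0, 1.0, False, False),
    "lag_years": (0.0, math.inf, False, True),
    "util_mult_thin": (0.0, 1.0, True, False),
    "util_mult_kc": (0.0, 1.0, True, False),
    "util_mult_thick": (0.0, 1.0, True, False),
    "cost_kc": (0.0, math.inf, False, True),
    "cost_thin": (0.0, math.inf, False, True),
    "cost_thick": (0.0, math.inf, False, True),
    "cost_melanoma_death": (0.0, math.inf, False, True),
    "cost_campaign": (0.0, math.inf, False, True),
    "prev_18_female": (0.0, 1.0, False, False),
    "prev_18_male": (0.0, 1.0, False, False),
    "female_male_ratio": (0.0, math.inf, True, True),
    "uptake_rate_initial": (0.0, 1.0, False, False),
    "uptake_decline": (0.0, 1.0, False, False),
    "post_ban_use": (0.0, 1.0, False, False),
}


def default_distributions() -> dict[str, DistributionSpec]:
    """PSA distributions for the base case.

    Relative risks are lognormal, median-matched to the published point
    estimate with log-scale SD from the published 95% CI.  The thick-melanoma
    proportion is Beta(28.3, 51.7).  Costs and utility multipliers are normal
    with SEs read off the published plausible bounds treated as 95% intervals
    (≈10% CV for costs).  The campaign cost is a Beta(2, 5) rescaled to
    [£0, £3 339 807].  Exposure-prevalence components default to ``fixed``.
    """
    return {
        "rr_melanoma": distribution_from_mean_ci(1.59, 1.36, 1.87),
        "rr_kc": distribution_from_mean_ci(1.48, 1.21, 2.08),
        "p_thick": DistributionSpec(kind="beta", alpha=28.3, beta=51.7),
        "lag_years": DistributionSpec(kind="normal", mean=9.0, se=0.9),
        "mort_thick_year1": DistributionSpec(kind="normal", mean=0.0555, se=0.00555),
        "util_mult_thin": DistributionSpec(kind="normal", mean=0.93, se=0.0153),
        "util_mult_kc": DistributionSpec(kind="normal", mean=0.93, se=0.0153),
        "util_mult_thick": DistributionSpec(kind="normal", mean=0.837, se=0.0357),
        "cost_kc": DistributionSpec(kind="normal", mean=1348.0, se=134.78),
        "cost_thin": DistributionSpec(kind="normal", mean=1338.0, se=133.80),
        "cost_thick": DistributionSpec(kind="normal", mean=3182.0, se=318.19),
        "cost_melanoma_death": DistributionSpec(kind="normal", mean=4686.0, se=468.55),
        "cost_campaign": DistributionSpec(
            kind="scaled-beta", alpha=2.0, beta=5.0, lo=0.0, hi=3_339_807.0
        ),
    }


def default_owsa_bounds() -> list[OwsaBounds]:
    """Published one-way sensitivity bounds (worst case favours the status
    quo).  The joint low/high sunbed-use row is expressed through the
    ``prevalence_scale`` multiplier, which scales both sexes' age-18
    prevalence by a common factor (low 0.0098/0.043, high 0.0869/0.043)."""
    rows = [
        ("cost_campaign", 3_339_807.0, 0.0),
        ("prevalence_scale", 0.0098 / 0.043, 0.0869 / 0.043),
        ("rr_melanoma", 1.36, 1.85),
        ("mort_thick_year1", 0.0446, 0.0664),
        ("p_thick", 0.25, 0.46),
        ("post_ban_use", 0.03, 0.01),
        ("rr_kc", 1.21, 2.08),
        ("util_mult_kc", 0.96, 0.90),
        ("cost_kc", 1083.66, 1612.00),
        ("util_mult_thick", 0.91, 0.77),
        ("util_mult_thin", 0.96, 0.90),
        ("cost_thick", 2558.36, 3805.68),
        ("cost_thin", 1075.81, 1600.32),
        ("cost_melanoma_death", 3767.19, 5603.89),
        ("female_male_ratio", 1.3, 2.9),
    ]
    return [OwsaBounds(parameter=p, worst=w, best=b) for p, w, b in rows]


_CONFIG_SECTIONS = {
    "cohort",
    "parameters",
    "distributions",
    "owsa_bounds",
    "scenarios",
    "population",
}


class ModelConfig(BaseModel):
    """A fully resolved configuration: parameters plus PSA distributions,
    OWSA bounds, scenario settings and synthetic-population overrides."""

    model_config = ConfigDict(extra="forbid")

    params: ParameterSet
    distributions: dict[str, DistributionSpec]
    owsa_bounds: list[OwsaBounds]
    scenarios: dict[str, Any] = Field(default_factory=dict)
    population: dict[str, Any] = Field(default_factory=dict)

    def to_document(self) -> dict[str, Any]:
        """Serialize back to the configuration-document layout."""
        p = self.params.model_dump()
        cohort_keys = ("cohort_n", "prop_male", "n_cycles", "rng_seed")
        doc: dict[str, Any] = {
            "cohort": {k: p.pop(k) for k in cohort_keys},
            "parameters": p,
            "distributions": {
                name: {k: v for k, v in spec.model_dump().items() if v is not None}
                for name, spec in self.distributions.items()
            },
            "owsa_bounds": [b.model_dump() for b in self.owsa_bounds],
        }
        if self.scenarios:
            doc["scenarios"] = dict(self.scenarios)
        if self.population:
            doc["population"] = dict(self.population)
        return doc


def _validate_owsa(bounds: list[OwsaBounds]) -> None:
    fields = set(ParameterSet.model_fields)
    for b in bounds:
        if b.parameter not in fields:
            raise ConfigurationError(f"unknown OWSA parameter: {b.parameter!r}")
        for v in (b.worst, b.best):
            try:
                ParameterSet(**{b.parameter: v})
            except Exception as exc:  # pragma: no cover - message path
                raise ConfigurationError(
                    f"OWSA bound {v} outside legal domain of {b.parameter}: {exc}"
                ) from exc


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> ModelConfig:
    """Load and validate a configuration document.

    ``source`` may be ``None`` (all defaults), a mapping, or a path to a YAML
    file.  Unknown sections or parameter names are rejected; every value is
    checked against its domain invariant.
    """
    if source is None:
        doc: dict[str, Any] = {}
    elif isinstance(source, Mapping):
        doc = dict(source)
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigurationError(f"configuration file not found: {path}")
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        if not isinstance(doc, dict):
            raise ConfigurationError("configuration document must be a mapping")

    unknown = set(doc) - _CONFIG_SECTIONS
    if unknown:
        raise ConfigurationError(f"unknown configuration sections: {sorted(unknown)}")

    overrides: dict[str, Any] = {}
    for section in ("cohort", "parameters"):
        sub = doc.get(section) or {}
        if not isinstance(sub, Mapping):
            raise ConfigurationError(f"section {section!r} must be a mapping")
        for key, value in sub.items():
            if key not in ParameterSet.model_fields:
                raise ConfigurationError(f"unknown parameter: {key!r}")
            if key in overrides:
                raise ConfigurationError(f"parameter {key!r} given twice")
            overrides[key] = value
    try:
        params = ParameterSet(**overrides)
    except Exception as exc:
        raise ConfigurationError(str(exc)) from exc

    dists = default_distributions()
    for name, spec in (doc.get("distributions") or {}).items():
        if name not in PARAMETER_DOMAINS:
            raise ConfigurationError(f"no sampling domain for parameter {name!r}")
        dists[name] = spec if isinstance(spec, DistributionSpec) else DistributionSpec(**spec)

    raw_bounds = doc.get("owsa_bounds")
    if raw_bounds is None:
        bounds = default_owsa_bounds()
    else:
        bounds = [
            b if isinstance(b, OwsaBounds) else OwsaBounds(**b) for b in raw_bounds
        ]
    _validate_owsa(bounds)

    return ModelConfig(
        params=params,
        distributions=dists,
        owsa_bounds=bounds,
        scenarios=dict(doc.get("scenarios") or {}),
        population=dict(doc.get("population") or {}),
    )


def _in_domain(name: str, value: float) -> bool:
    lo, hi, lo_open, hi_open = PARAMETER_DOMAINS[name]
    if lo_open and not value > lo:
        return False
    if not lo_open and not value >= lo:
        return False
    if hi_open and not value < hi:
        return False
    if not hi_open and not value <= hi:
        return False
    return True


def draw_psa_sample(
    base: ParameterSet,
    distributions: Mapping[str, DistributionSpec],
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> ParameterSet:
    """One joint PSA draw: independently sample every parameter with a
    non-``fixed`` spec, truncating to its legal domain by resampling.

    The same generator state reproduces the identical draw.
    """
    update: dict[str, float] = {}
    for name, spec in distributions.items():
        if name not in PARAMETER_DOMAINS:
            raise SamplingError(f"no sampling domain for parameter {name!r}")
        if spec.kind == "fixed":
            if spec.mean is not None:
                update[name] = float(spec.mean)
            continue
        value = float(spec.sample(rng))
        tries = 0
        while not _in_domain(name, value):
            tries += 1
            if tries > max_retries:
                raise SamplingError(
                    f"could not draw a legal value for {name!r} "
                    f"after {max_retries} retries"
                )
            value = float(spec.sample(rng))
        update[name] = value
    return base.model_copy(update=update)
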