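# Methods

## Decision problem and model structure

The package evaluates, from the perspective of a national healthcare payer,
a policy that bans commercial indoor tanning (sunbeds) and funds a one-off
public information campaign, against the status quo of continued commercial
availability. The modelled population is the national cohort of 18-year-olds
(618 873 people, 51% male), followed for life.

The core is a cohort state-transition (Markov) model with one-year cycles
over 83 cycles (ages 18–101). Sixteen states are tracked:

- **no melanoma** — the lesion-free state everyone starts in;
- **thin melanoma** (Breslow ≤ 1 mm) — a one-cycle incident state;
- **thick melanoma** (> 1 mm) — a ten-slot tunnel: the incident cycle is
  tunnel year 1 and nine further slots encode years 2–10 since diagnosis,
  because the excess death risk depends on time since diagnosis;
- **post-thick (lifetime)** — after the tunnel, with a constant residual
  excess risk;
- **post-thin** — living after thin melanoma with a constant excess risk;
- **death from melanoma** and **death from other causes** (absorbing).

Keratinocyte cancer (KC — basal plus squamous cell carcinoma) is deliberately
*not* a state: it is an overlay event that any alive state can experience
each cycle, contributing a treatment cost and a one-cycle utility decrement
but no mortality and no state memory. Post-melanoma states carry no
quality-of-life decrement of their own, and second primary melanomas are not
modelled (post-melanoma states cannot re-enter the incident states); both
choices are conservative with respect to the intervention.

### Within-cycle conventions

Competing risks act on start-of-cycle occupancy. From the lesion-free state,
other-cause death (probability q) takes precedence and melanoma incidence i
applies to survivors: the incident split is (1−q)·i, divided thin/thick by
`p_thick` (0.354). In the melanoma states the excess death risks are additive
with q, with the excess capped at the surviving probability 1−q so that rows
always sum to one (the cap only binds in pathological configurations such as
q→1). Incident events during a cycle are discounted at the start of that
cycle; a unit of thick melanoma incident in cycle 0 therefore contributes its
full treatment cost undiscounted.

## Exposure and risk adjustment

Ever-use of a sunbed is the binary exposure. Registry-style incidence
includes sunbed-attributable cases, so arm-specific incidence is built in two
steps:

1. remove the attributable share with Levin's population attributable
   fraction, PAF = p(RR−1)/(1+p(RR−1)), where p is the *status-quo* lagged
   exposure prevalence (what the registry actually observed), giving a
   baseline b = registry·(1−PAF);
2. re-apply the arm's own exposure: incidence = b·[(1−p_arm) + p_arm·RR].

When p_arm equals the attribution prevalence this reconstructs the registry
column exactly (a property test asserts this to 1e−12). Relative risks are
1.59 for melanoma (applied only to ever-use accrued before age 35) and 1.48
for KC (ever-use at any age). Exposure acts after a deterministic 9-year lag,
implemented as a shift of the prevalence curve with linear interpolation (the
Normal(9, 0.9) uncertainty enters only through the PSA, not as
individual-level jitter).

Thick-melanoma excess mortality starts at 0.0555 in the year of diagnosis and
falls by 0.0055 per year through year 10 (reaching 0.006), then persists at
0.0056 for life; thin melanoma carries a constant 0.0056 lifetime excess. The
yearly sequence is floored at zero rather than validated against a strict
positivity constraint, because the published worst-case first-year risk
(0.0446) would otherwise be unrunnable. Excess deaths from both thin and
thick melanoma are counted as melanoma deaths.

## Valuation

QALYs: per-cycle utility is occupancy × age-specific EQ-5D-3L norm × state
multiplier (thin melanoma and KC 0.93, thick melanoma 0.837, death 0). When a
KC coincides with an incident melanoma cycle, only the larger decrement
applies — the per-state effective multiplier under KC probability k is
(1−k)·m + k·min(m, 0.93). Utility streams are half-cycle corrected by
trapezoidal averaging of adjacent cycle values and discounted at 3.5% per
year.

Costs (2019 GBP): one-off lump sums at the event cycle — KC £1348, thin
melanoma £1338, thick melanoma £3182, melanoma death £4686 — discounted at
3.5% but not half-cycle corrected (they are point events, not state streams).
The £1 000 000 campaign is a single undiscounted national payment at cycle 0
in the intervention arm. Event counts are reported undiscounted at national
scale.

Decision metrics at willingness-to-pay λ (default £20 000/QALY): ICER =
ΔC/ΔQ (reported only when the differences share a sign; dominance —
ΔC < 0 and ΔQ > 0 — suppresses it), NMB/INB = λ·ΔQ − ΔC, NHB = ΔQ − ΔC/λ
(= NMB/λ identically).

## Synthetic population tables

The original analysis drew its age/sex tables from national sources that are
not redistributable, so the package generates synthetic tables with the same
statistical structure. The printed 18-year-old anchors are exact; every other
age is synthetic and chosen once to be epidemiologically plausible for
England, not to reproduce registry values.

- **Mortality**: Gompertz–Makeham hazard h(a) = A + B·e^{C·a}
  (female A = 1e−4, B = 1.6e−5, C = 0.099; male A = 1.5e−4, B = 3e−5,
  C = 0.095), giving q(18) ≈ 2–3 per 10 000 and q(90) ≈ 0.11–0.14. The final
  modelled age is forced to probability 1. The generated table is interpreted
  as mortality *net of melanoma* (the melanoma-death component defaults to
  zero), so the other-cause subtraction is exercised only when a caller
  supplies an explicit component.
- **Cancer incidence**: log-linear in age with a plateau at 80. Melanoma is
  anchored at 5e−5 (18-year-old female) with slope 0.05/year (≈1.1e−3 at 80,
  lifetime risk ≈2–3%); KC at 1e−5 with slope 0.115/year (≈1.25e−2 at 80,
  lifetime risk ≈15–20%). Male columns are scaled by 1.1 (melanoma) and 1.3
  (KC).
- **EQ-5D-3L norms**: 0.929 at 18, declining piecewise-linearly by
  0.0005/year to 35, 0.002/year to 55, 0.003/year to 75 and 0.005/year
  thereafter (≈0.69 at 101), approximating published English population
  norms.
- **Ever-use prevalence**: starts at the printed age-18 values (female
  0.043, male 0.02) and accumulates by P(a+1) = P(a) + u(a)·(1−P(a)) with
  first-use hazard u(a) = u₀·(1−δ)^{a−18}. The male initial hazard u₀ is
  0.0125/year with year-on-year decline δ = 0.12; the female hazard is u₀
  times the female:male use ratio (1.76). These give lifetime ever-use of
  roughly 20% (women) and 11% (men), and ever-use by 35 of roughly 19% and
  11% — plausible for a cohort with declining tanning uptake. Under the ban,
  pre-ban ever-users retain their exposure, new commercial uptake stops, and
  a residual pool of 2% of the population (continued non-commercial use)
  accrues first use under the same hazard; intervention-arm ever-use
  therefore rises from the age-18 level towards that level + 2%. The
  `prevalence_scale` parameter multiplies the whole exposure propensity
  (age-18 level and hazard) so low/high-use sensitivity scenarios move all
  ages consistently.

What the synthetic tables do *not* emulate: cohort effects in tanning
behaviour, geographic or socioeconomic heterogeneity, registry undercount of
KC, and correlated uncertainty between tables. Passing tests therefore
demonstrate the correctness and internal consistency of the method — not a
re-estimate of the published national figures, which depended on the
original source tables.

## Sensitivity analyses

- **OWSA**: each parameter set to its published worst/best plausible bound,
  full rerun, ordered by worst-case INB (tornado ordering). The joint
  low/high sunbed-use row uses `prevalence_scale` (0.228 / 2.021, the factors
  implied by the printed low/high 18-year-old female values).
- **TWSA**: melanoma treatment costs ×{1.0..2.0 step 0.2} crossed with
  thick-melanoma mortality schedule ×(1−r), r ∈ {0..0.5 step 0.05}.
- **PSA**: independent joint draws (no published correlation structure);
  lognormals median-matched to the point estimates with log-SD from the
  published CIs; Beta(28.3, 51.7) for the thick proportion; truncated
  normals (resampled into the legal domain, max 1000 retries) for costs,
  multipliers, first-year mortality and the lag; Beta(2, 5) scaled to
  [£0, £3 339 807] for the campaign cost. Cost and multiplier SEs are not
  published; they are set from the plausible bounds treated as 95% intervals
  (≈10% CV for costs). The CEAC reports the fraction of iterations with
  NMB > 0 on a £0–£50 000 grid (£1000 steps). Default 5000 iterations; the
  packaged acceptance checks use 1000, which is ample for a probability
  estimate with binomial SE < 0.016.
- **Scenarios**: (i) a ban-anxiety utility decrement applied every alive
  cycle to the denied-user fraction (status-quo minus intervention-arm
  ever-use), with the NMB-zero cutoff found by bisection — NMB is linear in
  the decrement, so bisection matches the analytic root; the duration and
  target population of this decrement are modelling choices, so the cutoff
  value is scenario-specific; (ii) melanoma RR lowered to 1.2 and applied to
  all users (age cap lifted); (iii) campaign-cost thresholds (cost-neutral
  price and the price at which the ICER reaches λ), exact by linearity of
  the one-off campaign payment and verified by rerun to within £1;
  (iv) doubled melanoma treatment costs.

## Numerical choices and reproducibility

Mass conservation is enforced at every cycle to 1e−9. The cohort trace is
cross-validated against an explicit per-cycle matrix-product oracle (1e−10)
and against a 200 000-person microsimulation that walks individuals through
the identical per-cycle probabilities (agreement within 3 Monte-Carlo
standard errors for costs, QALYs and all three event counts). A single
master seed drives every stochastic component (PSA, microsimulation), and
identical configuration + seed reproduce byte-identical outputs; run
manifests record a configuration digest for verification.

## Known limitations

- Ever-use is binary; no dose–response in number of tanning sessions.
- No stage-specific progression beyond the thin/thick dichotomy and no
  treatment-pathway modelling; costs are lump sums.
- KC confers no mortality and no persistent morbidity.
- Synthetic tables cannot reproduce the original national results
  numerically; headline comparisons are directional (sign of ΔC and ΔQ,
  dominance, tornado ordering) plus arithmetic identities among published
  summary numbers.
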