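# sunbedban

Cost-effectiveness analysis of a nationwide ban on commercial indoor tanning
(sunbeds) combined with a public information campaign, compared with the
status quo, for the national cohort of 18-year-olds in England — from an NHS
perspective, in 2019 GBP, over a lifetime horizon.

The package is aimed at health economists and modellers who want a tested,
scriptable implementation of this decision problem: a 16-state Markov cohort
model of melanoma natural history (thin/thick dichotomy, a ten-year tunnel
encoding time since thick-melanoma diagnosis, melanoma and other-cause
death) with keratinocyte cancer (KC) as a costed, non-fatal overlay event.
Because the original age/sex source tables are not redistributable, a
synthetic-population generator produces mortality, incidence, EQ-5D norm and
sunbed ever-use tables with the same statistical structure, anchored exactly
to the published 18-year-old values.

## Model in brief

Exposure (ever-use of a sunbed, prevalence p) raises cancer risk by relative
risk RR (melanoma 1.59, restricted to first use before 35; KC 1.48), acting
after a 9-year lag. Registry incidence is first stripped of its attributable
share using Levin's population attributable fraction,

    PAF = p(RR − 1) / (1 + p(RR − 1)),

and arm-specific incidence is rebuilt as b·[(1 − p_arm) + p_arm·RR], so the
status-quo arm reproduces registry incidence exactly while the ban arm sees
the benefit of suppressed new uptake (a 2% residual-use pool remains).
Outcomes are discounted (3.5%/year), half-cycle-corrected QALYs and
discounted event costs; strategies are compared by ΔCost, ΔQALY, ICER (or
dominance), and net monetary / net health benefit at λ = £20 000 per QALY:

    NMB = λ·ΔQALY − ΔCost,    NHB = ΔQALY − ΔCost/λ = NMB/λ.

Uncertainty is handled by one-way and two-way deterministic sensitivity
analysis, four scenario analyses, and a probabilistic sensitivity analysis
(default 5000 iterations) with a cost-effectiveness acceptability curve.
See `docs/methods.md` for the full account.

## Worked example

```
$ sunbedban --out-dir demo run
                   estimate  current_situation                           intervention     difference
             melanoma_cases       1.478922e+04                           13939.936485    -849.280208
            melanoma_deaths       2.427502e+03                            2293.951078    -133.551069
                   kc_cases       1.072545e+05                          101359.082051   -5895.429892
             total_cost_gbp       2.913999e+07                        28606982.125605 -533003.697579
                total_qalys       1.411485e+07                        14115158.843799     306.721165
          icer_gbp_per_qaly                NaN not applicable (intervention dominant)            NaN
   net_health_benefit_qalys                NaN                              333.37135            NaN
incremental_net_benefit_gbp                NaN                         6667426.994217            NaN
The intervention dominates the current situation (lower cost, more QALYs).
```

Reading the output: on the packaged synthetic scenario the ban averts about
849 melanoma cases (5.7%), 134 melanoma deaths and 5895 KCs over the
cohort's lifetime; discounted treatment savings (£1.53m) exceed the £1m
campaign cost, so the intervention costs £533 004 *less* while adding 306.7
QALYs — it dominates, with an incremental net benefit of £6.67m (NHB 333.4
QALYs) at £20 000 per QALY. Magnitudes differ from the published national
analysis because the tables behind it are synthetic here; the qualitative
findings (dominance, the tornado ordering led by use prevalence and campaign
cost, robustness of cost-effectiveness) are reproduced.

Other subcommands: `generate-tables`, `owsa`, `twsa`, `psa`, `scenarios`,
`print-defaults`; global flags `--config`, `--seed`, `--out-dir`,
`--threshold`. Everything is also available as a library:

```python
from sunbedban import load_config, evaluate, run_psa

config = load_config(None)                 # published base case
result = evaluate(config.params)
print(result.incremental.nmb)              # 6667426.99...
psa = run_psa(config.params, config.distributions, n_iterations=1000, seed=1)
print(psa.prob_cost_effective(20_000))     # 1.0
```

## Layout

- `src/sunbedban/parameters.py` — parameter set, validation, PSA
  distributions, configuration I/O
- `src/sunbedban/population.py` — synthetic age/sex tables
- `src/sunbedban/risk.py` — attributable-fraction and lag adjustment,
  excess-mortality schedules
- `src/sunbedban/markov.py` — cohort engine, tunnel states, microsimulation
  oracle
- `src/sunbedban/outcomes.py` — discounting, half-cycle correction,
  QALY/ICER/net-benefit metrics
- `src/sunbedban/pipeline.py` — end-to-end evaluation
- `src/sunbedban/sensitivity.py` — OWSA, TWSA, PSA/CEAC, scenarios
- `src/sunbedban/cli.py` — command-line interface and run manifests
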