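# quitcea

Model-based cost-effectiveness analysis of a high-intensity (HIT) versus a
low-intensity (LIT) smoking-cessation programme:

- **`quitcea.parameters`** — parameter containers with invariant validation, a
  seeded synthetic parameter generator (the original calibration tables are
  not redistributable), sensitivity scenarios (including the conservative
  *low cost / low risk* scenario: costs −25%, disease risks −50%, death risks
  −10%, post-quit residual-risk fractions −0.1), and packaged CSV fixtures
  transcribing the published summary tables.
- **`quitcea.markov_engine`** — annual-cycle Markov cohort model (well, lung
  cancer, COPD, CHD, stroke, dead) run to age 95 for lifelong smokers and for
  quitters whose excess risk decays with time since quitting; discounted
  societal costs and QALYs; per-person quit benefits by sex and age.
- **`quitcea.effectiveness`** — logistic model of sustained abstinence on
  programme, gender and age: prediction, odds ratios with Wald CIs,
  maximum-likelihood fitting (statsmodels) and a synthetic trial simulator.
- **`quitcea.cea`** — incremental analysis: group-wise aggregation of quit
  benefits, net incremental cost, ICER with explicit dominance handling
  (`<0`, never a negative ratio), population-level per-person analysis, and
  CPI/PPP cost adjustment.
- **`quitcea.psa`** — probabilistic sensitivity analysis drawing the HIT quit
  rate from a truncated normal (or beta) matched to its 95% CI, with a
  Monte-Carlo cost-effectiveness acceptability curve and its closed-form
  counterpart.
- **`quitcea.cli_io` / `quitcea.cli`** — pipeline orchestration with
  provenance-stamped CSV writers and the `quitcea` command-line interface.

## Command-line usage

```sh
# summary incremental CEA table (fixture-driven), short or long follow-up
quitcea report --horizon short --out-dir results
quitcea report --horizon long --scenario low_cost_low_risk --out-dir results
quitcea report --config run.yaml          # YAML config; flags override

# cohort model with synthetic parameters (or --params <stem> from CSVs)
quitcea synth-params --seed 1 --out params
quitcea simulate --sex F --age 40 --status quitter --params params
quitcea quit-benefit --sweep --seed 1 --out quit_benefit.csv

# logistic layer and PSA
quitcea synth-trial --seed 2 --n-per-arm 150 --out trial.csv
quitcea cea --per-person --gender M
quitcea psa --runs 10000 --seed 7 --lit 0.07 --hit-ci 0.09,0.22 --wtp 0:20000:500
```

All written CSVs carry `#`-prefixed provenance headers (seed, config hash,
fixture registry); read them back with `quitcea.cli_io.read_report_csv`.

## Notes on reproduction

The published per-arm intervention-cost totals are rounded independently of
their printed difference (117 011 − 27 927 = 89 084 vs the printed 89 085);
the fixture pipeline therefore uses the printed difference cell, which
reproduces every printed incremental cell exactly. Long-term group-wise
aggregation of rounded per-person estimates lands within €5 / 0.01 QALY of
the printed totals, as the originals were accumulated from unrounded model
output.
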