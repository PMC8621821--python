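# vitdfort

A vitamin D food-fortification prevention-impact model: pools randomized-trial
evidence on cancer mortality, maps a daily fortification dose (IU) to expected
serum 25(OH)D increase and relative-risk reduction, and computes prevented
cancer deaths, preventable years of life lost (YLL), program costs, savings
and net savings under ±20% cost sensitivity scenarios. The packaged defaults
reproduce a Germany-2016 worked example.

## Modules

| module | role |
|---|---|
| `vitdfort.meta_pool` | DerSimonian–Laird random-effects pooling of study RRs (CI-derived SEs), leave-one-out sensitivity |
| `vitdfort.dose_response` | linear dose→serum model; piecewise-linear dose→RRR interpolation between trial anchors (no extrapolation) |
| `vitdfort.burden` | total and preventable deaths/YLL from age/sex-stratified mortality + life tables, or calibrated totals |
| `vitdfort.economics` | fortification costs (overrides or parametric), savings at a flat cost per prevented death, net savings, €/life-year |
| `vitdfort.scenario_engine` | orchestrates the 4-dose × 3-variant scenario grid; YAML config; CSV output |
| `vitdfort.synthetic_data` | calibrated synthetic mortality tables, life tables and simulated study sets |

The four modeled doses carry fixed base program costs (thousand €/year:
400 IU → 15,166; 600 → 17,493; 800 → 19,819; 1000 → 22,146); other doses
need a configured `population` for the parametric ingredient-cost formula.
The total death count (229,827) and the synthetic-table calibration
(total YLL ≈ 2.794 M person-years) are back-solved calibration constants,
not registry values.

## CLI

```bash
vitdfort pool                          # pooled RR from the packaged evidence base
vitdfort pool --exclude "Scragg 2018"  # leave-one-out
vitdfort grid --out table5.csv         # full 12-row scenario grid
vitdfort run --defaults --dose 800     # single scenario
vitdfort synth deaths --out deaths.csv # synthetic mortality table
vitdfort synth life --out life.csv
vitdfort synth studies --k 20 --seed 1 --out studies.csv
vitdfort burden --deaths deaths.csv --life life.csv --rrr 0.11
```

Scenario configuration is a YAML file (see
`src/vitdfort/data/default_config.yaml` for the schema and defaults);
`vitdfort grid` with no `--config` uses the packaged defaults and is
bit-identical across runs.

Grid CSV columns:
`dose_iu,cost_variant,serum_increase_nmol_l,rrr,deaths_prevented,savings_keur,cost_keur,net_savings_keur,eur_per_life_year`.

## Known reproduction caveats

Two published cells are off by one from any consistent rounding of the
printed inputs and are matched to ±1 only: the 13% prevented-death count
(printed 29,877 vs computed 29,878 = 0.13 × 229,827 rounded) and the 600-IU
20%-higher cost (printed 20,991 vs computed 20,992 = 1.2 × 17,493 rounded);
the latter propagates one euro-thousand into that row's net savings. A
least-squares fit of the four printed base costs (≈11.63 k€ per IU + 10,513
k€ intercept) is documented here for reference but not asserted anywhere.
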