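# Default scenario configuration (Germany-2016 worked example).
# Every key is optional; omitted keys use these packaged defaults.

serum:
  source: table5        # table5 (2.0 nmol/L per ug) | supplementation (1.95) | fortification (1.2)
  # slope: 2.0          # or set an explicit slope, overriding `source`

anchors:                # (dose IU/day, relative risk reduction) interpolation nodes
  - [400, 0.11]
  - [800, 0.15]
  - [2000, 0.17]

cost:
  unit_ingredient_cost: 0.11   # EUR per person-year of ingredient at 800 IU/day
  loss_fraction: 0.41          # vitamin destroyed in food processing
  loss_convention: divide      # required = delivered / (1 - loss); or `multiply`
  component_shares:
    ingredient: 0.80
    marketing: 0.08
    monitoring: 0.07
    other: 0.05
  # population: 83000000       # enables the parametric formula for doses without overrides
  cost_overrides:              # base program costs, thousand EUR/year
    400: 15166
    600: 17493
    800: 19819
    1000: 22146

cost_per_death: 40000          # EUR end-of-life cancer care per death

total_deaths: 229827           # calibrated total cancer deaths (back-solved anchor)
total_yll: null                # null -> computed from burden tables at run time
# mortality_csv: deaths.csv    # columns: sex,age_low,age_high,deaths
# life_csv: life.csv           # columns: sex,age,ex

doses: [400, 600, 800, 1000]
variants: [base, low20, high20]
seed: 0
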