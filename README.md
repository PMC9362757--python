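# saltiod

Compare national salt-iodization standards with the WHO 2014
salt-fortification guidelines, and link the result to population
iodine status.

Universal salt iodization is the main global strategy against iodine
deficiency disorders. The 2014 WHO guidelines suggest how much iodine
to add to food-grade salt as a function of a population's daily salt
intake, and which fortification compounds (potassium iodate, potassium
iodide) to use. National standards, however, state their own amounts,
ranges, and compound lists. `saltiod` is a small analysis library for
epidemiologists and fortification-program analysts that answers, for a
table of country records:

- **How much of the guideline does each standard meet?**
  `percent_met = 100 × midpoint / amount_WHO(s)`, where `midpoint` is
  the standard's recorded iodine amount (midpoint of a range or the
  single/minimum value, mg iodine per kg salt) and
  `amount_WHO(s) = round_half_up(150 · 1.3 / s)` mg/kg is the suggested
  amount at salt intake `s` g/day (the adult RNI of 150 μg/day plus 30%
  production-to-household losses).
- **Are the allowed compounds WHO-recommended?** Three-way
  classification: all / mixed / none recommended.
- **Do high standards translate into high urinary iodine?** An
  eligibility filter (≥ 70% household iodized-salt coverage, surveyed
  1–5 y before the mUIC assessment and > 1 y after the standard issued)
  selects countries where the standard plausibly determines intake;
  Pearson correlation of percent-met against median urinary iodine
  concentration (mUIC, adequate in 100–299 μg/L) follows.
- **Does the pipeline work end to end?** A synthetic country
  generator with a urinary-excretion forward model produces all input
  tables with known ground truth, so every stage is testable without
  any external download.

## Worked example

A country requires 30–50 ppm iodine in salt and its estimated salt
intake is 10 g/day:

```python
from saltiod import IodineSpec, extract_midpoint, percent_guidelines_met

spec = IodineSpec(form="range", low=30, high=50)   # mg iodine / kg salt
midpoint = extract_midpoint(spec)                  # 40.0
score = percent_guidelines_met(midpoint, salt_intake_g_day=10, mode="table")
print(score.who_amount_mg_kg, score.percent_met, score.category.value)
```

prints

```
20.0 200.0 above
```

— at 10 g/day the guidelines suggest 20 mg/kg, so a 40 mg/kg midpoint
meets 200% of the guideline: the standard requires double the
suggested amount. The `examples/` directory holds one short script
per capability (guideline table, scoring, compound classification,
eligibility + correlation, synthetic round trip); each prints its
numbers with a note on what they mean. For instance
`examples/05_synthetic_roundtrip.py` generates 110 synthetic countries
and reports

```
max |recovered - true| / true for percent_met: 2.05e-16
countries above the guideline: 100 (91%)  [uniform multiplier on [0.68, 3.50] predicts 89%]
with survey noise (sigma=0.15): r=0.940, p=1.36e-37, n=79
```

## Command line

The same pipeline is scriptable from a shell:

```sh
saltiod guideline-table --out table.csv
saltiod score --standards standards.csv --intake intake.csv --mode table --out scores.csv
saltiod simulate --n 110 --seed 1 --out sim/
saltiod report --standards sim/standards.csv --intake sim/intake.csv \
               --coverage sim/coverage.csv --status sim/status.csv --out report/
```

Input CSV schemas are documented in the reader docstrings
(`saltiod.io`); invalid rows are excluded with row-numbered
diagnostics and itemized exclusion counts, so every input row is
either scored or accounted for. Exit code 2 signals a validation
failure.

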