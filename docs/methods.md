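# Methods

## The guideline model

The WHO 2014 salt-fortification guidelines suggest an average amount of
iodine to add to food-grade salt as a function of estimated daily salt
intake. `saltiod` encodes the table together with its generating
formula

```
amount(s) = round_half_up( RNI · (1 + L) / s )    [mg iodine / kg salt]
```

with RNI = 150 μg/day (mean adult recommended nutrient intake) and
L = 0.30 (proportion of added iodine lost between production and the
household). With these defaults the formula reproduces all twelve
published table cells for s = 3..14 g/day (65, 49, 39, 33, 28, 24, 22,
20, 18, 16, 15, 14). Rounding must be *half-up*: the s = 10 cell is
19.5 → 20 and the s = 6 cell 32.5 → 33, which banker's rounding would
break. Ties make the table and continuous modes differ by exactly
0.5 mg/kg at s = 10, so the cross-mode agreement bound is ≤ 0.5, not
< 0.5.

The guidelines also cite a 92% iodine bioavailability. The published
amounts are fully reproduced by the RNI-plus-losses formula alone, and
the footnote's exact arithmetic involving bioavailability is not
recoverable, so the constant is carried on `GuidelineParams` for the
record but enters no computation.

Two evaluation modes exist because national salt-intake estimates are
real-valued while the table is integer-gridded. `continuous` (the
scoring default) evaluates the formula unrounded; `table` rounds the
intake half-up to the nearest grid integer, clamps to [3, 14] with a
warning, and returns the published cell. The mode is a recorded config
field so runs are reproducible.

## Standards normalization

Standards state iodine as a range, a minimum, or a single value. The
recorded amount is the midpoint of a range or the stated single value;
a bare minimum is treated as the single stated amount, matching the
one-number-per-standard convention of the global fortification
database this schema emulates. Amounts written as compound mass are
converted to elemental iodine by mass fraction (KIO3 0.5930, KI 0.7644,
from atomic masses K 39.098, I 126.904, O 16.000); conversion is
idempotent and invertible to 1e-9 relative. One standard is kept per
country; duplicates are logged and excluded. Free-text compound names
are canonicalized case- and punctuation-insensitively; unknown names
are preserved as opaque identifiers, logged, and treated as
non-recommended.

## Scoring

`percent_met = 100 × (midpoint / who_amount(salt_intake))`. The ratio
is computed before scaling so that a midpoint equal to the WHO amount
scores exactly 100.0 and lands in the `meets` category under the
default exact comparison; real data essentially never hit the
boundary, and a documented `meets_tolerance` (default 0) exists for
synthetic tests. Reports print percentages at 0 decimals; full
precision is retained internally. Aggregation produces category counts
and percentages, extremes with country labels, a scope cross-tab
(both-stream legislation vs single-stream), and the three-way compound
classification counts.

## Status linkage

Population iodine status is classified from median urinary iodine
concentration: < 100 μg/L insufficient, 100–299 μg/L adequate,
≥ 300 μg/L excessive. Eligibility for the score–status comparison
requires, per country: ≥ 70% of households consuming salt iodized to
any level; the mUIC assessment 1–5 years (inclusive) after the
coverage survey; and the survey strictly more than 1 year after the
standard was issued. Design choices where the rules were genuinely
open:

- **Reference year of multi-year surveys** is the survey *end* year
  (configurable to start or midpoint). The documented example country
  (standard 2000, survey 2012–2013, assessment 2017) is eligible under
  any of the rules.
- **The > 1 year clause anchors on the survey**, i.e. the survey must
  postdate the standard by more than a year, following the sentence
  order of the eligibility description.
- **Population priority** when a country has several mUIC surveys:
  school-age children, then women of reproductive age, then general
  population; the latest assessment wins within a group.
- Failed criteria are enumerated, never short-circuited, so exclusion
  accounting is complete.

The Pearson correlation between percent-of-guidelines-met and mUIC is
computed with `scipy.stats.pearsonr`; the two-sided p-value is the t
transform `t = r·sqrt((n−2)/(1−r²))` with n − 2 df (the test suite
checks both against a from-scratch covariance oracle at 1e-12).
Fewer than 3 joined pairs or zero variance raise typed errors. The
relaxed filter (`post_legislation_sac`) keeps countries with a
school-age-children assessment after the standard's issue year.

## Synthetic data generator

The generator emulates the structure of the country extracts the
pipeline consumes, with known ground truth. Per country it draws a
salt intake (normal, mean 10 g/day, SD 2.5, truncated to the 3–14
guideline span), a guideline multiplier m ~ Uniform[0.68, 3.50]
(chosen to span the 68%–350% score range observed across real national
standards), sets the standard midpoint to m × who_amount(s), and
synthesizes a range/minimum/single clause (default half-width 25% of
the midpoint). Compound mixes default to 74% all-recommended / 25%
mixed / 1% none-recommended and legislation scope to 96/110 both-stream,
mirroring the observed composition of real standards tables.

The forward model maps the standard to urinary iodine:

```
c    = midpoint · compliance · (1 − L)        household concentration, mg/kg
I    = s · c + baseline_diet_iodine           daily iodine intake, μg/day
mUIC = excreted_fraction · I / urine_volume   μg/L, × lognormal(0, σ) noise
```

with excreted_fraction 0.90 (the fraction of ingested iodine excreted
in urine), urine volume 1.0 L/day — deliberately the simplest choice,
and the single largest abstraction in the generator — baseline
non-salt dietary iodine 0, and σ = 0.15 survey noise. With
compliance = 1, m ≡ 1 and s ≡ 10 the noise-free model gives
mUIC = 0.90 × (10 × 19.5 × 0.7) / 1.0 = 122.85 μg/L: salt iodized at
exactly the guideline level yields adequate status. In continuous
mode the intake cancels (I = 0.7 · RNI · 1.3 · m), so mUIC depends
only on the multiplier, compliance and noise.

Note a quantitative consequence of σ = 0.15: the noise-free compliant
mUIC of 122.85 μg/L sits only 1.37 lognormal SDs above the 100 μg/L
adequacy floor, so the expected fraction of fully compliant countries
classified adequate is Φ(1.372) ≈ 0.915, not ≈ 1. The generator-level
test asserts this closed form rather than a rounder bound.

Survey and standard years are drawn so that a configurable fraction of
countries (default 0.8) satisfies every strict eligibility criterion;
each remaining country violates exactly one randomly chosen criterion.
The ground-truth table (multiplier, designed eligibility, category) is
written alongside but never read by the pipeline.

What the generator does *not* emulate: within-country heterogeneity
("pockets" of deficient or excess intake), survey weighting, partial
iodization below the standard, correlated missingness, or realistic
country-level covariance between intake and legislation age. Passing
round-trip tests therefore demonstrates that the pipeline inverts its
own stated model exactly, not that it is robust to every failure mode
of real monitoring data.

## Numerical and degenerate-input choices

- Half-up rounding via `Decimal` on the shortest float repr, avoiding
  binary-float tie artefacts.
- Year arithmetic on calendar-year integers; windows inclusive at both
  ends.
- `n_countries = 0` yields empty tables with headers; empty score
  lists, < 3 correlation pairs, and zero-variance vectors raise typed
  errors rather than NaNs.
- Same seed and config ⇒ byte-identical generated CSVs; same config
  and inputs ⇒ byte-identical pipeline outputs (plots excluded from
  the byte guarantee).
- Problem sizes in the test suite and examples: 110 synthetic
  countries (matching the scale of the real mandatory-legislation
  cohort), 20 seeds for cross-seed properties — all complete in
  seconds.

## Known limitations

- One standard per country; concurrent table-salt and food-industry
  standards are not modelled (duplicates are logged).
- The historical 1994/1996 guideline amounts and regional-body
  standards are out of scope as scoring baselines.
- mUIC is consumed as a published summary statistic; estimation from
  raw urinary microdata and survey weighting are out of scope.
- Scores computed under the continuous mode differ from table mode by
  up to the rounding of the published table (≤ 0.5 mg/kg in the WHO
  amount); both modes are exposed and recorded in run config.
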