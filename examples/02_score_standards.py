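"""Score a handful of national standards against the guidelines.

Each standard's recorded amount (midpoint of its range, or its single
or minimum value, converted to elemental iodine where needed) is
divided by the WHO suggested amount at the country's salt intake and
multiplied by 100.  100% means the standard matches the guideline;
200% means it requires double the suggested amount.
"""

from saltiod import (
    IodineSpec,
    aggregate_scores,
    extract_midpoint,
    percent_guidelines_met,
    to_iodine_basis,
)

countries = [
    # (code, iodine clause, salt intake g/d)
    ("XXA", IodineSpec(form="range", low=30, high=50), 10.0),
    ("XXB", IodineSpec(form="single", value=15), 9.0),
    ("XXC", IodineSpec(form="minimum", low=30), 6.0),
    # a standard written as mass of potassium iodate, not iodine
    ("XXD", IodineSpec(form="single", value=33.7, basis="compound",
                       basis_compound="potassium_iodate"), 10.0),
]

scores = []
print("country  midpoint mg/kg  WHO mg/kg  % of guideline  category")
for code, spec, intake in countries:
    midpoint = extract_midpoint(to_iodine_basis(spec))
    s = percent_guidelines_met(midpoint, intake, mode="table", country=code)
    scores.append(s)
    print(f"{code:>7}  {midpoint:>14.2f}  {s.who_amount_mg_kg:>9.1f}  "
          f"{s.percent_met:>14.1f}  {s.category.value}")

summary = aggregate_scores(scores)
print()
print(f"range across countries: {summary.min_percent:.0f}% ({summary.min_country})"
      f" to {summary.max_percent:.0f}% ({summary.max_country})")
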