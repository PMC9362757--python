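"""Generate the WHO 2014 suggested-amount table from its formula.

The suggested iodine concentration for salt fortification is the adult
RNI (150 μg/day) inflated by 30% production-to-household losses,
divided by daily salt intake, rounded half-up.  Each printed row is the
amount of iodine (mg) to add per kg of salt for that intake.
"""

from saltiod import who_iodine_amount, who_table

table = who_table()
print("salt intake (g/d)  iodine to add (mg/kg)  unrounded formula")
for intake, amount in table.entries.items():
    cont = who_iodine_amount(intake, mode="continuous")
    print(f"{intake:>17}  {amount:>21}  {cont:>17.3f}")

print()
print("A non-integer intake uses the continuous formula directly:")
print(f"  6.5 g/d -> {who_iodine_amount(6.5, mode='continuous'):.1f} mg/kg")
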