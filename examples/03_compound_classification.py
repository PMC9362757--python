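"""Classify standards' allowed iodine compounds against the WHO set.

The guidelines recommend potassium iodate (KIO3) and potassium iodide
(KI).  A standard is classified by whether all, some, or none of its
allowed compounds are recommended.  Free-text names are canonicalized
first, so "KIO3" and "Potassium Iodate" are the same compound.
"""

from saltiod import canonicalize_compound, classify_compounds

standards = {
    "XXA": ["KIO3", "Potassium Iodide"],
    "XXB": ["potassium iodate", "calcium iodate"],
    "XXC": ["sodium iodide"],
}

for country, raw in standards.items():
    compounds = [canonicalize_compound(c) for c in raw]
    category = classify_compounds(compounds)
    print(f"{country}: {raw} -> {compounds} -> {category.value}")
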