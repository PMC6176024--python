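"""Stratify signature derivation by experimental category.

Signatures can shift between species and between in vitro and in vivo
systems, so they are re-derived per category; categories lacking an
activator for some pathway record the gap instead of crashing.
"""

import toxsig as ts

matrix, _, activators, _ = ts.generate(ts.default_study_mimic(seed=1))
matrix, _ = ts.filter_by_max_time(matrix, 24.0)

keys = [
    ts.CategoryKey(tissue="liver"),
    ts.CategoryKey(species="human", tissue="liver", setting="in_vitro"),
]
for sigset in ts.stratified_signatures(matrix, activators, keys):
    sizes = {p.value: len(sigset.signatures[p]) for p in ts.PATHWAYS}
    print(f"category {sigset.category.label()}: signature sizes {sizes}")
    if sigset.missing_pathways:
        print("  no activator coverage for:", [p.value for p in sigset.missing_pathways])
# The synthetic default generates one category (human liver in vitro), so the
# liver-wide and human-liver-in-vitro strata coincide here; on mixed datasets
# each key selects a different condition subset.
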