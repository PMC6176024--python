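"""Generate a study-scale synthetic fold-change dataset with planted truth.

The generator plants pathway-responsive genes (activated and inhibited),
overlap genes shared between pathways, reference activator chemicals and
inert chemicals, under additive Gaussian noise, and returns the ground
truth alongside the data.
"""

import toxsig as ts

config = ts.default_study_mimic(seed=1)
matrix, catalog, activators, truth = ts.generate(config)

print(matrix)
print(f"chemicals: {len(matrix.chemicals())}, catalog genes: {len(catalog)}")
for p in ts.PATHWAYS:
    print(
        f"{p.value}: reference activators {activators.for_pathway(p)}, "
        f"{len(truth.zone_genes(p.value))} planted exclusive genes"
    )
print(matrix.values.head(3).to_string(index=False))
# Each value is a log2 fold change over a time-matched control; the planted
# exclusive genes respond only to chemicals activating their pathway.
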