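"""Score chemicals by chemical activation capacity (CAC) and classify them.

A chemical's CAC vector holds, per pathway, the mean log2FC of that
pathway's exclusive signature genes over the chemical's conditions.
Specificity is |cos α| between the vector and a pathway axis (cut-off
1/√3 ≈ 0.57735), potency is the vector module (cut-off 0.5), and ranked
lists order passing chemicals by their product.
"""

import toxsig as ts

matrix, _, activators, _ = ts.generate(ts.default_study_mimic(seed=1))
result = ts.analyze(matrix, activators)

print("pass counts:", result.classification.pass_counts())
for p in ts.PATHWAYS:
    ranked = result.classification.per_pathway[p][:3]
    print(f"{p.value} top hits:")
    for s in ranked:
        print(
            f"  {s.chemical:<22} cos={s.cos_alpha[p]:.3f} "
            f"module={s.module:.3f} score={s.score[p]:.3f}"
        )

scatter = ts.export_scatter_data(result.scores)
print(scatter.head(6).to_string(index=False))
# The scatter table holds the potency-vs-specificity coordinates of every
# chemical for every pathway; 'passes' marks chemicals beyond both cut-offs.
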