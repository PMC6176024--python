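# Methods

## Model and assumptions

The analysis treats a toxicogenomic dataset as a sparse condition × gene
matrix of log2 fold changes over time-matched controls, with categorical
condition metadata (chemical, species ∈ {human, rat}, tissue ∈ {liver,
kidney}, in vitro/in vivo, bolus/repeated dosing, exposure time in
hours, a free-text dose label). Three assumptions underpin every stage:

1. **Additivity of reporting.** A gene's response to a chemical is
   summarized by arithmetic means of log2FC values; no dose–response or
   time-course model is fitted. Averaging over an activator's conditions
   and then over activators (mean of means) keeps unequal condition
   counts per activator from dominating the pathway profile; the two
   orders coincide only when condition counts are equal.
2. **Reference activators are faithful.** The signature of a pathway is
   whatever responds consistently to chemicals designated as specific
   activators of that pathway at ≤ 24 h exposure. If an "activator"
   engages other pathways at the tested doses, that contamination passes
   into the signature by construction.
3. **Outlyingness = membership.** A gene belongs to a signature when its
   average activation value is extreme relative to the whole gene pool
   (outside μ ± 2σ), not relative to a null model or replicate variance.
   The candidate pool for every pathway is the union of all genes with
   data (not each pathway's a-priori curated list), which is why a gene
   can end up in a signature of a pathway it was not curated under;
   a-priori membership is carried as reporting metadata only.

## Parameters

| Parameter | Default | Units | Why |
| --- | --- | --- | --- |
| `max_hours` | 24 | h | exposures beyond 24 h mix stress responses; the 24 h point itself is kept ("after 24 h" is strict) |
| `sigma_mult` | 2 | σ | the two-sided 2σ tail rule; configurable for sensitivity analysis |
| `ddof` | 0 | — | σ is the population SD; N vs N−1 is immaterial at ~800 genes but the choice is pinned and configurable |
| `cos_cutoff` | 1/√3 ≈ 0.57735 | — | beyond it a point can be nearer one of three orthogonal axes than the other two |
| `module_cutoff` | 0.5 | log2FC | minimum overall potency ‖OK‖ |
| scoring category | human / liver / in vitro | — | the risk-assessment-relevant category |

Both cut-offs are strict inequalities; a vector exactly on a boundary is
rejected. Ordering ties (equal |value| or equal score) break
alphabetically so all outputs are deterministic.

## Numerical and degenerate-input policies

* Blank fold-change cells mean *not measured* and are skipped by every
  mean; they are never imputed as 0. Genes with no data under any of a
  pathway's activators are excluded from that profile (and reported).
* σ computed from identical values is snapped to exactly 0 (clearing
  rounding dust below 1e−12 relative to the value scale); with σ = 0 the
  strict inequalities yield an empty signature plus a warning.
* A value above μ + 2σ that is still ≤ 0 (possible when μ is very
  negative) is not "activated"; the sign guard is symmetric for
  inhibited genes.
* A chemical with no measurement on some pathway's exclusive genes gets
  a null coordinate and is excluded from classification into a
  "not scorable" list — treating the null as 0 would fabricate
  specificity for the remaining axes. The zero CAC vector likewise has
  undefined direction and is specific to nothing.
* Chemical names are matched case-insensitively after whitespace
  trimming, with no fuzzy matching: a silently merged pair of distinct
  chemicals is worse than a reported miss.

## The nearest-axis rule in classification

The 1/√3 specificity cut-off is motivated by axis proximity: among three
orthogonal axes, a point strictly nearer one axis than the other two has
|cos α| > 1/√3 with it. The converse fails — e.g. (0, 1, 1) has
|cos α| = 1/√2 > 1/√3 with two axes at once — so thresholding alone does
not guarantee one pathway per chemical (that would need a cut-off of
1/√2). Classification therefore additionally requires the pathway to be
the chemical's strictly largest |cos α| (an exact tie means equidistant,
hence specific to neither). Wherever only one cosine clears the cut-off
— the generic case — this coincides with plain thresholding; it differs
only for points nearly equidistant between two axes, which plain
thresholding would list twice.

## Synthetic data: what it emulates and what it does not

The generator produces the long-format table the pipeline consumes from
an additive model: value = Σ_p a_p(chemical) · e_p(gene) + ε, with
i.i.d. Gaussian ε (optionally Student-t with 3 df, rescaled, to
stress-test the 2σ rule against heavy tails) and an optional
missing-cell mask. Planted genes occupy the seven Venn zones with
per-zone, per-pathway effect signs; background genes have all effects
zero. One `numpy` Generator is seeded per call and consumed in a fixed
documented order (effect magnitudes → noise → missing mask), so outputs
are bit-reproducible.

The `default_study_mimic` configuration pins the study conditions used
throughout the tests: 800 background genes; 30 exclusive planted genes
per pathway at |effect| = 1.0 in log2FC units; overlap zones of sizes
5 / 7 / 1 / 1 (AhR∩Nrf2 / Nrf2∩ATF4 / AhR∩ATF4 with discordant signs /
triple, inhibited); 160 chemicals — five reference activators named
after the classical pathway activators at potency 1.0, three selective
probes at potency 0.8, two equipotent probes at (0.5, 0.5, 0.5), 150
inert; four time points (2, 8, 24, 72 h) of which the 72 h point exists
to give the 24 h filter real work, leaving 3 conditions per chemical;
noise SD 0.1 per condition × gene; 2% missing cells.

The 27 activated / 3 inhibited split of each exclusive zone encodes the
design position that activator responses are dominated by up-regulated
target genes. It fixes the exclusive-zone mean effect at
(27 − 3)/30 = 0.8, so a fully selective activator of potency 1 has an
expected on-axis CAC of 0.8 and a 0.8-potency probe lands at 0.64 —
comfortably past the 0.5 potency cut-off. Because CAC is a plain mean
over a mixed-sign gene set, a more balanced split (real signatures run
50–63% activated) shrinks every chemical's CAC proportionally: at
15/15 the same activator's CAC would be 0, an intrinsic cancellation
property of the unsigned mean that users should keep in mind with
inhibition-heavy signatures.

What the generator does **not** emulate: probe-level microarray
intensities, normalization or batch artifacts, correlated noise across
genes or conditions, dose–response structure (the activation vector is
constant across a chemical's conditions), or co-regulation between
pathways beyond the planted overlap genes. Passing recovery tests on
this model therefore demonstrates that the pipeline's arithmetic and
thresholds do what they claim under the stated noise — not that the 2σ
rule is robust to the full error structure of real expression data.

### A boundary property of equipotent chemicals

An exactly equipotent chemical (equal expected CAC on all three axes)
sits precisely on the |cos α| = 1/√3 decision boundary. Under any
non-zero noise, one noisy coordinate is strictly largest with
probability 1, lifting that axis's |cos α| slightly above the cut-off
while the module (≈ 0.87 × mean effect) clears 0.5; the chemical is then
classified to one noise-selected pathway. Rejection of exactly
equipotent chemicals is therefore a noiseless-limit property (where the
strict inequality excludes the boundary), and the noiseless end-to-end
test asserts it there. On real data "equipotent" chemicals are never
exactly so, and the practical reading is that classifications with
|cos α| barely above 1/√3 are not robust.

## Problem sizes

The test suite and the reproduction script run the full pipeline on the
study-mimic scale (904 genes × 640 conditions, 160 chemicals) across 20
generator seeds, and brute-force oracle comparisons on 50-gene ×
30-condition matrices across 20 seeds; these sizes were chosen as the
smallest that exercise every code path at the study's structure.

## Known limitations

* The unsigned-mean CAC cancels between activated and inhibited
  signature genes (see above); a signed or two-channel score would avoid
  this but is out of scope.
* Overlap-zone genes are discarded for scoring, which can weaken
  detection of pathways whose strongest responders are shared (the Nrf2
  prototypical genes tend to co-respond with AhR activators via
  metabolic coupling).
* Signatures inherit any non-specificity of the reference activators;
  no deconvolution is attempted.
* Stratified signatures are derived independently per category; no
  shrinkage or sharing across categories.
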