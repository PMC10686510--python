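# Methods

`fsmatrix` scores domestic upholstered furniture product types for two
things at once: *relative* fire risk (injury and property damage) and
*relative* potential for human exposure to chemical flame retardants
(CFRs) while the furniture is in use. Both models consume structured
evaluator questionnaires — there is no laboratory measurement anywhere
in the pipeline — and both therefore rank product types against each
other rather than estimating absolute probabilities or doses. The point
of the reconciliation stage is to find coherent groups of product types
that combine low fire risk with high exposure potential, the region of
the matrix most relevant to deciding which products need chemical flame
retardancy at all.

## Fire-risk model

Fire injury is modelled as a failure chain: contact with an ignition
source must precede ignition, ignition must precede spread, and spread
must coincide with a user unable to react. Each link is one model
dimension on a 1–5 scale:

- **Contact** (Likert 1–5): likelihood the item meets an ignition
  source.
- **Ignition**: composite of two inputs. The *junction count* — the
  number of horizontal/vertical upholstery joins a smouldering object
  could lodge in — is transformed by the piecewise map 0→1, 1→2, 2→3,
  3→4, ≥4→5; four junctions make an open box, from which a dropped
  ignition source cannot roll anywhere except into a junction, so the
  score saturates there. *Ornateness* (Likert 1–5) captures catch-points
  offered by surface and shape. Junctions only matter for ignition
  sources that can fall into them, so the junction score enters only
  when the evaluators' free-text ignition narrative mentions candles or
  smokers' materials (word-initial stem match against a configurable
  lexicon: cigarette, smoker, smoking, candle, lighter, match, pipe).
- **Spread**: combustible volume (m³) mapped linearly onto 1–5 with
  saturation at 0.009 m³ — the volume of a small cushion, above which
  post-ignition flame spread is assumed guaranteed. The intercept at
  zero volume is fixed at 1 so the transform shares the Likert floor.
- **Reactivity** (Likert 1–5): likelihood the user cannot detect and
  escape a fire (sleep, intoxication, age, disability).

The aggregate is the **lowest quartile** of the dimension scores
(type-7 linear interpolation between order statistics by default,
configurable): weighted toward the weakest links of the chain without
letting the single lowest score dictate the output, which would be too
deterministic given the uncertainty of the inputs. Injury risk uses all
four dimensions; damage risk drops reactivity.

How junction and ornateness merge into the ignition dimension is a
genuinely open design point. The default takes their arithmetic mean
when the narrative gate is active and ornateness alone otherwise;
two alternatives are selectable through `ThresholdConfig.ignition_rule`
(`mean-zero`: a gated-out junction contributes a literal zero to the
mean; `pooled`: junction and ornateness enter the quartile pool as
separate values). All three preserve the monotonicity property checked
by the test suite: raising any raw input never lowers a risk score.

## CFR-exposure model

Five dimensions, equal weights: likelihood of use by a young child
(small children have high surface-area-to-body-weight ratios and are
the most susceptible users), bare-skin contact (dermal migration),
mouthing (oral migration), cumulative use (duration of contact) — all
Likert 1–5 — and surface area (m²), log-transformed onto 1–5 so that
small changes in small items count as much as large changes in large
items. The log anchors default to 0.05 m² → 1 and 10 m² → 5, chosen so
a realistic catalogue (cushion face to large sofa envelope) spans the
scale; they are stand-ins, configurable, and none of the reference
checks depend on them. With `sa_integer_binning` (default) the area
score is rounded half-up to a whole point, which keeps five-dimension
means on a 0.2 grid — the granularity the reference score table shows.
The overall score is the arithmetic mean: there is no empirical basis
for weighting one route of exposure over another.

## Consolidation

In the original study three evaluators scored independently and then
reached consensus in a moderated session; no arithmetic rule exists for
that discussion. The reproducible stand-in is a per-field median with
half-integer medians rounded *up*, i.e. toward higher risk
(`consensus_rule="median-round-half-up"`; a plain mean is selectable).
Junction counts round to the nearest integer (half up); narratives are
concatenated, so a lexicon mention by any evaluator gates the junction
score in. Consolidation is permutation-invariant in its inputs.
Genuinely missing cells (they occur in the published external-panel
table) stay missing and are excluded per field, never imputed as zero.

## Reconciliation

Each product type is evaluated as a relatively low-risk and a
relatively high-risk example item; the type's score per output is the
mean of the two and its range their spread. Inversions — the "low"
variant outscoring the "high" — are real (evaluators judge variants
independently per dimension) and are preserved. Types are then:

1. **ranked** per output (stable descending sort, ties broken
   lexicographically by type id for determinism);
2. **placed in quadrants** of the injury × exposure plane. Thresholds
   default to the midrange of each axis (median or explicit values
   selectable); a point exactly on a threshold counts right/upper. The
   upper-left quadrant — low fire risk, high exposure potential — is
   the policy-relevant region. Low/high ranges are drawn as ellipses
   around each mean;
3. **clustered** agglomeratively on Euclidean distance in
   (injury, damage, exposure) space. The dendrogram is cut at height
   0.56 (the published cut); leaves joined by merges strictly below the
   cut form clusters, unlinked leaves are outliers. The linkage behind
   the published dendrogram is not stated; the default is average
   linkage with all four standard linkages selectable, and
   `reproduce_reference_clusters` runs the cut under every linkage and
   reports adjusted-Rand agreement with the published five-group
   partition. Because the per-type damage coordinates were never
   printed, that experiment runs on the published (injury, exposure)
   coordinates only; it is reported as a validation experiment, not
   asserted as an exact reproduction. Trees export to Newick with
   branch lengths equal to merge-height differences (ultrametric under
   monotone linkages).

## Sensitivity analysis

Contact likelihood is the most judgement-dependent input. The sweep
imputes a systematic under-estimation of 1–4 points on every item's
contact score, capped at 5, and recomputes injury risk; per item the
scores are non-decreasing in the imputed error by construction. For
plotting, a seeded uniform jitter of ±0.05 is added to the coordinates
only — stored scores are never jittered. Cluster distinctness per error
level is quantified by `separation_statistic`: the best mean silhouette
over all contiguous k-splits of the sorted one-dimensional scores. On
synthetic panels k = 3 is used, matching the three generator
archetypes; the statistic declines as the cap compresses the score
bands, mirroring the qualitative observation that clusters blur once
the error reaches about 3 points. The external-panel comparison
computes signed differences (external − team) per category and item,
propagating missing cells, and flags whether each category's maximum
absolute difference stays within a tolerance; on the published
four-type panel table the largest contact gap is 3 points (pet-bed high
variant), so the within-2-points flag is honestly `False` there.

## Synthetic data

The generator emulates the study design, not its numbers: ~30 product
types, two variants each, three evaluators, with latent archetype
profiles (`child-product`, `resting-furniture`, `small-accessory`)
capturing the contrasts that drive the real matrix — child products
high on child use/mouthing but low on smoking-related contact, resting
furniture the reverse, accessories low on most dimensions. Evaluator
ordinals are the latent mean plus Gaussian noise (default sd 0.5,
about half a Likert point), rounded half-up and clamped to [1,5] — the
simplest noise model that produces the low/high inversions seen in real
panels; volumes and areas get multiplicative log-normal noise around
exact latent values; narratives are drawn from two template sentences
(with/without lexicon stems) with an archetype-specific mention
probability. At zero noise every evaluator reproduces the latent
profile exactly, which anchors the round-trip tests. `plant_clusters`
places k centroids at a guaranteed separation inside the [0,5]³ score
cube for cluster-recovery experiments with known labels.

What passing tests on synthetic data do *not* show: that real evaluator
noise is Gaussian, independent across dimensions, or free of the shared
training effects the consolidation session creates; nor that the three
archetypes exhaust real catalogue structure. They show that the
pipeline's arithmetic is correct and that its cluster-recovery behaviour
is as designed under known ground truth.

## Numerical choices and problem sizes

Quartiles: `numpy.percentile` with method `"linear"` (type 7) by
default; all numpy estimators selectable. Distances and linkage:
`scipy.spatial.distance.pdist` / `scipy.cluster.hierarchy.linkage`
(deterministic given the input). Rounding is half-up everywhere a rule
is needed (consolidation, surface-area binning, ordinal discretisation)
— ties break toward higher risk. Degenerate inputs raise rather than
guess: empty quartile pools, all-identical separation inputs, degenerate
midrange axes, k ≥ n splits. Test and experiment sizes are kept at the
scale of the real catalogue (30 types / 60 items; 10–20 replicates for
recovery experiments), which runs the whole suite in seconds.

## Known limitations

- Scores are relative; the package deliberately offers no absolute
  fire-probability or CFR-dose interpretation.
- The exact arithmetic behind the published per-dimension worked scores
  (e.g. values such as 4.63) depends on unpublished supplementary
  worksheets; the package reproduces the published transforms, means,
  rankings and extrema, but not per-dimension values it cannot see.
- The published dendrogram's linkage and the quadrant thresholds are
  unstated; both are configurable and the defaults are documented
  choices, not recovered facts.
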