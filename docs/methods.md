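# Methods

This note records the models, parameter choices and numerical conventions
behind `kscope`, and what the synthetic-cohort tests do and do not
establish.

## Questionnaire scoring

Category totals sum present item values (1–4) plus 2.5 points per
unanswered item. Bonuses are added to the total *before* the threshold
comparison, so a bonus is exactly equivalent to shifting the threshold:
S +4 (listed skin condition), P +5 (sunlight aggravates moles), W +5
(age strictly over 65). Axis calls use the ≥ rule only — half-point
totals that fall between the published high/low bounds (possible with
missing items, e.g. an S total of 29.5) are classified low, because only
the ≥ threshold is operative. The four published category sizes sum to
59, one short of the 60-item instrument; the scorer therefore accepts an
unscored 60th item (tag `X`), and the synthetic generator emits exactly
that layout. The condition/mole flags are caller-supplied booleans, not
inferred from item content, since no item mapping is published.

## Metric integration

* **Replicate averaging** is a NaN-aware arithmetic mean over all raw
  columns mapped to one parameter (site means and replicate means agree
  here because replicate counts per site are balanced). A parameter with
  all replicates missing stays NaN — flagged missing, never silently zero.
* **ITA** uses the standard CIELAB definition arctan((L\*−50)/b\*) in
  degrees; a\* is carried but unused. b\* = 0 maps to ±90° by the sign of
  L\*−50, and 0° when both vanish.
* **Representative selection** maximizes the mean |Pearson r| with the
  other members of the parameter's category; singletons pass through; exact
  ties break to the lexicographically smaller name (deterministic, and
  two-member categories therefore resolve by name). Correlations are
  pairwise-complete; zero-variance columns give flagged-NaN entries.
* **Normalization is rank-based**, score = 10(rank−½)/n with average ranks
  for ties: the cohort mean is pinned at 5 ("relative average" semantics),
  any strictly monotone rescaling of a raw metric leaves scores unchanged,
  and a constant metric scores 5 everywhere. Min–max scaling was rejected
  because device scales differ arbitrarily across parameters.
* **Severity direction is preserved** (higher pore/wrinkle score = more
  severe); composites are unweighted means of their two member scores, as
  no weighting is defensible a priori.

## Cutotyping and aging groups

Tertile boundaries sit at the ⌈n/3⌉ and ⌈2n/3⌉ order statistics; ties
share the lower band, which keeps the cut deterministic. A subject with
either composite in the middle band is gray-zone; gray subjects are
reassigned per composite by strictly-above-mean → H (a value exactly at
the mean is not "above" it, hence L).

Proportion curves are computed per single year of age over the whole-cohort
tertile bands (upper/lower/middle — upper + lower < 1 in general, which is
why halves are not used), smoothed with a centred moving average (window 3,
window 1 = identity). Crossing detection tracks the *established* ordering
of the two curves: a crossing is an age where the ordering flips and the
new ordering persists for the next 2 observed ages. A blip that fails
persistence does not reset the established state, so the end of a
transient excursion is not itself reported as a crossing. Crossings in
both directions are reported with their direction, because the oil
criterion genuinely crosses twice (upward in adolescence, downward in the
fifties) and the downstream rule needs the second one: c1 is the first
tone/elasticity crossing, c2 the first oil/moisture crossing after the age
of maximal smoothed upper-band oil proportion, and c1 < c2 is enforced.
Aging groups: Young ≤ c1−1, Aging I c1..c2−1, Old ≥ c2.

## Microbiome

* **Rarefaction** draws a multivariate hypergeometric per sample (exact
  without-replacement subsampling), drops and records samples below depth,
  and is deterministic per seed. Default depth 1391.
* **Alpha diversity**: Shannon uses log base 2; Pielou H/log₂S is
  base-invariant and flagged NaN for single-genus samples; Chao1 uses the
  bias-corrected F₁(F₁−1)/(2(F₂+1)) form.
* **Generalized UniFrac** follows the variance-adjusted family: branch
  terms weighted by (p+q)^α, α ∈ [0,1], branches absent from both samples
  skipped. α defaults to 0.5 — the canonical middle setting, since no
  value is otherwise specified; α = 1 reproduces weighted-normalized
  UniFrac (verified in tests against an independent implementation to
  1e-9). Unweighted UniFrac shares the traversal with presence/absence
  profiles.
* **PAM** is greedy BUILD plus best-improvement SWAP; all ties break to
  the lowest sample index, making the partition deterministic for a given
  matrix. The objective (sum of within-cluster distances to medoids) is
  non-increasing across SWAP steps, which a test asserts directly.
* **Optimal k** takes the modal vote of four indices, ties to the smaller
  k: Calinski–Harabasz on the first min(10, n−1) principal coordinates
  (CH needs coordinates; PCoA of the distance matrix is standard for
  distance-only data), mean silhouette on the distance matrix, the WSS
  elbow (argmax of the second forward difference, anchored by the k = 1
  solution), and prediction strength (10 random halvings, per-halving
  minimum over test clusters of pair co-membership agreement, averaged;
  the vote is the largest k with PS ≥ 0.8, or 1 — "no supported split" —
  when none qualifies). The full vote table is always returned: on a
  single homogeneous cloud the coordinate-based indices can still force a
  consensus ≥ 2, and the table is the diagnostic for that disagreement.
* **Divide-and-compare subclustering** re-runs the consensus on each top
  cluster's restricted distance matrix and splits only when the consensus
  is ≥ 2 *and* the split's mean silhouette is ≥ 0.25; samples with a
  negative silhouette at either level are set aside as unclassified
  rather than forced (an explicit stand-in for the original tool's
  unclassified handling, whose criterion is unpublished).
* **Core genera**: default prevalence mode (detected in ≥ 50 % of all
  samples) with a cumulative-abundance alternative (smallest set of top
  mean-abundance genera jointly comprising 50 % of the community), since
  both readings of "50 %" occur in practice. The differential filter is
  raw Kruskal–Wallis p < 0.05 (tie-corrected H, χ² with g−1 df);
  Benjamini–Hochberg is available but off by default to match the usual
  unadjusted-screen convention.
* **PERMANOVA** uses the squared-distance pseudo-F with
  p = (1 + #{F\_perm ≥ F\_obs})/(1 + n\_perm), 999 permutations by
  default, seeded. Single-member groups are allowed but warned about.
* **LEfSe-style scoring** is a documented simplification: a
  Kruskal–Wallis screen (α = 0.05) followed by bootstrapped (30 × ⅔
  subsamples) one-dimensional discriminant effects — for one feature the
  LDA projection difference reduces to the class-mean difference — scored
  as log₁₀(1 + |Δ| · 10⁶) on the relative-abundance scale and thresholded
  at 2.0. Exact parity with the original tool is a non-goal.
* **Pairwise differential matrices** (the rank-based stand-in for
  bias-corrected compositional testing): CLR with pseudocount 0.5 on
  counts, two-sided Wilcoxon rank-sum per strata pair,
  Benjamini–Hochberg within genus across pairs, entries
  sign(median CLR difference) · (−log₁₀ p\_adj), antisymmetric in pair
  order, masked at |entry| > 1.

## Prediction models

The classifier is a pluggable contract (fit / predict\_proba /
feature\_importances\_); the default binding is scikit-learn's
`GradientBoostingClassifier` (seeded; gain-based importances), recorded in
run metadata. SMOTE interpolates uniformly toward one of the k ≤ 5
nearest minority neighbours, so synthetics cannot leave the minority
convex hull; a single-sample minority falls back to duplication with a
warning. Splits are stratified 80/20 (class ratios preserved within one
count). AUC is the Mann–Whitney statistic with half-credit ties (equal to
exhaustive pairwise comparison, asserted in tests); micro-averaging pools
all one-vs-rest pairs, macro-averaging means per-class AUCs. A seeded
random hyperparameter search (n trials, 5-fold CV, optimizing AUC) is
built in but defaults to 0 trials: at desk scale the default
hyperparameters are already past the data's discriminability ceiling, and
the search budget belongs to real-cohort runs. Types with fewer than 5
samples on either side of a one-vs-rest split are skipped with a warning.
Samples with flagged-missing features (pediatric wrinkle scores) are
dropped with a warning before fitting.

## Synthetic cohort: what it emulates and what it does not

The generator is the stated world the tests run in:

* **Ages** uniform on 0–88; sex is a single covariate (default 80 %
  female) with no effect on any other draw.
* **Trend paths** are decade medians, linearly interpolated: tone (ITA)
  48 → 32.2°, elasticity (R7 × 100) 67 → 38, oil unimodal peaking ≈ 37 at
  age 30 then falling to ≈ 6, hydration age-flat (55 ± 8 a.u.). Noise is
  Gaussian on the natural scale, truncated to plausible ranges
  (R-ratios in [0, 1.5], L\* in [0, 100]).
* **Correlated blocks** make the representative-selection rule meaningful:
  R2/R5 load ≈ 0.9 on R7 with R weakly attached; colour indices load on
  ITA; nasolabial roughness is the strongest of the three wrinkle
  parameters. Wrinkle parameters are missing under age 10.
* **Community structure**: three Dirichlet-multinomial profiles over 30
  genera — two Streptococcus-dominant subcommunities (one enriched in
  Staphylococcus/Neisseria/Fusobacterium/Gemella/Prevotella/
  Granulicatella/Porphyromonas/Leptotrichia, the other in Rothia/
  Corynebacterium/Actinomyces/Lactobacillus/Lautropia) nested inside one
  top cluster, and a Cutibacterium-dominant cluster with no nesting.
  Mixing weights 0.34/0.37/0.29; concentration 150; depth Poisson(5000)
  so rarefaction at 1391 is exercised. Exactly 17 genera are planted
  above 50 % prevalence; 15 differ between subcommunities and 2
  (Haemophilus, Veillonella) are held at identical profile probabilities,
  so the core-genus filter has the known answer 17/15 (up to the
  irreducible α = 0.05 type-I error on the two homogeneous genera). The
  subcommunity contrast is deliberately scaled so that top-level
  clustering sees two communities (prediction strength rejects k = 3
  cohort-wide) while the restricted split remains separable — the regime
  in which recursive subclustering is the tool that finds the nesting.
  On a minority of seeds the restricted split falls below the silhouette
  gate and is (correctly, per the gate) withheld; recovery assertions
  therefore fix seeds or take modes across seeds.
* **Planted crossovers** redraw the criterion's raw measurement block
  (including dependent readouts) from a high regime with probability 0.85
  before the planted age and 0.15 from it onward — sharp enough that the
  modal detected crossing equals the planted age at n = 2000 (≈ 22
  subjects per year of age), with occasional ±1-year detections from
  single-year sampling noise.
* **Tree**: random coalescent-style topology over the genus labels with
  exponential branch lengths — generalized UniFrac needs *a* tree; the
  topology is otherwise unconstrained and carries no planted signal.
* **Questionnaire**: category latent traits tied to the matching
  biophysical percentile (oiliness ← sebum, pigmentation ← darker tone,
  wrinkle ← roughness/age; sensitivity independent), item values
  1 + Binomial(3, p).

What a green synthetic test does **not** establish: real measurement-device
error structure, real inter-genus covariance or compositional zeros beyond
the Dirichlet-multinomial, any genus → cutotype signal (none is planted —
type-model AUCs near 0.5 on synthetic cohorts are the correct null), and
none of the human-cohort headline quantities (type shares, real AUCs,
group sizes), which depend on controlled-access data.

## Reproducibility

Every stochastic step takes a seed; the pipeline derives per-stage seeds
from one global seed (CRC-salted SeedSequence), records them with
parameter values and output SHA-256 hashes in `manifest.json`, and
re-running an identical config reproduces byte-identical outputs (asserted
in tests).

## Known limitations

Read-level processing, taxonomy assignment and functional inference are
out of scope (the pipeline starts at genus count tables; the pathway
filter post-processes an externally produced table). The LEfSe-style and
pairwise-differential procedures are documented stand-ins, not
re-implementations of the original tools. PAM is exact best-improvement
SWAP (O(k·n²) per iteration), adequate for cohort-scale n but not for
tens of thousands of samples.
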