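"""Score the 60-item questionnaire into the 16 four-letter skin types.

Each of the four categories (oiliness O, sensitivity S, pigmentation P,
wrinkle W) is totalled (2.5 points per unanswered item), bonus points are
applied, and the published thresholds (27/30/31/41) call one letter per
axis — e.g. DRNT is dry, resistant, non-pigmented, tight.
"""

from kscope import bsti
from kscope.synthetic import CohortConfig, simulate_cohort, simulate_responses

cohort = simulate_cohort(CohortConfig(n_subjects=500, seed=3))
responses = simulate_responses(cohort, missing_rate=0.05, seed=4)

scores = bsti.score_table(responses, categories=responses.attrs["categories"])
print("Per-subject category totals and type (first 5 subjects):")
print(scores.head().round(1))

dist = bsti.type_distribution(scores["bsti"])
top = dist.sort_values("count", ascending=False).head(5)
print("\nMost common types in this cohort (percent of subjects):")
print(top.round(1))
print("\nA high share of D--- types means most totals fall below the "
      "oiliness threshold of 27 points.")
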