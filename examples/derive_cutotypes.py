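"""Assign cutotypes (HH/HL/LH/LL), detect aging cutpoints, stratify.

Subjects are cut at cohort tertiles on the two composites (middle band ->
gray zone, reassigned by the cohort mean), and the aging-group boundaries
are read off the ages where the upper/lower tertile-proportion curves
cross: the tone/elasticity crossing starts Aging I, the post-peak
oil/moisture crossing starts Old.
"""

from kscope import biophys, ksc
from kscope.synthetic import CohortConfig, plant_crossover, simulate_cohort

cohort = simulate_cohort(CohortConfig(n_subjects=2000, seed=2))
cohort = plant_crossover(cohort, "tone_elasticity", 35)
cohort = plant_crossover(cohort, "oil_moisture", 51)

panel = biophys.build_metric_panel(cohort.subjects)
ages = cohort.subjects["age"]

tone = ksc.proportion_curves(panel["tone_elasticity"], ages, "tone_elasticity")
oil = ksc.proportion_curves(panel["oil_moisture"], ages, "oil_moisture")
ksc.detect_crossovers(tone)
ksc.detect_crossovers(oil)
c1, c2 = ksc.select_cutpoints(tone, oil)
print(f"Detected crossings: tone {tone.crossovers}, oil {oil.crossovers}")
print(f"Aging-group cutpoints: Aging I starts at {c1}, Old at {c2} "
      f"(planted at 35 and 51)")

labels = ksc.assign_ksc(panel[["tone_elasticity", "oil_moisture"]], ages, c1, c2)
print("\nSubjects per aging group:")
print(labels["aging_group"].value_counts().to_string())
print("\n12-way strata (aging prefix y/a/o + type):")
print(labels["strata"].value_counts().sort_index().to_string())
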