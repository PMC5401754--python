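"""A small synthetic detachment study, end to end.

Simulates 6 animals (operated right eye vs control left eye; baseline,
day-7 and day-20 sessions; dark-adapted 3 and 10 cd*s/m^2 flashes) with
80% WDS attenuation in operated eyes post-surgery, extracts the feature
table, and runs the repeated-measures ANOVA with Bonferroni follow-ups.
"""

import ergwave as ew
from ergwave.pipeline import analyze_features

proto = ew.default_protocol()
spec = ew.CohortSpec(n_animals=6, steps=(proto[1], proto[2]),
                     wds_attenuation=0.8, seed=7)
cohort = ew.generate_cohort(spec)
table = ew.extract_features(cohort.traces)
results = analyze_features(table)

print("b-WDS difference, mean +/- SD (uV):")
print(results["summary"].to_string(index=False,
                                   float_format=lambda x: f"{x:.1f}"))
print()
print("Repeated-measures ANOVA (eye x session x intensity):")
cols = ["effect", "F", "p"]
print(results["anova"][cols].to_string(index=False,
                                       float_format=lambda x: f"{x:.4g}"))
print()
print(f"Bonferroni follow-ups (threshold p < {results['alpha_adj_rendered']}):")
cols = ["comparison", "t", "p", "significant"]
print(results["pairwise"][cols].to_string(index=False,
                                          float_format=lambda x: f"{x:.3g}"))
print()
print("Operated eyes show a larger b-WDS difference than controls at the")
print("post-operative sessions: the attenuated WDS no longer pulls the")
print("descending slope up toward the b-peak.")
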