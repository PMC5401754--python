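"""Quantify a shrinking retinal detachment from binary fundus masks.

Generates the default synthetic mask time-course (30% of the retina
detached at day 0, shrinking until reattachment at day 21) and quantifies
area fractions and percent reductions under the documented baseline policy
(day-0 baseline for days 3 and 7, chained baseline from day 14).
"""

import ergwave as ew

series = ew.generate_mask_series(ew.MaskTimeCourseSpec())
course = ew.reduction_series(series, baseline_policy="default")

print("day   area (% of retina)")
for day, frac in course.fractions:
    print(f"{day:3d}   {frac:6.2f}")
print()
print("day   vs day   reduction   reattached")
for day, base, red, unmeasurable in course.reductions:
    red_s = "  n/a " if red is None else f"{red:5.1f}%"
    print(f"{day:3d}   {base:5d}    {red_s}      {'yes' if unmeasurable else 'no'}")
print()
print("The reductions reproduce the study course: 40% by day 3 and 60% by")
print("day 7 (both vs day 0), another 70% by day 14 (vs day 7), and full")
print("reattachment -- no measurable detachment -- by day 21.")
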