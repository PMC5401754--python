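"""Detachment-area quantification on binary fundus masks.

Replaces the manual planimetry step of the original workflow: area is the
detached pixel count as a percentage of the retinal-disk pixel count. The
fundus image is 2-D, so no correction for detachment height or retinal
curvature is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import GeometryError, InsufficientDataError
from .masks import DetachmentMask, disk_pixels


@dataclass
class AreaTimeCourse:
    """Longitudinal area fractions and their percent reductions.

    ``fractions``: ordered (day, area %) pairs.
    ``reductions``: (day, baseline_day, percent reduction, unmeasurable)
    entries; ``unmeasurable`` marks fully reattached days, where the
    detachment can no longer be measured and the reduction is reported as
    100%. A zero-area baseline makes the reduction undefined (None).
    """

    fractions: list[tuple[int, float]]
    reductions: list[tuple[int, int, float | None, bool]] = field(default_factory=list)


def area_fraction(mask: DetachmentMask) -> float:
    """Detached area as percent of the retinal disk: 100 * n_detached / n_disk."""
    disk = disk_pixels(mask.mask.shape, mask.center, mask.radius)
    n_disk = int(disk.sum())
    if n_disk == 0:
        raise GeometryError("retina disk contains no pixels")
    return 100.0 * float(mask.mask.sum()) / n_disk


def reduction_series(
    masks: list[DetachmentMask],
    baseline_policy: str | dict[int, int] = "default",
) -> AreaTimeCourse:
    """Area fractions plus percent reductions under a baseline policy.

    Policies
    --------
    ``"day0"``
        Every follow-up day is compared against the first mask.
    ``"chained"``
        Each day is compared against the previous measured day.
    ``"default"``
        Day-0 baseline for early follow-ups, chained for later ones:
        mirrors a course quoted as reductions from the initial detachment
        at days 3 and 7 and "another" (incremental) reduction at day 14.
        Concretely: chained baselines from day 14 onward.
    dict
        Explicit {day: baseline_day} mapping.
    """
    if len(masks) < 2:
        raise InsufficientDataError("need at least two masks ordered by day")
    days = [m.day for m in masks]
    if days != sorted(days):
        raise InsufficientDataError("masks must be ordered by day")
    fractions = [(m.day, area_fraction(m)) for m in masks]
    frac_by_day = dict(fractions)

    def baseline_for(i: int) -> int:
        day = days[i]
        if isinstance(baseline_policy, dict):
            return baseline_policy[day]
        if baseline_policy == "day0":
            return days[0]
        if baseline_policy == "chained":
            return days[i - 1]
        if baseline_policy == "default":
            return days[i - 1] if day >= 14 else days[0]
        raise ValueError(f"unknown baseline policy {baseline_policy!r}")

    reductions: list[tuple[int, int, float | None, bool]] = []
    for i in range(1, len(masks)):
        day = days[i]
        base_day = baseline_for(i)
        a_base = frac_by_day[base_day]
        a_day = frac_by_day[day]
        unmeasurable = a_day == 0.0
        if a_base == 0.0:
            reductions.append((day, base_day, None, unmeasurable))
            continue
        red = 100.0 * (a_base - a_day) / a_base
        if red < 0:
            warnings.warn(
                f"day {day}: area grew relative to day {base_day} "
                f"(reduction {red:.1f}%)",
                stacklevel=2,
            )
        reductions.append((day, base_day, red, unmeasurable))
    return AreaTimeCourse(fractions=fractions, reductions=reductions)
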