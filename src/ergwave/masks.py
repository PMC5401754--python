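"""Synthetic fundus detachment masks.

The detachment is modelled as a contiguous region at the inferior margin of
the retinal disk (where a subretinal bleb settles), shrinking across
follow-up days. Masks are built by filling disk pixels from the bottom row
upwards — whole rows plus one partial row — which makes the realized pixel
count exact to rounding, keeps the region contiguous, and nests every
later-day mask inside the earlier one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, GeometryError, ResolutionError


@dataclass
class DetachmentMask:
    """Binary detachment mask with its retinal-disk geometry."""

    mask: np.ndarray          # bool, detached pixels
    center: tuple[int, int]   # (row, col) of the retina disk
    radius: int               # disk radius, pixels
    day: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.radius <= 0:
            raise GeometryError("retina radius must be > 0")
        if np.any(self.mask & ~disk_pixels(self.mask.shape, self.center, self.radius)):
            raise GeometryError("detached pixels must lie inside the retina disk")


@dataclass(frozen=True)
class MaskTimeCourseSpec:
    """Study time-course of the detachment area.

    ``reductions`` is an ordered list of (day, percent_reduction,
    baseline_day) triples; each day's target area is the baseline day's
    area reduced by the given percentage. The default mirrors the study:
    30% of the retina detached at day 0, 40% and 60% reductions from day 0
    at days 3 and 7, a further 70% reduction from day 7 at day 14, and full
    reattachment (empty mask) at day 21.
    """

    image_size: int = 512
    retina_radius: int = 230
    day0_fraction: float = 30.0
    reductions: tuple[tuple[int, float, int], ...] = (
        (3, 40.0, 0),
        (7, 60.0, 0),
        (14, 70.0, 7),
        (21, 100.0, 14),
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.day0_fraction <= 100.0):
            raise ConfigurationError("day0_fraction must lie in (0, 100]")
        for day, red, base in self.reductions:
            if not (0.0 < red <= 100.0):
                raise ConfigurationError(f"day {day}: reduction must lie in (0, 100]")


def disk_pixels(shape: tuple[int, ...], center: tuple[int, int],
                radius: int) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _fill_inferior(disk: np.ndarray, k: int) -> np.ndarray:
    """Select the k bottom-most disk pixels: whole rows from the inferior
    edge upward, the final partial row filled left-to-right."""
    mask = np.zeros_like(disk)
    remaining = k
    for r in range(disk.shape[0] - 1, -1, -1):
        cols = np.flatnonzero(disk[r])
        if cols.size == 0:
            continue
        take = min(remaining, cols.size)
        mask[r, cols[:take]] = True
        remaining -= take
        if remaining == 0:
            break
    return mask


def generate_mask_series(spec: MaskTimeCourseSpec) -> list[DetachmentMask]:
    """Build the day-0 mask plus one mask per reduction entry.

    The realized pixel count of each mask matches its target fraction to
    rounding (|realized - requested| < 1 pixel). A 100% reduction yields an
    empty mask (reattached retina).
    """
    n = spec.image_size
    center = (n // 2, n // 2)
    if spec.retina_radius >= n // 2:
        raise ConfigurationError("retina_radius must fit inside the image")
    disk = disk_pixels((n, n), center, spec.retina_radius)
    disk_count = int(disk.sum())
    if disk_count == 0:
        raise GeometryError("empty retina disk")

    targets: dict[int, float] = {0: spec.day0_fraction}
    for day, red, base_day in spec.reductions:
        if base_day not in targets:
            raise ConfigurationError(
                f"day {day}: baseline day {base_day} precedes no generated mask"
            )
        targets[day] = targets[base_day] * (1.0 - red / 100.0)

    series: list[DetachmentMask] = []
    prev_k = disk_count + 1
    for day in sorted(targets):
        frac = targets[day]
        k = int(round(frac / 100.0 * disk_count))
        if frac > 0 and k == 0:
            raise ResolutionError(
                f"day {day}: fraction {frac:.3g}% is below one pixel at "
                f"image_size {n}"
            )
        if k >= prev_k:
            k = prev_k - 1  # area series strictly decreasing
        prev_k = k
        series.append(
            DetachmentMask(
                mask=_fill_inferior(disk, k),
                center=center,
                radius=spec.retina_radius,
                day=day,
            )
        )
    return series
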