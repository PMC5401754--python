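"""Recording-protocol model and loader.

The protocol is the ordered sequence of stimulus steps of a standard
ISCEV-style full-field ERG session: three dark-adapted flash strengths, a
10-minute light-adaptation step, two light-adapted flashes and two flicker
trains. The packaged default reproduces that eight-step sequence exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .errors import FormatError, ValidationError

VALID_KINDS = ("flash", "adaptation", "flicker")
VALID_ADAPTATION = ("dark", "light")


@dataclass(frozen=True)
class ProtocolStep:
    """One row of the recording sequence.

    ``intensity`` is flash strength in cd*s/m^2 for flash/flicker steps and
    background luminance in cd/m^2 for adaptation steps. ``duration_min``
    applies to adaptation steps only.
    """

    index: int
    kind: str
    intensity: float
    adaptation_state: str
    n_flashes: int = 0
    inter_flash_interval: float = 0.0
    duration_min: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in VALID_KINDS:
            raise ValidationError(f"step {self.index}: unknown kind {self.kind!r}")
        if self.adaptation_state not in VALID_ADAPTATION:
            raise ValidationError(
                f"step {self.index}: unknown adaptation state {self.adaptation_state!r}"
            )
        if self.kind in ("flash", "flicker") and self.n_flashes < 1:
            raise ValidationError(f"step {self.index}: n_flashes must be >= 1")
        if self.kind == "flicker" and self.inter_flash_interval > 0.05:
            raise ValidationError(
                f"step {self.index}: flicker inter-flash interval must be <= 0.05 s"
            )


def default_protocol() -> list[ProtocolStep]:
    """The packaged eight-step protocol (dark-adapted 0.01/3/10 cd*s/m^2
    flashes, 30 cd/m^2 light adaptation for 10 min, light-adapted 3/10
    flashes, 3/10 flicker trains)."""
    return [
        ProtocolStep(1, "flash", 0.01, "dark", n_flashes=10, inter_flash_interval=2.0),
        ProtocolStep(2, "flash", 3.0, "dark", n_flashes=4, inter_flash_interval=10.0),
        ProtocolStep(3, "flash", 10.0, "dark", n_flashes=4, inter_flash_interval=20.0),
        ProtocolStep(4, "adaptation", 30.0, "light", duration_min=10.0),
        ProtocolStep(5, "flash", 3.0, "light", n_flashes=32, inter_flash_interval=0.5),
        ProtocolStep(6, "flash", 10.0, "light", n_flashes=32, inter_flash_interval=0.5),
        ProtocolStep(7, "flicker", 3.0, "light", n_flashes=128, inter_flash_interval=0.032),
        ProtocolStep(8, "flicker", 10.0, "light", n_flashes=128, inter_flash_interval=0.032),
    ]


def validate_protocol(steps: list[ProtocolStep]) -> list[ProtocolStep]:
    """Check the cross-step invariants (unique, contiguous 1-based indices)."""
    if not steps:
        raise ValidationError("protocol contains no steps")
    indices = [s.index for s in steps]
    if len(set(indices)) != len(indices):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise ValidationError(f"duplicate step index: {dupes}")
    if indices != list(range(1, len(steps) + 1)):
        raise ValidationError("step indices must be contiguous and 1-based")
    return steps


def load_protocol(path: str | Path) -> list[ProtocolStep]:
    """Read a protocol from a YAML file (a list of step mappings)."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise FormatError(f"{path}: cannot parse protocol file: {exc}") from exc
    if raw is None:
        raise FormatError(f"{path}: empty protocol file")
    if isinstance(raw, dict) and "steps" in raw:
        raw = raw["steps"]
    if not isinstance(raw, list):
        raise FormatError(f"{path}: protocol must be a list of steps")
    steps = []
    for i, item in enumerate(raw):
        if not isinstance(item, dict):
            raise FormatError(f"{path}: step entry {i + 1} is not a mapping")
        try:
            steps.append(ProtocolStep(**item))
        except TypeError as exc:
            raise FormatError(f"{path}: step entry {i + 1}: {exc}") from exc
    return validate_protocol(steps)


def save_protocol(steps: list[ProtocolStep], path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump([asdict(s) for s in steps], sort_keys=False)
    )


def flash_steps(steps: list[ProtocolStep]) -> list[ProtocolStep]:
    """Steps that produce an averaged trace (flash and flicker, not adaptation)."""
    return [s for s in steps if s.kind != "adaptation"]
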