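"""The in-memory ERG trace container.

An :class:`ERGTrace` is one averaged time-voltage response on a uniform
grid, in milliseconds and microvolts, with time 0 at stimulus onset and a
pre-stimulus baseline segment before it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ValidationError

#: minimum pre-stimulus baseline the measurement chain assumes, ms
MIN_BASELINE_MS = 20.0


@dataclass
class ERGTrace:
    """A single averaged time-voltage response.

    Parameters
    ----------
    time : ndarray
        Uniform time grid in ms; stimulus onset at t = 0.
    voltage : ndarray
        Corneal potential in microvolts, same length as ``time``.
    rate : float
        Sampling rate in samples/s.
    meta : dict
        Session metadata: ``animal``, ``eye`` ("operated"/"control"),
        ``session`` ("baseline"/"day7"/"day20"), ``step`` (1-based protocol
        index), plus stimulus descriptors (``kind``, ``adaptation``,
        ``intensity``).
    """

    time: np.ndarray
    voltage: np.ndarray
    rate: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.voltage = np.asarray(self.voltage, dtype=float)
        if self.time.shape != self.voltage.shape or self.time.ndim != 1:
            raise ValidationError("time and voltage must be equal-length 1-D arrays")
        if self.time.size < 2:
            raise ValidationError("trace needs at least two samples")
        dt = np.diff(self.time)
        step = 1000.0 / self.rate
        if np.any(dt <= 0) or not np.allclose(dt, step, rtol=1e-6, atol=1e-9):
            raise ValidationError("time grid is not uniform at the stated rate")
        if not (np.all(np.isfinite(self.time)) and np.all(np.isfinite(self.voltage))):
            raise ValidationError("trace contains non-finite values")
        if self.time[0] > 0:
            raise ValidationError("stimulus onset (t=0) must lie inside the record")
        if -self.time[0] < MIN_BASELINE_MS:
            warnings.warn(
                f"pre-stimulus baseline {-self.time[0]:.1f} ms is shorter than "
                f"the recommended {MIN_BASELINE_MS:.0f} ms",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.rate

    def pre_stimulus(self) -> np.ndarray:
        """Voltage samples strictly before stimulus onset."""
        return self.voltage[self.time < 0]

    def baseline(self) -> float:
        """Mean of the pre-stimulus segment (the zero reference)."""
        return float(np.mean(self.pre_stimulus()))

    def with_voltage(self, voltage: np.ndarray) -> "ERGTrace":
        """Copy of this trace with a new voltage vector on the same grid."""
        return replace(self, voltage=np.asarray(voltage, dtype=float))

    def value_at(self, t_ms: float) -> float:
        """Voltage at the sample nearest to ``t_ms``."""
        idx = int(np.argmin(np.abs(self.time - t_ms)))
        return float(self.voltage[idx])

    def same_grid(self, other: "ERGTrace") -> bool:
        return (
            self.n == other.n
            and self.rate == other.rate
            and np.allclose(self.time, other.time, atol=1e-9)
        )
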