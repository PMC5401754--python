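"""Synthetic full-field ERG generator with known ground truth.

The generator is phenomenological: each transient flash response is a sum of
smooth unimodal lobes — a cornea-negative a-lobe, a dominant positive b-lobe
and a smaller positive secondary lobe on the descending slope of the b-wave
(the WDS) — plus an oscillatory-potential burst modelled as a
Gaussian-windowed sinusoid confined to the 100-300 Hz band on the ascending
limb. No biophysical retina model (no PII/PIII dynamics) is attempted; the
point is a ground-truthed test bed for the measurement chain.

Cohorts emulate the study design: n animals, operated right eye vs control
left eye, sessions a week before and 7 and 20 days after surgery. The only
condition effect is multiplicative attenuation of the WDS amplitude in
operated eyes at post-operative sessions; a- and b-wave parameters are
drawn from the same distribution in every condition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SamplingError
from .protocol import ProtocolStep, default_protocol, flash_steps
from .traces import ERGTrace

# ---------------------------------------------------------------------------
# component parameters

@dataclass(frozen=True)
class ComponentParams:
    """Latent parameters of one transient flash response.

    Amplitudes are in microvolts (``a_amplitude`` is the magnitude of the
    negative a-lobe; its contribution to the trace is ``-a_amplitude``),
    latencies and widths in ms (widths are Gaussian sigmas), the
    oscillatory-potential (OP) burst is a sinusoid at ``op_center_freq`` Hz
    under a Gaussian window centred at ``op_burst_center``.
    """

    a_amplitude: float
    a_latency: float
    a_width: float
    b_amplitude: float
    b_latency: float
    b_width: float
    wds_amplitude: float
    wds_latency: float
    wds_width: float
    op_amplitude: float = 0.0
    op_center_freq: float = 200.0
    op_burst_center: float = 30.0
    op_burst_width: float = 5.0

    def __post_init__(self) -> None:
        for name in ("a_width", "b_width", "wds_width", "op_burst_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if not (self.a_latency < self.b_latency < self.wds_latency):
            raise ConfigurationError(
                "latencies must be ordered a_latency < b_latency < wds_latency"
            )
        if not (100.0 <= self.op_center_freq <= 300.0):
            raise ConfigurationError("op_center_freq must lie in [100, 300] Hz")
        if self.wds_amplitude < 0:
            raise ConfigurationError("wds_amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseParams:
    """Additive noise: white Gaussian noise plus optional mains interference."""

    white_sd: float = 4.0
    mains_amplitude: float = 2.0
    mains_freq: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.white_sd < 0 or self.mains_amplitude < 0:
            raise ConfigurationError("noise amplitudes must be >= 0")


NOISE_OFF = NoiseParams(white_sd=0.0, mains_amplitude=0.0)


def _lobe(t: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - mu) / sigma) ** 2)


def component_model(params: ComponentParams, t_ms: np.ndarray) -> np.ndarray:
    """Closed-form noiseless component sum evaluated on an arbitrary grid.

    The response is gated to t >= 0 so the pre-stimulus segment is exactly
    zero (the baseline reference).
    """
    t = np.asarray(t_ms, dtype=float)
    v = (
        -params.a_amplitude * _lobe(t, params.a_latency, params.a_width)
        + params.b_amplitude * _lobe(t, params.b_latency, params.b_width)
        + params.wds_amplitude * _lobe(t, params.wds_latency, params.wds_width)
    )
    if params.op_amplitude:
        v = v + (
            params.op_amplitude
            * np.sin(2e-3 * np.pi * params.op_center_freq * (t - params.op_burst_center))
            * _lobe(t, params.op_burst_center, params.op_burst_width)
        )
    return np.where(t >= 0.0, v, 0.0)


# ---------------------------------------------------------------------------
# default templates, keyed by (adaptation_state, flash intensity)

#: Control-eye component defaults per protocol condition. Latencies of the
#: WDS follow the control-eye means reported for the dark-adapted 3 and
#: 10 cd*s/m^2 flashes (64.0 and 62.8 ms); the WDS amplitude is larger at
#: 10 than at 3 cd*s/m^2 so that the b-wave-WDS difference decreases with
#: flash strength, and the dim 0.01 cd*s/m^2 flash carries neither an
#: a-wave nor a WDS. All amplitudes are free defaults.
DEFAULT_TEMPLATES: dict[tuple[str, float], ComponentParams] = {
    ("dark", 0.01): ComponentParams(
        a_amplitude=0.0, a_latency=14.0, a_width=5.0,
        b_amplitude=80.0, b_latency=60.0, b_width=14.0,
        wds_amplitude=0.0, wds_latency=95.0, wds_width=8.0,
        op_amplitude=0.0,
    ),
    ("dark", 3.0): ComponentParams(
        a_amplitude=45.0, a_latency=15.0, a_width=5.0,
        b_amplitude=150.0, b_latency=38.0, b_width=6.0,
        wds_amplitude=15.0, wds_latency=64.0, wds_width=6.0,
        op_amplitude=12.0, op_center_freq=200.0,
        op_burst_center=30.0, op_burst_width=5.0,
    ),
    ("dark", 10.0): ComponentParams(
        a_amplitude=60.0, a_latency=13.5, a_width=5.0,
        b_amplitude=165.0, b_latency=36.0, b_width=6.0,
        wds_amplitude=50.0, wds_latency=62.8, wds_width=6.0,
        op_amplitude=15.0, op_center_freq=200.0,
        op_burst_center=28.0, op_burst_width=5.0,
    ),
    ("light", 3.0): ComponentParams(
        a_amplitude=8.0, a_latency=12.0, a_width=4.0,
        b_amplitude=90.0, b_latency=32.0, b_width=6.0,
        wds_amplitude=0.0, wds_latency=70.0, wds_width=6.0,
        op_amplitude=5.0, op_center_freq=200.0,
        op_burst_center=24.0, op_burst_width=5.0,
    ),
    ("light", 10.0): ComponentParams(
        a_amplitude=10.0, a_latency=12.0, a_width=4.0,
        b_amplitude=110.0, b_latency=30.0, b_width=6.0,
        wds_amplitude=0.0, wds_latency=70.0, wds_width=6.0,
        op_amplitude=6.0, op_center_freq=200.0,
        op_burst_center=23.0, op_burst_width=5.0,
    ),
}

#: Additive Gaussian jitter SD (ms) on WDS latency per condition; the
#: dark-adapted values follow the reported control-eye SDs (6.3 and 7.6 ms).
DEFAULT_WDS_LATENCY_SD: dict[tuple[str, float], float] = {
    ("dark", 3.0): 6.3,
    ("dark", 10.0): 7.6,
}

#: Additive Gaussian jitter SD (ms) on the other latencies.
DEFAULT_LATENCY_SD = {"a_latency": 1.0, "b_latency": 1.5}

DEFAULT_RATE = 2000.0     # samples/s; resolves the 0.3-300 Hz band
DEFAULT_DURATION = 250.0  # ms post-stimulus
DEFAULT_PRE = 25.0        # ms pre-stimulus baseline


def default_template(adaptation: str, intensity: float) -> ComponentParams:
    try:
        return DEFAULT_TEMPLATES[(adaptation, float(intensity))]
    except KeyError:
        raise ConfigurationError(
            f"no default template for {adaptation}-adapted {intensity} cd*s/m^2"
        ) from None


# ---------------------------------------------------------------------------
# single-trace generation

def time_grid(duration: float = DEFAULT_DURATION, rate: float = DEFAULT_RATE,
              pre: float = DEFAULT_PRE) -> np.ndarray:
    dt = 1000.0 / rate
    n_pre = int(round(pre / dt))
    n_post = int(round(duration / dt))
    return (np.arange(n_pre + n_post + 1) - n_pre) * dt


def generate_trace(
    params: ComponentParams,
    noise: NoiseParams = NOISE_OFF,
    duration: float = DEFAULT_DURATION,
    rate: float = DEFAULT_RATE,
    pre: float = DEFAULT_PRE,
    meta: dict | None = None,
) -> tuple[ERGTrace, ComponentParams]:
    """Generate one trace; returns the trace and its realized ground truth.

    ``duration`` must cover the WDS lobe (wds_latency + 3*wds_width) and the
    rate must resolve the 300 Hz upper band edge.
    """
    if rate < 1000.0:
        raise SamplingError(f"rate {rate} samples/s cannot resolve 300 Hz content")
    if duration < params.wds_latency + 3.0 * params.wds_width:
        raise ConfigurationError(
            f"duration {duration} ms does not cover the WDS lobe "
            f"(needs >= {params.wds_latency + 3 * params.wds_width:.1f} ms)"
        )
    t = time_grid(duration, rate, pre)
    v = component_model(params, t)
    if noise.white_sd > 0 or noise.mains_amplitude > 0:
        rng = np.random.default_rng(noise.seed)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        if noise.mains_amplitude > 0:
            v = v + noise.mains_amplitude * np.sin(
                2e-3 * np.pi * noise.mains_freq * t + phase
            )
        if noise.white_sd > 0:
            v = v + rng.normal(0.0, noise.white_sd, size=t.size)
    trace = ERGTrace(time=t, voltage=v, rate=rate, meta=dict(meta or {}))
    return trace, params


def _flicker_voltage(params: ComponentParams, t: np.ndarray,
                     interval_s: float) -> np.ndarray:
    """Steady-state flicker train: the b-lobe repeated at the flicker rate."""
    period = interval_s * 1000.0
    v = np.zeros_like(t)
    onset = 0.0
    while onset < t[-1]:
        v += 0.3 * params.b_amplitude * _lobe(t, onset + params.b_latency, params.b_width)
        onset += period
    return np.where(t >= 0.0, v, 0.0)


# ---------------------------------------------------------------------------
# cohort generation

@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort."""

    n_animals: int = 10
    sessions: tuple[str, ...] = ("baseline", "day7", "day20")
    steps: tuple[ProtocolStep, ...] = tuple(default_protocol())
    wds_attenuation: float = 0.8
    inter_animal_sd: float = 0.15
    noise: NoiseParams = field(default_factory=NoiseParams)
    duration: float = DEFAULT_DURATION
    rate: float = DEFAULT_RATE
    pre: float = DEFAULT_PRE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise ConfigurationError("n_animals must be >= 2")
        if not (0.0 <= self.wds_attenuation <= 1.0):
            raise ConfigurationError("wds_attenuation must lie in [0, 1]")
        if not self.sessions or not self.steps:
            raise ConfigurationError("sessions and steps must be non-empty")


@dataclass
class Cohort:
    """Generated traces plus their lossless ground truth.

    ``truth`` holds one row per trace: the metadata key columns and the
    realized component parameters after inter-animal jitter and condition
    effects.
    """

    traces: list[ERGTrace]
    truth: pd.DataFrame
    spec: CohortSpec

    def skeleton(self) -> pd.DataFrame:
        """Empty long-format feature-table skeleton (key columns only)."""
        return self.truth[["animal", "eye", "session", "step"]].copy()


def _animal_jitter(rng: np.random.Generator) -> dict[str, float]:
    """Standard-normal draws for one animal, shared across both eyes, all
    sessions and every protocol step (a stable per-animal trait)."""
    return {name: float(rng.standard_normal())
            for name in ("a_amp", "b_amp", "wds_amp", "op_amp",
                         "a_lat", "b_lat", "wds_lat")}


def apply_jitter(template: ComponentParams, z: dict[str, float], rel_sd: float,
                 wds_latency_sd: float) -> ComponentParams:
    """Realize one animal's parameters: lognormal multiplicative jitter on
    amplitudes, additive Gaussian jitter on latencies, with
    ordering-preserving clamps."""
    sigma = float(np.sqrt(np.log1p(rel_sd**2)))

    def amp(x: float, key: str) -> float:
        if x == 0.0 or rel_sd == 0.0:
            return x
        return float(x * np.exp(-0.5 * sigma**2 + sigma * z[key]))

    a_lat = template.a_latency + z["a_lat"] * DEFAULT_LATENCY_SD["a_latency"]
    b_lat = template.b_latency + z["b_lat"] * DEFAULT_LATENCY_SD["b_latency"]
    b_lat = max(b_lat, a_lat + 5.0)
    wds_lat = template.wds_latency + z["wds_lat"] * wds_latency_sd
    wds_lat = float(np.clip(wds_lat, b_lat + 8.0, 110.0))
    return replace(
        template,
        a_amplitude=amp(template.a_amplitude, "a_amp"),
        b_amplitude=amp(template.b_amplitude, "b_amp"),
        wds_amplitude=amp(template.wds_amplitude, "wds_amp"),
        op_amplitude=amp(template.op_amplitude, "op_amp"),
        a_latency=float(a_lat),
        b_latency=float(b_lat),
        wds_latency=wds_lat,
    )


def draw_params(
    rng: np.random.Generator,
    template: ComponentParams,
    rel_sd: float,
    wds_latency_sd: float = 0.0,
) -> ComponentParams:
    """One independent inter-animal draw (see :func:`apply_jitter`)."""
    return apply_jitter(template, _animal_jitter(rng), rel_sd, wds_latency_sd)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate the full animal x eye x session x step trace collection.

    Parameter draws are made once per animal x step (a stable trait shared
    by both eyes across sessions); operated-eye post-operative traces have
    the WDS amplitude multiplied by ``1 - wds_attenuation`` and nothing
    else changed. White noise is scaled by 1/sqrt(n_flashes) to represent
    the within-step sweep average; mains interference, being coherent
    across sweeps, is not scaled.
    """
    steps = flash_steps(list(spec.steps))
    if not steps:
        raise ConfigurationError("spec contains no flash/flicker steps")
    root = np.random.SeedSequence(spec.seed)
    param_rng = np.random.default_rng(root.spawn(1)[0])
    noise_seeds = np.random.SeedSequence(root.entropy, spawn_key=(1,))

    animals = [f"A{i + 1:02d}" for i in range(spec.n_animals)]
    traces: list[ERGTrace] = []
    rows: list[dict] = []
    trace_counter = 0
    for animal in animals:
        z = _animal_jitter(param_rng)
        per_step: dict[int, ComponentParams] = {}
        for step in steps:
            key = (step.adaptation_state, float(step.intensity))
            template = DEFAULT_TEMPLATES.get(key)
            if template is None:
                raise ConfigurationError(f"no template for protocol step {step.index}")
            per_step[step.index] = apply_jitter(
                template, z, spec.inter_animal_sd,
                DEFAULT_WDS_LATENCY_SD.get(key, 1.0),
            )
        for session in spec.sessions:
            for eye in ("operated", "control"):
                for step in steps:
                    params = per_step[step.index]
                    if eye == "operated" and session != "baseline":
                        params = replace(
                            params,
                            wds_amplitude=params.wds_amplitude
                            * (1.0 - spec.wds_attenuation),
                        )
                    meta = {
                        "animal": animal,
                        "eye": eye,
                        "session": session,
                        "step": step.index,
                        "kind": step.kind,
                        "adaptation": step.adaptation_state,
                        "intensity": float(step.intensity),
                    }
                    seed = np.random.SeedSequence(
                        noise_seeds.entropy, spawn_key=(1, trace_counter)
                    )
                    trace_counter += 1
                    t = time_grid(spec.duration, spec.rate, spec.pre)
                    if step.kind == "flicker":
                        v = _flicker_voltage(params, t, step.inter_flash_interval)
                    else:
                        v = component_model(params, t)
                    rng = np.random.default_rng(seed)
                    phase = rng.uniform(0.0, 2.0 * np.pi)
                    if spec.noise.mains_amplitude > 0:
                        v = v + spec.noise.mains_amplitude * np.sin(
                            2e-3 * np.pi * spec.noise.mains_freq * t + phase
                        )
                    if spec.noise.white_sd > 0:
                        sd = spec.noise.white_sd / np.sqrt(max(step.n_flashes, 1))
                        v = v + rng.normal(0.0, sd, size=t.size)
                    traces.append(ERGTrace(time=t, voltage=v, rate=spec.rate, meta=meta))
                    rows.append({**meta, **asdict(params)})
    truth = pd.DataFrame(rows)
    return Cohort(traces=traces, truth=truth, spec=spec)
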