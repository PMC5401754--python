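"""Measurement-chain contracts: filtering, averaging, a/b metrics, WDS
detection, the b-WDS difference, and the OP/WDS band split."""

from dataclasses import replace

import numpy as np
import pytest
from scipy import signal as sps

import ergwave as ew
from ergwave.errors import AlignmentError, ConfigurationError, UnresolvedFeatureError
from ergwave.features import (
    FilterSpec,
    WDS_LP_ORDER,
    analysis_chain,
    apply_filter,
    band_energy,
)
from ergwave.simulate import time_grid
from tests.conftest import dense_extrema


def _trace(voltage, rate=2000.0, meta=None):
    t = time_grid(rate=rate)
    v = np.broadcast_to(voltage, t.shape).astype(float) if np.isscalar(voltage) \
        else np.asarray(voltage, dtype=float)
    return ew.ERGTrace(time=t, voltage=v, rate=rate, meta=meta or {})


# ---------------------------------------------------------------------------
# filtering

def test_lowpass_dc_gain_is_unity():
    trace = _trace(5.0)
    out = apply_filter(trace, FilterSpec("lowpass", high_cut=150.0))
    assert np.allclose(out.voltage, 5.0, atol=1e-6)


def test_130hz_tone_suppressed_below_5_percent():
    """Residual through the <100 Hz OP-exclusion low-pass matches the
    analytic zero-phase magnitude response |H(130)|^2 and stays under 5%."""
    t = time_grid()
    # Gaussian-windowed tone away from the record edges (no edge transient)
    tone = np.sin(2e-3 * np.pi * 130.0 * t) * np.exp(-0.5 * ((t - 110) / 40) ** 2)
    trace = _trace(tone)
    out = apply_filter(trace, FilterSpec("lowpass", high_cut=100.0,
                                         order=WDS_LP_ORDER))
    ratio = np.sqrt(np.mean(out.voltage**2) / np.mean(tone**2))
    analytic = 1.0 / (1.0 + (130.0 / 100.0) ** (2 * WDS_LP_ORDER))  # |H|^2
    assert ratio < 0.05
    assert ratio == pytest.approx(analytic, rel=0.25)


def test_bandpass_preserves_lobe_peak_time():
    t = time_grid()
    lobe = 40.0 * np.exp(-0.5 * ((t - 60.0) / 8.0) ** 2)
    trace = _trace(np.where(t >= 0, lobe, 0.0))
    out = apply_filter(trace, FilterSpec("bandpass", low_cut=0.3, high_cut=300.0))
    t_in = trace.time[np.argmax(trace.voltage)]
    t_out = out.time[np.argmax(out.voltage)]
    assert abs(t_out - t_in) <= 0.5


def test_cutoff_beyond_nyquist_rejected():
    trace = _trace(0.0)
    with pytest.raises(ConfigurationError):
        apply_filter(trace, FilterSpec("lowpass", high_cut=1500.0))


@pytest.mark.parametrize("intensity", [3.0, 10.0])
def test_zero_phase_chain_never_shifts_b_peak(intensity):
    """Zero-phase contract: the full analysis chain moves the b-peak of a
    noiseless template by at most one sample (OP burst off, so the raw
    argmax is the smooth b-peak and not an oscillatory-potential crest)."""
    params = replace(ew.default_template("dark", intensity), op_amplitude=0.0)
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    raw_peak = trace.time[np.argmax(trace.voltage)]
    filt = analysis_chain(trace, notch=None)
    filt_peak = filt.time[np.argmax(filt.voltage)]
    assert abs(filt_peak - raw_peak) <= 1000.0 / trace.rate


# ---------------------------------------------------------------------------
# sweep averaging

def test_average_of_identical_sweeps_is_the_sweep(da3):
    trace, _ = ew.generate_trace(da3, ew.NOISE_OFF)
    avg = ew.average_sweeps([trace] * 5)
    assert np.allclose(avg.voltage, trace.voltage)


def test_average_of_opposite_sweeps_is_zero(da3):
    trace, _ = ew.generate_trace(da3, ew.NOISE_OFF)
    flipped = trace.with_voltage(-trace.voltage)
    avg = ew.average_sweeps([trace, flipped])
    assert np.allclose(avg.voltage, 0.0)


def test_white_noise_averages_down_as_sqrt_n():
    rng = np.random.default_rng(1234)
    t = time_grid()
    sweeps = [_trace(rng.normal(0.0, 8.0, size=t.size)) for _ in range(128)]
    avg = ew.average_sweeps(sweeps)
    expected = 8.0 / np.sqrt(128)
    assert np.std(avg.voltage) == pytest.approx(expected, rel=0.15)


def test_mismatched_grids_rejected(da3):
    a, _ = ew.generate_trace(da3, rate=2000.0)
    b, _ = ew.generate_trace(da3, rate=4000.0)
    with pytest.raises(AlignmentError):
        ew.average_sweeps([a, b])


# ---------------------------------------------------------------------------
# a/b metrics

def test_ab_metrics_on_separated_lobes():
    """a-lobe of -25 uV at 15 ms plus a b-lobe reaching +80 uV: amplitudes
    follow the baseline-to-trough / trough-to-peak conventions."""
    params = ew.ComponentParams(
        a_amplitude=25.0, a_latency=15.0, a_width=3.0,
        b_amplitude=80.0, b_latency=40.0, b_width=6.0,
        wds_amplitude=0.0, wds_latency=70.0, wds_width=6.0,
    )
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    f = ew.measure_ab(trace)
    t_or, v_or = dense_extrema(params, 5.0, 30.0, "min")
    assert f.a_present and f.b_present
    assert f.a_implicit == pytest.approx(t_or, abs=0.5)
    assert f.a_amplitude == pytest.approx(25.0, rel=0.01)
    assert f.b_amplitude == pytest.approx(105.0, rel=0.01)
    assert f.b_peak_voltage == pytest.approx(80.0, rel=0.01)


def test_zero_trace_has_all_features_absent():
    f = ew.measure_ab(_trace(0.0))
    assert not f.a_present and not f.b_present
    assert f.a_amplitude is None and f.b_amplitude is None


def test_dim_flash_b_measured_from_baseline():
    params = ew.default_template("dark", 0.01)
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    f = ew.measure_ab(trace)
    assert not f.a_present
    assert f.b_present
    assert f.b_amplitude == pytest.approx(f.b_peak_voltage)
    assert f.b_amplitude == pytest.approx(80.0, rel=0.02)


# ---------------------------------------------------------------------------
# WDS detection

@pytest.mark.parametrize("intensity,latency", [(3.0, 64.0), (10.0, 62.8)])
def test_wds_detected_at_configured_latency(intensity, latency):
    params = ew.default_template("dark", intensity)
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    chain = analysis_chain(trace, notch=None)
    f = ew.detect_wds(chain, ew.measure_ab(chain))
    assert f.wds_present and f.wds_mode == "peak"
    assert abs(f.wds_implicit - latency) <= 0.5


def test_wds_absent_when_amplitude_zero(da3):
    params = replace(da3, wds_amplitude=0.0)
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    chain = analysis_chain(trace, notch=None)
    f = ew.detect_wds(chain, ew.measure_ab(chain))
    assert not f.wds_present


def test_greatest_prominence_bump_selected():
    """Two descending-slope bumps (55 and 70 ms); the more prominent one at
    55 ms wins, matching a brute-force prominence oracle."""
    params = ew.ComponentParams(
        a_amplitude=45.0, a_latency=15.0, a_width=5.0,
        b_amplitude=150.0, b_latency=38.0, b_width=6.0,
        wds_amplitude=22.0, wds_latency=57.0, wds_width=4.0,
    )
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    extra = 6.0 * np.exp(-0.5 * ((trace.time - 70.0) / 4.0) ** 2)
    trace = trace.with_voltage(trace.voltage + np.where(trace.time >= 0, extra, 0.0))
    chain = analysis_chain(trace, notch=None)
    ab = ew.measure_ab(chain)
    f = ew.detect_wds(chain, ab)

    # oracle: prominence of every local max of the <100 Hz trace in-window
    lp = apply_filter(chain, FilterSpec("lowpass", high_cut=100.0,
                                        order=WDS_LP_ORDER))
    sel = (lp.time > ab.b_implicit + 5.0) & (lp.time <= 120.0)
    seg = lp.voltage[sel]
    peaks, _ = sps.find_peaks(seg)
    proms = sps.peak_prominences(seg, peaks)[0]
    t_oracle = lp.time[sel][peaks[np.argmax(proms)]]

    assert f.wds_present
    assert f.wds_implicit == pytest.approx(t_oracle, abs=1e-9)
    assert abs(f.wds_implicit - 57.0) <= 1.0  # the earlier, more prominent bump


def test_shoulder_plateau_qualifies_as_wds(da3):
    """A WDS reduced to an inflection (no local max) is still caught by the
    derivative-plateau rule."""
    params = replace(da3, wds_amplitude=6.0, wds_latency=56.0, wds_width=7.0,
                     op_amplitude=0.0)
    trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
    chain = analysis_chain(trace, notch=None)
    ab = ew.measure_ab(chain)
    f = ew.detect_wds(chain, ab)
    assert f.wds_present
    assert f.wds_mode == "shoulder"
    assert 50.0 <= f.wds_implicit <= 80.0


# ---------------------------------------------------------------------------
# b-WDS difference

def test_difference_definition(da3):
    trace, _ = ew.generate_trace(da3, ew.NOISE_OFF)
    f = ew.WaveFeatures(b_present=True, b_peak_voltage=100.0, wds_present=True,
                        wds_voltage=70.0)
    out = ew.wds_difference(trace, f)
    assert out.wds_difference == pytest.approx(30.0)


def test_fallback_reads_trace_at_baseline_latency():
    t = time_grid()
    v = np.where(t >= 0, 100.0 * np.exp(-0.5 * ((t - 40.0) / 10.0) ** 2), 0.0)
    trace = _trace(v)
    f = ew.WaveFeatures(b_present=True, b_peak_voltage=100.0, wds_present=False)
    baseline = ew.WaveFeatures(wds_implicit=64.0)
    out = ew.wds_difference(trace, f, baseline_features=baseline)
    expected = 100.0 - trace.value_at(64.0)
    assert out.wds_fallback
    assert out.wds_difference == pytest.approx(expected)
    assert out.wds_difference >= 0.0


def test_fallback_without_baseline_latency_raises():
    trace = _trace(0.0)
    f = ew.WaveFeatures(b_present=True, b_peak_voltage=50.0, wds_present=False)
    with pytest.raises(UnresolvedFeatureError):
        ew.wds_difference(trace, f)


def test_difference_monotone_in_wds_attenuation(da3):
    """Attenuating the generator WDS amplitude from 30 to 0 uV monotonically
    increases the b-WDS difference (closed-form traces, fixed fallback)."""
    deltas = []
    baseline = None
    for amp in [30.0, 24.0, 18.0, 12.0, 6.0, 2.0, 0.0]:
        params = replace(da3, wds_amplitude=amp, op_amplitude=0.0)
        trace, _ = ew.generate_trace(params, ew.NOISE_OFF)
        chain = analysis_chain(trace, notch=None)
        f = ew.detect_wds(chain, ew.measure_ab(chain))
        if baseline is None:
            assert f.wds_present
            baseline = f
        f = ew.wds_difference(chain, f, baseline_features=baseline)
        deltas.append(f.wds_difference)
    assert all(b > a for a, b in zip(deltas, deltas[1:]))


# ---------------------------------------------------------------------------
# spectral split

def test_op_only_trace_splits_into_high_branch(da3):
    burst = replace(da3, a_amplitude=0.0, b_amplitude=0.0, wds_amplitude=0.0)
    trace, _ = ew.generate_trace(burst, ew.NOISE_OFF)
    low, high, report = ew.spectral_split(trace)
    rms = lambda x: np.sqrt(np.mean(x**2))
    assert rms(low.voltage) < 0.10 * rms(trace.voltage)
    assert rms(high.voltage) > 0.90 * rms(trace.voltage)
    assert report["op_band_energy_high"] > 0.9 * report["op_band_energy_input"]


def test_wds_only_trace_has_no_high_frequency_component(da3):
    lobes = replace(da3, a_amplitude=0.0, b_amplitude=0.0, op_amplitude=0.0)
    trace, _ = ew.generate_trace(lobes, ew.NOISE_OFF)
    low, high, _ = ew.spectral_split(trace)
    assert np.max(np.abs(high.voltage)) < 0.02 * np.max(np.abs(trace.voltage))
    assert np.max(low.voltage) == pytest.approx(np.max(trace.voltage), rel=0.05)


def test_zero_trace_splits_to_zero():
    low, high, _ = ew.spectral_split(_trace(0.0))
    assert np.allclose(low.voltage, 0.0, atol=1e-9)
    assert np.allclose(high.voltage, 0.0, atol=1e-9)


def test_wds_detector_invariant_to_op_burst(da3, da10):
    """Adding/removing the OP burst moves the detected WDS by <= 1 sample
    and <= 2% amplitude: the band-split logic in computational form."""
    for params in (da3, da10):
        with_op, _ = ew.generate_trace(params, ew.NOISE_OFF)
        without_op, _ = ew.generate_trace(replace(params, op_amplitude=0.0),
                                          ew.NOISE_OFF)
        feats = []
        for trace in (with_op, without_op):
            chain = analysis_chain(trace, notch=None)
            feats.append(ew.detect_wds(chain, ew.measure_ab(chain)))
        a, b = feats
        assert a.wds_present and b.wds_present
        assert abs(a.wds_implicit - b.wds_implicit) <= 0.5
        assert a.wds_voltage == pytest.approx(b.wds_voltage, rel=0.02)


# ---------------------------------------------------------------------------
# cohort extraction

def test_every_dark_adapted_trace_gets_a_difference_row(small_cohort):
    table = ew.extract_features(small_cohort.traces)
    wide = ew.feature_wide(table)
    assert len(wide) == len(small_cohort.traces)
    assert wide["wds_difference"].notna().all()


def test_full_attenuation_routes_operated_postop_through_fallback(dark_steps):
    spec = ew.CohortSpec(n_animals=3, steps=dark_steps, wds_attenuation=1.0,
                         seed=5)
    cohort = ew.generate_cohort(spec)
    wide = ew.feature_wide(ew.extract_features(cohort.traces))
    postop = wide[(wide.eye == "operated") & (wide.session != "baseline")]
    assert (postop.wds_fallback == 1.0).all()
    assert postop.wds_difference.notna().all()
    baseline_ctrl = wide[(wide.eye == "control")]
    assert (baseline_ctrl.wds_fallback == 0.0).mean() > 0.9


def test_higher_intensity_gives_smaller_control_difference(small_cohort):
    """Control eyes: the b-WDS difference decreases from 3 to 10 cd*s/m^2
    (the more prominent WDS at the higher flash strength)."""
    wide = ew.feature_wide(ew.extract_features(small_cohort.traces))
    ctrl = wide[wide.eye == "control"]
    d3 = ctrl[ctrl.step == 2].wds_difference.mean()
    d10 = ctrl[ctrl.step == 3].wds_difference.mean()
    assert d10 < d3


def test_recovered_wds_latency_statistics_match_ground_truth(da3):
    """Parameter recovery: over a few hundred noisy jittered control traces,
    the mean recovered WDS implicit time is within 1 ms of the configured
    64.0 ms and its SD within 25% of the configured 6.3 ms jitter."""
    from ergwave.simulate import draw_params

    rng = np.random.default_rng(2024)
    recovered = []
    for i in range(600):
        params = draw_params(rng, da3, rel_sd=0.15, wds_latency_sd=6.3)
        noise = ew.NoiseParams(white_sd=2.0, mains_amplitude=2.0, seed=int(i))
        trace, _ = ew.generate_trace(params, noise)
        chain = analysis_chain(trace)
        f = ew.detect_wds(chain, ew.measure_ab(chain))
        if f.wds_present:
            recovered.append(f.wds_implicit)
    recovered = np.array(recovered)
    assert recovered.size >= 540
    assert np.mean(recovered) == pytest.approx(64.0, abs=1.0)
    assert np.std(recovered, ddof=1) == pytest.approx(6.3, rel=0.25)
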