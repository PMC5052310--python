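"""Pulse detection, amplitude extraction, curve assembly and sigmoid fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest

from crir import (
    CRIRCurve,
    KnobSettings,
    RecordingConfig,
    assemble_curve,
    bessel_bandpass,
    build_protocol,
    classify_region,
    detect_pulses,
    fit_sigmoid,
    knob_to_params,
    measure_amplitude,
    simulate_recording,
)
from crir.analysis import AnalysisConfig, PulseMeasurement
from crir.signal_chain import RecordedTrace

FS = 5000.0
SETTINGS = KnobSettings(50, 65)


def _measurements(trace, protocol):
    return detect_pulses(trace, protocol)


def test_noiseless_detection_finds_all_pulses_at_delayed_times(protocol9, noiseless_trace):
    ms = _measurements(noiseless_trace, protocol9)
    assert len(ms) == 2 * protocol9.n_steps  # phase 0: two pulses per 350 ms flash
    for m in ms:
        assert not m.flags
        delay = m.pulse_time_s - m.expected_time_s
        assert 0.0 < delay < 0.01  # causal band-pass delay, well inside the window


def test_pure_noise_trace_flags_all_low_snr(protocol9):
    rng = np.random.default_rng(0)
    cfg = RecordingConfig()
    n = int(protocol9.total_duration_s * FS)
    trace = RecordedTrace(
        time=np.arange(n) / FS,
        v_filter=rng.normal(0, cfg.noise_rms_v, n),
        meta={"protocol": protocol9.to_dict(), "recording": cfg.to_dict()},
    )
    ms = detect_pulses(trace)
    assert ms and all("low_snr" in m.flags for m in ms)


def test_trace_shorter_than_protocol_raises(protocol9, noiseless_trace):
    short = RecordedTrace(
        time=noiseless_trace.time[:1000],
        v_filter=noiseless_trace.v_filter[:1000],
        meta=noiseless_trace.meta,
    )
    with pytest.raises(ValueError):
        detect_pulses(short, protocol9)


def test_measure_amplitude_matches_simulated_peak(protocol9, noiseless_trace):
    """Extracted amplitude equals the known post-filter peak of a clean pulse."""
    ms = _measurements(noiseless_trace, protocol9)
    top = [m for m in ms if m.step_index == protocol9.n_steps - 1]
    i0 = int(round(top[0].expected_time_s * FS))
    window = noiseless_trace.v_filter[i0 : i0 + int(0.02 * FS)]
    assert top[0].amplitude_v == pytest.approx(window.max(), abs=2e-7)


def test_measure_amplitude_flat_zero_window():
    amp, base, flags = measure_amplitude(np.zeros(100), np.zeros(100))
    assert amp == 0.0 and base == 0.0 and "low_snr" not in flags


def test_measure_amplitude_clipped_rail():
    rail = 0.05
    window = np.concatenate([np.zeros(10), np.full(5, rail), np.zeros(10)])
    amp, _, flags = measure_amplitude(window, np.zeros(50), rail_v=rail, lsb_v=1e-6)
    assert "clipped" in flags
    # a single rail sample is not clipping
    window1 = np.concatenate([np.zeros(10), [rail], np.zeros(10)])
    _, _, flags1 = measure_amplitude(window1, np.zeros(50), rail_v=rail, lsb_v=1e-6)
    assert "clipped" not in flags1


def test_measure_amplitude_rejects_empty_windows():
    with pytest.raises(ValueError):
        measure_amplitude(np.array([]), np.zeros(10))


def test_peak_to_peak_convention_option():
    window = np.array([0.0, 1.0, -0.4, 0.0])
    base = np.zeros(10)
    a_bp, _, _ = measure_amplitude(window, base)
    a_pp, _, _ = measure_amplitude(window, base, analysis=AnalysisConfig(peak_to_peak=True))
    assert a_bp == pytest.approx(1.0) and a_pp == pytest.approx(1.4)


def test_assemble_nine_points_two_pulses_each(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    assert curve.fittable
    assert len(curve.luminances) == 9
    assert list(curve.n_averaged) == [2] * 9
    assert curve.needs_repeat == ()
    assert np.all(np.diff(curve.amplitudes) > 0)  # monotone with luminance


def test_artifacted_step_merged_from_repeat(protocol9, noiseless_trace):
    ms = _measurements(noiseless_trace, protocol9)
    spoiled = [
        replace(m, flags=frozenset({"artifact"})) if m.step_index == 4 else m for m in ms
    ]
    curve = assemble_curve(spoiled, protocol9, SETTINGS)
    assert curve.needs_repeat == (4,)
    assert math.isnan(curve.amplitudes[4])
    repeat = {4: [m for m in ms if m.step_index == 4]}
    merged = assemble_curve(spoiled, protocol9, SETTINGS, repeats=repeat)
    assert merged.needs_repeat == ()
    assert merged.amplitudes[4] == pytest.approx(curve.amplitudes[3], rel=2)  # finite again
    assert list(merged.n_averaged) == [2] * 9


def test_empty_measurements_give_unfittable_curve(protocol9):
    curve = assemble_curve([], protocol9, SETTINGS)
    assert not curve.fittable
    assert len(curve.needs_repeat) == 9
    fit = fit_sigmoid(curve)
    assert not fit.converged and fit.degenerate


def _reference_vmax_amplitude():
    """Expected amplitude-domain plateau: chip v_max x attenuation x filter peak gain."""
    from crir.signal_chain import DEFAULT_COUPLING

    params = knob_to_params(SETTINGS)
    x = np.zeros(int(FS))
    x[1000:1005] = 1.0
    a = math.exp(-1.0 / (FS * DEFAULT_COUPLING.tau_s))
    from scipy.signal import lfilter

    pulse_gain = bessel_bandpass(lfilter([1, -1], [1, -a], x)).max()
    return params.v_max * DEFAULT_COUPLING.attenuation * pulse_gain


def test_noiseless_fit_recovers_generating_parameters(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    fit = fit_sigmoid(curve, seed=0)
    assert fit.converged and not fit.degenerate
    true = knob_to_params(SETTINGS)
    assert fit.params.x_mid == pytest.approx(true.x_mid, abs=0.05)
    assert fit.params.v_max == pytest.approx(_reference_vmax_amplitude(), rel=0.02)
    assert fit.rmse_v < 0.02 * fit.params.v_max


def test_noiseless_fit_dynamic_range_near_two_log_units(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    fit = fit_sigmoid(curve, seed=0)
    assert fit.dynamic_range_log10 == pytest.approx(2.0, abs=0.3)


def test_constant_amplitude_curve_is_degenerate(protocol9):
    curve = CRIRCurve(
        settings=SETTINGS,
        luminances=np.asarray(protocol9.luminances),
        amplitudes=np.full(9, 5e-3),
        n_averaged=np.ones(9, dtype=int),
    )
    fit = fit_sigmoid(curve)
    assert fit.degenerate
    with pytest.raises(ValueError):
        classify_region(1.0, fit)


def test_region_classification_and_boundary_tiebreak(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    fit = fit_sigmoid(curve, seed=0)
    l10, l90 = fit.region_bounds
    assert classify_region(l10 / 2, fit) == "subthreshold"
    assert classify_region(math.sqrt(l10 * l90), fit) == "slope"
    assert classify_region(l90 * 2, fit) == "saturation"
    # bounds belong to the slope region (closed interval)
    assert classify_region(l10, fit) == "slope"
    assert classify_region(l90, fit) == "slope"


def test_round_trip_ordering_over_settings_grid(protocol9, noiseless_cfg):
    """Simulate -> analyze -> fit reproduces the generating x_mid ordering
    across v_gl and v_max ordering across v_bias exactly."""
    v_gls = (10, 35, 60, 85)
    v_biases = (45, 65, 90)
    fits = {}
    for v_gl in v_gls:
        for v_bias in v_biases:
            s = KnobSettings(v_gl, v_bias)
            trace = simulate_recording(protocol9, s, cfg=noiseless_cfg)
            curve = assemble_curve(detect_pulses(trace, protocol9), protocol9, s)
            fits[(v_gl, v_bias)] = fit_sigmoid(curve, seed=0)
    for v_bias in v_biases:
        x_mids = [fits[(g, v_bias)].params.x_mid for g in v_gls]
        assert x_mids == sorted(x_mids) and len(set(x_mids)) == len(x_mids)
    for v_gl in v_gls:
        v_maxes = {b: fits[(v_gl, b)].params.v_max for b in v_biases}
        true = {b: knob_to_params(KnobSettings(v_gl, b)).v_max for b in v_biases}
        assert sorted(v_maxes, key=v_maxes.get) == sorted(true, key=true.get)


def test_amplitudes_invariant_to_dc_offset_and_equivariant_to_scaling(
    protocol9, noiseless_trace
):
    base = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    shifted = RecordedTrace(
        time=noiseless_trace.time,
        v_filter=noiseless_trace.v_filter + 3e-3,
        meta=noiseless_trace.meta,
    )
    c1 = assemble_curve(_measurements(shifted, protocol9), protocol9, SETTINGS)
    np.testing.assert_allclose(c1.amplitudes, base.amplitudes, atol=1e-12)
    scaled = RecordedTrace(
        time=noiseless_trace.time,
        v_filter=noiseless_trace.v_filter * 2.0,
        meta=noiseless_trace.meta,
    )
    c2 = assemble_curve(_measurements(scaled, protocol9), protocol9, SETTINGS)
    np.testing.assert_allclose(c2.amplitudes, 2.0 * base.amplitudes, rtol=1e-9)


def test_non_monotone_amplitudes_raise_data_quality_warning(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    bad = np.array(curve.amplitudes)
    bad[5] = bad[7] * 1.5  # implausible drop afterwards
    spoiled = CRIRCurve(
        settings=SETTINGS,
        luminances=curve.luminances,
        amplitudes=bad,
        n_averaged=curve.n_averaged,
    )
    fit = fit_sigmoid(spoiled, seed=0)
    assert any("non-monotone" in w for w in fit.warnings)


def test_unknown_flag_rejected():
    with pytest.raises(ValueError):
        PulseMeasurement(0, 0, 1.0, 1.0, 1e-3, 0.0, flags=frozenset({"bogus"}))


def test_curve_json_round_trip(protocol9, noiseless_trace):
    curve = assemble_curve(_measurements(noiseless_trace, protocol9), protocol9, SETTINGS)
    back = CRIRCurve.from_dict(curve.to_dict())
    np.testing.assert_allclose(back.amplitudes, curve.amplitudes)
    assert back.settings == curve.settings
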