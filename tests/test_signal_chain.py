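"""Forward chain: pulses, capacitive coupling, ADC, Bessel band-pass, noise."""

import numpy as np
import pytest
from scipy import signal as sps

from crir import (
    ChipConfig,
    KnobSettings,
    RecordingConfig,
    bessel_bandpass,
    build_protocol,
    couple_to_cornea,
    knob_to_params,
    measure_minus3db,
    simulate_recording,
    synthesize_chip_waveform,
    transfer_voltage,
)
from crir.signal_chain import (
    ConfigError,
    DEFAULT_COUPLING,
    add_noise_and_artifacts,
    amplify_and_digitize,
)

FS = 5000.0


def _single_pulse_chip(amplitude_scale=1.0, settings=KnobSettings(50, 65)):
    # 150 ms flash at 5 Hz holds exactly one chip pulse
    proto = build_protocol(100.0, 100.0, 0.5, flash_duration_ms=150.0, inter_step_interval_ms=500.0)
    return synthesize_chip_waveform(proto, settings, output_scale=amplitude_scale)


def test_chip_pulse_width_is_1ms_at_defaults(protocol9):
    cw = synthesize_chip_waveform(protocol9, KnobSettings(50, 65))
    nonzero = np.flatnonzero(cw.v_chip)
    runs = np.split(nonzero, np.where(np.diff(nonzero) > 1)[0] + 1)
    assert all(len(r) == round(1e-3 * FS) for r in runs)
    assert cw.pulse_duration_s == pytest.approx(1e-3)
    assert np.all(cw.v_chip >= 0)  # anodic monophasic


def test_chip_amplitudes_follow_transfer_oracle(protocol9):
    s = KnobSettings(50, 65)
    params = knob_to_params(s)
    cw = synthesize_chip_waveform(protocol9, s)
    for lum, onset in zip(protocol9.luminances, protocol9.flash_onsets):
        i0 = int(round(onset * FS))
        assert cw.v_chip[i0] == pytest.approx(transfer_voltage(lum, params), rel=1e-12)


def test_dark_output_amplitude_is_vmin():
    s = KnobSettings(50, 85)  # elevated dark output setting
    params = knob_to_params(s)
    proto = build_protocol(1e-6, 1e-6, 0.5)
    cw = synthesize_chip_waveform(proto, s)
    assert cw.v_chip.max() == pytest.approx(params.v_min, rel=1e-6)


def test_coupling_charge_balance_per_pulse():
    cw = _single_pulse_chip()
    co = couple_to_cornea(cw)
    i0 = int(round(cw.pulse_onsets[0] * FS))
    window = co.v_cornea[i0 : i0 + int(0.3 * FS)]
    pulse_area = np.max(np.abs(window)) * 1e-3  # peak x pulse-width scale, V*s
    assert abs(np.sum(window) / FS) < 1e-6 * pulse_area


def test_coupling_peak_is_attenuation_times_pulse_amplitude():
    cw = _single_pulse_chip()
    co = couple_to_cornea(cw)
    assert co.v_cornea.max() == pytest.approx(
        DEFAULT_COUPLING.attenuation * cw.v_chip.max(), rel=1e-9
    )


def test_coupling_linearity_by_superposition():
    cw1 = _single_pulse_chip(1.0)
    cw2 = _single_pulse_chip(2.0)
    y1 = couple_to_cornea(cw1).v_cornea
    y2 = couple_to_cornea(cw2).v_cornea
    np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-12, atol=1e-18)


def test_corneal_morphology_biphasic_dominant_first_lobe():
    cw = _single_pulse_chip()
    co = couple_to_cornea(cw)
    i0 = int(round(cw.pulse_onsets[0] * FS))
    seg = co.v_cornea[i0 : i0 + int(0.05 * FS)]
    peak_pos, peak_neg = seg.max(), seg.min()
    assert peak_pos > 0 > peak_neg  # biphasic
    assert peak_pos > abs(peak_neg)  # dominant anodic first lobe
    assert np.argmax(seg) < np.argmin(seg)  # overshoot follows pulse offset
    assert abs(seg[-1]) < 1e-6 * peak_pos  # returns to baseline


def test_positive_lobe_charge_reported():
    co = couple_to_cornea(_single_pulse_chip())
    assert len(co.q_chip) == 1 and co.q_chip[0] > 0


def test_corneal_peak_bounded_by_35mV_over_coarse_settings_grid(protocol9):
    """Simulated corneal CRIR amplitude never exceeds the 35 mV device bound."""
    proto = build_protocol(1000.0, 1000.0, 0.5, inter_step_interval_ms=500.0)
    peak = 0.0
    grid = list(range(0, 100, 11)) + [65]
    for v_bias in grid:
        cw = synthesize_chip_waveform(proto, KnobSettings(0, v_bias))
        peak = max(peak, couple_to_cornea(cw).v_cornea.max())
    assert 0.030 < peak <= 0.035  # calibrated optimum sits just below the bound


def test_adc_headroom_for_35mV_pulse_and_clipping_beyond():
    cfg = RecordingConfig(noise_rms_v=0.0)
    v, clipped = amplify_and_digitize(np.array([0.035]), cfg)  # 35 mV * 10 = 350 mV < 500 mV
    assert not clipped.any()
    v, clipped = amplify_and_digitize(np.array([0.02, 0.06, 0.07]), cfg)  # > 50 mV rails
    assert list(clipped) == [False, True, True]
    assert v[1] == pytest.approx(cfg.rail_v)


def test_adc_zero_in_zero_out_and_half_lsb_error():
    cfg = RecordingConfig()
    rng = np.random.default_rng(0)
    x = rng.uniform(-cfg.rail_v, cfg.rail_v, 1000)
    v, _ = amplify_and_digitize(x, cfg)
    assert amplify_and_digitize(np.zeros(3), cfg)[0] == pytest.approx(0.0)
    assert np.max(np.abs(v - x)) <= cfg.lsb_v / 2 + 1e-15


def test_bandpass_minus3db_points_within_2_percent():
    f_lo, f_hi = measure_minus3db(RecordingConfig())
    assert f_lo == pytest.approx(0.312, rel=0.02)
    assert f_hi == pytest.approx(300.0, rel=0.02)


def test_bandpass_rejects_cutoff_at_nyquist():
    with pytest.raises(ConfigError):
        RecordingConfig(f_high_hz=2500.0)


def test_dc_input_decays_to_zero():
    y = bessel_bandpass(np.ones(int(20 * FS)))
    assert abs(y[-1]) < 1e-4


def test_filter_delay_and_broadening_of_1ms_pulse():
    x = np.zeros(int(FS))
    x[1000:1005] = 1.0  # 1 ms pulse
    y = bessel_bandpass(x)
    peak = int(np.argmax(y))
    assert peak > 1000  # causal delay
    width_ms = np.count_nonzero(y > 0.1 * y[peak]) / FS * 1e3
    assert width_ms > 1.0  # broadened beyond the 1 ms input
    seg = y[1000:1400]
    assert seg.min() < 0 < seg.max() and seg.max() > abs(seg.min())  # biphasic response


def _analog_cascade():
    b_hp, a_hp = sps.bessel(2, 2 * np.pi * 0.312, "highpass", analog=True, norm="mag")
    b_lp, a_lp = sps.bessel(2, 2 * np.pi * 300.0, "lowpass", analog=True, norm="mag")
    return np.polymul(b_hp, b_lp), np.polymul(a_hp, a_lp)


@pytest.mark.parametrize("width_ms,tol", [(1, 0.03), (10, 0.005)])
def test_digital_filter_matches_analog_convolution_oracle(width_ms, tol):
    """Oracle: direct convolution with the analytic impulse response of the
    analog Bessel cascade (oversampled 20x for quadrature accuracy).  The
    bilinear realization deviates more for the 1 ms pulse, whose spectrum
    reaches the prewarping region, than for a 10 ms pulse."""
    b, a = _analog_cascade()
    os = 20
    fso = FS * os
    n = int(fso * 3.0)
    t = np.arange(n) / fso
    _, h = sps.impulse((b, a), T=t)
    x_fine = np.zeros(n)
    x_fine[100 * os : 100 * os + int(width_ms * 1e-3 * fso)] = 1.0
    y_oracle = sps.fftconvolve(x_fine, h)[:n] / fso
    x = np.zeros(int(FS * 3.0))
    x[100 : 100 + int(width_ms * 5)] = 1.0
    y_dig = bessel_bandpass(x)
    assert y_dig.max() == pytest.approx(y_oracle.max(), rel=tol)


def test_noise_zero_and_no_artifacts_is_identity():
    cfg = RecordingConfig(noise_rms_v=0.0)
    t = np.arange(1000) / FS
    x = np.sin(2 * np.pi * 10 * t) * 1e-3
    y, log = add_noise_and_artifacts(t, x, cfg)
    np.testing.assert_array_equal(y, x)
    assert log == []


def test_same_seed_reproduces_trace(protocol9):
    a = simulate_recording(protocol9, KnobSettings(50, 65), seed=11)
    b = simulate_recording(protocol9, KnobSettings(50, 65), seed=11)
    np.testing.assert_array_equal(a.v_filter, b.v_filter)
    c = simulate_recording(protocol9, KnobSettings(50, 65), seed=12)
    assert not np.array_equal(a.v_filter, c.v_filter)


def test_end_to_end_linearity_below_clipping(protocol9, noiseless_trace):
    """Recorded CRIR peak is proportional to the chip pulse amplitude."""
    from crir.analysis import detect_pulses

    s = KnobSettings(50, 65)
    params = knob_to_params(s)
    amps = {}
    for m in detect_pulses(noiseless_trace, protocol9):
        amps.setdefault(m.step_index, []).append(m.amplitude_v)
    x = np.array([transfer_voltage(l, params) for l in protocol9.luminances])
    y = np.array([np.mean(amps[i]) for i in range(protocol9.n_steps)])
    slope = np.sum(x * y) / np.sum(x * x)
    r2 = 1 - np.sum((y - slope * x) ** 2) / np.sum((y - y.mean()) ** 2)
    assert r2 > 0.999
    assert slope > 0


def test_trace_meta_carries_provenance(noisy_trace):
    meta = noisy_trace.meta
    assert meta["seed"] == 7
    assert meta["settings"] == {"v_gl": 50, "v_bias": 65}
    assert meta["recording"]["sampling_rate_hz"] == FS
    assert np.all(np.abs(noisy_trace.v_filter) <= 0.5 / 10 + 1e-12)
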