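"""Recover the in-vivo transfer characteristic from recorded traces.

The clinical workflow — read pulse amplitudes off the screen at each
luminance step, note them as a curve, and judge its shape — is formalized
here: stimulus-locked pulse windows, a fixed amplitude convention
(first-lobe peak minus pre-pulse median baseline), artifact/clipping/SNR
flags, per-step averaging with a repeat-merge policy, a seeded multi-start
four-parameter logistic fit in log10 luminance, and segmentation of the
fitted curve into subthreshold / slope / saturation regions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares
from scipy.special import expit

from .implant import ChipConfig, DynamicRange, KnobSettings, TransferParams, dynamic_range
from .protocol import StimulusProtocol, expected_pulse_times
from .signal_chain import RecordedTrace, RecordingConfig

__all__ = [
    "FLAG_VOCABULARY",
    "PulseMeasurement",
    "CRIRCurve",
    "SigmoidFit",
    "AnalysisConfig",
    "detect_pulses",
    "measure_amplitude",
    "assemble_curve",
    "fit_sigmoid",
    "classify_region",
    "predict_amplitude",
]

FLAG_VOCABULARY = frozenset({"clipped", "artifact", "low_snr"})

#: flags that make a pulse unusable for curve assembly
_EXCLUDING_FLAGS = frozenset({"clipped", "artifact"})


@dataclass(frozen=True)
class AnalysisConfig:
    """Windowing and flagging policy for pulse extraction.

    The ±20 ms search window absorbs the band-pass filter delay; the 50 ms
    pre-window baseline stays clear of the previous pulse at the 5 Hz frame
    rate.  ``snr_k`` multiplies the recording's noise RMS to give the
    detection threshold; ``peak_to_peak`` switches the amplitude convention
    from baseline-to-peak (default, as fitted curves are reported) to
    peak-to-peak.
    """

    search_halfwidth_s: float = 0.020
    baseline_s: float = 0.050
    snr_k: float = 5.0
    artifact_k: float = 12.0
    artifact_floor_v: float = 1e-3
    dropout_min_s: float = 0.005
    peak_to_peak: bool = False


DEFAULT_ANALYSIS = AnalysisConfig()


@dataclass(frozen=True)
class PulseMeasurement:
    """One stimulus-locked pulse: location, amplitude, baseline, flags."""

    step_index: int
    pulse_index: int
    expected_time_s: float
    pulse_time_s: float
    amplitude_v: float  # NaN when unmeasurable
    baseline_v: float
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not self.flags <= FLAG_VOCABULARY:
            raise ValueError(f"unknown flags {set(self.flags) - FLAG_VOCABULARY}")

    @property
    def usable(self) -> bool:
        return not (self.flags & _EXCLUDING_FLAGS) and math.isfinite(self.amplitude_v)


@dataclass(frozen=True)
class CRIRCurve:
    """Per-step averaged CRIR amplitudes versus flash luminance."""

    settings: KnobSettings
    luminances: np.ndarray  # cd/m^2, strictly increasing
    amplitudes: np.ndarray  # volts, NaN for steps without usable pulses
    n_averaged: np.ndarray  # pulses averaged per step
    needs_repeat: tuple = ()  # step indices with no usable pulse
    meta: dict = field(default_factory=dict)

    @property
    def fittable(self) -> bool:
        return int(np.count_nonzero(np.isfinite(self.amplitudes))) >= 3

    def to_dict(self) -> dict:
        return {
            "schema": "crir-curve-1",
            "settings": {"v_gl": self.settings.v_gl, "v_bias": self.settings.v_bias},
            "luminances_cd_m2": [float(v) for v in self.luminances],
            "amplitudes_v": [float(v) for v in self.amplitudes],
            "n_averaged": [int(v) for v in self.n_averaged],
            "needs_repeat": list(self.needs_repeat),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CRIRCurve":
        return cls(
            settings=KnobSettings(int(d["settings"]["v_gl"]), int(d["settings"]["v_bias"])),
            luminances=np.asarray(d["luminances_cd_m2"], dtype=float),
            amplitudes=np.asarray(d["amplitudes_v"], dtype=float),
            n_averaged=np.asarray(d["n_averaged"], dtype=int),
            needs_repeat=tuple(d.get("needs_repeat", ())),
        )


@dataclass(frozen=True)
class SigmoidFit:
    """Fitted four-parameter logistic plus region bounds and quality metrics."""

    params: Optional[TransferParams]  # amplitude domain (volts at amp input)
    region_bounds: Optional[tuple]  # (l_10pct, l_90pct) in cd/m^2
    dynamic_range_log10: Optional[float]
    rmse_v: float
    converged: bool
    degenerate: bool
    n_points: int
    warnings: tuple = ()

    def to_dict(self) -> dict:
        return {
            "schema": "crir-fit-1",
            "params": None
            if self.params is None
            else {
                "v_min": self.params.v_min,
                "v_max": self.params.v_max,
                "x_mid": self.params.x_mid,
                "slope": self.params.slope,
            },
            "region_bounds_cd_m2": None if self.region_bounds is None else list(self.region_bounds),
            "dynamic_range_log10": self.dynamic_range_log10,
            "rmse_v": self.rmse_v,
            "converged": self.converged,
            "degenerate": self.degenerate,
            "n_points": self.n_points,
            "warnings": list(self.warnings),
        }


def measure_amplitude(
    window: np.ndarray,
    baseline: np.ndarray,
    *,
    rail_v: float = math.inf,
    lsb_v: float = 0.0,
    noise_rms_v: float = 0.0,
    analysis: AnalysisConfig = DEFAULT_ANALYSIS,
    sampling_rate_hz: float = 5000.0,
) -> tuple[float, float, frozenset]:
    """Amplitude of one pulse window relative to its pre-pulse baseline.

    Amplitude is the dominant (positive) first-lobe extremum minus the median
    of the baseline window; with ``analysis.peak_to_peak`` the negative lobe
    is included.  Flags:

    * ``clipped`` — two or more consecutive samples at the amplifier rail;
    * ``artifact`` — baseline peak-to-peak excursion beyond
      ``max(artifact_k * noise, artifact_floor_v)``, or a flatline run of at
      least ``dropout_min_s`` when noise is present;
    * ``low_snr`` — amplitude below ``snr_k * noise``.

    Deterministic; raises on empty windows.
    """
    window = np.asarray(window, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if window.size == 0 or baseline.size == 0:
        raise ValueError("pulse and baseline windows must be non-empty")
    flags = set()
    base = float(np.median(baseline))
    peak = float(np.max(window))
    if analysis.peak_to_peak:
        amplitude = peak - float(np.min(window))
    else:
        amplitude = peak - base
    # clipping: >= 2 consecutive rail samples anywhere in the window
    at_rail = np.abs(window) >= rail_v - 1.5 * lsb_v
    if np.any(at_rail[:-1] & at_rail[1:]):
        flags.add("clipped")
    # artifact: baseline excursion far beyond the noise floor
    thresh = max(analysis.artifact_k * noise_rms_v, analysis.artifact_floor_v)
    if float(np.ptp(baseline)) > thresh:
        flags.add("artifact")
    if noise_rms_v > 0:
        run = int(round(analysis.dropout_min_s * sampling_rate_hz))
        joined = np.concatenate([baseline, window])
        if run >= 2 and joined.size >= run:
            same = np.diff(joined) == 0.0
            count = 0
            for s in same:
                count = count + 1 if s else 0
                if count >= run - 1:
                    flags.add("artifact")
                    break
    if amplitude < analysis.snr_k * noise_rms_v:
        flags.add("low_snr")
    return amplitude, base, frozenset(flags)


def detect_pulses(
    trace: RecordedTrace,
    protocol: Optional[StimulusProtocol] = None,
    chip: Optional[ChipConfig] = None,
    *,
    phase: Optional[float] = None,
    analysis: AnalysisConfig = DEFAULT_ANALYSIS,
) -> list:
    """Locate and measure every expected chip pulse in a recorded trace.

    One search window (expected time ± 20 ms, extended to the filtered
    pulse's delay) per expected pulse; missing pulses are reported with a
    ``low_snr`` flag rather than dropped, so the curve keeps its subthreshold
    points.  Protocol, chip and phase default to the trace metadata.
    """
    meta = trace.meta or {}
    if protocol is None:
        if "protocol" not in meta:
            raise ValueError("no protocol given and none in trace metadata")
        protocol = StimulusProtocol.from_dict(meta["protocol"])
    if chip is None:
        chip = ChipConfig(**meta["chip"]) if "chip" in meta else ChipConfig()
    if phase is None:
        phase = float(meta.get("phase_s", 0.0))
    cfg = (
        RecordingConfig.from_dict(meta["recording"])
        if "recording" in meta
        else RecordingConfig(sampling_rate_hz=trace.sampling_rate_hz)
    )
    fs = trace.sampling_rate_hz
    n = len(trace.v_filter)
    if trace.time[-1] + 1.0 / fs < protocol.flash_onsets[-1] + protocol.flash_duration_s:
        raise ValueError("trace is shorter than the protocol it claims to realize")
    noise = cfg.noise_rms_v
    out = []
    for step, times in enumerate(expected_pulse_times(protocol, chip, phase=phase)):
        for j, t in enumerate(times):
            i_lo = max(int(round((t - analysis.search_halfwidth_s) * fs)), 0)
            i_hi = min(int(round((t + analysis.search_halfwidth_s) * fs)) + 1, n)
            b_lo = max(int(round((t - analysis.search_halfwidth_s - analysis.baseline_s) * fs)), 0)
            window = trace.v_filter[i_lo:i_hi]
            baseline = trace.v_filter[b_lo:i_lo]
            amplitude, base, flags = measure_amplitude(
                window,
                baseline,
                rail_v=cfg.rail_v,
                lsb_v=cfg.lsb_v,
                noise_rms_v=noise,
                analysis=analysis,
                sampling_rate_hz=fs,
            )
            peak_idx = i_lo + int(np.argmax(window))
            out.append(
                PulseMeasurement(
                    step_index=step,
                    pulse_index=j,
                    expected_time_s=float(t),
                    pulse_time_s=float(trace.time[peak_idx]),
                    amplitude_v=amplitude,
                    baseline_v=base,
                    flags=flags,
                )
            )
    return out


def assemble_curve(
    measurements: Sequence[PulseMeasurement],
    protocol: StimulusProtocol,
    settings: KnobSettings,
    repeats: Optional[Mapping[int, Sequence[PulseMeasurement]]] = None,
    meta: Optional[dict] = None,
) -> CRIRCurve:
    """Average usable pulse amplitudes per luminance step into a CRIR curve.

    Artifact- or clip-flagged pulses are excluded; ``low_snr`` pulses are
    kept (their near-zero amplitude is the subthreshold information).  A step
    whose pulses are all excluded is marked for repeat, and filled from
    ``repeats[step]`` when a repeat recording's measurements are supplied —
    mirroring the clinical rule of repeating an artifacted luminance step.
    """
    per_step: dict[int, list] = {i: [] for i in range(protocol.n_steps)}
    for m in measurements:
        if m.step_index not in per_step:
            raise ValueError(f"measurement step {m.step_index} outside protocol")
        per_step[m.step_index].append(m)
    amplitudes = np.full(protocol.n_steps, np.nan)
    n_avg = np.zeros(protocol.n_steps, dtype=int)
    needs_repeat = []
    for step in range(protocol.n_steps):
        usable = [m for m in per_step[step] if m.usable]
        if not usable and repeats and step in repeats:
            usable = [m for m in repeats[step] if m.usable and m.step_index == step]
        if usable:
            amplitudes[step] = float(np.mean([m.amplitude_v for m in usable]))
            n_avg[step] = len(usable)
        else:
            needs_repeat.append(step)
    return CRIRCurve(
        settings=settings,
        luminances=np.asarray(protocol.luminances, dtype=float),
        amplitudes=amplitudes,
        n_averaged=n_avg,
        needs_repeat=tuple(needs_repeat),
        meta=meta or {},
    )


def _logistic4(x: np.ndarray, v_min: float, dv: float, x_mid: float, slope: float) -> np.ndarray:
    return v_min + dv * expit(slope * (x - x_mid))


def predict_amplitude(fit: "SigmoidFit", luminance) -> float:
    """Fitted CRIR amplitude (volts) at a luminance (cd/m^2)."""
    if fit.params is None:
        raise ValueError("fit has no parameters")
    p = fit.params
    lum = np.asarray(luminance, dtype=float)
    v = _logistic4(np.log10(lum), p.v_min, p.span, p.x_mid, p.slope)
    return float(v) if np.ndim(luminance) == 0 else v


def fit_sigmoid(
    curve: CRIRCurve,
    *,
    seed: int = 0,
    n_restarts: int = 5,
    lo_frac: float = 0.1,
    hi_frac: float = 0.9,
) -> SigmoidFit:
    """Least-squares four-parameter logistic fit in log10 luminance.

    Initialization: v_min/v_max from the amplitude extremes, x_mid from the
    half-range crossing, slope from the endpoint secant; then ``n_restarts``
    seeded jittered restarts, keeping the best cost.  Non-convergence and
    degeneracy (flat curve) are reported in the result, never raised.  Region
    bounds are the 10%/90% output crossings of the fitted curve.
    """
    finite = np.isfinite(curve.amplitudes)
    x = np.log10(curve.luminances[finite])
    y = curve.amplitudes[finite]
    n = int(finite.sum())
    if n < 3:
        return SigmoidFit(None, None, None, math.nan, False, True, n, ("unfittable: <3 points",))
    y_lo, y_hi = float(np.min(y)), float(np.max(y))
    span = y_hi - y_lo
    if span <= max(1e-12, 1e-6 * max(abs(y_lo), abs(y_hi))):
        return SigmoidFit(None, None, None, 0.0, False, True, n, ("degenerate: flat amplitudes",))

    # half-range crossing for the midpoint initial guess
    half = y_lo + 0.5 * span
    above = np.nonzero(y >= half)[0]
    x_mid0 = float(x[above[0]]) if len(above) else float(np.median(x))
    slope0 = 4.0 / max(float(x[-1] - x[0]), 1e-3)  # endpoint secant of a logistic
    p0 = np.array([max(y_lo, 0.0), span, x_mid0, max(slope0, 0.1)])
    lo = np.array([0.0, 0.0, x.min() - 5.0, 1e-2])
    hi = np.array([max(y_hi, 1e-12), 10.0 * max(span, 1e-12), x.max() + 5.0, 50.0])

    def resid(p: np.ndarray) -> np.ndarray:
        return _logistic4(x, *p) - y

    rng = np.random.default_rng(seed)
    best = None
    starts = [p0]
    for _ in range(max(n_restarts - 1, 0)):
        jitter = p0 * (1.0 + 0.3 * rng.standard_normal(4))
        starts.append(np.clip(jitter, lo + 1e-12, hi - 1e-12))
    for start in starts:
        try:
            res = least_squares(resid, np.clip(start, lo, hi), bounds=(lo, hi))
        except Exception:  # noqa: BLE001 - non-convergence is a reported state
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res
    if best is None:
        return SigmoidFit(None, None, None, math.nan, False, False, n, ("fit did not converge",))

    v_min, dv, x_mid, slope = (float(v) for v in best.x)
    params = TransferParams(v_min=v_min, v_max=v_min + dv, x_mid=x_mid, slope=slope)
    rmse = float(np.sqrt(np.mean(resid(best.x) ** 2)))
    warnings = []
    # robust residual scale so a single outlier cannot mask itself
    mad = float(np.median(np.abs(resid(best.x))))
    drop_tol = max(8.0 * mad, 1e-12)
    if np.any(np.diff(y) < -drop_tol):
        warnings.append("non-monotone amplitudes beyond noise tolerance")
    degenerate = dv <= max(1e-12, 1e-3 * max(abs(y_hi), 1e-12))
    if degenerate:
        return SigmoidFit(params, None, None, rmse, True, True, n, tuple(warnings))
    dr: DynamicRange = dynamic_range(params, lo_frac, hi_frac)
    return SigmoidFit(
        params=params,
        region_bounds=(dr.l_lo, dr.l_hi),
        dynamic_range_log10=dr.span_log10,
        rmse_v=rmse,
        converged=True,
        degenerate=False,
        n_points=n,
        warnings=tuple(warnings),
    )


def classify_region(luminance: float, fit: SigmoidFit) -> str:
    """Assign a luminance to the subthreshold, slope or saturation region.

    Regions are bounded by the fitted 10%/90% output crossings; the bounds
    themselves belong to the slope region (closed interval).  Luminance
    intervals are resolvable by the implant only when fully inside the slope
    region.
    """
    if not fit.converged or fit.degenerate or fit.region_bounds is None:
        raise ValueError("cannot classify regions on a degenerate or unconverged fit")
    if luminance <= 0:
        raise ValueError("luminance must be positive")
    l_lo, l_hi = fit.region_bounds
    if luminance < l_lo:
        return "subthreshold"
    if luminance > l_hi:
        return "saturation"
    return "slope"
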