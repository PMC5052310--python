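"""Settings selection over fitted CRIR curve families and device fault triage.

Clinical rules implemented:

* among curves whose slope (graded) region covers the ambient luminance
  range, prefer the lowest saturation output — good perception with the
  lowest possible stimulation voltage;
* reject curves with elevated output at low luminances (they stimulate
  continuously in the dark and compress the contrast range);
* triage a sudden loss of perception: no measurable pulses in any gaze
  direction points to a dead device (e.g. broken wire); pulses present only
  in some gaze directions, or coming and going across repeats, point to a
  loose connection; a clean, stable signal shifts suspicion to biological
  causes, which are outside the device's scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .analysis import SigmoidFit, classify_region, predict_amplitude
from .implant import KnobSettings
from .signal_chain import RecordingConfig

__all__ = [
    "CurveFamily",
    "Recommendation",
    "DiagnosisReport",
    "EquipmentReport",
    "REASON_CODES",
    "recommend_settings",
    "resolvable_contrast",
    "diagnose",
    "check_equipment",
]

REASON_CODES = ("no_coverage", "high_saturation_output", "elevated_dark_output")


@dataclass(frozen=True)
class CurveFamily:
    """Fitted CRIR curves for several knob combinations in one session."""

    entries: tuple  # of (KnobSettings, SigmoidFit)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        settings = [s for s, _ in self.entries]
        if len(set(settings)) != len(settings):
            raise ValueError("settings must be unique within a family")
        if not any(f.converged and not f.degenerate for _, f in self.entries):
            raise ValueError("family needs at least one converged, non-degenerate fit")


@dataclass(frozen=True)
class Recommendation:
    """Chosen knob settings with the full qualify/reject bookkeeping."""

    chosen: Optional[KnobSettings]
    qualifying: tuple  # KnobSettings that cover ambient with acceptable dark output
    rejected: tuple  # (KnobSettings, reason-code) pairs
    ambient_cd_m2: tuple  # (lo, hi)
    dark_luminance_cd_m2: float
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema": "crir-recommendation-1",
            "chosen": None if self.chosen is None else {"v_gl": self.chosen.v_gl, "v_bias": self.chosen.v_bias},
            "qualifying": [{"v_gl": s.v_gl, "v_bias": s.v_bias} for s in self.qualifying],
            "rejected": [
                {"v_gl": s.v_gl, "v_bias": s.v_bias, "reason": r} for s, r in self.rejected
            ],
            "ambient_cd_m2": list(self.ambient_cd_m2),
            "dark_luminance_cd_m2": self.dark_luminance_cd_m2,
            "details": self.details,
        }


def recommend_settings(
    family: CurveFamily,
    ambient: tuple,
    dark_luminance: float = 0.01,
    *,
    dark_frac: float = 0.10,
    max_saturation_v: Optional[float] = None,
) -> Recommendation:
    """Pick the knob combination for an ambient luminance range.

    A curve qualifies when (a) its fit converged, (b) its slope region fully
    contains ``ambient = (lo, hi)`` cd/m^2, (c) its fitted output at
    ``dark_luminance`` does not exceed ``dark_frac`` of the family-wide
    maximum output, and (d) — when ``max_saturation_v`` is set — its
    saturation output stays below that absolute safety cap
    (``high_saturation_output`` otherwise).  Among qualifying curves the one
    with the lowest saturation output wins; ties go to the lower dark
    output, then the lower v_bias.  With no qualifying curve an empty
    recommendation with per-curve reasons is returned, never an exception.
    """
    lo, hi = float(ambient[0]), float(ambient[1])
    if not 0 < lo <= hi:
        raise ValueError("ambient interval must be positive and ordered")
    if dark_luminance <= 0:
        raise ValueError("dark_luminance must be positive")
    usable = [(s, f) for s, f in family.entries if f.converged and not f.degenerate]
    family_max = max(f.params.v_max for _, f in usable)
    qualifying: list[KnobSettings] = []
    rejected: list[tuple] = []
    details: dict = {}
    candidates = []
    # deterministic processing order makes the result order-invariant
    for settings, fit in sorted(family.entries, key=lambda e: (e[0].v_gl, e[0].v_bias)):
        key = settings.label
        if not fit.converged or fit.degenerate or fit.region_bounds is None:
            rejected.append((settings, "no_coverage"))
            details[key] = {"reason": "no_coverage", "note": "fit unusable"}
            continue
        l10, l90 = fit.region_bounds
        dark_out = predict_amplitude(fit, dark_luminance)
        details[key] = {
            "slope_region_cd_m2": [l10, l90],
            "v_max": fit.params.v_max,
            "dark_output_v": dark_out,
        }
        if not (l10 <= lo and hi <= l90):
            rejected.append((settings, "no_coverage"))
            details[key]["reason"] = "no_coverage"
            continue
        if dark_out > dark_frac * family_max:
            rejected.append((settings, "elevated_dark_output"))
            details[key]["reason"] = "elevated_dark_output"
            continue
        if max_saturation_v is not None and fit.params.v_max > max_saturation_v:
            rejected.append((settings, "high_saturation_output"))
            details[key]["reason"] = "high_saturation_output"
            continue
        qualifying.append(settings)
        candidates.append((fit.params.v_max, dark_out, settings.v_bias, settings))
    chosen = min(candidates)[3] if candidates else None
    return Recommendation(
        chosen=chosen,
        qualifying=tuple(qualifying),
        rejected=tuple(rejected),
        ambient_cd_m2=(lo, hi),
        dark_luminance_cd_m2=float(dark_luminance),
        details=details,
    )


def resolvable_contrast(fit: SigmoidFit, l1: float, l2: float) -> tuple[bool, float]:
    """Can the implant distinguish two luminances, and by how much output?

    True only when both luminances fall in the slope region of the fitted
    curve — in the subthreshold or saturation regions different luminances
    produce (nearly) identical output and contrast borders are invisible.
    Returns the predicted amplitude difference alongside.
    """
    if l1 == l2:
        raise ValueError("luminances must differ")
    r1 = classify_region(l1, fit)
    r2 = classify_region(l2, fit)
    diff = abs(predict_amplitude(fit, l2) - predict_amplitude(fit, l1))
    return (r1 == "slope" and r2 == "slope"), float(diff)


@dataclass(frozen=True)
class DiagnosisReport:
    """Rule-based device status with the evidence to re-derive it."""

    status: str  # device_output_absent | gaze_dependent_intermittent | device_functional
    evidence: dict  # per gaze condition: per-repeat max amplitudes + detection flags
    threshold_v: float
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "schema": "crir-diagnosis-1",
            "status": self.status,
            "evidence": self.evidence,
            "threshold_v": self.threshold_v,
            "note": self.note,
        }


def diagnose(
    recordings: Mapping[str, Sequence],
    noise_rms_v: float,
    *,
    k: float = 5.0,
) -> DiagnosisReport:
    """Triage device status from per-gaze-condition pulse amplitude sets.

    ``recordings`` maps a gaze-condition label to a list of repeats, each a
    sequence of pulse amplitudes (volts).  A repeat "has output" when its
    largest amplitude reaches ``k * noise_rms_v``.  Rule order:

    a. no condition has output in any repeat → ``device_output_absent``
       (e.g. a damaged wire);
    b. output present in some but not all gaze conditions, or present
       intermittently across repeats within a condition →
       ``gaze_dependent_intermittent`` (e.g. a loose cable connection);
    c. otherwise ``device_functional`` — a persisting perception problem
       then points to biological causes, outside device scope.
    """
    if not recordings:
        raise ValueError("at least one gaze condition is required")
    threshold = k * noise_rms_v
    evidence: dict = {}
    any_detected = False
    all_conditions_detected = True
    intermittent = False
    for label in sorted(recordings):
        repeats = list(recordings[label])
        if not repeats:
            raise ValueError(f"gaze condition {label!r} has no repeats")
        maxima = [float(np.max(r)) if len(np.atleast_1d(r)) else 0.0 for r in repeats]
        detected = [m >= threshold for m in maxima]
        evidence[label] = {"max_amplitudes_v": maxima, "detected": detected}
        cond_detected = any(detected)
        any_detected = any_detected or cond_detected
        all_conditions_detected = all_conditions_detected and all(detected)
        if cond_detected and not all(detected):
            intermittent = True
    if not any_detected:
        status, note = "device_output_absent", "no pulses above threshold in any gaze direction"
    elif not all_conditions_detected or intermittent:
        status, note = (
            "gaze_dependent_intermittent",
            "pulses present only in some gaze directions or repeats; suspect loose connection",
        )
    else:
        status, note = (
            "device_functional",
            "stable output in all gaze directions; biological causes are outside device scope",
        )
    return DiagnosisReport(status=status, evidence=evidence, threshold_v=threshold, note=note)


@dataclass(frozen=True)
class EquipmentReport:
    """Pass/fail checklist for the recording equipment."""

    items: tuple  # (name, passed, detail)

    @property
    def all_pass(self) -> bool:
        return all(ok for _, ok, _ in self.items)

    def to_dict(self) -> dict:
        return {
            "schema": "crir-equipment-1",
            "items": [{"name": n, "passed": ok, "detail": d} for n, ok, d in self.items],
            "all_pass": self.all_pass,
        }


#: largest corneal response amplitude the recorder must handle unclipped
MAX_CRIR_AMPLITUDE_V = 0.035
MIN_SAMPLING_HZ = 1000.0
RECOMMENDED_SAMPLING_HZ = 5000.0
MIN_STIMULATOR_CD_M2 = 500.0


def check_equipment(
    cfg: RecordingConfig, stimulator_max_cd_m2: float
) -> EquipmentReport:
    """Check an ERG setup against the requirements for CRIR recording.

    Three items: sampling rate of at least 1 kHz (5 kHz recommended, given
    the 1 ms pulse), unclipped headroom for corneal pulses up to 35 mV, and
    a stimulator reaching at least 500 cd/m^2 (daily-living light levels).
    """
    items = (
        (
            "sampling_rate",
            cfg.sampling_rate_hz >= MIN_SAMPLING_HZ,
            f"{cfg.sampling_rate_hz:g} Hz (minimum {MIN_SAMPLING_HZ:g}, "
            f"recommended {RECOMMENDED_SAMPLING_HZ:g})",
        ),
        (
            "amplitude_headroom",
            cfg.rail_v >= MAX_CRIR_AMPLITUDE_V,
            f"input headroom {cfg.rail_v * 1e3:g} mV for pulses up to "
            f"{MAX_CRIR_AMPLITUDE_V * 1e3:g} mV",
        ),
        (
            "stimulator_luminance",
            stimulator_max_cd_m2 >= MIN_STIMULATOR_CD_M2,
            f"{stimulator_max_cd_m2:g} cd/m^2 (minimum {MIN_STIMULATOR_CD_M2:g})",
        ),
    )
    return EquipmentReport(items=items)
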