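"""Luminance-step flash protocol and stimulus-locked timing grid.

The clinical recording protocol presents a series of long-duration (350 ms)
full-field flashes of increasing photopic luminance — by default 9 steps from
0.1 to 1000 cd/m^2 in 0.5 log10 steps.  The chip free-runs at its working
frequency (5 Hz), so each 350 ms flash captures one or two chip pulses
depending on the phase of the pulse train relative to flash onset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .implant import ChipConfig

__all__ = ["StimulusProtocol", "build_protocol", "expected_pulse_times"]

_LOG_SPACING_TOL = 1e-9


@dataclass(frozen=True)
class StimulusProtocol:
    """An ordered series of full-field flashes of increasing luminance.

    Times are in seconds from trace start; luminances in photopic cd/m^2.
    ``lead_in_s`` of darkness precedes the first flash so baselines and the
    band-pass filter can settle.
    """

    luminances: tuple
    flash_duration_ms: float = 350.0
    inter_step_interval_ms: float = 2000.0
    lead_in_s: float = 1.0

    def __post_init__(self) -> None:
        lum = np.asarray(self.luminances, dtype=float)
        if lum.size == 0:
            raise ValueError("protocol needs at least one luminance step")
        if np.any(lum <= 0.0):
            raise ValueError("luminances must be positive (cd/m^2)")
        if lum.size > 1:
            steps = np.diff(np.log10(lum))
            if np.any(steps <= 0.0):
                raise ValueError("luminances must be strictly increasing")
            if np.any(np.abs(steps - steps[0]) > _LOG_SPACING_TOL):
                raise ValueError("luminances must be uniformly spaced in log10")
        if self.flash_duration_ms <= 0.0 or self.inter_step_interval_ms <= 0.0:
            raise ValueError("flash duration and inter-step interval must be positive")
        object.__setattr__(self, "luminances", tuple(float(v) for v in lum))

    @property
    def n_steps(self) -> int:
        return len(self.luminances)

    @property
    def flash_duration_s(self) -> float:
        return self.flash_duration_ms * 1e-3

    @property
    def step_period_s(self) -> float:
        return (self.flash_duration_ms + self.inter_step_interval_ms) * 1e-3

    @property
    def flash_onsets(self) -> np.ndarray:
        """Flash onset times in seconds (non-overlapping by construction)."""
        return self.lead_in_s + np.arange(self.n_steps) * self.step_period_s

    @property
    def total_duration_s(self) -> float:
        return self.lead_in_s + self.n_steps * self.step_period_s

    @property
    def log_step(self) -> float:
        if self.n_steps < 2:
            return 0.0
        return math.log10(self.luminances[1] / self.luminances[0])

    def to_dict(self) -> dict:
        return {
            "luminances_cd_m2": list(self.luminances),
            "flash_duration_ms": self.flash_duration_ms,
            "inter_step_interval_ms": self.inter_step_interval_ms,
            "lead_in_s": self.lead_in_s,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(
            luminances=tuple(d["luminances_cd_m2"]),
            flash_duration_ms=d["flash_duration_ms"],
            inter_step_interval_ms=d["inter_step_interval_ms"],
            lead_in_s=d["lead_in_s"],
        )


def build_protocol(
    l_min: float = 0.1,
    l_max: float = 1000.0,
    log_step: float = 0.5,
    flash_duration_ms: float = 350.0,
    inter_step_interval_ms: float = 2000.0,
    lead_in_s: float = 1.0,
) -> StimulusProtocol:
    """Geometric luminance series from ``l_min`` up to at most ``l_max``.

    Levels are ``l_min * 10**(k*log_step)`` for ``k = 0..floor(log10(l_max /
    l_min)/log_step)``; the defaults reproduce the clinical 9-step series
    0.1 → 1000 cd/m^2 in 0.5 log steps.
    """
    if l_min <= 0.0 or l_max < l_min or log_step <= 0.0:
        raise ValueError("require l_min > 0, l_max >= l_min, log_step > 0")
    n_steps = int(math.floor(math.log10(l_max / l_min) / log_step + 1e-9)) + 1
    luminances = tuple(l_min * 10.0 ** (k * log_step) for k in range(n_steps))
    return StimulusProtocol(
        luminances=luminances,
        flash_duration_ms=flash_duration_ms,
        inter_step_interval_ms=inter_step_interval_ms,
        lead_in_s=lead_in_s,
    )


def expected_pulse_times(
    protocol: StimulusProtocol, chip: ChipConfig, phase: float = 0.0
) -> list:
    """Chip pulse onset times (s) falling inside each flash window.

    The chip free-runs at its working frequency; ``phase`` is the delay of
    the first pulse after flash onset (the train is not stimulus-locked in
    the clinic, so the phase is arbitrary).  At the 350 ms / 5 Hz defaults
    each flash contains one or two pulses depending on phase.

    Returns one ``np.ndarray`` of onset times per protocol step.
    """
    period = chip.frame_period_s
    if not 0.0 <= phase < period:
        raise ValueError(f"phase must lie in [0, {period}) s, got {phase}")
    flash = protocol.flash_duration_s
    out = []
    for onset in protocol.flash_onsets:
        k_max = int(math.ceil((flash - phase) / period))
        times = onset + phase + period * np.arange(max(k_max, 0))
        out.append(times[times - onset < flash])
    return out
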