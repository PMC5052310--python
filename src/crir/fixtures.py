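"""Seeded synthetic session generator standing in for patient recordings.

Each scenario realizes a clinically meaningful situation end to end through
the forward simulator, with the generating ground truth embedded in the
bundle for tests:

* ``clean_family`` — a session of several v_gl/v_bias combinations at the
  default noise level, the normal settings-selection workflow;
* ``vgl_sweep`` — noiseless sensitivity sweep: the curve translates along
  the log-luminance axis;
* ``vbias_sweep`` — noiseless gain sweep: the saturation output is unimodal
  with its in-vivo optimum between knob values 55 and 75;
* ``elevated_dark`` — a high-gain setting with raised dark output alongside
  a healthy one, exercising the dark-output rejection rule;
* ``broken_wire`` — no device output in any gaze direction;
* ``loose_connection`` — output present in only a random subset of gaze
  directions;
* ``artifact_heavy`` — blink and dropout artifacts plus a clean repeat of
  the spoiled steps.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .implant import ChipConfig, KnobSettings
from .protocol import StimulusProtocol, build_protocol
from .signal_chain import (
    BlinkArtifact,
    DropoutArtifact,
    RecordedTrace,
    RecordingConfig,
    simulate_recording,
)

__all__ = ["SCENARIOS", "BundleEntry", "SessionBundle", "generate_fixture"]

SCENARIOS = (
    "clean_family",
    "vgl_sweep",
    "vbias_sweep",
    "elevated_dark",
    "broken_wire",
    "loose_connection",
    "artifact_heavy",
)

GAZE_DIRECTIONS = ("center", "up", "down", "left", "right")


@dataclass(frozen=True)
class BundleEntry:
    """One recorded trace with its acquisition labels."""

    label: str
    settings: KnobSettings
    trace: RecordedTrace
    gaze: Optional[str] = None
    repeat: int = 0


@dataclass(frozen=True)
class SessionBundle:
    """A self-contained synthetic recording session with ground truth."""

    scenario: str
    seed: int
    chip: ChipConfig
    recording: RecordingConfig
    protocol: StimulusProtocol
    entries: tuple
    ground_truth: dict = field(default_factory=dict)
    version: str = "crir-bundle-1"


def _short_protocol() -> StimulusProtocol:
    # 3-step series for the quick per-gaze triage recordings
    return build_protocol(1.0, 100.0, 1.0, inter_step_interval_ms=650.0)


def generate_fixture(scenario: str, seed: int = 0) -> SessionBundle:
    """Build the named scenario with all randomness derived from ``seed``."""
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; options: {', '.join(SCENARIOS)}")
    rng = np.random.default_rng(seed)
    chip = ChipConfig()
    cfg = RecordingConfig(seed=seed)
    noiseless = replace(cfg, noise_rms_v=0.0)
    protocol = build_protocol()
    entries: list[BundleEntry] = []
    truth: dict = {}

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    if scenario == "clean_family":
        combos = [(30, 65), (50, 65), (70, 65), (50, 45), (50, 55), (50, 80)]
        for v_gl, v_bias in combos:
            s = KnobSettings(v_gl, v_bias)
            entries.append(
                BundleEntry(s.label, s, simulate_recording(protocol, s, chip, cfg, seed=sub_seed()))
            )
        truth["combos"] = combos

    elif scenario == "vgl_sweep":
        v_bias = 65
        for v_gl in (10, 30, 50, 70, 90):
            s = KnobSettings(v_gl, v_bias)
            entries.append(BundleEntry(s.label, s, simulate_recording(protocol, s, chip, noiseless)))
        truth["v_gl_values"] = [10, 30, 50, 70, 90]

    elif scenario == "vbias_sweep":
        v_gl = 50
        values = [5, 25, 45, 55, 65, 75, 85, 95]
        for v_bias in values:
            s = KnobSettings(v_gl, v_bias)
            entries.append(BundleEntry(s.label, s, simulate_recording(protocol, s, chip, noiseless)))
        truth["v_bias_values"] = values

    elif scenario == "elevated_dark":
        for v_gl, v_bias in ((50, 65), (50, 85)):
            s = KnobSettings(v_gl, v_bias)
            entries.append(
                BundleEntry(s.label, s, simulate_recording(protocol, s, chip, cfg, seed=sub_seed()))
            )
        truth["elevated"] = "50/85"

    elif scenario in ("broken_wire", "loose_connection"):
        protocol = _short_protocol()
        s = KnobSettings(50, 65)
        if scenario == "broken_wire":
            connected = {g: False for g in GAZE_DIRECTIONS}
        else:
            n_connected = int(rng.integers(1, len(GAZE_DIRECTIONS)))
            chosen = rng.choice(len(GAZE_DIRECTIONS), size=n_connected, replace=False)
            connected = {g: (i in set(chosen)) for i, g in enumerate(GAZE_DIRECTIONS)}
        for gaze in GAZE_DIRECTIONS:
            for rep in range(2):
                trace = simulate_recording(
                    protocol,
                    s,
                    chip,
                    cfg,
                    output_scale=1.0 if connected[gaze] else 0.0,
                    seed=sub_seed(),
                )
                entries.append(BundleEntry(f"{gaze}#{rep}", s, trace, gaze=gaze, repeat=rep))
        truth["connected_gazes"] = {g: bool(c) for g, c in connected.items()}
        truth["expected_status"] = (
            "device_output_absent" if scenario == "broken_wire" else "gaze_dependent_intermittent"
        )

    elif scenario == "artifact_heavy":
        s = KnobSettings(50, 65)
        onsets = protocol.flash_onsets
        arts = (
            BlinkArtifact(onset_s=float(onsets[4] - 0.05), duration_s=0.3, amplitude_v=0.02),
            DropoutArtifact(onset_s=float(onsets[6] - 0.05), duration_s=0.3),
        )
        entries.append(
            BundleEntry(s.label, s, simulate_recording(protocol, s, chip, cfg, artifacts=arts, seed=sub_seed()))
        )
        entries.append(
            BundleEntry(s.label + "#repeat", s, simulate_recording(protocol, s, chip, cfg, seed=sub_seed()), repeat=1)
        )
        truth["artifact_steps"] = [4, 6]

    return SessionBundle(
        scenario=scenario,
        seed=seed,
        chip=chip,
        recording=cfg if scenario not in ("vgl_sweep", "vbias_sweep") else noiseless,
        protocol=protocol,
        entries=tuple(entries),
        ground_truth=truth,
    )
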