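"""Compose simulate → analyze → fit → advise/diagnose over a session bundle."""

from __future__ import annotations

import logging
from collections import defaultdict
from pathlib import Path
from typing import Optional

from .advisor import CurveFamily, diagnose, recommend_settings
from .analysis import assemble_curve, detect_pulses, fit_sigmoid
from .fixtures import SessionBundle
from .io import write_json

__all__ = ["PipelineError", "run_pipeline"]

logger = logging.getLogger("crir")


class PipelineError(RuntimeError):
    """Structural failure in a pipeline stage; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def run_pipeline(
    bundle: SessionBundle,
    outdir: Optional[Path] = None,
    ambient: tuple = (2.0, 100.0),
) -> dict:
    """Analyze every trace in a bundle and run the appropriate decision stage.

    Gaze-labeled bundles (fault-triage scenarios) end in a diagnosis report;
    settings-family bundles end in a settings recommendation over the fitted
    curves.  Returns a JSON-serializable results dict; writes
    ``results.json`` into ``outdir`` when given.  All randomness comes from
    the bundle's seed, so reruns are byte-identical.
    """
    if not bundle.entries:
        raise PipelineError("analyze", "bundle contains no traces")
    results: dict = {"schema": "crir-results-1", "scenario": bundle.scenario, "seed": bundle.seed}
    warnings: list[str] = []

    measurements = {}
    for entry in bundle.entries:
        try:
            measurements[entry.label] = detect_pulses(entry.trace, bundle.protocol, bundle.chip)
        except ValueError as exc:
            raise PipelineError("detect", str(exc)) from exc
        logger.info("detect: %s -> %d pulses", entry.label, len(measurements[entry.label]))

    gaze_labeled = any(e.gaze is not None for e in bundle.entries)
    if gaze_labeled:
        conditions = defaultdict(list)
        for entry in bundle.entries:
            amps = [m.amplitude_v for m in measurements[entry.label]]
            conditions[entry.gaze].append(amps)
        report = diagnose(dict(conditions), bundle.recording.noise_rms_v)
        results["diagnosis"] = report.to_dict()
    else:
        curves, fits, family_entries = {}, {}, []
        repeat_measurements = {
            e.label.rsplit("#", 1)[0]: measurements[e.label]
            for e in bundle.entries
            if e.repeat > 0
        }
        primary = [e for e in bundle.entries if e.repeat == 0]
        for entry in primary:
            repeats = None
            if entry.label in repeat_measurements:
                by_step = defaultdict(list)
                for m in repeat_measurements[entry.label]:
                    by_step[m.step_index].append(m)
                repeats = dict(by_step)
            curve = assemble_curve(
                measurements[entry.label], bundle.protocol, entry.settings, repeats=repeats
            )
            fit = fit_sigmoid(curve, seed=bundle.seed)
            warnings.extend(f"{entry.label}: {w}" for w in fit.warnings)
            curves[entry.label] = curve.to_dict()
            fits[entry.label] = fit.to_dict()
            family_entries.append((entry.settings, fit))
            logger.info("fit: %s converged=%s", entry.label, fit.converged)
        results["curves"] = curves
        results["fits"] = fits
        try:
            family = CurveFamily(entries=tuple(family_entries))
        except ValueError as exc:
            raise PipelineError("advise", str(exc)) from exc
        results["recommendation"] = recommend_settings(family, ambient).to_dict()

    results["warnings"] = warnings
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_json(outdir / "results.json", results)
    return results
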