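"""Amplitude-versus-log-luminance plots with region shading."""

from __future__ import annotations

import numpy as np

from .analysis import CRIRCurve, SigmoidFit, predict_amplitude

__all__ = ["plot_curve"]


def plot_curve(curve: CRIRCurve, fit: SigmoidFit | None = None, ax=None):
    """Plot one CRIR curve (mV vs log luminance), optionally with its fit.

    The slope region of the fitted curve is shaded; the subthreshold and
    saturation regions are left white.  Returns the matplotlib axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.semilogx(curve.luminances, curve.amplitudes * 1e3, "o", label=curve.settings.label)
    if fit is not None and fit.converged and not fit.degenerate:
        lum = np.logspace(
            np.log10(curve.luminances[0]) - 0.5, np.log10(curve.luminances[-1]) + 0.5, 200
        )
        ax.semilogx(lum, predict_amplitude(fit, lum) * 1e3, "-", lw=1)
        l10, l90 = fit.region_bounds
        ax.axvspan(l10, l90, alpha=0.15, label="slope region")
    ax.set_xlabel("luminance (cd/m$^2$)")
    ax.set_ylabel("CRIR amplitude (mV)")
    ax.legend(fontsize=8)
    return ax
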