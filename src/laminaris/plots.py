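"""Figure helpers: ITD curves with cosine overlays and phase–frequency fits."""

from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from . import itd as _itd


def plot_itd_curve(curve, fit=None, ax=None):
    """One ITD curve (mean ± SD) with its cosine fit overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(curve.itds, curve.mean_response, yerr=curve.response_sd,
                fmt="o", ms=4, capsize=2,
                label=f"{curve.stimulus_frequency:.0f} Hz")
    if fit is not None:
        grid = np.linspace(curve.itds.min(), curve.itds.max(), 400)
        ax.plot(grid, fit.predict(grid), "--", lw=1)
    ax.axvline(0, color="k", ls=":", lw=0.8)
    ax.set_xlabel("ITD (μs, negative = ipsi-leading)")
    ax.set_ylabel("response")
    return ax


def plot_phase_frequency(pf_fit, ax=None):
    """Unwrapped best IPD vs frequency with the CD/CP regression line."""
    if ax is None:
        _, ax = plt.subplots()
    f = np.array([p[0] for p in pf_fit.points])
    y = np.array([p[1] for p in pf_fit.points])
    ax.plot(f, y, "o")
    grid = np.linspace(f.min(), f.max(), 50)
    ax.plot(grid, pf_fit.cd * 1e-6 * grid + pf_fit.intercept, "-",
            label=f"CD={pf_fit.cd:.0f} μs, CP={pf_fit.cp:.2f} cyc")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("best IPD (cycles)")
    ax.legend(fontsize=8)
    return ax


def plot_site_overview(site, path) -> Path:
    """ITD curves at every tested frequency of one site, saved to ``path``."""
    freqs = site.test_frequencies()
    fig, ax = plt.subplots(figsize=(6, 4))
    metric = "analog" if site.recording_kind == "neurophonic" else "spike_rate"
    for f in freqs:
        curve = _itd.itd_curve_from_epochs(site.epochs_at(f), f, metric=metric)
        try:
            fit = _itd.fit_cosine(curve)
        except ValueError:
            fit = None
        plot_itd_curve(curve, fit, ax=ax)
    ax.legend(fontsize=7)
    ax.set_title(site.site_id)
    path = Path(path)
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    return path
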