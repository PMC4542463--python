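"""Recording-type classification and per-condition response summaries.

A site is classified offline from its recorded data as a single unit (at
most 1% of interspike intervals shorter than the 1 ms refractory period),
a multi-unit spike recording, or a neurophonic (analog field potential).
"""

from __future__ import annotations

from collections import OrderedDict
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .containers import Epoch, RecordingSite, ResponseSummary, StimulusCondition

ISI_REFRACTORY_MS = 1.0
ISI_VIOLATION_MAX = 0.01
DEFAULT_WINDOW = (10.0, 60.0)
STEADY_WINDOW = (15.0, 55.0)


class UnclassifiableRecording(ValueError):
    """Raised when too few spikes exist to apply the ISI criterion."""


def classify_single_unit(epochs: Iterable[Epoch]) -> Tuple[bool, float]:
    """Apply the refractory-period criterion for single-unit isolation.

    Interspike intervals are pooled within epochs (never across the gap
    between epochs). Returns ``(is_single_unit, violation_fraction)`` where
    the recording qualifies as a single unit iff at most 1% of ISIs are
    shorter than 1 ms.
    """
    isis: list = []
    total_spikes = 0
    for e in epochs:
        total_spikes += e.n_spikes
        if e.n_spikes >= 2:
            isis.append(np.diff(e.spike_times))
    if total_spikes < 2 or not isis:
        raise UnclassifiableRecording(
            "need at least two spikes within one epoch to compute ISIs")
    all_isis = np.concatenate(isis)
    frac = float(np.mean(all_isis < ISI_REFRACTORY_MS))
    return frac <= ISI_VIOLATION_MAX, frac


def classify_recording(site: RecordingSite) -> str:
    """Assign single_unit / multi_unit / neurophonic from the recorded data."""
    has_spikes = any(e.n_spikes > 0 for e in site.epochs)
    has_analog = any(e.analog is not None for e in site.epochs)
    if has_spikes:
        try:
            single, _ = classify_single_unit(site.epochs)
        except UnclassifiableRecording:
            return "unclassified"
        return "single_unit" if single else "multi_unit"
    if has_analog:
        return "neurophonic"
    return "unclassified"


def _window_rate(epoch: Epoch, window: Tuple[float, float]) -> float:
    lo, hi = window
    count = np.count_nonzero((epoch.spike_times >= lo) & (epoch.spike_times < hi))
    return 1000.0 * count / (hi - lo)


def analog_amplitude(epochs: Sequence[Epoch],
                     window: Tuple[float, float] = STEADY_WINDOW) -> float:
    """RMS amplitude of the trial-averaged waveform in the steady-state window.

    The mean is removed before the RMS so a pure cosine of amplitude ``a``
    yields a/√2 regardless of DC offset. The default 15–55 ms window excludes
    the 5 ms onset/offset ramps of the 10–60 ms stimulus.
    """
    waves = [e.analog for e in epochs if e.analog is not None]
    if not waves:
        raise ValueError("no analog data in these epochs")
    avg = np.mean(np.stack([np.asarray(w, dtype=float) for w in waves]), axis=0)
    fs = epochs[0].sample_rate
    lo, hi = int(round(window[0] * fs / 1000.0)), int(round(window[1] * fs / 1000.0))
    seg = avg[lo:hi]
    seg = seg - seg.mean()
    return float(np.sqrt(np.mean(seg ** 2)))


def summarize_condition(epochs: Sequence[Epoch],
                        window: Tuple[float, float] = DEFAULT_WINDOW) -> ResponseSummary:
    """Trial-mean spike rate (and SD) in the stimulus window for one condition.

    For analog epochs, additionally the average analog amplitude (RMS of the
    trial-averaged waveform in the steady-state sub-window).
    """
    epochs = list(epochs)
    if not epochs:
        raise ValueError("empty epoch list")
    cond = epochs[0].condition
    if any(e.condition != cond for e in epochs):
        raise ValueError("all epochs must share one stimulus condition")
    rates = np.array([_window_rate(e, window) for e in epochs])
    sd = float(np.std(rates, ddof=1)) if len(rates) > 1 else 0.0
    amp = None
    if any(e.analog is not None for e in epochs):
        amp = analog_amplitude(epochs)
    return ResponseSummary(condition=cond, mean_rate=float(rates.mean()),
                           rate_sd=sd, analog_amplitude=amp,
                           n_trials=len(epochs))


def spontaneous_rate(silent_epochs: Sequence[Epoch],
                     epoch_ms: float = 80.0) -> float:
    """Mean firing rate (spikes/s) over full-length silent epochs."""
    silent_epochs = list(silent_epochs)
    if not silent_epochs:
        raise ValueError("at least one silent epoch is required")
    total = sum(e.n_spikes for e in silent_epochs)
    return 1000.0 * total / (epoch_ms * len(silent_epochs))


def group_by_condition(epochs: Iterable[Epoch]) -> "OrderedDict":
    """Group epochs by their stimulus condition, preserving first-seen order."""
    groups: OrderedDict = OrderedDict()
    for e in epochs:
        groups.setdefault(e.condition, []).append(e)
    return groups


def site_summary_table(site: RecordingSite,
                       window: Tuple[float, float] = DEFAULT_WINDOW) -> pd.DataFrame:
    """Tidy per-condition summary table for one site (one row per condition)."""
    rows = []
    for cond, eps in group_by_condition(site.epochs).items():
        s = summarize_condition(eps, window=window)
        rows.append({
            "site_id": site.site_id,
            "frequency": cond.frequency,
            "spl": cond.spl,
            "itd": cond.itd,
            "ear": cond.ear,
            "is_silent": cond.is_silent,
            "mean_rate": s.mean_rate,
            "rate_sd": s.rate_sd,
            "analog_amplitude": s.analog_amplitude,
            "n_trials": s.n_trials,
        })
    return pd.DataFrame(rows)


def detect_spikes(analog: np.ndarray, sample_rate: float, threshold: float,
                  lockout_ms: float = 1.0) -> np.ndarray:
    """Fixed-threshold spike detection on an analog trace.

    Upward threshold crossings with a post-detection lockout. Provided for
    building spike fixtures from analog traces; the simulator emits spike
    times directly.
    """
    x = np.asarray(analog, dtype=float)
    above = x >= threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    times = crossings / sample_rate * 1000.0
    out: list = []
    for t in times:
        if not out or t - out[-1] >= lockout_ms:
            out.append(t)
    return np.asarray(out)


def neurophonic_significance(epochs: Sequence[Epoch], frequency: float,
                             window: Tuple[float, float] = STEADY_WINDOW,
                             n_boot: int = 200, n_segments: int = 8,
                             rng: Optional[np.random.Generator] = None,
                             alpha: float = 0.05) -> Tuple[float, float, bool]:
    """Bootstrap test for a stimulus-frequency component in the waveform.

    The cosine-fit amplitude of the trial-averaged waveform at the stimulus
    frequency is compared against the (1−alpha) quantile of amplitudes from
    surrogate waveforms built by randomly permuting and circularly rolling
    equal-length segments of the same waveform (which destroys the phase
    coherence of the stimulus-frequency component but preserves the sample
    distribution). Returns ``(amplitude, null_quantile, significant)``.
    """
    from .itd import fit_cosine_waveform  # local import to avoid a cycle

    waves = [e.analog for e in epochs if e.analog is not None]
    if not waves:
        raise ValueError("no analog data in these epochs")
    rng = rng or np.random.default_rng(0)
    fs = epochs[0].sample_rate
    avg = np.mean(np.stack([np.asarray(w, dtype=float) for w in waves]), axis=0)
    lo, hi = int(round(window[0] * fs / 1000.0)), int(round(window[1] * fs / 1000.0))
    seg = avg[lo:hi]
    amp = fit_cosine_waveform(seg, frequency, fs).amplitude
    pieces = np.array_split(seg, n_segments)
    null = np.empty(n_boot)
    for b in range(n_boot):
        order = rng.permutation(n_segments)
        shuffled = np.concatenate(
            [np.roll(pieces[i], rng.integers(0, max(len(pieces[i]), 1)))
             for i in order])
        null[b] = fit_cosine_waveform(shuffled, frequency, fs).amplitude
    q = float(np.quantile(null, 1.0 - alpha))
    return float(amp), q, bool(amp > q)
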