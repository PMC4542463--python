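"""ITD tuning curves, selectivity criteria and fixed-frequency cosine fits.

Spike responses are screened with the modulation-depth criterion
(max−min mean rate over the maximal across-trial SD ≥ 1.5); analog
responses with the cosine fit index (fitted amplitude over √2 times the
SD of the averaged waveform > 0.7). Accepted responses are fitted with a
cosine at the stimulus frequency; the fitted phase is the best interaural
phase difference (best IPD), and the best ITD is the corresponding delay
closest to zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .containers import Epoch, RecordingSite
from .recordings import (DEFAULT_WINDOW, STEADY_WINDOW, analog_amplitude,
                         group_by_condition, summarize_condition)

SPIKE_SELECTIVITY_MIN = 1.5
ANALOG_FIT_INDEX_MIN = 0.7


@dataclass
class ITDCurve:
    """Mean response (± across-trial SD) versus ITD at one stimulus frequency."""

    stimulus_frequency: float          # Hz
    itds: np.ndarray                   # μs; negative = ipsilateral-leading
    mean_response: np.ndarray
    response_sd: np.ndarray
    metric: str = "spike_rate"         # or "analog"

    def __post_init__(self) -> None:
        self.itds = np.asarray(self.itds, dtype=float)
        self.mean_response = np.asarray(self.mean_response, dtype=float)
        self.response_sd = np.asarray(self.response_sd, dtype=float)
        if not (len(self.itds) == len(self.mean_response) == len(self.response_sd)):
            raise ValueError("ITD grid and responses must have equal length")
        if self.metric not in ("spike_rate", "analog"):
            raise ValueError("metric must be 'spike_rate' or 'analog'")

    @property
    def period_us(self) -> float:
        return 1e6 / self.stimulus_frequency


@dataclass
class CosineFit:
    """m + a·cos(2π(f·t·1e-6 − φ)) with the frequency fixed, not fitted."""

    frequency: float         # Hz
    mean_level: float        # response units
    amplitude: float         # response units, ≥ 0
    phase: float             # cycles, collapsed to (−0.5, 0.5]
    fit_index: float         # amplitude / (SD of data · √2)
    phase_defined: bool = True

    def predict(self, itd_us: np.ndarray) -> np.ndarray:
        itd_us = np.asarray(itd_us, dtype=float)
        return self.mean_level + self.amplitude * np.cos(
            2 * np.pi * (self.frequency * itd_us * 1e-6 - self.phase))


@dataclass
class ITDTuningResult:
    """Best IPD/ITD of one accepted response at one stimulus frequency."""

    frequency: float
    best_ipd: float          # cycles in (−0.5, 0.5]
    best_itd: float          # μs; the response maximum closest to 0
    selectivity: float
    accepted: bool
    acceptance_rule: str     # "spike_ratio_1.5" or "analog_index_0.7"
    fit: Optional[CosineFit] = None


def collapse_phase(x):
    """Collapse a phase (cycles) into the principal cycle (−0.5, 0.5].

    The half-cycle boundary maps to +0.5. Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    y = x - np.round(x)
    # np.round's even-rounding can leave ±0.5; force the +0.5 convention
    y = np.where(y <= -0.5, y + 1.0, y)
    y = np.where(y > 0.5, y - 1.0, y)
    if y.ndim == 0:
        return float(y)
    return y


def itd_curve_from_epochs(epochs: Sequence[Epoch], frequency: float,
                          metric: str = "spike_rate",
                          window: Tuple[float, float] = DEFAULT_WINDOW) -> ITDCurve:
    """Build the per-ITD response curve from the epochs of one test frequency."""
    by_itd: dict = {}
    for cond, eps in group_by_condition(epochs).items():
        if cond.is_silent or cond.itd is None:
            continue
        if abs(cond.frequency - frequency) > 1e-6:
            continue
        by_itd[cond.itd] = eps
    if not by_itd:
        raise ValueError(f"no ITD-tagged epochs at {frequency} Hz")
    itds = np.array(sorted(by_itd))
    means, sds = [], []
    for itd in itds:
        s = summarize_condition(by_itd[itd], window=window)
        if metric == "analog":
            if s.analog_amplitude is None:
                raise ValueError("analog metric requested but no analog data")
            means.append(s.analog_amplitude)
            # across-trial SD of single-trial amplitudes
            amps = [analog_amplitude([e]) for e in by_itd[itd]]
            sds.append(np.std(amps, ddof=1) if len(amps) > 1 else 0.0)
        else:
            means.append(s.mean_rate)
            sds.append(s.rate_sd)
    return ITDCurve(stimulus_frequency=frequency, itds=itds,
                    mean_response=np.array(means), response_sd=np.array(sds),
                    metric=metric)


def spike_selectivity(curve: ITDCurve) -> Tuple[float, bool]:
    """Modulation-depth criterion for spike ITD curves.

    s = (max − min mean rate) / (maximal across-trial SD); the response is
    accepted as ITD-selective iff s ≥ 1.5. A noiseless modulated curve
    (all SDs zero) gives s = +inf and is accepted; a noiseless flat curve
    is rejected.
    """
    if curve.metric != "spike_rate":
        raise ValueError("spike selectivity applies to spike-rate curves")
    if len(curve.itds) < 3:
        raise ValueError("need at least three ITD points")
    span = float(curve.mean_response.max() - curve.mean_response.min())
    max_sd = float(curve.response_sd.max())
    if max_sd == 0.0:
        s = np.inf if span > 0 else 0.0
    else:
        s = span / max_sd
    return float(s), bool(s >= SPIKE_SELECTIVITY_MIN)


def _fit_cosine_design(phase_cycles: np.ndarray, y: np.ndarray) -> Tuple[float, float, float]:
    """Least-squares (m, a, φ) for y = m + a·cos(2π·phase − 2π·φ)."""
    theta = 2 * np.pi * phase_cycles
    design = np.column_stack([np.ones_like(theta), np.cos(theta), np.sin(theta)])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    m, c, s = coef
    a = float(np.hypot(c, s))
    phi = float(np.arctan2(s, c) / (2 * np.pi))
    return float(m), a, phi


def fit_cosine(curve: ITDCurve) -> CosineFit:
    """Fit a cosine at the stimulus frequency to an ITD curve (closed form).

    The frequency is fixed; the fit reduces to a linear least-squares
    projection onto 1, cos and sin at the stimulus frequency over the ITD
    grid. The amplitude is non-negative by construction (phase flip) and the
    phase is returned collapsed to (−0.5, 0.5].
    """
    if len(curve.itds) < 4:
        raise ValueError("need at least four ITD points for the cosine fit")
    if np.ptp(curve.itds) == 0:
        raise ValueError("degenerate ITD grid (all points equal)")
    phase_cycles = curve.stimulus_frequency * curve.itds * 1e-6
    m, a, phi = _fit_cosine_design(phase_cycles, curve.mean_response)
    sd = float(np.std(curve.mean_response))
    index = a / (sd * np.sqrt(2.0)) if sd > 0 else 0.0
    phase_defined = a > 1e-12 * max(1.0, abs(m))
    return CosineFit(frequency=curve.stimulus_frequency, mean_level=m,
                     amplitude=a, phase=collapse_phase(phi),
                     fit_index=float(index), phase_defined=phase_defined)


def fit_cosine_waveform(waveform: np.ndarray, frequency: float,
                        sample_rate: float) -> CosineFit:
    """Cosine fit at the stimulus frequency over analog time samples.

    ``fit_index`` = amplitude / (SD(waveform)·√2) lies in [0, 1+ε]: 1 for a
    pure sinusoid at the stimulus frequency, 0 when no component at that
    frequency is present.
    """
    y = np.asarray(waveform, dtype=float)
    if y.size < 4:
        raise ValueError("waveform too short")
    sd = float(np.std(y))
    if sd == 0.0:
        raise ValueError("zero-variance waveform")
    t_s = np.arange(y.size) / sample_rate
    m, a, phi = _fit_cosine_design(frequency * t_s, y)
    return CosineFit(frequency=frequency, mean_level=m, amplitude=a,
                     phase=collapse_phase(phi),
                     fit_index=float(a / (sd * np.sqrt(2.0))),
                     phase_defined=a > 0)


def analog_fit_index(epochs: Sequence[Epoch], frequency: float,
                     window: Tuple[float, float] = STEADY_WINDOW) -> CosineFit:
    """Fit index of the trial-averaged analog waveform at one condition.

    The averaged waveform inside the analysis window (default 15–55 ms,
    excluding ramps) is fitted with a cosine at the stimulus frequency; the
    recording is accepted as stimulus-following iff the index exceeds 0.7.
    """
    waves = [e.analog for e in epochs if e.analog is not None]
    if not waves:
        raise ValueError("no analog epochs")
    fs = epochs[0].sample_rate
    avg = np.mean(np.stack([np.asarray(w, dtype=float) for w in waves]), axis=0)
    lo, hi = int(round(window[0] * fs / 1000.0)), int(round(window[1] * fs / 1000.0))
    return fit_cosine_waveform(avg[lo:hi], frequency, fs)


def best_itd_ipd(fit: CosineFit, selectivity: float = np.inf,
                 acceptance_rule: str = "spike_ratio_1.5") -> ITDTuningResult:
    """Best IPD (collapsed) and the best ITD closest to zero from a fit.

    The cosine peak positions repeat every stimulus period; the reported
    best ITD is the peak closest to 0 μs (|best ITD| ≤ period/2). Peaks at
    best_itd + k·period remain implicit candidates for CD-based
    disambiguation.
    """
    if not fit.phase_defined:
        raise ValueError("phase undefined (zero-amplitude fit)")
    ipd = collapse_phase(fit.phase)
    itd = ipd / fit.frequency * 1e6
    return ITDTuningResult(frequency=fit.frequency, best_ipd=ipd,
                           best_itd=float(itd), selectivity=float(selectivity),
                           accepted=True, acceptance_rule=acceptance_rule,
                           fit=fit)


def analyze_itd_curve(curve: ITDCurve,
                      epochs: Optional[Sequence[Epoch]] = None,
                      window: Tuple[float, float] = STEADY_WINDOW) -> Optional[ITDTuningResult]:
    """Screen one ITD curve and, if accepted, return its best ITD/IPD.

    Spike curves use the 1.5 modulation-depth ratio; analog curves the 0.7
    waveform fit index (computed from ``epochs`` at the best-modulated ITD).
    Returns None for rejected responses.
    """
    if curve.metric == "spike_rate":
        s, ok = spike_selectivity(curve)
        if not ok:
            return None
        fit = fit_cosine(curve)
        return best_itd_ipd(fit, selectivity=s,
                            acceptance_rule="spike_ratio_1.5")
    # analog: gate on the waveform fit index at the strongest condition
    if epochs is None:
        raise ValueError("analog curves need the underlying epochs for the fit index")
    best_itd_grid = curve.itds[int(np.argmax(curve.mean_response))]
    cond_epochs = [e for e in epochs
                   if e.condition.itd is not None
                   and abs(e.condition.itd - best_itd_grid) < 1e-9
                   and abs(e.condition.frequency - curve.stimulus_frequency) < 1e-9]
    wf_fit = analog_fit_index(cond_epochs, curve.stimulus_frequency, window=window)
    if wf_fit.fit_index <= ANALOG_FIT_INDEX_MIN:
        return None
    curve_fit = fit_cosine(curve)
    return best_itd_ipd(curve_fit, selectivity=wf_fit.fit_index,
                        acceptance_rule="analog_index_0.7")
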