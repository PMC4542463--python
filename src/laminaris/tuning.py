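"""Frequency threshold curves and scalar tuning metrics.

From a frequency × SPL response matrix (typically 100 Hz / 5 dB steps) the
iso-response contour at a criterion (default 20 spikes/s above spontaneous
rate) is interpolated after loess smoothing along frequency. Scalar metrics:
CF (frequency of the lowest-threshold point), threshold at CF, Q10/Q40
(CF over the contour bandwidth 10/40 dB above threshold), flank slopes
(dB/octave between 3 and 23 dB above the CF threshold), and best frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_CRITERION_ABOVE_SPONT = 20.0  # spikes/s
FLANK_RANGE_DB = (3.0, 23.0)


@dataclass
class FTCMatrix:
    """Response matrix over a frequency × SPL grid (rows: frequency)."""

    frequencies: np.ndarray    # Hz, strictly increasing
    spls: np.ndarray           # dB SPL, strictly increasing
    response: np.ndarray       # shape (n_freq, n_spl), non-negative
    smoothed: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.spls = np.asarray(self.spls, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0) or np.any(np.diff(self.spls) <= 0):
            raise ValueError("frequency and SPL grids must be strictly increasing")
        if self.response.shape != (len(self.frequencies), len(self.spls)):
            raise ValueError("response shape must be (n_freq, n_spl)")
        if np.any(self.response < 0):
            raise ValueError("responses must be non-negative")

    @property
    def values(self) -> np.ndarray:
        """Smoothed response if available, else the raw matrix."""
        return self.response if self.smoothed is None else self.smoothed


@dataclass
class TuningResult:
    """Scalar tuning metrics extracted from one FTC."""

    cf: float
    threshold_at_cf: float
    q10: Optional[float] = None
    q40: Optional[float] = None
    flank_slope_low: Optional[float] = None    # dB/octave (negative: falling)
    flank_slope_high: Optional[float] = None   # dB/octave (positive: rising)
    bf: Optional[float] = None
    bf_ambiguous: bool = False
    criterion_used: float = 0.0


@dataclass
class FTCContour:
    """Iso-response threshold contour: threshold (dB SPL) per frequency."""

    frequencies: np.ndarray
    thresholds: np.ndarray     # NaN where the criterion is never reached

    def defined(self) -> Tuple[np.ndarray, np.ndarray]:
        ok = ~np.isnan(self.thresholds)
        return self.frequencies[ok], self.thresholds[ok]


def smooth_matrix(matrix: FTCMatrix, span: float = 0.5) -> FTCMatrix:
    """Loess-smooth the response matrix along frequency at each SPL.

    Local linear regression with tricube weights (loess); the default span
    covers half the frequency grid. Constants and linear-in-frequency
    surfaces pass through unchanged.
    """
    if len(matrix.frequencies) < 3 or len(matrix.spls) < 3:
        raise ValueError("need at least a 3×3 matrix to smooth")
    out = np.empty_like(matrix.response)
    for j in range(len(matrix.spls)):
        out[:, j] = lowess(matrix.response[:, j], matrix.frequencies,
                           frac=span, it=0, return_sorted=False)
    out = np.clip(out, 0.0, None)
    return FTCMatrix(frequencies=matrix.frequencies.copy(),
                     spls=matrix.spls.copy(),
                     response=matrix.response.copy(), smoothed=out)


def _column_threshold(spls: np.ndarray, resp: np.ndarray,
                      criterion: float) -> float:
    """Lowest SPL at which the (linearly interpolated) response reaches criterion."""
    reached = resp >= criterion
    if not np.any(reached):
        return np.nan
    i = int(np.argmax(reached))
    if i == 0:
        return float(spls[0])
    lo, hi = resp[i - 1], resp[i]
    if hi == lo:
        return float(spls[i])
    frac = (criterion - lo) / (hi - lo)
    return float(spls[i - 1] + frac * (spls[i] - spls[i - 1]))


def _bandwidth_at(freqs: np.ndarray, thr: np.ndarray, cf: float,
                  level: float) -> Optional[float]:
    """Contour width (Hz) at a horizontal cut ``level`` dB SPL, around CF.

    Crossing points are linearly interpolated on each flank; None when the
    contour does not rise to the cut level on both sides of CF within the
    tested range.
    """
    i_cf = int(np.argmin(np.abs(freqs - cf)))

    def crossing(indices) -> Optional[float]:
        prev = i_cf
        for i in indices:
            if np.isnan(thr[i]):
                return None
            if thr[i] >= level:
                f0, f1 = freqs[prev], freqs[i]
                t0, t1 = thr[prev], thr[i]
                if t1 == t0:
                    return float(f1)
                return float(f0 + (level - t0) / (t1 - t0) * (f1 - f0))
            prev = i
        return None

    left = crossing(range(i_cf - 1, -1, -1))
    right = crossing(range(i_cf + 1, len(freqs)))
    if left is None or right is None:
        return None
    return right - left


def _flank_slope(freqs: np.ndarray, thr: np.ndarray, cf: float,
                 thr_cf: float, side: str) -> Optional[float]:
    """Least-squares slope (dB/octave) of one contour flank, 3–23 dB above CF threshold."""
    lo, hi = thr_cf + FLANK_RANGE_DB[0], thr_cf + FLANK_RANGE_DB[1]
    ok = ~np.isnan(thr) & (thr >= lo) & (thr <= hi)
    ok &= (freqs < cf) if side == "low" else (freqs > cf)
    if np.count_nonzero(ok) < 2:
        return None
    res = stats.linregress(np.log2(freqs[ok]), thr[ok])
    return float(res.slope)


def best_frequency(frequencies: Sequence[float], responses: Sequence[float],
                   rel_tol: float = 1e-9) -> Tuple[float, bool]:
    """Frequency of maximal response on an (already smoothed) iso-SPL curve.

    Ties (within relative tolerance) are broken toward the lower frequency
    and flagged as ambiguous; a flat curve is fully ambiguous.
    """
    f = np.asarray(frequencies, dtype=float)
    r = np.asarray(responses, dtype=float)
    if len(f) < 3:
        raise ValueError("need at least three frequencies")
    top = r.max()
    at_top = np.flatnonzero(r >= top - rel_tol * max(abs(top), 1.0))
    ambiguous = len(at_top) > 1
    return float(f[at_top[0]]), ambiguous


def extract_ftc(matrix: FTCMatrix, criterion: float,
                smooth: bool = True, span: float = 0.5) -> Tuple[FTCContour, TuningResult]:
    """Extract the iso-response contour and scalar tuning metrics.

    ``criterion`` is in response units (for spikes, typically the
    spontaneous rate + 20 spikes/s). The threshold at each frequency is the
    lowest SPL whose smoothed response reaches the criterion (linear
    interpolation in SPL); CF minimizes threshold over frequency (ties to
    the lower frequency). Q40 and flank slopes are absent when the contour
    does not extend far enough.
    """
    if smooth and matrix.smoothed is None:
        matrix = smooth_matrix(matrix, span=span)
    vals = matrix.values
    if criterion > vals.max():
        raise ValueError("criterion above every response in the matrix")
    thr = np.array([_column_threshold(matrix.spls, vals[i], criterion)
                    for i in range(len(matrix.frequencies))])
    contour = FTCContour(frequencies=matrix.frequencies.copy(), thresholds=thr)
    if np.all(np.isnan(thr)):
        raise ValueError("criterion never reached at any frequency")
    i_cf = int(np.nanargmin(thr))
    cf = float(matrix.frequencies[i_cf])
    thr_cf = float(thr[i_cf])

    def q_at(delta: float) -> Optional[float]:
        bw = _bandwidth_at(matrix.frequencies, thr, cf, thr_cf + delta)
        return None if bw is None or bw <= 0 else cf / bw

    bf, bf_amb = best_frequency(matrix.frequencies, vals[:, -1])
    return contour, TuningResult(
        cf=cf, threshold_at_cf=thr_cf,
        q10=q_at(10.0), q40=q_at(40.0),
        flank_slope_low=_flank_slope(matrix.frequencies, thr, cf, thr_cf, "low"),
        flank_slope_high=_flank_slope(matrix.frequencies, thr, cf, thr_cf, "high"),
        bf=bf, bf_ambiguous=bf_amb, criterion_used=float(criterion))


@dataclass
class RateLevelResult:
    """Threshold and saturation estimates from a monaural rate-level series."""

    threshold: float           # dB SPL
    saturation: float          # dB SPL
    saturated_at_edge: bool    # True when the series never plateaus


def rate_level_threshold(spls: Sequence[float], rates: Sequence[float],
                         spont_rate: float,
                         criterion: float = DEFAULT_CRITERION_ABOVE_SPONT,
                         saturation_frac: float = 0.05) -> RateLevelResult:
    """Threshold and saturation SPL from a rate-level curve at one frequency.

    Threshold: lowest tested SPL whose rate exceeds spontaneous + criterion.
    Saturation: lowest SPL within ``saturation_frac`` of the maximum rate;
    flagged when that is the highest tested SPL (no plateau observed).
    """
    spls = np.asarray(spls, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if len(spls) < 4:
        raise ValueError("need at least four SPL points")
    order = np.argsort(spls)
    spls, rates = spls[order], rates[order]
    above = rates > spont_rate + criterion
    if not np.any(above):
        raise ValueError("rate never exceeds the criterion above spontaneous")
    threshold = float(spls[np.argmax(above)])
    top = rates.max()
    sat_idx = int(np.argmax(rates >= (1.0 - saturation_frac) * top))
    return RateLevelResult(threshold=threshold,
                           saturation=float(spls[sat_idx]),
                           saturated_at_edge=bool(sat_idx == len(spls) - 1))


def ftc_matrix_from_site(site, ear: str = "ipsi",
                         window: Tuple[float, float] = (10.0, 60.0)) -> FTCMatrix:
    """Assemble the frequency × SPL mean-response matrix from a recorded site."""
    from .recordings import group_by_condition, summarize_condition

    cells: dict = {}
    for cond, eps in group_by_condition(site.epochs).items():
        if cond.is_silent or cond.ear != ear:
            continue
        s = summarize_condition(eps, window=window)
        resp = s.analog_amplitude if s.analog_amplitude is not None else s.mean_rate
        cells[(cond.frequency, cond.spl)] = resp
    if not cells:
        raise ValueError(f"no {ear} epochs in this site")
    freqs = np.array(sorted({f for f, _ in cells}))
    spls = np.array(sorted({l for _, l in cells}))
    resp = np.full((len(freqs), len(spls)), np.nan)
    for (f, l), v in cells.items():
        resp[np.searchsorted(freqs, f), np.searchsorted(spls, l)] = v
    if np.any(np.isnan(resp)):
        raise ValueError("incomplete frequency × SPL matrix")
    return FTCMatrix(frequencies=freqs, spls=spls, response=resp)
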