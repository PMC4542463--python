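"""Characteristic delay/phase analysis and best-ITD disambiguation.

Best IPDs measured at several stimulus frequencies are unwrapped (integer
cycle offsets) and regressed linearly on frequency: the slope is the
characteristic delay (CD, μs) — the frequency-invariant component of the
internal delay — and the collapsed intercept is the characteristic phase
(CP, cycles): CP ≈ 0 means the CD falls on response peaks (pure time
delay), CP ≈ ±0.5 on troughs. The CD then disambiguates the best ITD by
selecting the response maximum closest to it. Downstream classifiers cover
the pi limit, CP bands, slope midpoints and paired spike/neurophonic
mismatches.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .itd import CosineFit, collapse_phase

UNWRAP_OFFSETS = range(-2, 3)
CP_PEAK_BAND = 0.15
CP_TROUGH_BAND = 0.35
DEFAULT_CANDIDATE_BOUND_PERIODS = 1.5


@dataclass
class PhaseFrequencyFit:
    """Linear fit of unwrapped best IPD (cycles) on frequency (Hz)."""

    points: list                   # (frequency, unwrapped best_ipd, offset)
    cd: float                      # μs (slope × 1e6)
    cp: float                      # cycles, collapsed
    intercept: float               # cycles, uncollapsed regression intercept
    r_squared: float
    linearity_p: float
    n_frequencies: int

    def is_linear(self, alpha: float = 0.05) -> bool:
        """Linear phase–frequency relation at significance level ``alpha``."""
        return self.linearity_p <= alpha


@dataclass
class DisambiguatedBestITD:
    """Response maximum selected as the best ITD using the CD."""

    candidates: np.ndarray         # μs, all maxima within the search bound
    chosen: float                  # μs
    distance_to_cd: float          # μs
    changed_from_nearest_zero: bool


@dataclass
class SlopeMidpoint:
    """Midpoint of the ITD-curve slope nearest the midline (steepest point)."""

    midpoint: float                # μs
    direction: str                 # ipsi_to_contra_downward | contra_to_ipsi_downward
    source_best_itd: float         # μs
    frequency: float               # Hz


def _linear_ss(x: np.ndarray, y: np.ndarray) -> float:
    """Residual sum of squares of the least-squares line through (x, y)."""
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    if sxx == 0:
        return float(yc @ yc)
    sxy = float(xc @ yc)
    return float(yc @ yc) - sxy * sxy / sxx


def unwrap_phases(points: Sequence[Tuple[float, float]],
                  method: str = "exhaustive") -> list:
    """Undo cycle wrapping of collapsed best IPDs before the regression.

    Collapsed phases lie in (−0.5, 0.5] and cannot be regressed directly;
    each point (after the first, whose offset is fixed at 0) receives an
    integer cycle offset in {−2..2}. ``exhaustive`` minimizes the residual
    sum of squares of the linear fit over all offset vectors; ``sequential``
    unwraps each point toward the prediction of the line fitted to the
    already-unwrapped points (first two: nearest neighbour).

    Returns a list of (frequency, unwrapped_phase, offset) sorted by frequency.
    """
    pts = sorted(points)
    if len(pts) < 3:
        raise ValueError("need at least three (frequency, phase) points")
    f = np.array([p[0] for p in pts])
    if len(np.unique(f)) != len(f):
        raise ValueError("frequencies must be distinct")
    y = np.array([p[1] for p in pts])

    if method == "exhaustive":
        best_ss, best_k = np.inf, None
        combos = itertools.product(*([list(UNWRAP_OFFSETS)] * (len(pts) - 1)))
        for tail in combos:
            k = np.array((0,) + tail, dtype=float)
            ss = _linear_ss(f, y + k)
            if ss < best_ss - 1e-15:
                best_ss, best_k = ss, k
        offsets = best_k
    elif method == "sequential":
        offsets = np.zeros(len(pts))
        for i in range(1, len(pts)):
            if i == 1:
                pred = y[0] + offsets[0]
            else:
                xs, ys = f[:i], y[:i] + offsets[:i]
                res = stats.linregress(xs, ys)
                pred = res.slope * f[i] + res.intercept
            offsets[i] = np.round(pred - y[i])
        offsets -= offsets[0]
    else:
        raise ValueError(f"unknown unwrap method {method!r}")
    return [(float(fi), float(yi + ki), int(ki))
            for fi, yi, ki in zip(f, y, offsets)]


def linearity_pvalue(frequencies: np.ndarray, phases: np.ndarray) -> float:
    """Significance of the linear phase–frequency regression (F-test).

    With a single predictor this equals the two-sided t-test on the slope;
    a small p indicates reliable linear structure. Isolated here so an
    alternative linearity test can be swapped in.
    """
    res = stats.linregress(frequencies, phases)
    return float(res.pvalue)


def fit_cd_cp(points: Sequence[Tuple[float, float]],
              unwrap: bool = True, method: str = "exhaustive") -> PhaseFrequencyFit:
    """Characteristic delay and phase from best IPDs at 3–7 frequencies.

    Ordinary (unweighted) least squares of best IPD in cycles on frequency
    in Hz: CD = slope × 1e6 μs; CP = intercept collapsed to (−0.5, 0.5].
    ``linearity_p`` reports the regression-significance test at the
    conventional 0.05 / 0.005 levels.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need at least three frequencies")
    if unwrap and len(pts[0]) == 2:
        unwrapped = unwrap_phases(pts, method=method)
    else:
        unwrapped = [(p[0], p[1], int(p[2]) if len(p) > 2 else 0) for p in sorted(pts)]
    f = np.array([p[0] for p in unwrapped])
    y = np.array([p[1] for p in unwrapped])
    if np.ptp(f) == 0:
        raise ValueError("degenerate input: all frequencies equal")
    res = stats.linregress(f, y)
    return PhaseFrequencyFit(
        points=unwrapped,
        cd=float(res.slope * 1e6),
        cp=collapse_phase(res.intercept),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue ** 2),
        linearity_p=linearity_pvalue(f, y),
        n_frequencies=len(f),
    )


def choose_candidate(candidates: Sequence[float], cd: float) -> Tuple[float, float]:
    """Pick the response maximum closest to the CD (ties → contralateral).

    Returns (chosen ITD μs, |chosen − cd| μs). The contralateral (positive)
    member wins exact ties, with a warning; in practice a CP of exactly 0.5
    (the only way a tie arises) does not occur.
    """
    cands = np.asarray(candidates, dtype=float)
    if cands.size == 0:
        raise ValueError("no candidate maxima supplied")
    d = np.abs(cands - cd)
    dmin = d.min()
    at_min = cands[np.isclose(d, dmin, rtol=0.0, atol=1e-9)]
    if at_min.size > 1:
        warnings.warn("tie between candidate maxima; choosing the "
                      "contralateral (positive) candidate", stacklevel=2)
        chosen = float(at_min.max())
    else:
        chosen = float(at_min[0])
    return chosen, float(abs(chosen - cd))


def disambiguate_best_itd(fit: CosineFit, cd: float,
                          bound_periods: float = DEFAULT_CANDIDATE_BOUND_PERIODS
                          ) -> DisambiguatedBestITD:
    """Resolve the period ambiguity of the best ITD using the CD.

    Candidate maxima sit at (best_ipd + k)/f for integer k, limited to
    |candidate| ≤ ``bound_periods`` stimulus periods (the tested ITD range
    plus margin). The candidate closest to the CD is the unambiguous best ITD.
    """
    period_us = 1e6 / fit.frequency
    ipd = collapse_phase(fit.phase)
    bound = bound_periods * period_us
    ks = np.arange(-int(np.ceil(bound_periods)) - 1,
                   int(np.ceil(bound_periods)) + 2)
    cands = (ipd + ks) * period_us
    cands = cands[np.abs(cands) <= bound + 1e-9]
    if cands.size == 0:
        raise ValueError("no candidate maxima within the search bound")
    chosen, dist = choose_candidate(cands, cd)
    nearest_zero = float(cands[np.argmin(np.abs(cands))])
    return DisambiguatedBestITD(candidates=np.sort(cands), chosen=chosen,
                                distance_to_cd=dist,
                                changed_from_nearest_zero=not np.isclose(
                                    chosen, nearest_zero))


def pi_limit_flag(best_itd: float, frequency: float) -> bool:
    """True iff |best ITD| exceeds half the stimulus period.

    Half a period (±0.5 cycles) is the largest best ITD a pure phase-delay
    mechanism can generate; values beyond it indicate a time-delay
    contribution. Exactly half a period counts as inside the limit.
    """
    if frequency <= 0:
        raise ValueError("frequency must be positive")
    return bool(abs(best_itd) > 0.5e6 / frequency)


def classify_cp(cp: float) -> str:
    """CP band: peak-type (|CP| ≤ 0.15), intermediate, or trough-type (≥ 0.35).

    Peak-type CPs put the CD on response peaks (pure time delay);
    trough-type near troughs; intermediate on the slopes. The 0.35 boundary
    is assigned to trough-type (the adjacent bands touch).
    """
    if not (-0.5 - 1e-12 <= cp <= 0.5 + 1e-12):
        raise ValueError("cp must be collapsed to (-0.5, 0.5]")
    a = abs(cp)
    if a <= CP_PEAK_BAND:
        return "peak_type"
    if a < CP_TROUGH_BAND:
        return "intermediate"
    return "trough_type"


def slope_midpoint(best_itd: float, frequency: float) -> SlopeMidpoint:
    """Steepest point of the ITD curve: quarter period toward zero from the peak.

    midpoint = best_itd − sign(best_itd)·period/4 (sign(0) taken as +1);
    the formula is applied even when the midpoint crosses zero. The slope
    direction is named for its downward direction: descending from a
    contralateral peak toward ipsilateral, or the reverse. Only
    disambiguated best ITDs should be passed here, since the direction
    depends on which peak is the true one.
    """
    period = 1e6 / frequency
    sign = 1.0 if best_itd >= 0 else -1.0
    mid = best_itd - sign * period / 4.0
    direction = ("contra_to_ipsi_downward" if best_itd > mid
                 else "ipsi_to_contra_downward")
    return SlopeMidpoint(midpoint=float(mid), direction=direction,
                         source_best_itd=float(best_itd), frequency=frequency)


def paired_mismatch(spike: Tuple[float, float],
                    neuro: Tuple[float, float]) -> Tuple[float, float]:
    """Best-ITD and best-IPD mismatch between paired spike/neurophonic sites.

    Each pair is (frequency Hz, best ITD μs). The IPD mismatch converts each
    site's best ITD to phase at its own test frequency before differencing,
    which reduces to itd_diff·f when the frequencies match.
    """
    f_s, itd_s = spike
    f_n, itd_n = neuro
    itd_diff = abs(itd_s - itd_n)
    ipd_diff = abs(itd_s * f_s - itd_n * f_n) * 1e-6
    return float(itd_diff), float(ipd_diff)
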