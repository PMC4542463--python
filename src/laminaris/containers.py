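"""Core data containers shared across the pipeline.

Sign convention used throughout: interaural time differences (ITDs) are in
microseconds, with negative values meaning ipsilateral-leading and positive
values contralateral-leading sounds. Interaural phase differences (IPDs) and
all other phases are in cycles of the stimulus frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

EARS = ("ipsi", "contra", "binaural")
RECORDING_KINDS = ("single_unit", "multi_unit", "neurophonic", "unclassified")
FREQUENCY_PROVENANCE = ("CF", "BF", "stimulus")


@dataclass(frozen=True)
class StimulusCondition:
    """One stimulus configuration: tone frequency, level, ITD and ear.

    Silent trials (used to estimate spontaneous rate) carry no frequency,
    SPL or ITD.
    """

    frequency: Optional[float] = None  # Hz
    spl: Optional[float] = None       # dB SPL
    itd: Optional[float] = None       # μs; negative = ipsilateral-leading
    ear: str = "binaural"
    is_silent: bool = False

    def __post_init__(self) -> None:
        if self.ear not in EARS:
            raise ValueError(f"ear must be one of {EARS}, got {self.ear!r}")
        if self.is_silent:
            if self.frequency is not None or self.itd is not None:
                raise ValueError("silent trials carry no frequency or ITD")
        else:
            if self.frequency is None or self.frequency <= 0:
                raise ValueError("stimulus frequency must be positive")
            if self.itd is not None and self.ear != "binaural":
                raise ValueError("ITD is only defined for binaural stimulation")


@dataclass
class Epoch:
    """A single recording epoch: spike times and/or an analog waveform.

    Spike times are in ms from epoch onset and sorted ascending. Analog
    waveforms are sampled at ``sample_rate`` Hz over the whole epoch.
    """

    condition: StimulusCondition
    spike_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    analog: Optional[np.ndarray] = None
    trial_index: int = 0
    sample_rate: float = 48000.0

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike times must be sorted ascending")
        if self.analog is not None:
            self.analog = np.asarray(self.analog, dtype=np.float32)

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)


@dataclass(frozen=True)
class SiteGroundTruth:
    """Generative parameters of one simulated recording site.

    ``cd_true`` (μs) and ``cp_true`` (cycles) define the site's internal
    delay: the best IPD at stimulus frequency f is
    ``cp_true + cd_true·1e-6·f`` (plus an optional quadratic term,
    ``phase_curvature`` in cycles/Hz², used to exercise the linearity-test
    rejection path).
    """

    cf: float                      # Hz
    cd_true: float = 0.0           # μs; negative = ipsilateral-leading
    cp_true: float = 0.0           # cycles, strictly inside (-0.5, 0.5]
    spont_rate: float = 80.0       # spikes/s
    peak_rate: float = 260.0       # spikes/s
    tuning_bandwidth: float = 350.0  # Hz (Gaussian SD of the spectral filter)
    threshold_spl: float = 30.0    # dB SPL
    neurophonic_amp: float = 1.0   # arbitrary units
    noise_sd: float = 0.1          # arbitrary units
    seed: int = 0
    phase_curvature: float = 0.0   # cycles/Hz²; 0 → exactly linear phase

    def __post_init__(self) -> None:
        if self.cf <= 0:
            raise ValueError("cf must be positive")
        if not (self.spont_rate >= 0 and self.peak_rate > self.spont_rate):
            raise ValueError("require peak_rate > spont_rate >= 0")
        if not (-0.5 < self.cp_true <= 0.5):
            raise ValueError("cp_true must lie in (-0.5, 0.5]")
        if self.tuning_bandwidth <= 0:
            raise ValueError("tuning_bandwidth must be positive")


@dataclass(frozen=True)
class ProtocolConfig:
    """Stimulus protocol: epoch timing, trial counts and the ITD grid.

    The ITD grid at each test frequency spans ``±itd_range_periods`` stimulus
    periods in steps of ``itd_step_fraction`` of a period (default ±1 period
    in 1/10-period steps, 21 points).
    """

    frequencies: tuple = (700.0,)   # Hz, ITD-test frequencies
    n_trials: int = 5
    itd_step_fraction: float = 0.1  # of one stimulus period
    itd_range_periods: float = 1.0
    spl: Optional[float] = None     # dB SPL; None → 20 dB above site threshold
    epoch_ms: float = 80.0
    stim_on_ms: float = 10.0
    stim_off_ms: float = 60.0
    ramp_ms: float = 5.0
    n_silent: int = 10
    sample_rate: float = 48000.0

    def __post_init__(self) -> None:
        if self.itd_step_fraction <= 0:
            raise ValueError("ITD step must be positive")
        if not (0 <= self.stim_on_ms < self.stim_off_ms <= self.epoch_ms):
            raise ValueError("stimulus window must lie inside the epoch")
        if self.n_trials < 1:
            raise ValueError("need at least one trial per condition")
        if len(self.frequencies) == 0:
            raise ValueError("at least one test frequency is required")

    def itd_grid(self, frequency: float) -> np.ndarray:
        """ITD grid (μs) for one test frequency: ±range periods in step-fraction steps."""
        period_us = 1e6 / frequency
        n = int(round(self.itd_range_periods / self.itd_step_fraction))
        return np.arange(-n, n + 1) * (period_us * self.itd_step_fraction)


@dataclass
class ResponseSummary:
    """Per-condition response: trial-mean rate, across-trial SD, analog amplitude."""

    condition: StimulusCondition
    mean_rate: float               # spikes/s over the analysis window
    rate_sd: float                 # spikes/s across trials
    analog_amplitude: Optional[float] = None
    n_trials: int = 0

    def __post_init__(self) -> None:
        if self.mean_rate < 0 or self.rate_sd < 0:
            raise ValueError("rates and SDs are non-negative")


@dataclass
class RecordingSite:
    """All epochs and metadata for one electrode site."""

    site_id: str
    epochs: list = field(default_factory=list)
    recording_kind: str = "unclassified"
    assigned_frequency: Optional[float] = None
    frequency_provenance: Optional[str] = None
    ground_truth: Optional[SiteGroundTruth] = None
    protocol: Optional[ProtocolConfig] = None

    def __post_init__(self) -> None:
        if self.recording_kind not in RECORDING_KINDS:
            raise ValueError(f"unknown recording kind {self.recording_kind!r}")
        if self.frequency_provenance is not None and \
                self.frequency_provenance not in FREQUENCY_PROVENANCE:
            raise ValueError(
                f"frequency provenance must be one of {FREQUENCY_PROVENANCE}")

    def silent_epochs(self) -> list:
        return [e for e in self.epochs if e.condition.is_silent]

    def driven_epochs(self) -> list:
        return [e for e in self.epochs if not e.condition.is_silent]

    def epochs_at(self, frequency: float, tol: float = 1e-6) -> list:
        """Driven epochs whose stimulus frequency matches ``frequency``."""
        return [e for e in self.driven_epochs()
                if abs(e.condition.frequency - frequency) <= tol]

    def test_frequencies(self) -> list:
        seen: list = []
        for e in self.driven_epochs():
            f = e.condition.frequency
            if f is not None and f not in seen:
                seen.append(f)
        return sorted(seen)


def assign_frequency(cf: Optional[float] = None,
                     bf: Optional[float] = None,
                     stimulus: Optional[float] = None) -> tuple:
    """Pick the frequency label for a site with its provenance.

    Preference order: characteristic frequency, then best frequency, then
    the stimulus frequency of the ITD test.
    """
    if cf is not None:
        return float(cf), "CF"
    if bf is not None:
        return float(bf), "BF"
    if stimulus is not None:
        return float(stimulus), "stimulus"
    raise ValueError("no frequency available for this site")
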