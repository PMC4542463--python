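"""Synthetic spike-train and neurophonic generators for binaural sites.

The generative model is a minimal coincidence detector: the driven firing
rate at stimulus frequency ``f`` (Hz) and interaural time difference ``t``
(μs) is

    r(t, f) = spont + g(f) · (peak − spont) · (1 + cos(2π·(f·t·1e-6 − φ(f)))) / 2

where ``g(f)`` is a Gaussian spectral gain centred on the site's CF and
``φ(f) = cp + cd·1e-6·f`` is the best interaural phase at frequency ``f``
(a pure linear phase–frequency relation; an optional quadratic term breaks
linearity on purpose). Spikes are drawn as an inhomogeneous Poisson process
with a 1 ms dead time; the driving intensity is dead-time-corrected so that
the observed rate converges to r(t, f).

Neurophonic (field-potential) epochs carry an analog carrier at the stimulus
frequency whose envelope is modulated by the same ITD/frequency term, plus
white Gaussian noise.

All randomness derives deterministically from the site seed: each epoch gets
its own stream keyed by (seed, condition index, trial index).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .containers import (Epoch, ProtocolConfig, RecordingSite,
                         SiteGroundTruth, StimulusCondition)

DEAD_TIME_MS = 1.0
#: maximum sustainable rate given the 1 ms dead time correction
_MAX_RATE = 900.0


# ---------------------------------------------------------------------------
# deterministic components of the rate model
# ---------------------------------------------------------------------------

def best_ipd(gt: SiteGroundTruth, frequency: float) -> float:
    """True best interaural phase (cycles, uncollapsed) at ``frequency``."""
    ipd = gt.cp_true + gt.cd_true * 1e-6 * frequency
    if gt.phase_curvature:
        ipd += gt.phase_curvature * (frequency - gt.cf) ** 2
    return ipd


def interaural_modulation(gt: SiteGroundTruth, frequency: float,
                          itd_us: float) -> float:
    """Raised-cosine ITD modulation in [0, 1]; 1 at the best ITD."""
    phase = frequency * itd_us * 1e-6 - best_ipd(gt, frequency)
    return 0.5 * (1.0 + np.cos(2 * np.pi * phase))


def spectral_gain(gt: SiteGroundTruth, frequency: float) -> float:
    """Gaussian frequency filter centred on CF, 1 at CF."""
    return float(np.exp(-0.5 * ((frequency - gt.cf) / gt.tuning_bandwidth) ** 2))


def level_gain(gt: SiteGroundTruth, spl: float,
               dynamic_range: float = 30.0) -> float:
    """Linear-ramp level gain: 0 at threshold SPL, 1 at threshold+dynamic_range."""
    return float(np.clip((spl - gt.threshold_spl) / dynamic_range, 0.0, 1.0))


def expected_rate(gt: SiteGroundTruth, frequency: float, itd_us: float) -> float:
    """Expected driven rate (spikes/s) in the stimulus plateau."""
    drive = spectral_gain(gt, frequency) * (gt.peak_rate - gt.spont_rate)
    return gt.spont_rate + drive * interaural_modulation(gt, frequency, itd_us)


def _envelope(t_ms: np.ndarray, protocol: ProtocolConfig) -> np.ndarray:
    """Cosine-squared-ramped stimulus envelope over the epoch (0 outside)."""
    on, off, ramp = protocol.stim_on_ms, protocol.stim_off_ms, protocol.ramp_ms
    env = np.zeros_like(t_ms, dtype=float)
    inside = (t_ms >= on) & (t_ms < off)
    env[inside] = 1.0
    if ramp > 0:
        rising = inside & (t_ms < on + ramp)
        env[rising] = np.sin(0.5 * np.pi * (t_ms[rising] - on) / ramp) ** 2
        falling = inside & (t_ms >= off - ramp)
        env[falling] = np.sin(0.5 * np.pi * (off - t_ms[falling]) / ramp) ** 2
    return env


# ---------------------------------------------------------------------------
# spike generation
# ---------------------------------------------------------------------------

def _epoch_rng(seed: int, *key: int) -> np.random.Generator:
    """Independent, reproducible stream for one epoch."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _dead_time_corrected(rate: np.ndarray) -> np.ndarray:
    """Driving intensity whose dead-time-thinned output has the target rate.

    For a Poisson process of intensity λ with dead time τ the observed rate
    is λ/(1+λτ); inverting gives λ = r/(1−rτ).
    """
    tau_s = DEAD_TIME_MS / 1000.0
    r = np.asarray(rate, dtype=float)
    if np.any(r * tau_s >= 0.95):
        raise ValueError(f"rates above {_MAX_RATE} spikes/s are not supported")
    return r / (1.0 - r * tau_s)


def draw_spike_train(rng: np.random.Generator, driven_rate: float,
                     spont_rate: float, protocol: ProtocolConfig) -> np.ndarray:
    """One epoch of spike times (ms): spont outside, ramped drive inside.

    ``driven_rate`` is the plateau rate r(t, f) inside the stimulus window;
    the increment above spontaneous follows the stimulus envelope ramps.
    Thinning of a homogeneous Poisson process at the (dead-time-corrected)
    peak intensity, followed by a 1 ms dead-time filter.
    """
    if driven_rate < spont_rate:
        raise ValueError("driven rate below spontaneous rate")
    peak = float(_dead_time_corrected(np.array([max(driven_rate, spont_rate)]))[0])
    if peak <= 0:
        return np.empty(0)
    duration_ms = protocol.epoch_ms
    n = rng.poisson(peak * duration_ms / 1000.0)
    if n == 0:
        return np.empty(0)
    times = np.sort(rng.uniform(0.0, duration_ms, size=n))
    env = _envelope(times, protocol)
    lam = _dead_time_corrected(spont_rate + (driven_rate - spont_rate) * env)
    keep = rng.uniform(0.0, peak, size=n) < lam
    times = times[keep]
    if times.size == 0:
        return times
    # enforce the absolute refractory period
    out = [times[0]]
    for t in times[1:]:
        if t - out[-1] >= DEAD_TIME_MS:
            out.append(t)
    return np.asarray(out)


def _silent_epochs(gt: SiteGroundTruth, protocol: ProtocolConfig,
                   cond_index: int) -> list:
    cond = StimulusCondition(is_silent=True)
    epochs = []
    for j in range(protocol.n_silent):
        rng = _epoch_rng(gt.seed, cond_index, j)
        spikes = draw_spike_train(rng, gt.spont_rate, gt.spont_rate, protocol)
        epochs.append(Epoch(condition=cond, spike_times=spikes, trial_index=j))
    return epochs


def simulate_spike_site(gt: SiteGroundTruth,
                        protocol: ProtocolConfig) -> RecordingSite:
    """Simulate the full binaural ITD protocol for a spiking site.

    For every test frequency, an ITD grid of ±1 stimulus period (per the
    protocol) is presented ``n_trials`` times; randomly interleaved silent
    trials estimate the spontaneous rate. Fully reproducible from the seed.
    """
    spl = protocol.spl if protocol.spl is not None else gt.threshold_spl + 20.0
    epochs: list = []
    cond_index = 0
    for fi, f in enumerate(protocol.frequencies):
        for ii, itd in enumerate(protocol.itd_grid(f)):
            cond = StimulusCondition(frequency=float(f), spl=spl,
                                     itd=float(itd), ear="binaural")
            rate = expected_rate(gt, f, itd)
            for j in range(protocol.n_trials):
                rng = _epoch_rng(gt.seed, 1, fi, ii, j)
                spikes = draw_spike_train(rng, rate, gt.spont_rate, protocol)
                epochs.append(Epoch(condition=cond, spike_times=spikes,
                                    trial_index=j))
            cond_index += 1
    epochs.extend(_silent_epochs(gt, protocol, cond_index))
    return RecordingSite(site_id=f"sim-spike-{gt.seed}", epochs=epochs,
                         ground_truth=gt, protocol=protocol,
                         assigned_frequency=gt.cf, frequency_provenance="CF")


# ---------------------------------------------------------------------------
# neurophonic generation
# ---------------------------------------------------------------------------

def neurophonic_waveform(gt: SiteGroundTruth, frequency: float, itd_us: float,
                         protocol: ProtocolConfig,
                         rng: Optional[np.random.Generator] = None) -> np.ndarray:
    """One analog epoch: ITD-modulated carrier at ``frequency`` plus noise."""
    n = int(round(protocol.epoch_ms * protocol.sample_rate / 1000.0))
    t_ms = np.arange(n) / protocol.sample_rate * 1000.0
    m = interaural_modulation(gt, frequency, itd_us)
    carrier = np.cos(2 * np.pi * frequency * t_ms / 1000.0)
    wave = gt.neurophonic_amp * m * _envelope(t_ms, protocol) * carrier
    if rng is not None and gt.noise_sd > 0:
        wave = wave + rng.normal(0.0, gt.noise_sd, size=n)
    return wave.astype(np.float32)


def simulate_neurophonic_site(gt: SiteGroundTruth,
                              protocol: ProtocolConfig) -> RecordingSite:
    """Simulate the binaural ITD protocol for a neurophonic (analog) site."""
    spl = protocol.spl if protocol.spl is not None else gt.threshold_spl + 20.0
    epochs: list = []
    for fi, f in enumerate(protocol.frequencies):
        for ii, itd in enumerate(protocol.itd_grid(f)):
            cond = StimulusCondition(frequency=float(f), spl=spl,
                                     itd=float(itd), ear="binaural")
            for j in range(protocol.n_trials):
                rng = _epoch_rng(gt.seed, 2, fi, ii, j)
                wave = neurophonic_waveform(gt, f, itd, protocol, rng)
                epochs.append(Epoch(condition=cond, analog=wave,
                                    trial_index=j,
                                    sample_rate=protocol.sample_rate))
    return RecordingSite(site_id=f"sim-neuro-{gt.seed}", epochs=epochs,
                         ground_truth=gt, protocol=protocol,
                         recording_kind="neurophonic",
                         assigned_frequency=gt.cf, frequency_provenance="CF")


# ---------------------------------------------------------------------------
# frequency × level protocols (monaural)
# ---------------------------------------------------------------------------

def monaural_rate(gt: SiteGroundTruth, frequency: float, spl: float) -> float:
    """Plateau rate under monaural stimulation (half the binaural peak drive)."""
    drive = 0.5 * spectral_gain(gt, frequency) * (gt.peak_rate - gt.spont_rate)
    return gt.spont_rate + drive * level_gain(gt, spl)


def simulate_ftc_site(gt: SiteGroundTruth, frequencies: Sequence[float],
                      spls: Sequence[float], ear: str = "ipsi",
                      n_trials: int = 5,
                      protocol: Optional[ProtocolConfig] = None) -> RecordingSite:
    """Monaural frequency × SPL matrix protocol (for threshold-curve extraction)."""
    protocol = protocol or ProtocolConfig(frequencies=tuple(frequencies),
                                          n_trials=n_trials)
    epochs: list = []
    for fi, f in enumerate(frequencies):
        for si, spl in enumerate(spls):
            cond = StimulusCondition(frequency=float(f), spl=float(spl), ear=ear)
            rate = monaural_rate(gt, f, spl)
            for j in range(n_trials):
                rng = _epoch_rng(gt.seed, 3, fi, si, j, 0 if ear == "ipsi" else 1)
                spikes = draw_spike_train(rng, rate, gt.spont_rate, protocol)
                epochs.append(Epoch(condition=cond, spike_times=spikes,
                                    trial_index=j))
    epochs.extend(_silent_epochs(gt, protocol, 10_000))
    return RecordingSite(site_id=f"sim-ftc-{gt.seed}", epochs=epochs,
                         ground_truth=gt, protocol=protocol)


def simulate_rate_level_site(gt: SiteGroundTruth, frequency: float,
                             spls: Sequence[float], ear: str = "ipsi",
                             n_trials: int = 5) -> RecordingSite:
    """Monaural rate-level series at a single frequency near BF."""
    return simulate_ftc_site(gt, [frequency], spls, ear=ear, n_trials=n_trials)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

def random_site(rng: np.random.Generator, seed: int,
                cd_range: tuple = (-500.0, 500.0),
                cp_range: tuple = (-0.4, 0.4),
                cf_range: tuple = (300.0, 1250.0)) -> SiteGroundTruth:
    """Draw one plausible low-frequency site for cohort simulations.

    Spontaneous rates span the range observed for single units in this
    nucleus (tens to ~140 spikes/s); thresholds 15–60 dB SPL.
    """
    spont = rng.uniform(26.0, 138.0)
    return SiteGroundTruth(
        cf=rng.uniform(*cf_range),
        cd_true=rng.uniform(*cd_range),
        cp_true=rng.uniform(*cp_range),
        spont_rate=spont,
        peak_rate=spont + rng.uniform(150.0, 250.0),
        tuning_bandwidth=rng.uniform(250.0, 450.0),
        threshold_spl=rng.uniform(15.0, 60.0),
        neurophonic_amp=1.0,
        noise_sd=0.1,
        seed=int(seed),
    )


def itd_test_frequencies(cf: float, n: int = 5, span: float = 400.0) -> tuple:
    """ITD-test frequencies spanning ``span`` Hz centred on CF (min 100 Hz)."""
    freqs = np.linspace(cf - span / 2.0, cf + span / 2.0, n)
    return tuple(float(f) for f in np.maximum(freqs, 100.0))
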