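# Methods

## Scope and conventions

The package analyzes ITD tuning of binaural coincidence detectors from
per-trial recording epochs (80 ms, stimulus from 10 to 60 ms with 5 ms
ramps, 5 stimuli/s presentation). Signs: negative ITD/CD = ipsilateral-
leading, positive = contralateral-leading. Phases are in cycles and, where
a principal value is needed, collapsed to (−0.5, 0.5] with the half-cycle
boundary mapped to +0.5 (both ±0.5 are printed in the field; one convention
had to be fixed).

## Generative model of the simulator

A site is parameterized by CF, characteristic delay `cd` (μs),
characteristic phase `cp` (cycles), spontaneous and peak rates (spikes/s),
a Gaussian spectral bandwidth (Hz), a threshold SPL, and analog
amplitude/noise parameters. The expected plateau firing rate at stimulus
frequency f and ITD t is

    r(t, f) = spont + g(f) · (peak − spont) · (1 + cos 2π(f·t·10⁻⁶ − φ(f))) / 2
    φ(f)    = cp + cd·10⁻⁶·f            (+ optional curvature·(f − CF)²)
    g(f)    = exp(−(f − CF)² / 2σ²)

The raised-cosine IPD modulation is the minimal model for which a
fixed-frequency cosine fit of the ITD curve is exactly well specified; the
linear φ(f) makes best IPD vs frequency linear by construction, so CD/CP
recovery is an identifiable parameter-recovery problem. The optional
quadratic phase term (`phase_curvature`, cycles/Hz², centred on CF)
produces deliberately non-linear phase–frequency relations to exercise the
linearity-test rejection path.

Spikes are an inhomogeneous Poisson process with a 1 ms absolute dead time
(so simulated single units satisfy the <1% ISI criterion by construction).
Because a dead time depresses the observed rate by a factor 1/(1 + λτ),
the driving intensity is set to λ = r/(1 − rτ) (quasi-static renewal
correction), which makes the observed rate converge to r(t, f) itself;
rates are limited to < 900 spikes/s where the correction is well defined.
Stimulus onset/offset are cosine-squared ramps applied to the rate
increment above spontaneous; spontaneous firing continues throughout the
epoch, and randomly interleaved silent trials estimate it. Each epoch draws
from an independent stream keyed by (site seed, protocol block, frequency
index, ITD index, trial index), so simulations are bit-reproducible and
insensitive to evaluation order.

Neurophonic epochs are an amplitude-modulated carrier at the stimulus
frequency: amp · m(t, f) · envelope · cos(2πf·time), with m the same
raised-cosine ITD modulation normalized to [0, 1], plus white Gaussian
noise (SD `noise_sd`). White noise is an assumption — no noise model for
the neurophonic is established; real neurophonic noise is colored and
stimulus-dependent.

SPL enters only the monaural frequency×level protocols, as a linear ramp
gain from threshold SPL to threshold+30 dB, with monaural drive half the
binaural peak drive (a coincidence-detector heuristic). The binaural ITD
protocol is assumed to run at a fixed supra-threshold level (default
threshold + 20 dB), consistent with its use in practice.

## Analysis chain

**Recording classification.** A recording is a single unit when at most 1%
of interspike intervals are below 1 ms; ISIs are pooled within epochs only
(never across the inter-epoch gap — whether pooling crossed epochs in the
original workflow is unstated). Fewer than two spikes in any single epoch
raises `UnclassifiableRecording`, distinct from "multi-unit". Sites with
analog data and no spikes are neurophonics.

**Condition summaries.** Mean rate = trial mean of (spike count in the
10–60 ms window)/50 ms; SD across trials (ddof = 1). The "average analog
amplitude" is implemented as the RMS (after mean removal) of the
trial-averaged waveform in a 15–55 ms steady-state sub-window that excludes
the ramps; it is robust, monotone in modulation depth, and equals a/√2 for
a cosine of amplitude a. Window bounds are arguments.

**Selectivity and fits.** Spike ITD curves pass when
(max − min mean rate)/max SD ≥ 1.5; with all SDs zero the ratio is +∞ for
modulated curves (accepted) and the flat case is rejected. The cosine fit
holds the frequency fixed, so it is a linear least-squares projection onto
{1, cos, sin} over the ITD grid, solved in closed form; amplitude is made
non-negative by phase flip. Unweighted least squares is used (no
trial-variance weighting — the simplest consistent reading of the
procedure). The analog fit index a/(SD·√2) is computed on the trial-
averaged waveform inside the steady-state window (whether the original SD
used the full epoch or the stimulus window is unstated; the window is an
argument), and gates analog sites at 0.7.

**Phase unwrapping.** Collapsed best IPDs cannot be regressed directly.
Integer cycle offsets k ∈ {−2..2} (first point fixed at 0) are chosen to
minimize the residual SS of the linear fit, by exhaustive search (≤ 5⁶
combinations for 7 points); a sequential nearest-prediction unwrapper is
provided and agrees with the exhaustive search on linear-phase data (tested).
The ±2 bound covers all cycle slips for |CD| ≤ 1500 μs over a 600 Hz span.

**CD/CP regression.** Ordinary least squares of unwrapped best IPD
(cycles) on frequency (Hz); CD = slope·10⁶ μs, CP = collapsed intercept.
The published linearity criterion cites a formula that is not reproduced in
the available text; it is implemented here as the significance test of the
linear regression (F-test, equal to the slope t-test with one predictor),
evaluated at the conventional 0.05 and 0.005 levels, and isolated in
`delay.linearity_pvalue` so an alternative can be swapped in. This is a
documented substitute, not the original statistic. Under this reading a
flat phase–frequency relation (CD ≈ 0, constant CP) has no linear structure
to detect and is classified non-linear.

**Disambiguation.** Response maxima lie at (best IPD + k)/f; candidates
are limited to |ITD| ≤ 1.5 periods (the tested ±1 period plus margin), and
the candidate closest to the CD is the unambiguous best ITD. Exact ties —
only possible at CP exactly 0.5, which is not observed in practice — break
toward the contralateral (positive) candidate with a warning.

**Classifiers.** Pi limit: |best ITD| strictly greater than half a period
(exactly half counts as inside). CP bands: |CP| ≤ 0.15 peak-type,
0.15–0.35 intermediate, ≥ 0.35 trough-type (the published bands touch at
0.15/0.35; the boundaries are assigned outward as stated). Slope midpoint:
best ITD − sign(best ITD)·period/4 with sign(0) = +1, applied even when the
midpoint crosses zero; the direction label names the downward direction of
the slope. Paired spike/neurophonic mismatches convert each site's best
ITD to phase at its own frequency before differencing, which reproduces the
published pairs including those with mismatched test frequencies.

**Frequency tuning.** The frequency×SPL matrix is loess-smoothed along
frequency at each SPL (tricube weights, local linear, span 0.5, no
robustness iterations — exact on linear data). Thresholds are interpolated
linearly in SPL per frequency column at a criterion of spontaneous + 20
spikes/s for spikes (the published criterion was hand-adjusted per curve,
which is not automatable; the default is fixed and config-exposed, for
analog data the lowest amplitude yielding a connected contour is the
recommended choice). CF minimizes threshold (ties toward lower frequency);
Q10/Q40 use interpolated contour widths at +10/+40 dB and are absent when
the contour does not extend that far; flank slopes are least-squares lines
through contour points 3–23 dB above the CF threshold, in dB/octave
(standard units; unspecified in the source). Whether smoothing operated on
the matrix or the contour was ambiguous; matrix smoothing is implemented,
and `extract_ftc(smooth=False)` allows pre-smoothed input. `best_frequency`
takes an already-smoothed iso-SPL curve (the pipeline smooths the matrix
first); ties break toward the lower frequency with an ambiguity flag.

## Problem sizes and frozen tolerances

Stochastic tests run at sizes chosen to keep the full suite fast while
leaving comfortable statistical margins:

- Rate convergence: 500 epochs per condition, relative error < 5% (the
  dead-time correction leaves ~0.3% bias in pilot runs).
- CD/CP parameter recovery: 50 random sites (CD uniform ±500 μs, CP ±0.4
  cycles, CF 300–1250 Hz, 5 test frequencies spanning 400 Hz, 20
  trials/condition). Pilot oracle runs across six seeds gave median
  absolute errors of 10.6–20.3 μs (CD) and 0.009–0.013 cycles (CP); the
  test tolerances are frozen at 40 μs and 0.03 cycles (~2× the worst pilot)
  and are properties of this synthetic design, not published values.
- Selectivity false-accept: 300 spontaneous-only curves (80 spikes/s, 21
  ITDs × 5 trials); pilot rate 3.25%, asserted ≤ 5%.
- Fit-index analytics: equal-power noise at 40 ms × 48 kHz, 50 repetitions;
  mean within 0.02 of 1/√2 (pilot: 0.7064, per-repetition SD 0.0097).
- Oracle equivalence: closed-form cosine fit vs a 2001-point phase-grid
  scan on 100 noisy curves; disambiguation vs dense enumeration of maxima
  on 1000 random cases.

## What the synthetic data does and does not show

The simulator emulates the stimulus protocol, Poisson-like spike counts,
refractoriness, spectral tuning and the exact cosine ITD dependence the
analysis assumes. It does **not** emulate adaptation, phase-locking jitter
(vector-strength roll-off), rate saturation nonlinearity, colored
neurophonic noise, electrode drift, or non-cosine ITD-curve shapes (e.g.
Gabor envelopes). Passing parameter-recovery tests therefore demonstrates
the correctness and internal consistency of the analysis chain under its
own assumptions, not its robustness to every feature of real recordings.
The neurophonic significance check is a segment-shuffle bootstrap (cosine
amplitude vs the 95th percentile of amplitudes from permuted and circularly
rolled waveform segments) — a documented substitute for an unavailable
published method.

## Known limitations

- The SPL dependence of the binaural rate model is a deliberate
  simplification (level gain only in monaural protocols).
- Population inferential statistics (two-sample KS and friends) are exposed
  as generic utilities; published p-values from animal cohorts depend on
  unavailable data and are not reproduced.
- Spike detection from analog traces is a plain threshold-with-lockout
  helper; no spike sorting is included.
- For sites whose true CF lies outside the tested frequency grid the CF/BF
  estimators return boundary values; callers should check the ambiguity
  flags.
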