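"""Cosine fits, selectivity criteria and phase collapsing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from laminaris import (ITDCurve, analog_fit_index, analyze_itd_curve,
                       best_itd_ipd, collapse_phase, fit_cosine,
                       fit_cosine_waveform, itd_curve_from_epochs,
                       spike_selectivity)
from laminaris.containers import Epoch, StimulusCondition


def _curve(f, itds, means, sds=None, metric="spike_rate"):
    sds = np.zeros_like(np.asarray(means, float)) if sds is None else sds
    return ITDCurve(stimulus_frequency=f, itds=itds, mean_response=means,
                    response_sd=sds, metric=metric)


def _grid(f, n_steps=10):
    period = 1e6 / f
    return np.arange(-n_steps, n_steps + 1) * period / n_steps


class TestCollapsePhase:
    @pytest.mark.parametrize("x, expected", [
        (0.572, -0.428), (-0.6, 0.4), (0.0, 0.0), (0.5, 0.5), (-0.5, 0.5),
        (1.5, 0.5), (0.25, 0.25),
    ])
    def test_known_values(self, x, expected):
        assert collapse_phase(x) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(-10, 10), st.integers(-5, 5))
    def test_periodicity_and_range(self, x, k):
        y = collapse_phase(x)
        assert -0.5 < y <= 0.5
        assert collapse_phase(x + k) == pytest.approx(y, abs=1e-9)


class TestSpikeSelectivity:
    def test_direct_formula(self):
        s, ok = spike_selectivity(_curve(700.0, _grid(700.0),
                                         np.linspace(40, 100, 21),
                                         np.full(21, 30.0)))
        assert s == pytest.approx(2.0) and ok

    def test_flat_noisy_curve_rejected(self):
        s, ok = spike_selectivity(_curve(700.0, np.array([0., 100., 200.]),
                                         np.full(3, 50.0), np.full(3, 5.0)))
        assert s == 0.0 and not ok

    def test_noiseless_modulated_curve_accepted_with_infinite_ratio(self):
        itds = _grid(700.0)
        means = 50 + 40 * np.cos(2 * np.pi * 700e-6 * itds)
        s, ok = spike_selectivity(_curve(700.0, itds, means))
        assert np.isinf(s) and ok

    def test_noiseless_flat_curve_rejected(self):
        s, ok = spike_selectivity(_curve(700.0, np.array([0., 100., 200.]),
                                         np.full(3, 50.0)))
        assert not ok

    def test_single_point_errors(self):
        with pytest.raises(ValueError):
            spike_selectivity(_curve(700.0, np.array([0.]), np.array([1.])))


class TestFitCosine:
    def test_exact_recovery(self):
        itds = _grid(700.0)
        y = 10 + 5 * np.cos(2 * np.pi * (700e-6 * itds - 0.2))
        fit = fit_cosine(_curve(700.0, itds, y))
        assert fit.mean_level == pytest.approx(10.0, abs=1e-9)
        assert fit.amplitude == pytest.approx(5.0, abs=1e-9)
        assert fit.phase == pytest.approx(0.2, abs=1e-9)

    def test_flat_data_has_zero_amplitude_and_undefined_phase(self):
        fit = fit_cosine(_curve(700.0, _grid(700.0), np.full(21, 7.0)))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-9)
        assert not fit.phase_defined

    def test_phase_matches_published_best_itd_conversion(self):
        # a best ITD of -519 μs at 700 Hz corresponds to -0.363 cycles
        itds = _grid(700.0)
        phi = -519.0 * 700.0 * 1e-6
        y = 30 + 12 * np.cos(2 * np.pi * (700e-6 * itds - phi))
        fit = fit_cosine(_curve(700.0, itds, y))
        assert fit.phase == pytest.approx(-0.3633, abs=1e-4)
        res = best_itd_ipd(fit)
        assert res.best_itd == pytest.approx(-519.0, abs=1e-6)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.integers(0, 10_000))
    def test_invariant_to_whole_period_itd_shifts(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.uniform(300, 1200)
        itds = _grid(f)
        y = rng.uniform(20, 80) + rng.uniform(1, 30) * np.cos(
            2 * np.pi * (f * 1e-6 * itds - rng.uniform(-0.5, 0.5))) \
            + rng.normal(0, 2, itds.size)
        f1 = fit_cosine(_curve(f, itds, y))
        f2 = fit_cosine(_curve(f, itds + 3 * 1e6 / f, y))
        assert f2.amplitude == pytest.approx(f1.amplitude, abs=1e-6)
        assert collapse_phase(f2.phase - f1.phase) == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_cosine(_curve(700.0, np.zeros(5), np.arange(5.0)))

    def test_sign_convention_matches_argmax_side(self):
        # peak placed at +300 μs (contralateral-leading)
        itds = _grid(800.0)
        y = 50 + 30 * np.cos(2 * np.pi * 800e-6 * (itds - 300.0))
        res = best_itd_ipd(fit_cosine(_curve(800.0, itds, y)))
        assert res.best_itd == pytest.approx(300.0, abs=1e-6)
        # argmax within the principal half-period sits on the same side
        inner = np.abs(itds) <= 0.5e6 / 800.0
        assert itds[inner][np.argmax(y[inner])] > 0


class TestBruteForceOracle:
    @staticmethod
    def oracle_fit(f, itds, y, n_phase=4001):
        """Independent oracle: scan phase, solve (m, a) per phase by lstsq."""
        phis = np.linspace(-0.5, 0.5, n_phase, endpoint=False)
        best = None
        for phi in phis:
            regress = np.cos(2 * np.pi * (f * 1e-6 * itds - phi))
            design = np.column_stack([np.ones_like(itds), regress])
            coef, res, *_ = np.linalg.lstsq(design, y, rcond=None)
            sse = float(np.sum((design @ coef - y) ** 2))
            if coef[1] >= 0 and (best is None or sse < best[0]):
                best = (sse, coef[0], coef[1], phi)
        return best[1], best[2], best[3]

    def test_closed_form_matches_grid_search(self, rng):
        for _ in range(10):
            f = rng.uniform(300, 1200)
            itds = _grid(f)
            y = rng.uniform(20, 80) + rng.uniform(5, 30) * np.cos(
                2 * np.pi * (f * 1e-6 * itds - rng.uniform(-0.49, 0.49))) \
                + rng.normal(0, 3, itds.size)
            fit = fit_cosine(_curve(f, itds, y))
            m, a, phi = self.oracle_fit(f, itds, y)
            assert fit.mean_level == pytest.approx(m, abs=0.05)
            assert fit.amplitude == pytest.approx(a, abs=0.05)
            assert collapse_phase(fit.phase - phi) == pytest.approx(0, abs=5e-4)


class TestAnalogFitIndex:
    fs = 48000.0

    def _epochs(self, wave, f):
        cond = StimulusCondition(frequency=f, spl=50.0, itd=0.0)
        return [Epoch(condition=cond, analog=wave)]

    def test_pure_sinusoid_index_is_one(self):
        t = np.arange(int(0.080 * self.fs)) / self.fs
        wave = 1.3 + 0.8 * np.cos(2 * np.pi * 700.0 * t + 0.9)
        fit = analog_fit_index(self._epochs(wave, 700.0), 700.0)
        assert fit.fit_index == pytest.approx(1.0, abs=1e-6)

    def test_white_noise_index_near_zero(self, rng):
        fit = fit_cosine_waveform(rng.normal(0, 1, 10_000), 700.0, self.fs)
        assert fit.fit_index < 0.2

    def test_equal_power_noise_gives_index_near_inverse_sqrt2(self, rng):
        t = np.arange(int(0.040 * self.fs)) / self.fs
        vals = []
        for _ in range(30):
            wave = np.cos(2 * np.pi * 700.0 * t) + rng.normal(0, 1 / np.sqrt(2), t.size)
            vals.append(fit_cosine_waveform(wave, 700.0, self.fs).fit_index)
        assert np.mean(vals) == pytest.approx(1 / np.sqrt(2), abs=0.02)

    def test_zero_variance_waveform_rejected(self):
        with pytest.raises(ValueError):
            fit_cosine_waveform(np.zeros(100), 700.0, self.fs)


def test_analyze_itd_curve_spike_route(trough_type_site):
    eps = trough_type_site.epochs_at(700.0)
    curve = itd_curve_from_epochs(eps, 700.0)
    res = analyze_itd_curve(curve)
    assert res is not None and res.acceptance_rule == "spike_ratio_1.5"
    true_ipd = collapse_phase(0.46 + 160e-6 * 700.0)
    assert collapse_phase(res.best_ipd - true_ipd) == pytest.approx(0.0, abs=0.05)
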