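"""Phase unwrapping, CD/CP regression, disambiguation and midpoints."""

import numpy as np
import pytest

from laminaris import (CosineFit, choose_candidate, classify_cp, collapse_phase,
                       disambiguate_best_itd, fit_cd_cp, paired_mismatch,
                       pi_limit_flag, slope_midpoint, unwrap_phases)
from laminaris.datasets import paired_mismatch_table
from laminaris.synth import best_ipd
from laminaris.containers import SiteGroundTruth

FREQS = np.array([500.0, 600.0, 700.0, 800.0, 900.0, 1000.0])


def _phase_points(cd_us, cp, freqs=FREQS, collapse=True):
    ipd = cp + cd_us * 1e-6 * freqs
    return list(zip(freqs, collapse_phase(ipd) if collapse else ipd))


class TestUnwrap:
    def test_already_linear_points_get_zero_offsets(self):
        pts = _phase_points(160.0, 0.1, collapse=False)
        out = unwrap_phases(pts)
        assert [k for *_, k in out] == [0] * len(pts)

    def test_single_wrapped_point_is_restored(self):
        pts = _phase_points(160.0, 0.1, collapse=False)
        shifted = [(f, p + (1.0 if i == 3 else 0.0)) for i, (f, p) in enumerate(pts)]
        out = unwrap_phases(shifted)
        fit_ref = fit_cd_cp(pts, unwrap=False)
        fit_shift = fit_cd_cp(out, unwrap=False)
        assert out[3][2] == -1
        assert fit_shift.cd == pytest.approx(fit_ref.cd, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_exhaustive_and_sequential_agree_on_linear_sites(self, seed):
        rng = np.random.default_rng(seed)
        cd, cp = rng.uniform(-500, 500), rng.uniform(-0.4, 0.4)
        freqs = np.sort(rng.choice(np.arange(400, 1201, 50), 5, replace=False))
        pts = [(float(f), collapse_phase(cp + cd * 1e-6 * f)
                + rng.normal(0, 0.01)) for f in freqs]
        a = unwrap_phases(pts, method="exhaustive")
        b = unwrap_phases(pts, method="sequential")
        # identical fits (offsets may differ by a common constant)
        assert fit_cd_cp(a, unwrap=False).cd == pytest.approx(
            fit_cd_cp(b, unwrap=False).cd, abs=1e-9)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            unwrap_phases([(500.0, 0.1), (600.0, 0.2)])


class TestFitCdCp:
    def test_exact_recovery_from_trough_type_configuration(self):
        fit = fit_cd_cp(_phase_points(160.0, 0.46))
        assert fit.cd == pytest.approx(160.0, abs=1e-9)
        assert fit.cp == pytest.approx(0.46, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.is_linear(0.005)

    def test_zero_delay_flat_fit(self):
        fit = fit_cd_cp(_phase_points(0.0, 0.0))
        assert fit.cd == pytest.approx(0.0, abs=1e-9)
        assert fit.cp == pytest.approx(0.0, abs=1e-9)

    def test_exactness_survives_arbitrary_offsets(self, rng):
        pts = _phase_points(-320.0, 0.22, collapse=False)
        jittered = [(f, p + rng.integers(-2, 3)) for f, p in pts]
        fit = fit_cd_cp(jittered)
        assert fit.cd == pytest.approx(-320.0, abs=1e-6)
        assert fit.cp == pytest.approx(0.22, abs=1e-9)

    def test_quadratic_phase_fails_linearity(self):
        # symmetric curvature around CF leaves no linear trend to detect
        gt = SiteGroundTruth(cf=750.0, cd_true=0.0, cp_true=0.1,
                             phase_curvature=1.5e-6)
        pts = [(f, collapse_phase(best_ipd(gt, f))) for f in FREQS]
        fit = fit_cd_cp(pts)
        assert not fit.is_linear(0.05)

    def test_type_i_control_of_linearity_test(self, rng):
        """Truly linear sites are called non-linear in at most 5% of cases."""
        freqs = np.linspace(500, 900, 5)
        miss = 0
        n = 500
        for _ in range(n):
            cd = rng.uniform(200, 500) * rng.choice([-1, 1])
            cp = rng.uniform(-0.4, 0.4)
            pts = [(float(f), cd * 1e-6 * f + cp + rng.normal(0, 0.01))
                   for f in freqs]
            if not fit_cd_cp(pts, unwrap=False).is_linear(0.05):
                miss += 1
        assert miss / n <= 0.05

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_cd_cp([(700.0, 0.1), (700.0, 0.2), (700.0, 0.3)], unwrap=False)


class TestDisambiguation:
    def test_published_example_candidates_and_distances(self):
        chosen, dist = choose_candidate([-519.0, 910.0], cd=160.0)
        assert chosen == -519.0 and dist == 679.0
        assert abs(910.0 - 160.0) == 750.0  # the rejected alternative

    def test_from_cosine_fit_at_700hz(self):
        fit = CosineFit(frequency=700.0, mean_level=50.0, amplitude=20.0,
                        phase=collapse_phase(-519.0 * 700e-6), fit_index=1.0)
        res = disambiguate_best_itd(fit, cd=160.0)
        assert res.chosen == pytest.approx(-519.0, abs=1e-9)
        assert res.distance_to_cd == pytest.approx(679.0, abs=1e-9)
        assert not res.changed_from_nearest_zero
        # candidate one period away sits at ~+910 μs
        period = 1e6 / 700.0
        assert res.candidates == pytest.approx(
            sorted([-519.0 - period, -519.0, -519.0 + period]))

    def test_tie_broken_toward_contralateral_with_warning(self):
        with pytest.warns(UserWarning):
            chosen, _ = choose_candidate([-100.0, 300.0], cd=100.0)
        assert chosen == 300.0

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(200):
            f = rng.uniform(300, 1200)
            period = 1e6 / f
            ipd = rng.uniform(-0.5, 0.5)
            cd = rng.uniform(-1000, 1000)
            fit = CosineFit(frequency=f, mean_level=1.0, amplitude=1.0,
                            phase=ipd, fit_index=1.0)
            res = disambiguate_best_itd(fit, cd)
            # oracle: dense enumeration of maxima within ±3 periods
            ks = np.arange(-4, 5)
            cands = (collapse_phase(ipd) + ks) * period
            cands = cands[np.abs(cands) <= 1.5 * period + 1e-9]
            oracle = cands[np.argmin(np.abs(cands - cd))]
            assert res.chosen == pytest.approx(oracle, abs=1e-9)

    def test_no_candidates_within_bound_rejected(self):
        fit = CosineFit(frequency=700.0, mean_level=1.0, amplitude=1.0,
                        phase=0.3, fit_index=1.0)
        with pytest.raises(ValueError):
            disambiguate_best_itd(fit, cd=0.0, bound_periods=0.1)


class TestPiLimit:
    @pytest.mark.parametrize("itd, f, expected", [
        (910.0, 700.0, True),      # half-period 714.3 μs
        (-519.0, 700.0, False),
        (1e6 * 0.5 / 700.0, 700.0, False),  # exactly half a period: inside
    ])
    def test_flags(self, itd, f, expected):
        assert pi_limit_flag(itd, f) is expected


class TestCpBands:
    @pytest.mark.parametrize("cp, expected", [
        (0.46, "trough_type"), (0.0, "peak_type"), (-0.25, "intermediate"),
        (0.15, "peak_type"), (0.35, "trough_type"), (-0.5, "trough_type"),
    ])
    def test_bands(self, cp, expected):
        assert classify_cp(cp) == expected


class TestSlopeMidpoint:
    @pytest.mark.parametrize("itd, f, mid, direction", [
        (1000.0, 1000.0, 750.0, "contra_to_ipsi_downward"),
        (-1000.0, 1000.0, -750.0, "ipsi_to_contra_downward"),
        (100.0, 1000.0, -150.0, "contra_to_ipsi_downward"),  # crosses zero
    ])
    def test_quarter_period_toward_zero(self, itd, f, mid, direction):
        res = slope_midpoint(itd, f)
        assert res.midpoint == pytest.approx(mid)
        assert res.direction == direction

    def test_magnitude_shrinks_when_peak_beyond_quarter_period(self, rng):
        for _ in range(100):
            f = rng.uniform(300, 1200)
            period = 1e6 / f
            itd = rng.uniform(period / 4 + 1, 2 * period) * rng.choice([-1, 1])
            res = slope_midpoint(itd, f)
            assert abs(res.midpoint) < abs(itd)
            assert abs(res.midpoint - itd) == pytest.approx(period / 4)


class TestPairedMismatch:
    def test_matching_frequency_pair(self):
        assert paired_mismatch((500.0, -500.0), (500.0, -400.0)) == \
            pytest.approx((100.0, 0.050))

    def test_mismatched_frequency_pair(self):
        itd_d, ipd_d = paired_mismatch((714.0, -472.0), (800.0, -375.0))
        assert itd_d == pytest.approx(97.0)
        assert round(ipd_d, 3) == 0.037

    def test_identical_inputs_give_zero(self):
        assert paired_mismatch((800.0, 625.0), (800.0, 625.0)) == (0.0, 0.0)

    def test_reference_table_reproduces_published_mismatches(self):
        table = paired_mismatch_table()
        expected_ipd = [0.028, 0.050, 0.050, 0.037, 0.000,
                        0.024, 0.080, 0.011, 0.080, 0.068]
        assert list(table.ipd_mismatch_cycles.round(3)) == expected_ipd
        expected_itd = [71, 100, 88, 97, 0, 30, 80, 10, 64, 52]
        assert list(table.itd_mismatch_us) == expected_itd
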