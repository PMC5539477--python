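"""HRV parameter definitions against hand arithmetic and brute-force oracles."""

import math

import numpy as np
import pytest

from wearhrv.ecg import RRSeries
from wearhrv.hrv import (
    HRV_NAMES,
    HRVParams,
    compute_all,
    correlation_dimension,
    correlation_sums,
    dfa,
    entropy,
    frequency_domain,
    poincare,
    rqa,
    time_domain,
)

from oracles import (
    apen_oracle,
    correlation_sum_oracle,
    rqa_oracle,
    sampen_oracle,
    time_domain_oracle,
)


def series(rr_ms):
    return RRSeries.from_intervals(np.asarray(rr_ms, dtype=float))


def random_series(n, rng, mean=850.0, sd=40.0):
    return series(rng.normal(mean, sd, size=n))


class TestTimeDomain:
    def test_constant_rhythm_all_variability_zero(self):
        out = time_domain(series([1000.0] * 60))
        assert out["mRR"] == 1000.0
        assert out["mHR"] == 60.0
        for key in ("SDRR", "SDHR", "RMSSD", "NN50", "pNN50"):
            assert out[key] == 0.0

    def test_alternating_hand_case(self):
        out = time_domain(series([800.0, 860.0, 800.0, 860.0]))
        assert out["mRR"] == pytest.approx(830.0)
        assert out["RMSSD"] == pytest.approx(60.0)
        assert out["NN50"] == 3
        assert out["pNN50"] == pytest.approx(75.0)

    def test_matches_formula_oracle(self, rng):
        rr = random_series(80, rng)
        mine = time_domain(rr)
        ref = time_domain_oracle(rr.rr_ms)
        for key, val in ref.items():
            assert mine[key] == pytest.approx(val, abs=1e-9)

    def test_too_short_window_names_requirement(self):
        with pytest.raises(ValueError, match="RMSSD"):
            time_domain(series([800.0, 820.0]))


class TestFrequencyDomain:
    def test_pure_hf_tone_peak_and_power(self):
        """A 0.25 Hz modulation must put its peak in the HF band and
        dominate the LF power."""
        beats, t = [], 0.0
        while t < 120.0:
            rr = 1.0 + 0.05 * math.sin(2 * math.pi * 0.25 * t)
            beats.append(rr * 1000.0)
            t += rr
        vals, flags = frequency_domain(series(beats))
        assert vals["HF"] == pytest.approx(0.25, abs=0.04)
        assert vals["pHF"] > 10.0 * vals["pLF"]
        assert "nLF" not in flags

    def test_equal_tones_balance_lf_hf(self):
        beats, t = [], 0.0
        while t < 300.0:
            rr = 1.0 + 0.04 * (math.sin(2 * math.pi * 0.10 * t)
                               + math.sin(2 * math.pi * 0.30 * t))
            beats.append(rr * 1000.0)
            t += rr
        vals, _ = frequency_domain(series(beats))
        assert 0.8 <= vals["LF_HF"] <= 1.25
        assert vals["nLF"] + vals["nHF"] == pytest.approx(1.0)
        assert vals["LF_HF"] == pytest.approx(vals["nLF"] / vals["nHF"])

    def test_constant_tachogram_flagged_zero_power(self):
        vals, flags = frequency_domain(series([900.0] * 70))
        assert vals["pLF"] == pytest.approx(0.0, abs=1e-12)
        assert flags["nLF"] == "zero-total-power"

    def test_relative_powers_sum_to_100_under_band_limited_total(self, rng):
        vals, flags = frequency_domain(random_series(90, rng))
        assert (vals["prcVLF"] + vals["prcLF"] + vals["prcHF"]
                == pytest.approx(100.0))

    def test_needs_thirty_intervals(self):
        with pytest.raises(ValueError):
            frequency_domain(series([800.0] * 29))


class TestPoincare:
    def test_constant_series_zero(self):
        out = poincare(series([800.0] * 10))
        assert out["SD1"] == out["SD2"] == 0.0

    def test_alternating_series_limit(self):
        out = poincare(series([800.0, 860.0] * 150))
        assert out["SD1"] == pytest.approx(60.0 / math.sqrt(2.0), rel=1e-2)

    def test_sd1_rmssd_exact_relation(self, rng):
        """SD1^2 = M/(M-1) * (RMSSD^2 - dbar^2) / 2 with M successive
        differences (the documented sample-SD convention)."""
        rr = random_series(61, rng)
        sd1 = poincare(rr)["SD1"]
        td = time_domain(rr)
        d = np.diff(rr.rr_ms)
        m = d.size
        expected = m / (m - 1) * (td["RMSSD"] ** 2 - d.mean() ** 2) / 2.0
        assert sd1**2 == pytest.approx(expected, rel=1e-12)


class TestEntropy:
    def test_constant_series_convention_zero(self):
        vals, flags = entropy(series([700.0] * 30))
        assert vals == {"ApEn": 0.0, "SampEn": 0.0}
        assert flags["SampEn"] == "constant-series"

    def test_perfectly_periodic_series_sampen_zero(self):
        vals, _ = entropy(series(([1000.0, 2000.0] * 10)[:20]), m=2, r=100.0)
        assert vals["SampEn"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_oracles(self, rng):
        x = rng.normal(850.0, 40.0, size=150)
        rr = series(x)
        r = 0.2 * np.std(x, ddof=1)
        vals, _ = entropy(rr, m=2, r=r)
        assert vals["ApEn"] == pytest.approx(apen_oracle(x, 2, r), abs=1e-9)
        ref = sampen_oracle(x, 2, r)
        assert ref is not None
        assert vals["SampEn"] == pytest.approx(ref, abs=1e-9)


class TestDFA:
    def test_white_noise_exponent_near_half(self):
        alphas = []
        for seed in range(50):
            x = np.random.default_rng(seed).normal(800.0, 30.0, size=1000)
            vals, _ = dfa(series(x))
            alphas.append(vals["Alpha1"])
        assert 0.4 <= float(np.mean(alphas)) <= 0.6

    def test_integrated_noise_exponent_near_three_halves(self):
        alphas = []
        for seed in range(20):
            steps = np.random.default_rng(seed).normal(0.0, 5.0, size=1000)
            x = 2000.0 + np.cumsum(steps)
            x = np.clip(x, 1.0, None)
            vals, _ = dfa(series(x))
            alphas.append(vals["Alpha1"])
        assert 1.3 <= float(np.mean(alphas)) <= 1.7

    def test_constant_series_is_error(self):
        with pytest.raises(ValueError, match="zero-fluctuation"):
            dfa(series([900.0] * 100))

    def test_short_series_alpha2_policy(self, rng):
        """Below the nominal 70 intervals Alpha2 is estimated from the
        usable long-range box sizes but flagged; with no usable size it is
        missing."""
        vals, flags = dfa(random_series(40, rng))
        assert math.isfinite(vals["Alpha2"])
        assert flags["Alpha2"] == "short-window"
        vals, flags = dfa(random_series(30, rng))
        assert math.isnan(vals["Alpha2"])
        assert flags["Alpha2"] == "too-short"


class TestCorrelationDimension:
    def test_constant_series_flagged_zero(self):
        d2, flag = correlation_dimension(series([800.0] * 40))
        assert d2 == 0.0 and flag == "degenerate"

    def test_limit_cycle_dimension_near_one(self):
        i = np.arange(500)
        x = 1000.0 + 100.0 * np.sin(2 * math.pi * i / 40.0)
        d2, flag = correlation_dimension(series(x + 800.0 * 0))
        assert flag is None
        assert 0.8 <= d2 <= 1.2

    def test_correlation_sums_match_pairwise_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=60)
        radii = np.array([0.5, 1.0, 2.0, 4.0])
        mine = correlation_sums(x, radii, m=5)
        ref = [correlation_sum_oracle(x, r, m=5) for r in radii]
        np.testing.assert_allclose(mine, ref, atol=1e-12)


class TestRQA:
    def test_constant_series_fully_recurrent(self):
        """Every point recurs; DET approaches 100 up to the single corner
        points of the finite recurrence matrix, which no diagonal of
        length >= lmin can cover."""
        vals, _ = rqa(series([800.0] * 20), m=10, r=1.0)
        assert vals["REC"] == 100.0
        assert vals["DET"] == pytest.approx(100.0, abs=2.0)
        vals_long, _ = rqa(series([800.0] * 120), m=10, r=1.0)
        assert vals_long["DET"] > vals["DET"]

    def test_toy_series_matches_enumeration_oracle(self, rng):
        x = rng.normal(0.0, 1.0, size=24)
        r = 1.5
        vals, _ = rqa(series(x + 800.0), m=3, delay=1, r=r, lmin=2)
        ref = rqa_oracle(x + 800.0, m=3, delay=1, r=r, lmin=2)
        for key, val in ref.items():
            assert vals[key] == pytest.approx(val, abs=1e-9), key

    def test_diverging_series_has_no_recurrences(self):
        x = 300.0 + 50.0 * np.arange(30)
        vals, flags = rqa(series(x), m=5, r=1.0)
        assert vals["REC"] == 0.0
        assert vals["DET"] == 0.0
        assert flags["REC"] == "no-recurrences"


class TestComputeAll:
    def test_valid_window_has_31_values(self, profile):
        from wearhrv.generate import generate_rr_series

        rr = generate_rr_series("SI", 60.0, profile, 0)
        fs = compute_all(rr)
        assert len(fs) == 31
        assert list(fs.values) == list(HRV_NAMES)
        assert np.all(np.isfinite(fs.to_array()))

    def test_constant_window_flags_degenerate_fields(self):
        fs = compute_all(series([900.0] * 70))
        assert fs["SDRR"] == 0.0 and fs["RMSSD"] == 0.0
        assert fs["ApEn"] == 0.0 and fs["SampEn"] == 0.0
        assert fs["REC"] == 100.0
        assert "Alpha1" in fs.flags and "nLF" in fs.flags
        assert fs.flags["D2"] == "degenerate"

    def test_session_batch_yields_one_set_per_minute(self, profile):
        from wearhrv.ecg import window_rr
        from wearhrv.generate import generate_rr_series

        rr = generate_rr_series("SI", 300.0, profile, 1)
        sets = [compute_all(w) for w in window_rr(rr, 60.0, span_s=300.0)]
        assert len(sets) == 5

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            compute_all(RRSeries(times=np.empty(0), rr_ms=np.empty(0)))


class TestScaleProperties:
    @pytest.mark.parametrize("c", [0.5, 2.0])
    def test_linear_statistics_scale_with_rr(self, rng, c):
        rr = random_series(80, rng, mean=900.0, sd=30.0)
        scaled = series(rr.rr_ms * c)
        base_t, scaled_t = time_domain(rr), time_domain(scaled)
        for key in ("mRR", "SDRR", "RMSSD"):
            assert scaled_t[key] == pytest.approx(c * base_t[key], rel=1e-9)
        base_p, scaled_p = poincare(rr), poincare(scaled)
        assert scaled_p["SD1"] == pytest.approx(c * base_p["SD1"], rel=1e-9)
        assert scaled_p["SD2"] == pytest.approx(c * base_p["SD2"], rel=1e-9)

    def test_band_peaks_recover_configured_modulations(self, profile):
        """On generator output the LF and HF peak frequencies land within a
        spectral bin of the configured modulation tones."""
        from wearhrv.generate import generate_rr_series

        rr = generate_rr_series("SI", 300.0, profile, 12)
        par = profile.cardiac_for("SI")
        vals, _ = frequency_domain(rr)
        bin_hz = 1.0 / 32.0
        assert abs(vals["LF"] - par.lf_freq_hz) <= bin_hz + 1e-9
        assert abs(vals["HF"] - par.hf_freq_hz) <= bin_hz + 1e-9
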