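"""Featurization: oracle equivalence, spectral targets, respiration."""

import math

import numpy as np
import pytest

import painhrv as ph
from painhrv.errors import InsufficientDataError
from painhrv.features import (
    BANDS,
    FEATURE_FAMILIES,
    FEATURE_NAMES,
    FREQUENCY_DOMAIN_FEATURES,
    NONLINEAR_FEATURES,
    PSD_FS,
    RESPIRATION_FEATURES,
    TIME_DOMAIN_FEATURES,
    _interpolate_uniform,
)

from conftest import make_epoch
from oracles import oracle_poincare, oracle_time_domain


def random_epochs(n, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        m = rng.integers(40, 100)
        iv = rng.uniform(500, 1200, size=m)
        out.append(make_epoch(iv))
    return out


class TestTimeDomain:
    def test_matches_brute_force_oracle_on_random_epochs(self):
        for epoch in random_epochs(100, seed=11):
            got = ph.compute_time_domain(epoch)
            want = oracle_time_domain(epoch.intervals)
            for name in TIME_DOMAIN_FEATURES:
                assert got[name] == pytest.approx(want[name], rel=1e-9), name

    def test_worked_example(self):
        # intervals [800, 860, 790, 815]: diffs 60, -70, 25
        got = ph.compute_time_domain(make_epoch([800, 860, 790, 815]))
        assert got["rmssd"] == pytest.approx(math.sqrt((60**2 + 70**2 + 25**2) / 3))
        assert got["rmssd"] == pytest.approx(55.151307, abs=1e-6)
        assert got["nn50"] == 2
        assert got["pnn50"] == pytest.approx(200.0 / 3)
        assert got["nn20"] == 3
        assert got["rridiff_mean"] == pytest.approx((60 + 70 + 25) / 3)

    def test_constant_series_degenerates_to_zero_variability(self):
        got = ph.compute_time_domain(make_epoch([800.0] * 75))
        assert got["rri_mean"] == 800.0
        assert got["hr_mean"] == 75.0
        assert got["sdnn"] == got["rmssd"] == got["nn50"] == 0.0

    def test_nn20_dominates_nn50(self):
        for epoch in random_epochs(20, seed=3):
            got = ph.compute_time_domain(epoch)
            assert got["nn20"] >= got["nn50"]
            assert 0 <= got["pnn50"] <= got["pnn20"] <= 100

    def test_insufficient_data(self):
        with pytest.raises(InsufficientDataError):
            ph.compute_time_domain(make_epoch([800.0]))


class TestNonlinear:
    def test_matches_oracle_and_rmssd_identity(self):
        for epoch in random_epochs(100, seed=12):
            got = ph.compute_nonlinear(epoch)
            want = oracle_poincare(epoch.intervals)
            for name in NONLINEAR_FEATURES:
                assert got[name] == pytest.approx(want[name], rel=1e-9), name
            rmssd = ph.compute_time_domain(epoch)["rmssd"]
            assert got["sd1"] == pytest.approx(rmssd / math.sqrt(2), rel=1e-9)
            assert got["ellipse_area"] == pytest.approx(
                math.pi * got["sd1"] * got["sd2"], rel=1e-9
            )

    def test_worked_example(self):
        got = ph.compute_nonlinear(make_epoch([800, 860, 790, 815]))
        assert got["sd1"] == pytest.approx(55.151307 / math.sqrt(2), abs=1e-5)

    def test_constant_series(self):
        got = ph.compute_nonlinear(make_epoch([900.0] * 50))
        assert got["sd1"] == got["sd2"] == got["ellipse_area"] == 0.0
        assert math.isnan(got["sd_ratio"])


def modulated_epoch(freq, amplitude=40.0, hr=60, seed=1, noise=0.0):
    s = ph.simulate_rri_series(
        120, hr, rsa_amplitude_ms=amplitude, resp_freq=freq,
        lf_amplitude_ms=0.0, noise_sd_ms=noise, seed=seed,
    )
    return ph.segment_epochs(s)[0]


class TestFrequencyDomain:
    def test_hf_peak_and_dominance_at_quarter_hz(self):
        got = ph.compute_frequency_domain(modulated_epoch(0.25))
        bin_hz = PSD_FS / (60 * PSD_FS)  # 1/60 Hz for a 60-s segment
        assert got["hf_peak_freq"] == pytest.approx(0.25, abs=bin_hz)
        assert got["hf_rel_power"] > 90.0

    def test_relative_powers_sum_to_hundred(self):
        for epoch in random_epochs(10, seed=5):
            got = ph.compute_frequency_domain(epoch)
            total_rel = sum(got[f"{b}_rel_power"] for b in BANDS)
            assert total_rel == pytest.approx(100.0, abs=0.1)
            assert got["lf_norm"] + got["hf_norm"] == pytest.approx(100.0, abs=0.1)
            assert got["total_power"] == pytest.approx(
                sum(got[f"{b}_abs_power"] for b in BANDS), rel=1e-9
            )

    def test_peak_frequencies_stay_inside_their_bands(self):
        for epoch in random_epochs(10, seed=6):
            got = ph.compute_frequency_domain(epoch)
            for band, (lo, hi) in BANDS.items():
                assert lo <= got[f"{band}_peak_freq"] <= hi

    def test_lf_modulation_pushes_ratio_above_one(self):
        s = ph.simulate_rri_series(
            120, 60, rsa_amplitude_ms=0.0, lf_amplitude_ms=40.0,
            lf_freq=0.1, noise_sd_ms=0.0, seed=2,
        )
        epoch = ph.segment_epochs(s)[0]
        got = ph.compute_frequency_domain(epoch)
        assert got["lf_hf_ratio"] > 1.0

    def test_total_power_tracks_series_variance(self):
        """Parseval sanity on white-jitter epochs: band-total power matches
        the variance of the interpolated, de-meaned series within 10% on
        average (a single Hann segment fluctuates epoch to epoch)."""
        s = ph.simulate_rri_series(
            600, 70, rsa_amplitude_ms=0, lf_amplitude_ms=0,
            noise_sd_ms=30, seed=21,
        )
        ratios = []
        for epoch in ph.segment_epochs(s):
            got = ph.compute_frequency_domain(epoch)
            x = _interpolate_uniform(epoch, PSD_FS)
            ratios.append(got["total_power"] / np.var(x - x.mean()))
        assert np.mean(ratios) == pytest.approx(1.0, abs=0.1)

    def test_constant_series_reports_missing_log_power(self):
        got = ph.compute_frequency_domain(make_epoch([800.0] * 70))
        assert got["total_power"] == 0.0
        assert math.isnan(got["hf_log_power"])


class TestRespiration:
    def test_recovers_18_breaths_per_minute_at_point_three_hz(self):
        _, feats = ph.derive_respiration(modulated_epoch(0.30))
        assert feats["resp_mean"] == pytest.approx(18.0, abs=0.5)
        assert feats["resp_min"] <= feats["resp_mean"] <= feats["resp_max"]

    def test_rates_are_reciprocal_inter_breath_intervals(self):
        rates, _ = ph.derive_respiration(modulated_epoch(0.25))
        assert np.all((rates >= 12.0) & (rates <= 48.0))

    def test_out_of_band_modulation_yields_missing_sentinel(self):
        s = ph.simulate_rri_series(
            120, 60, rsa_amplitude_ms=0.0, lf_amplitude_ms=40.0,
            lf_freq=0.1, noise_sd_ms=0.0, seed=1,
        )
        epoch = ph.segment_epochs(s)[0]
        _, feats = ph.derive_respiration(epoch)
        assert all(math.isnan(feats[n]) for n in RESPIRATION_FEATURES)


class TestAssembleFeatureVector:
    def test_forty_six_features_partitioned_18_20_4_4(self):
        vec = ph.assemble_feature_vector(modulated_epoch(0.25, noise=15.0))
        assert len(vec.values) == 46
        assert list(vec.values) == FEATURE_NAMES
        counts = {"time_domain": 0, "frequency_domain": 0,
                  "nonlinear": 0, "respiration": 0}
        for name in vec.values:
            counts[FEATURE_FAMILIES[name]] += 1
        assert counts == {"time_domain": 18, "frequency_domain": 20,
                          "nonlinear": 4, "respiration": 4}
        assert len(TIME_DOMAIN_FEATURES) == 18
        assert len(FREQUENCY_DOMAIN_FEATURES) == 20

    def test_deterministic_on_identical_epochs(self):
        a = ph.assemble_feature_vector(modulated_epoch(0.25, noise=10.0))
        b = ph.assemble_feature_vector(modulated_epoch(0.25, noise=10.0))
        assert a.values == b.values
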