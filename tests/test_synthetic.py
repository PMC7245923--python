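"""Synthetic imaging-like data: calibration fidelity and round trips."""

import filecmp
import json

import numpy as np
import pandas as pd
import pytest

from hsnfkb.metrics import PeakConfig, detect_peaks, summarize
from hsnfkb.synthetic import (CalibrationError, REGIMES, RegimeSpec,
                              SyntheticCondition, generate_trajectories,
                              make_fixture_suite)


@pytest.fixture(scope="module")
def tnf_control():
    cond = SyntheticCondition("TNF", "control_37C", n_cells=1000, seed=5)
    return generate_trajectories(cond)


@pytest.fixture(scope="module")
def il1_control():
    cond = SyntheticCondition("IL1", "control_37C", n_cells=1000, seed=5)
    return generate_trajectories(cond)


class TestCalibrationFidelity:
    def test_tnf_amplitude_mean_within_3se(self, tnf_control):
        _, truth = tnf_control
        amps = truth["first_peak_amplitude"].dropna()
        se = 44.0 / np.sqrt(len(amps))
        assert abs(amps.mean() - 101.0) < 3 * se

    def test_il1_single_peak_fraction_within_3se(self, il1_control):
        _, truth = il1_control
        frac = (truth["n_peaks"] == 1).mean()
        se = np.sqrt(0.8 * 0.2 / len(truth))
        assert abs(frac - 0.80) < 3 * se

    def test_tnf_count_distribution_bounds(self, tnf_control):
        _, truth = tnf_control
        counts = truth["n_peaks"]
        assert (counts <= 5).all()
        frac_le3 = (counts <= 3).mean()
        se = np.sqrt(0.5 * 0.5 / len(truth))
        assert abs(frac_le3 - 0.50) < 4 * se

    def test_post_hs_4h_mostly_five_plus(self):
        _, truth = generate_trajectories(SyntheticCondition(
            "TNF", "post_HS_4h", n_cells=1000, seed=8))
        frac = (truth["n_peaks"] >= 5).mean()
        se = np.sqrt(0.9 * 0.1 / len(truth))
        assert abs(frac - 0.90) < 3 * se

    def test_infeasible_truncation_raises(self):
        bad = RegimeSpec(amplitude_mean=30.0, amplitude_sd=44.0,
                         peak_count_probs={1: 1.0})
        cond = SyntheticCondition("TNF", "control_37C", n_cells=10,
                                  seed=0, calibration=bad)
        with pytest.raises(CalibrationError):
            generate_trajectories(cond)


class TestRoundTrips:
    def test_noiseless_single_peak_recovered_at_grid_resolution(self):
        spec = RegimeSpec(amplitude_mean=100.0, amplitude_sd=0.0,
                          peak_count_probs={1: 1.0}, delay_sd_h=0.0)
        cond = SyntheticCondition("TNF", "control_37C", n_cells=5,
                                  seed=2, noise_sd=0.0,
                                  calibration=spec)
        ts, truth = generate_trajectories(cond)
        cfg = PeakConfig(smooth_window=1)
        for i in range(ts.n_cells):
            peaks = detect_peaks(ts.times, ts.values[i], cfg)
            assert len(peaks) == 1
            assert peaks[0][0] == pytest.approx(
                truth.loc[i, "first_peak_time"], abs=5 / 60 + 1e-9)

    def test_detector_challenge_at_ten_percent_noise(self):
        """At noise SD = 10% of the mean amplitude the default detector
        recovers planted counts for at least 95% of cells."""
        chal = RegimeSpec(amplitude_mean=100.0, amplitude_sd=10.0,
                          peak_count_probs={k: 0.2 for k in
                                            range(1, 6)})
        ts, truth = generate_trajectories(SyntheticCondition(
            "TNF", "control_37C", n_cells=400, seed=13, noise_sd=10.0,
            calibration=chal))
        pc = summarize(ts, window=(0, 10)).per_cell \
            .sort_values("cell_id")
        agree = (pc["n_peaks"].to_numpy() ==
                 truth["n_peaks"].to_numpy()).mean()
        assert agree >= 0.95
        # planted amplitude and response timing are also recovered
        resp = truth["n_peaks"] > 0
        da = pc.loc[resp.values, "first_peak_amplitude"].to_numpy()
        ta = truth.loc[resp, "first_peak_amplitude"].to_numpy()
        assert (np.abs(da - ta) <= 2 * 10.0).mean() >= 0.95

    def test_detected_histogram_tracks_planted(self, tnf_control):
        ts, truth = tnf_control
        pc = summarize(ts, window=(0, 10)).per_cell \
            .sort_values("cell_id")
        agree = (pc["n_peaks"].to_numpy() ==
                 truth["n_peaks"].to_numpy()).mean()
        assert agree >= 0.95
        for k in range(1, 6):
            planted = (truth["n_peaks"] == k).mean()
            detected = (pc["n_peaks"] == k).mean()
            se = np.sqrt(max(planted * (1 - planted), 0.01) /
                         len(truth))
            assert abs(detected - planted) < 4 * se + 0.01


class TestFixtureSuite:
    def test_deterministic_and_complete(self, tmp_path):
        d1 = make_fixture_suite(11, tmp_path / "a")
        d2 = make_fixture_suite(11, tmp_path / "b")
        assert filecmp.cmp(d1["trajectories"], d2["trajectories"],
                           shallow=False)
        assert filecmp.cmp(d1["ground_truth"], d2["ground_truth"],
                           shallow=False)
        df = pd.read_csv(d1["trajectories"])
        truth = json.loads(d1["ground_truth"].read_text())
        assert len(truth["conditions"]) == len(REGIMES)
        for cond, cells in truth["conditions"].items():
            assert len(cells) == 50
            assert df[df.condition == cond]["cell_id"].nunique() == 50

    def test_different_seed_differs(self, tmp_path):
        d1 = make_fixture_suite(11, tmp_path / "a")
        d3 = make_fixture_suite(12, tmp_path / "c")
        assert not filecmp.cmp(d1["trajectories"], d3["trajectories"],
                               shallow=False)
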