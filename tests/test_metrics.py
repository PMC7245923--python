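"""Trajectory metrics against independent oracles and invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hsnfkb.metrics import (HeatmapMatrix, PeakConfig, compare_groups,
                            detect_peaks, dunn_test, normalize_heatmap,
                            significance_tier, summarize)


def brute_force_local_maxima(values, prominence, min_sep):
    """Exhaustive local-maximum scan with a prominence criterion."""
    peaks = []
    for i in range(1, len(values) - 1):
        if not (values[i] > values[i - 1] and values[i] >= values[i + 1]):
            continue
        # walk outwards to the nearest higher point; the valley floors
        # on the way bound the prominence
        lmin = values[i]
        j = i - 1
        while j >= 0 and values[j] <= values[i]:
            lmin = min(lmin, values[j])
            j -= 1
        rmin = values[i]
        j = i + 1
        while j < len(values) and values[j] <= values[i]:
            rmin = min(rmin, values[j])
            j += 1
        if values[i] - max(lmin, rmin) >= prominence:
            peaks.append(i)
    # enforce separation, keeping the higher peak
    kept = []
    for i in peaks:
        if kept and i - kept[-1] < min_sep:
            if values[i] > values[kept[-1]]:
                kept[-1] = i
        else:
            kept.append(i)
    return kept


class TestDetectPeaks:
    def test_constant_series_has_no_peaks(self):
        t = np.arange(0, 10, 5 / 60)
        assert detect_peaks(t, np.full_like(t, 7.0)) == []

    def test_two_gaussian_bumps_match_exhaustive_scan(self):
        """Two bumps (amplitudes 100 and 60, 100 min apart) against a
        brute-force local-maximum oracle at prominence 20."""
        t = np.arange(0, 10, 5 / 60)
        v = (100 * np.exp(-0.5 * ((t - 2.0) / 0.2) ** 2) +
             60 * np.exp(-0.5 * ((t - 2.0 - 100 / 60) / 0.2) ** 2))
        cfg = PeakConfig(prominence=20.0, smooth_window=1)
        got = detect_peaks(t, v, cfg)
        oracle = brute_force_local_maxima(v, 20.0, int(0.5 / (5 / 60)))
        assert [round(p[0], 4) for p in got] == \
            [round(t[i], 4) for i in oracle]
        assert len(got) == 2
        assert got[0][0] == pytest.approx(2.0, abs=5 / 60)
        assert got[1][0] == pytest.approx(2.0 + 100 / 60, abs=5 / 60)
        assert got[0][1] == pytest.approx(100.0, rel=0.02)

    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            detect_peaks(np.array([0.0, 1.0, 3.0]),
                         np.array([0.0, 1.0, 0.0]))

    def test_non_finite_rejected(self):
        t = np.arange(5.0)
        with pytest.raises(ValueError, match="finite"):
            detect_peaks(t, np.array([0, 1, np.nan, 1, 0]))


def make_long(cells, dt=5 / 60, condition="c"):
    rows = []
    for cid, v in enumerate(cells):
        t = np.arange(len(v)) * dt
        rows.append(pd.DataFrame(dict(time_h=t, cell_id=cid, value=v,
                                      condition=condition)))
    return pd.concat(rows, ignore_index=True)


class TestSummarize:
    def test_constant_series_is_nonresponder_with_zero_auc(self):
        df = make_long([np.full(121, 5.0)])
        met = summarize(df)
        row = met.per_cell.iloc[0]
        assert row.n_peaks == 0 and not row.responder
        assert row.auc == pytest.approx(0.0)
        assert np.isnan(row.first_peak_amplitude)
        assert np.isnan(row.time_to_first_response)

    def test_triangular_pulse_auc_matches_geometry(self):
        """AUC of a triangular pulse of height h and base b is h*b/2."""
        dt = 5 / 60
        t = np.arange(121) * dt
        h, b = 90.0, 2.0
        v = np.interp(t, [3.0, 3.0 + b / 2, 3.0 + b], [0, h, 0])
        met = summarize(make_long([v]), config=PeakConfig(smooth_window=1))
        assert met.per_cell.iloc[0].auc == pytest.approx(h * b / 2,
                                                         rel=1e-6)

    def test_scale_equivariance(self):
        """Scaling every trajectory by c scales AUC and amplitudes by c
        and leaves counts and responder calls unchanged."""
        rng = np.random.default_rng(5)
        t = np.arange(121) * 5 / 60
        cells = []
        for _ in range(8):
            v = 10 + 100 * np.exp(-0.5 * ((t - rng.uniform(1, 3)) / 0.25)
                                  ** 2) + rng.normal(0, 2, t.size)
            cells.append(v)
        base = summarize(make_long(cells)).per_cell
        c = 37.5
        scaled = summarize(make_long([c * v for v in cells])).per_cell
        np.testing.assert_array_equal(base.n_peaks, scaled.n_peaks)
        np.testing.assert_array_equal(base.responder, scaled.responder)
        np.testing.assert_allclose(scaled.auc, c * base.auc, rtol=1e-9)
        np.testing.assert_allclose(scaled.first_peak_amplitude,
                                   c * base.first_peak_amplitude,
                                   rtol=1e-9)


class TestHeatmap:
    def test_global_maximum_maps_to_three(self):
        t = np.arange(121) * 5 / 60
        v1 = 10 + 50 * np.exp(-0.5 * ((t - 2) / 0.3) ** 2)
        df = make_long([v1], condition="a")
        maps = normalize_heatmap(df)
        assert maps["a"].matrix.max() == pytest.approx(3.0)

    def test_shared_scale_across_conditions(self):
        t = np.arange(121) * 5 / 60
        small = 10 + 50 * np.exp(-0.5 * ((t - 2) / 0.3) ** 2)
        big = 10 + 200 * np.exp(-0.5 * ((t - 2) / 0.3) ** 2)
        solo = normalize_heatmap(make_long([small], condition="a"))
        both = normalize_heatmap(pd.concat(
            [make_long([small], condition="a"),
             make_long([big], condition="b")], ignore_index=True))
        assert both["a"].matrix.max() < solo["a"].matrix.max()
        assert both["b"].matrix.max() == pytest.approx(3.0)
        # identical trajectory in both conditions → identical rows
        dup = normalize_heatmap(pd.concat(
            [make_long([small], condition="a"),
             make_long([small], condition="b")], ignore_index=True))
        np.testing.assert_allclose(dup["a"].matrix, dup["b"].matrix)

    def test_all_zero_input_rejected(self):
        df = make_long([np.zeros(50)])
        with pytest.raises(ValueError, match="zero"):
            normalize_heatmap(df)


def brute_force_kruskal_h(groups):
    """Direct evaluation of the tie-corrected H statistic with ranks
    assigned by explicit sorting."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j < len(pooled) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2.0
        i = j
    n = len(pooled)
    start, h = 0, 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += len(g) * (r.mean() - (n + 1) / 2) ** 2
        start += len(g)
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
    return h / tie


class TestGroupComparison:
    def test_kruskal_matches_brute_force_oracle(self):
        groups = [np.array([1.0, 2, 3, 4, 5]),
                  np.array([10.0, 20, 30, 40, 50])]
        report = compare_groups({"a": groups[0], "b": groups[1]})
        assert report["kruskal_wallis"]["H"] == pytest.approx(
            brute_force_kruskal_h(groups), rel=1e-12)

    def test_kruskal_with_ties_matches_oracle(self):
        groups = [np.array([1.0, 1, 2, 3]), np.array([2.0, 2, 3, 4]),
                  np.array([1.0, 4, 4, 5])]
        report = compare_groups(
            {"a": groups[0], "b": groups[1], "c": groups[2]})
        assert report["kruskal_wallis"]["H"] == pytest.approx(
            brute_force_kruskal_h(groups), rel=1e-12)

    def test_identical_groups_not_significant(self):
        g = np.array([3.0, 3, 3, 3])
        report = compare_groups({"a": g, "b": g.copy()})
        assert report["kruskal_wallis"]["p"] > 0.99
        assert (report["dunn"]["tier"] == "ns").all()

    def test_chi_square_matches_closed_form(self):
        """2×2 responder table (50,0 / 25,25): χ² by hand, p < 1e-4."""
        table = np.array([[50, 0], [25, 25]], float)
        col = table.sum(0)
        row = table.sum(1)
        expected = np.outer(row, col) / table.sum()
        chi2 = ((table - expected) ** 2 / expected).sum()
        report = compare_groups(
            {"a": np.arange(3.0), "b": np.arange(3.0) + 1},
            responder_counts={"a": (50, 0), "b": (25, 25)})
        assert report["chi_square"]["statistic"] == pytest.approx(
            chi2, rel=1e-12)
        assert report["chi_square"]["p"] < 1e-4
        assert report["chi_square"]["tier"] == "****"

    def test_degenerate_contingency_rejected(self):
        with pytest.raises(ValueError, match="contingency"):
            compare_groups({"a": np.arange(3.0), "b": np.arange(3.0)},
                           responder_counts={"a": (0, 3), "b": (0, 5)})

    def test_dunn_adjusted_not_below_unadjusted(self):
        rng = np.random.default_rng(1)
        groups = {c: rng.normal(i, 1, 12) for i, c in
                  enumerate("abcd")}
        table = dunn_test(groups)
        assert (table.p_adjusted >= table.p - 1e-15).all()

    def test_dunn_z_matches_brute_force(self):
        """Dunn z for two groups equals the direct pooled-rank formula."""
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([10.0, 20, 30, 40, 50])
        pooled = np.concatenate([a, b])
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        se = np.sqrt((n * (n + 1) / 12) * (1 / 5 + 1 / 5))
        z_expected = (ranks[:5].mean() - ranks[5:].mean()) / se
        table = dunn_test({"a": a, "b": b})
        assert table.z.iloc[0] == pytest.approx(z_expected, rel=1e-12)

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            compare_groups({"a": np.arange(3.0)})
        with pytest.raises(ValueError):
            compare_groups({"a": np.arange(3.0), "b": np.arange(2.0)})


def test_significance_tiers():
    assert significance_tier(0.5) == "ns"
    assert significance_tier(0.04) == "*"
    assert significance_tier(0.004) == "**"
    assert significance_tier(4e-4) == "***"
    assert significance_tier(4e-5) == "****"
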