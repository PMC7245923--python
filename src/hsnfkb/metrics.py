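"""Quantification of single-cell nuclear NF-κB time series.

Implements the study's trajectory descriptors — area under the curve,
first-peak amplitude, time to first response, number of translocation
peaks, responder calls — plus heat-map normalization across conditions
and the group-comparison statistics (D'Agostino–Pearson normality,
Kruskal–Wallis with Dunn's multiple comparisons, chi-square on responder
counts).

The trajectory source is irrelevant: simulated ensembles and
imaging-like synthetic data go through the same code path (long-format
``time_h``/``cell_id``/``value``/``condition`` tables or
:class:`~hsnfkb.population.TrajectorySet`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = ["PeakConfig", "TrajectoryMetrics", "HeatmapMatrix",
           "detect_peaks", "summarize", "normalize_heatmap",
           "compare_groups", "dunn_test", "significance_tier"]


@dataclass(frozen=True)
class PeakConfig:
    """Peak-calling configuration.

    ``prominence`` — absolute prominence threshold (signal units); when
    ``None`` each series uses ``prominence_fraction`` of its own
    baseline-to-maximum excursion (the set-level pass in
    :func:`summarize` replaces this with a shared absolute threshold:
    ``prominence_fraction`` of the condition-set median first-peak
    amplitude).  ``min_interval_h`` — minimum peak separation (0.5 h).
    ``baseline_frames`` — frames used for the baseline when no
    pre-stimulation window exists.  ``response_sd_mult`` — the response
    threshold is baseline + max(this × pre-stimulation SD, half the
    prominence threshold).  ``smooth_window`` — odd width of the
    quadratic Savitzky–Golay filter applied before peak extraction
    (1 disables smoothing); frame noise otherwise dominates the
    peak-amplitude estimate.
    """

    prominence: float | None = None
    prominence_fraction: float = 0.2
    min_interval_h: float = 0.5
    baseline_frames: int = 3
    response_sd_mult: float = 3.0
    smooth_window: int = 5
    noise_mult: float = 4.0

    def _smooth(self, values: np.ndarray) -> np.ndarray:
        w = self.smooth_window
        if w <= 1 or len(values) < w:
            return values
        return signal.savgol_filter(values, w, polyorder=2)

    def _noise_floor(self, values: np.ndarray) -> float:
        """Robust frame-noise scale from second differences.

        Second differences cancel smooth trends, so the estimate stays
        near zero on noise-free model output while tracking the frame
        noise of imaging-like traces; ``noise_mult`` × this scale is a
        lower bound on an acceptable peak prominence.
        """
        if len(values) < 3:
            return 0.0
        d2 = np.diff(values, n=2)
        sigma = 1.4826 * float(np.median(np.abs(d2))) / np.sqrt(6.0)
        return self.noise_mult * sigma


def _check_uniform(times: np.ndarray) -> float:
    dt = np.diff(times)
    if len(dt) == 0:
        raise ValueError("need at least two time points")
    # tolerate the rounding of serialized time stamps
    if np.max(np.abs(dt - dt[0])) > 1e-3 * max(dt[0], 1e-12):
        raise ValueError("time grid must be uniform")
    return float(dt[0])


def _baseline(values: np.ndarray, pre: np.ndarray | None,
              config: PeakConfig) -> tuple[float, float]:
    """(baseline level, pre-stimulation SD) for one series."""
    if pre is not None and len(pre) >= 2:
        return float(np.mean(pre)), float(np.std(pre))
    k = min(config.baseline_frames, len(values))
    return float(np.mean(values[:k])), 0.0


def detect_peaks(times: np.ndarray, values: np.ndarray,
                 config: PeakConfig | None = None
                 ) -> list[tuple[float, float]]:
    """Translocation peaks as ``(time, amplitude-above-baseline)`` pairs.

    Local maxima whose prominence exceeds the configured threshold and
    that are separated by at least the minimum inter-peak interval.
    Deterministic given the config; rejects non-uniform grids.
    """
    config = config or PeakConfig()
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if not np.all(np.isfinite(values)):
        raise ValueError("trajectory contains non-finite values")
    dt = _check_uniform(times)
    smooth = config._smooth(values)
    base, _ = _baseline(smooth, None, config)
    if config.prominence is not None:
        prom = config.prominence
    else:
        excursion = float(np.max(smooth)) - base
        prom = config.prominence_fraction * excursion
    prom = max(prom, config._noise_floor(values))
    if prom <= 0:
        return []
    distance = max(int(round(config.min_interval_h / dt)), 1)
    idx, _props = signal.find_peaks(smooth, prominence=prom,
                                    distance=distance,
                                    height=base + prom)
    return [(float(times[i]), float(smooth[i] - base)) for i in idx]


@dataclass
class TrajectoryMetrics:
    """Per-cell descriptors plus per-condition summaries."""

    per_cell: pd.DataFrame     # cell_id, condition, auc, n_peaks, ...
    config: PeakConfig
    prominence_used: float

    def condition_summary(self) -> pd.DataFrame:
        g = self.per_cell.groupby("condition")
        out = g.agg(
            n_cells=("cell_id", "size"),
            responders=("responder", "sum"),
            auc_mean=("auc", "mean"), auc_sd=("auc", "std"),
            amplitude_mean=("first_peak_amplitude", "mean"),
            amplitude_sd=("first_peak_amplitude", "std"),
            response_time_mean=("time_to_first_response", "mean"),
        ).reset_index()
        out["responder_fraction"] = out["responders"] / out["n_cells"]
        return out

    def peak_count_histogram(self) -> pd.DataFrame:
        return (self.per_cell.groupby(["condition", "n_peaks"])
                .size().rename("n_cells").reset_index())


def _to_long(trajs) -> pd.DataFrame:
    if isinstance(trajs, pd.DataFrame):
        return trajs
    if hasattr(trajs, "to_frame"):
        return trajs.to_frame()
    return pd.concat([t.to_frame() for t in trajs], ignore_index=True)


def summarize(trajs, config: PeakConfig | None = None,
              window: tuple[float, float] = (0.0, 10.0)
              ) -> TrajectoryMetrics:
    """Quantify every cell of one or more conditions.

    Peak calling is two-pass: a provisional per-cell pass estimates the
    condition-set median first-peak amplitude, and the final pass uses
    one shared absolute prominence threshold
    (``prominence_fraction`` × that median) so that every condition in a
    comparison set is scored on the same scale.  AUC is the trapezoid of
    the baseline-subtracted signal (floored at 0) over the observation
    window; the baseline is the pre-stimulation mean (or the first
    frames when no pre-stimulation samples exist).
    """
    config = config or PeakConfig()
    df = _to_long(trajs)
    t0, t1 = window

    cells = []
    for (cond, cid), sub in df.groupby(["condition", "cell_id"],
                                       sort=True):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(float)
        v = sub["value"].to_numpy(float)
        pre = v[t < t0 - 1e-9]
        m = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        cells.append((cond, cid, t[m], v[m],
                      pre if len(pre) >= 2 else None))
    if not cells:
        raise ValueError("no trajectories to summarize")
    short = any(c[2][-1] - c[2][0] < (t1 - t0) - 1e-6 for c in cells)

    if config.prominence is None:
        first_amps = []
        for _, _, t, v, pre in cells:
            peaks = detect_peaks(t, v, config)
            if peaks:
                first_amps.append(peaks[0][1])
        med = float(np.median(first_amps)) if first_amps else 0.0
        prom = config.prominence_fraction * med if med > 0 else None
        final_cfg = (PeakConfig(prominence=prom,
                                prominence_fraction=config.prominence_fraction,
                                min_interval_h=config.min_interval_h,
                                baseline_frames=config.baseline_frames,
                                response_sd_mult=config.response_sd_mult)
                     if prom else config)
    else:
        final_cfg = config
        prom = config.prominence

    rows = []
    for cond, cid, t, v, pre in cells:
        vs = final_cfg._smooth(v)
        base, pre_sd = _baseline(vs, pre, final_cfg)
        peaks = detect_peaks(t, v, final_cfg)
        n_peaks = len(peaks)
        responder = n_peaks > 0
        auc = float(np.trapezoid(np.maximum(v - base, 0.0), t))
        amp = peaks[0][1] if responder else np.nan
        peak_t = peaks[0][0] if responder else np.nan
        ttr = np.nan
        if responder:
            thr = base + max(final_cfg.response_sd_mult * pre_sd,
                             0.5 * (prom if prom else amp *
                                    final_cfg.prominence_fraction))
            above = np.nonzero(vs > thr)[0]
            ttr = float(t[above[0]]) if len(above) else peak_t
        rows.append(dict(condition=cond, cell_id=cid, auc=auc,
                         first_peak_amplitude=amp, first_peak_time=peak_t,
                         time_to_first_response=ttr, n_peaks=n_peaks,
                         responder=responder, baseline=base,
                         window_truncated=short))
    return TrajectoryMetrics(per_cell=pd.DataFrame(rows),
                             config=final_cfg,
                             prominence_used=float(prom or 0.0))


@dataclass
class HeatmapMatrix:
    """Cells × timepoints matrix on the shared 0–3 display scale."""

    condition: str
    times: np.ndarray
    matrix: np.ndarray      # rows ordered by (response time, AUC)
    cell_order: np.ndarray
    scale_max: float        # raw value that maps to 3.0


def normalize_heatmap(trajsets, config: PeakConfig | None = None
                      ) -> dict[str, HeatmapMatrix]:
    """Normalize all conditions of a comparison set to a shared 0–3 scale.

    Every value is divided by the global maximum across all conditions
    and multiplied by 3, so the hottest cell-timepoint of the whole set
    maps to 3.0.  Rows are ordered by time of first response, then AUC.
    """
    df = _to_long(trajsets)
    global_max = float(df["value"].max())
    if global_max <= 0:
        raise ValueError("all-zero comparison set cannot be normalized")
    metrics = summarize(df, config=config).per_cell.set_index(
        ["condition", "cell_id"])
    out: dict[str, HeatmapMatrix] = {}
    for cond, sub in df.groupby("condition", sort=True):
        wide = sub.pivot_table(index="cell_id", columns="time_h",
                               values="value", sort=True)
        met = metrics.loc[cond].reindex(wide.index)
        order = met.sort_values(
            ["time_to_first_response", "auc"],
            ascending=[True, False], na_position="last").index.to_numpy()
        mat = wide.loc[order].to_numpy(float) * 3.0 / global_max
        out[str(cond)] = HeatmapMatrix(
            condition=str(cond), times=wide.columns.to_numpy(float),
            matrix=mat, cell_order=order, scale_max=global_max)
    return out


def significance_tier(p: float) -> str:
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def dunn_test(groups: dict[str, np.ndarray],
              adjust: bool = True) -> pd.DataFrame:
    """Dunn's pairwise rank comparisons after Kruskal–Wallis.

    Pooled-rank z statistics with the tie correction, two-sided normal
    p values, Bonferroni-adjusted over all pairwise comparisons (the
    convention of the common commercial implementation).  Adjusted
    p values are never smaller than the unadjusted ones.
    """
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for g in names:
        mean_ranks[g] = float(np.mean(ranks[start:start + sizes[g]]))
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = np.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            if se == 0:  # every observation tied
                z = 0.0
            else:
                z = (mean_ranks[gi] - mean_ranks[gj]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = min(1.0, p * m) if adjust else p
            rows.append(dict(group_1=gi, group_2=gj, z=z, p=p,
                             p_adjusted=p_adj,
                             tier=significance_tier(p_adj)))
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray],
                   responder_counts: dict[str, tuple[int, int]] | None
                   = None) -> dict:
    """The study's group-comparison battery on one metric.

    ``groups`` maps condition name to the per-cell metric values
    (each n ≥ 3).  Reports D'Agostino–Pearson normality per group,
    the tie-corrected Kruskal–Wallis H and p, Dunn's pairwise table and
    (when ``responder_counts`` — (responders, non-responders) per
    condition — is given) the chi-square test on the responder
    contingency table.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    clean = {}
    for g, v in groups.items():
        v = np.asarray(v, float)
        v = v[np.isfinite(v)]
        if len(v) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 values")
        clean[g] = v

    normality = {}
    for g, v in clean.items():
        if len(v) >= 8 and np.ptp(v) > 0:
            k2, p = stats.normaltest(v)
            normality[g] = dict(statistic=float(k2), p=float(p),
                                normal=bool(p >= 0.05))
        else:
            normality[g] = dict(statistic=np.nan, p=np.nan, normal=None)

    if all(np.ptp(v) == 0 for v in clean.values()) and \
            len({v[0] for v in clean.values()}) == 1:
        h, p_kw = 0.0, 1.0   # all observations tied across all groups
    else:
        h, p_kw = stats.kruskal(*clean.values())
    report = dict(
        normality=normality,
        kruskal_wallis=dict(H=float(h), p=float(p_kw),
                            tier=significance_tier(p_kw)),
        dunn=dunn_test(clean),
    )
    if responder_counts is not None:
        table = np.array([responder_counts[g] for g in responder_counts])
        if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
            raise ValueError("degenerate responder contingency table")
        chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
        report["chi_square"] = dict(statistic=float(chi2), p=float(p),
                                    dof=int(dof),
                                    tier=significance_tier(p))
    return report
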