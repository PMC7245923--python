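"""Synthetic p65-EGFP-like single-cell fluorescence trajectories.

A generative stand-in for time-lapse nuclear NF-κB imaging data,
calibrated to the summary statistics reported for the real experiments:
TNFα control trajectories have first-peak amplitudes of 101 ± 44
arbitrary units with ≤5 translocations in 10 h (~50% of cells ≤3);
IL1β control gives a single translocation in 80% of cells; post-heat-
shock regimes are delayed/suppressed and (for TNFα) shifted towards
many translocations after recovery.  Every generated cell carries its
planted ground truth (peak times, amplitudes, counts), so the
trajectory-metrics pipeline can be benchmarked without any experimental
data.  Regime parameters the source experiments did not quantify
(delay distributions, pulse shapes) are synthetic conventions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .population import TrajectorySet

__all__ = ["RegimeSpec", "SyntheticCondition", "CalibrationError",
           "generate_trajectories", "make_fixture_suite", "REGIMES"]

REGIME_NAMES = ("control_37C", "post_HS_0h", "post_HS_1h", "post_HS_2h",
                "post_HS_4h", "post_41C", "repeated_HS")


class CalibrationError(ValueError):
    """Raised when a regime's amplitude calibration is infeasible."""


@dataclass(frozen=True)
class RegimeSpec:
    """Calibration block of one (cytokine, regime) condition.

    ``amplitude_mean``/``amplitude_sd`` parameterize the truncated-normal
    first-peak amplitude (arbitrary fluorescence units);
    ``peak_count_probs`` is the distribution of translocation counts
    among responders; ``delay_mean_h``/``delay_sd_h`` the response-onset
    delay; ``responder_fraction`` the fraction of cells with any
    response; ``damping`` the (lo, hi) range of the per-cell geometric
    damping of successive peak amplitudes.
    """

    amplitude_mean: float
    amplitude_sd: float
    peak_count_probs: dict[int, float]
    delay_mean_h: float = 0.35
    delay_sd_h: float = 0.10
    responder_fraction: float = 1.0
    damping: tuple[float, float] = (0.85, 0.97)

    def __post_init__(self) -> None:
        total = sum(self.peak_count_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"peak-count probabilities must sum to 1, got {total}")
        if self.amplitude_mean < 0 or self.amplitude_sd < 0:
            raise ValueError("amplitudes must be >= 0")
        if not (0.0 <= self.responder_fraction <= 1.0):
            raise ValueError("responder_fraction must be in [0, 1]")


def _tnf(mean_scale, counts, delay, delay_sd=0.1, resp=1.0):
    return RegimeSpec(amplitude_mean=101.0 * mean_scale,
                      amplitude_sd=44.0 * mean_scale,
                      peak_count_probs=counts, delay_mean_h=delay,
                      delay_sd_h=delay_sd, responder_fraction=resp)


def _il1(mean_scale, counts, delay, delay_sd=0.1, resp=1.0):
    return RegimeSpec(amplitude_mean=115.0 * mean_scale,
                      amplitude_sd=40.0 * mean_scale,
                      peak_count_probs=counts, delay_mean_h=delay,
                      delay_sd_h=delay_sd, responder_fraction=resp)


#: calibrated regimes: reported statistics where available, synthetic
#: conventions (scales/delays) elsewhere
REGIMES: dict[tuple[str, str], RegimeSpec] = {
    # TNFα control: 101 ± 44 a.u.; ~50% of cells ≤3 peaks; none >5
    ("TNF", "control_37C"): _tnf(
        1.0, {1: 0.10, 2: 0.15, 3: 0.25, 4: 0.30, 5: 0.20}, 0.35),
    ("TNF", "post_HS_0h"): _tnf(
        0.20, {1: 0.50, 2: 0.30, 3: 0.20}, 2.0, 0.8, resp=0.55),
    ("TNF", "post_HS_1h"): _tnf(
        0.55, {2: 0.20, 3: 0.30, 4: 0.30, 5: 0.20}, 0.8, 0.3),
    # 50% of cells with >=5 translocations after 2 h recovery
    ("TNF", "post_HS_2h"): _tnf(
        0.78, {3: 0.20, 4: 0.30, 5: 0.30, 6: 0.20}, 0.55, 0.15),
    # ~90% of cells with >=5 translocations after 4 h recovery
    ("TNF", "post_HS_4h"): _tnf(
        0.90, {4: 0.10, 5: 0.55, 6: 0.35}, 0.45, 0.12),
    # 41 °C: first-peak amplitude 56% of control
    ("TNF", "post_41C"): _tnf(
        0.56, {1: 0.15, 2: 0.25, 3: 0.30, 4: 0.20, 5: 0.10}, 0.6, 0.2),
    ("TNF", "repeated_HS"): _tnf(
        0.88, {4: 0.15, 5: 0.50, 6: 0.35}, 0.55, 0.25),
    # IL1β control: 80% single translocation, remainder ≤4
    ("IL1", "control_37C"): _il1(
        1.0, {1: 0.80, 2: 0.12, 3: 0.05, 4: 0.03}, 0.30),
    ("IL1", "post_HS_0h"): _il1(
        0.35, {1: 0.80, 2: 0.15, 3: 0.05}, 1.6, 0.7, resp=0.70),
    ("IL1", "post_HS_1h"): _il1(
        0.75, {1: 0.80, 2: 0.13, 3: 0.05, 4: 0.02}, 0.6, 0.2),
    ("IL1", "post_HS_2h"): _il1(
        0.92, {1: 0.80, 2: 0.12, 3: 0.05, 4: 0.03}, 0.4, 0.15),
    ("IL1", "post_HS_4h"): _il1(
        1.0, {1: 0.80, 2: 0.12, 3: 0.05, 4: 0.03}, 0.32),
    ("IL1", "post_41C"): _il1(
        1.0, {1: 0.80, 2: 0.12, 3: 0.05, 4: 0.03}, 0.32),
    ("IL1", "repeated_HS"): _il1(
        0.97, {1: 0.78, 2: 0.14, 3: 0.05, 4: 0.03}, 0.40, 0.2),
}


@dataclass(frozen=True)
class SyntheticCondition:
    """One synthetic-imaging condition to generate."""

    cytokine: str
    regime: str
    n_cells: int = 50
    seed: int = 0
    frame_interval_min: float = 5.0
    duration_h: float = 10.0
    baseline: float = 10.0
    noise_sd: float = 5.0
    interpeak_mean_h: float = 100.0 / 60.0
    interpeak_sd_h: float = 0.25
    calibration: RegimeSpec | None = None

    def __post_init__(self) -> None:
        if self.cytokine not in ("TNF", "IL1"):
            raise ValueError(f"unknown cytokine {self.cytokine!r}")
        if self.regime not in REGIME_NAMES:
            raise ValueError(f"unknown regime {self.regime!r}")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")

    @property
    def spec(self) -> RegimeSpec:
        return self.calibration or REGIMES[(self.cytokine, self.regime)]

    @property
    def label(self) -> str:
        return f"{self.cytokine}_{self.regime}"


#: log-normal pulse shape parameter (dimensionless width)
_PULSE_S = 0.5
#: time scale of one pulse (h); the mode sits at _PULSE_TAU*exp(-s^2)
_PULSE_TAU = 0.60
_PULSE_OFFSET = _PULSE_TAU * np.exp(-_PULSE_S ** 2)  # start→peak lag


def _pulse(t: np.ndarray, peak_time: float, amplitude: float) -> np.ndarray:
    """A log-normal-in-time bump peaking at ``peak_time`` with height
    ``amplitude`` (asymmetric rise/decay, like imaged translocations)."""
    u = (t - (peak_time - _PULSE_OFFSET)) / _PULSE_TAU
    out = np.zeros_like(t)
    pos = u > 0
    lu = np.log(u[pos])
    out[pos] = amplitude * np.exp(
        -(lu + _PULSE_S ** 2) ** 2 / (2 * _PULSE_S ** 2))
    return out


def _calibrated_loc(mean: float, sd: float, lower: float = 0.0) -> float:
    """Location of a lower-truncated normal whose mean equals ``mean``.

    Raises :class:`CalibrationError` when truncation at ``lower`` warps
    the naive mean by more than 5% (the requested amplitude
    distribution cannot be realised by truncation alone).
    """
    if sd == 0:
        return mean

    def trunc_mean(loc: float) -> float:
        a = (lower - loc) / sd
        return float(stats.truncnorm.mean(a, np.inf, loc=loc, scale=sd))

    warp = abs(trunc_mean(mean) - mean)
    if warp > 0.05 * max(mean, 1e-12):
        raise CalibrationError(
            f"truncation at {lower} warps the mean by {warp:.3g} "
            f"(> 5% of {mean}); amplitude SD {sd} is infeasible")
    lo, hi = mean - 2 * warp - 1e-9, mean + 1e-9
    return float(optimize.brentq(
        lambda loc: trunc_mean(loc) - mean, lo - sd, hi))


def generate_trajectories(cond: SyntheticCondition
                          ) -> tuple[TrajectorySet, pd.DataFrame]:
    """Generate one condition; returns (trajectories, planted truth).

    Per cell: a translocation count drawn from the regime's
    distribution, a first-peak amplitude from a truncated normal whose
    post-truncation mean equals the calibrated mean, a response delay,
    and successive peaks damped by a per-cell geometric factor; rendered
    as log-normal bumps on a flat baseline plus Gaussian noise.
    """
    spec = cond.spec
    dt = cond.frame_interval_min / 60.0
    n_frames = int(round(cond.duration_h / dt)) + 1
    times = np.arange(n_frames) * dt

    counts = sorted(spec.peak_count_probs)
    probs = np.array([spec.peak_count_probs[k] for k in counts])
    lower = min(20.0, 0.2 * spec.amplitude_mean)
    loc = _calibrated_loc(spec.amplitude_mean, spec.amplitude_sd, lower)
    a_trunc = (lower - loc) / spec.amplitude_sd if spec.amplitude_sd else 0.0

    values = np.empty((cond.n_cells, n_frames))
    clean_values = np.empty((cond.n_cells, n_frames))
    truth_rows = []
    children = np.random.SeedSequence(cond.seed).spawn(cond.n_cells)
    for cell_id, child in enumerate(children):
        rng = np.random.default_rng(child)
        responder = rng.random() < spec.responder_fraction
        clean = np.full(n_frames, cond.baseline)
        peak_times: list[float] = []
        peak_amps: list[float] = []
        if responder:
            k = int(rng.choice(counts, p=probs))
            if spec.amplitude_sd:
                amp = float(stats.truncnorm.rvs(
                    a_trunc, np.inf, loc=loc, scale=spec.amplitude_sd,
                    random_state=rng))
            else:
                amp = spec.amplitude_mean
            delay = max(float(rng.normal(spec.delay_mean_h,
                                         spec.delay_sd_h)), 0.2)
            damping = float(rng.uniform(*spec.damping))
            tp = delay + _PULSE_OFFSET
            a = amp
            for _ in range(k):
                if tp > cond.duration_h - 0.3:
                    break
                peak_times.append(tp)
                peak_amps.append(a)
                clean += _pulse(times, tp, a)
                tp += max(float(rng.normal(cond.interpeak_mean_h,
                                           cond.interpeak_sd_h)), 0.6)
                a *= damping
        noisy = clean + rng.normal(0.0, cond.noise_sd, n_frames)
        values[cell_id] = noisy
        clean_values[cell_id] = clean
        truth_rows.append(dict(
            cell_id=cell_id, responder=bool(peak_times),
            n_peaks=len(peak_times),
            first_peak_time=peak_times[0] if peak_times else np.nan,
            first_peak_amplitude=peak_amps[0] if peak_amps else np.nan,
            peak_times=peak_times, peak_amplitudes=peak_amps))
    ts = TrajectorySet(times=times, values=values, condition=cond.label,
                       seed=cond.seed, extra={"clean": clean_values})
    return ts, pd.DataFrame(truth_rows)


def make_fixture_suite(seed: int, out_dir: str | Path,
                       n_cells: int = 50) -> dict[str, Path]:
    """Write one small fixture per (cytokine, regime) pair.

    ``n_cells`` defaults to 50, matching the per-condition cell counts
    of the imaging experiments.  Deterministic given ``seed``: the same
    seed produces byte-identical files.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    truth_all: dict[str, dict] = {}
    sub = np.random.SeedSequence(seed)
    offsets = {}
    for i, (cyt, regime) in enumerate(sorted(REGIMES)):
        offsets[(cyt, regime)] = seed + 1000 * (i + 1)
    frames = []
    for (cyt, regime), cseed in sorted(offsets.items()):
        cond = SyntheticCondition(cytokine=cyt, regime=regime,
                                  n_cells=n_cells, seed=cseed)
        ts, truth = generate_trajectories(cond)
        frames.append(ts.to_frame())
        truth_all[cond.label] = {
            str(r["cell_id"]): dict(
                responder=bool(r["responder"]), n_peaks=int(r["n_peaks"]),
                peak_times=[round(float(x), 6) for x in r["peak_times"]],
                peak_amplitudes=[round(float(x), 6)
                                 for x in r["peak_amplitudes"]])
            for _, r in truth.iterrows()}
    df = pd.concat(frames, ignore_index=True)
    csv_path = out_dir / "synthetic_trajectories.csv"
    df.to_csv(csv_path, index=False, float_format="%.6g")
    written["trajectories"] = csv_path
    truth_path = out_dir / "ground_truth.json"
    truth_path.write_text(json.dumps(
        dict(seed=seed, n_cells=n_cells, conditions=truth_all),
        indent=1, sort_keys=True))
    written["ground_truth"] = truth_path
    return written
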