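"""Heterogeneous single-cell ensembles (extrinsic noise only).

Cell-to-cell variability enters through log-normal initial totals of the
IKK, IKKK_TNF, IKKK_IL1, HSPc and HSF1 pools (the study's μ/σ pairs);
every other species starts from the nominal resting value.  Each sampled
cell is re-equilibrated at 37 °C before any protocol, so the ensemble is
a population of cells each at its own resting state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import species as sp
from .metrics import PeakConfig, detect_peaks
from .model import default_initial_state, steady_state
from .params import ParameterSet
from .protocols import Trajectory, TreatmentProtocol, run_single_cell

__all__ = ["EnsembleSpec", "TrajectorySet", "sample_initial_conditions",
           "simulate_ensemble", "first_peak_ratio"]

#: log-normal (μ, σ) of the randomized totals
DEFAULT_LOGNORMAL = {
    "IKK_TOTAL": (11.5, 0.15),
    "IKKKT_TOTAL": (11.5, 0.15),
    "IKKKI_TOTAL": (11.5, 0.15),
    "HSPC_TOTAL": (10.1, 0.15),
    "HSF1_TOTAL": (9.2, 0.15),
}


@dataclass(frozen=True)
class EnsembleSpec:
    """Size, seed and log-normal heterogeneity of an ensemble.

    ``correlate_ikkk=True`` draws one common factor for both IKKK pools
    instead of independent draws (the default).
    """

    n_cells: int = 1000
    seed: int = 0
    lognormal: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LOGNORMAL))
    correlate_ikkk: bool = False

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for k, (mu, sigma) in self.lognormal.items():
            if sigma < 0:
                raise ValueError(f"sigma for {k} must be >= 0")


@dataclass
class TrajectorySet:
    """Ensemble of single-cell nuclear NF-κB series on a common grid."""

    times: np.ndarray                  # (n_times,) h from cytokine onset
    values: np.ndarray                 # (n_cells, n_times) nuclear NF-κB
    condition: str
    protocol: TreatmentProtocol | None = None
    seed: int | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def mean_trajectory(self) -> np.ndarray:
        return self.values.mean(axis=0)

    def window(self, start: float = 0.0, end: float = 10.0):
        m = (self.times >= start - 1e-9) & (self.times <= end + 1e-9)
        return self.times[m], self.values[:, m]

    def to_frame(self) -> pd.DataFrame:
        """Long/tidy format: time_h, cell_id, value, condition."""
        n_cells, n_t = self.values.shape
        return pd.DataFrame({
            "time_h": np.tile(self.times, n_cells),
            "cell_id": np.repeat(np.arange(n_cells), n_t),
            "value": self.values.ravel(),
            "condition": self.condition,
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   condition: str | None = None) -> "TrajectorySet":
        if condition is not None:
            df = df[df["condition"] == condition]
        elif df["condition"].nunique() == 1:
            condition = str(df["condition"].iloc[0])
        else:
            raise ValueError("frame holds several conditions; pick one")
        wide = df.pivot_table(index="cell_id", columns="time_h",
                              values="value", sort=True)
        return cls(times=wide.columns.to_numpy(float),
                   values=wide.to_numpy(float), condition=condition)


def sample_totals(spec: EnsembleSpec, params: ParameterSet) -> pd.DataFrame:
    """Draw the randomized totals, one row per cell.

    Per-cell substreams are spawned from the root seed so draws are
    independent of execution order.
    """
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_cells)
    rows = []
    for child in children:
        rng = np.random.default_rng(child)
        row = dict(params.totals)
        if spec.correlate_ikkk:
            z = rng.standard_normal()
            draws = {}
            for key, (mu, sigma) in spec.lognormal.items():
                if key in ("IKKKT_TOTAL", "IKKKI_TOTAL"):
                    draws[key] = float(np.exp(mu + sigma * z))
                else:
                    draws[key] = float(np.exp(mu + sigma *
                                              rng.standard_normal()))
        else:
            draws = {key: float(np.exp(mu + sigma * rng.standard_normal()))
                     for key, (mu, sigma) in spec.lognormal.items()}
        row.update(draws)
        rows.append(row)
    return pd.DataFrame(rows)


def sample_initial_conditions(spec: EnsembleSpec, params: ParameterSet,
                              equilibrate: bool = True) -> list[np.ndarray]:
    """Sampled (and, by default, re-equilibrated) per-cell resting states."""
    totals = sample_totals(spec, params)
    states = []
    for _, row in totals.iterrows():
        cell_params = ParameterSet(values=dict(params.values),
                                   totals={k: float(row[k])
                                           for k in params.totals})
        y0 = default_initial_state(cell_params)
        states.append(steady_state(params, y0=y0) if equilibrate else y0)
    return states


def simulate_ensemble(spec: EnsembleSpec, params: ParameterSet,
                      protocol: TreatmentProtocol,
                      initial_states: list[np.ndarray] | None = None,
                      record: tuple[str, ...] = (),
                      failure_budget: int = 0) -> TrajectorySet:
    """Run ``protocol`` on every cell; returns the nuclear NF-κB set.

    ``initial_states`` (pre-equilibrated, e.g. from
    :func:`sample_initial_conditions`) lets several conditions share one
    expensive equilibration pass.  ``record`` adds per-cell series of
    further species to ``extra``.  Any per-cell solver failure beyond
    ``failure_budget`` aborts with the cell id.
    """
    if initial_states is None:
        initial_states = sample_initial_conditions(spec, params)
    if len(initial_states) != spec.n_cells:
        raise ValueError("initial state count does not match n_cells")
    series: list[np.ndarray] = []
    extras: dict[str, list[np.ndarray]] = {name: [] for name in record}
    times = None
    failures: list[int] = []
    for cell_id, y0 in enumerate(initial_states):
        try:
            traj = run_single_cell(y0, params, protocol)
        except RuntimeError as exc:
            failures.append(cell_id)
            if len(failures) > failure_budget:
                raise RuntimeError(
                    f"solver failed for cell {cell_id}: {exc}") from exc
            continue
        t, states = traj.window(0.0, protocol.cytokine.duration)
        if times is None:
            times = t
        series.append(states[:, sp.NFKB_N])
        for name in record:
            extras[name].append(states[:, sp.SPECIES_INDEX[name]])
    return TrajectorySet(
        times=times, values=np.vstack(series),
        condition=protocol.label or "unnamed", protocol=protocol,
        seed=spec.seed,
        extra={k: np.vstack(v) for k, v in extras.items()})


def mean_first_peak(ts: TrajectorySet,
                    config: PeakConfig | None = None) -> tuple[float, float]:
    """(time, amplitude) of the first peak of the ensemble-mean trajectory."""
    t, vals = ts.window(0.0, 10.0)
    mean = vals.mean(axis=0)
    peaks = detect_peaks(t, mean, config)
    if not peaks:
        raise ValueError(
            f"no detectable peak in the mean trajectory of "
            f"{ts.condition!r}")
    return peaks[0]


def first_peak_ratio(condition: TrajectorySet, control: TrajectorySet,
                     config: PeakConfig | None = None) -> float:
    """Ratio of mean-trajectory first-peak amplitudes (condition/control).

    By convention the ratio is computed on the first peak of the
    ensemble-mean trajectory; if the condition's mean shows no
    detectable peak the response is fully suppressed and the ratio is 0.
    """
    _, a_control = mean_first_peak(control, config)
    try:
        _, a_cond = mean_first_peak(condition, config)
    except ValueError:
        return 0.0
    return a_cond / a_control
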