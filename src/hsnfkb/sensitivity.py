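"""One-at-a-time temperature × parameter sensitivity screens.

Reproduces the model's sensitivity analysis design: each kinetic
parameter is scaled over an 8-fold multiplicative range (log2-spaced
factors in [1/8, 8], nominal at the centre) while the heat-shock
temperature runs over 37–43 °C in 1 °C steps; every grid cell records
the mean first-peak nuclear NF-κB amplitude of an ensemble stimulated
immediately after a 1 h heat shock, and each parameter's grid is
min–max normalized to [0, 1].  A companion routine characterizes the
temperature response itself (soluble kinase fractions, peak active
HSF1, HSPi accumulation, peak active IKK per cytokine).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import species as sp
from .metrics import PeakConfig, detect_peaks
from .model import CytokineInput
from .params import MODULE_GROUPS, PARAM_INDEX, ParameterSet
from .population import (EnsembleSpec, sample_initial_conditions,
                         simulate_ensemble)
from .protocols import TreatmentProtocol, run_single_cell

__all__ = ["SensitivityGrid", "default_factors", "scan_parameter",
           "temperature_interaction_index", "temperature_characterization"]

DEFAULT_TEMPERATURES = tuple(float(t) for t in range(37, 44))


def default_factors(n: int = 7, span: float = 8.0) -> np.ndarray:
    """Log2-spaced multipliers in [1/span, span], nominal at the centre."""
    if n < 3 or n % 2 == 0:
        raise ValueError("need an odd number of factors >= 3")
    return np.logspace(-np.log2(span), np.log2(span), n, base=2.0)


@dataclass
class SensitivityGrid:
    """Normalized sensitivity index grid for one parameter.

    ``values[i, j]`` is the mean first-peak nuclear NF-κB amplitude at
    ``factors[i]`` × nominal and ``temperatures[j]``; ``normalized`` is
    the same grid min–max scaled to [0, 1] (all-zero with
    ``degenerate=True`` when the parameter has no influence at all).
    """

    param: str
    group: str
    cytokine: str
    factors: np.ndarray
    temperatures: np.ndarray
    values: np.ndarray
    normalized: np.ndarray
    degenerate: bool
    nominal_index: int
    failed_cells: list[tuple[float, float]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, f in enumerate(self.factors):
            for j, T in enumerate(self.temperatures):
                rows.append(dict(param=self.param, cytokine=self.cytokine,
                                 factor=f, temperature=T,
                                 value=self.values[i, j],
                                 normalized=self.normalized[i, j]))
        return pd.DataFrame(rows)


def _mean_first_peak_amp(ts, config: PeakConfig | None = None) -> float:
    t, vals = ts.window(0.0, 10.0)
    peaks = detect_peaks(t, vals.mean(axis=0), config)
    return peaks[0][1] if peaks else 0.0


def scan_parameter(param: str, params: ParameterSet, cytokine: str,
                   spec: EnsembleSpec,
                   factors: np.ndarray | None = None,
                   temperatures=DEFAULT_TEMPERATURES,
                   initial_states: dict | None = None,
                   config: PeakConfig | None = None) -> SensitivityGrid:
    """Scan one parameter over (factor, temperature).

    The protocol at every grid cell is 1 h heat shock at T followed by
    immediate 10 h cytokine stimulation (T = 37 °C means no heat
    shock).  ``initial_states`` may carry a cache mapping each scanned
    parameter factor to pre-equilibrated ensemble states; otherwise
    each factor re-equilibrates its own ensemble (the resting state
    depends on the perturbed parameter).
    """
    if param not in PARAM_INDEX:
        raise KeyError(f"unknown parameter {param!r}")
    if factors is None:
        factors = default_factors()
    factors = np.asarray(factors, float)
    if np.any(factors <= 0):
        raise ValueError("factors must be positive")
    temperatures = np.asarray(temperatures, float)
    values = np.zeros((len(factors), len(temperatures)))
    failed: list[tuple[float, float]] = []
    for i, f in enumerate(factors):
        pset = params.scaled(param, float(f))
        if initial_states is not None and f in initial_states:
            states = initial_states[f]
        else:
            states = sample_initial_conditions(spec, pset)
            if initial_states is not None:
                initial_states[f] = states
        for j, T in enumerate(temperatures):
            protocol = TreatmentProtocol(
                hs_temperature=None if T <= 37.0 else float(T),
                recovery_time=0.0, cytokine=CytokineInput(cytokine),
                label=f"{param}x{f:g}_{T:g}C_{cytokine}")
            try:
                ts = simulate_ensemble(spec, pset, protocol,
                                       initial_states=states)
            except RuntimeError:
                failed.append((float(f), float(T)))
                values[i, j] = np.nan
                continue
            values[i, j] = _mean_first_peak_amp(ts, config)
    finite = values[np.isfinite(values)]
    lo, hi = (float(finite.min()), float(finite.max())) if finite.size \
        else (0.0, 0.0)
    # tolerance above the solver's per-cell noise floor, so a parameter
    # with no influence normalizes to the flagged all-zero grid
    degenerate = hi - lo <= 1e-6 * max(abs(hi), 1.0)
    if degenerate:
        normalized = np.zeros_like(values)
    else:
        normalized = (values - lo) / (hi - lo)
    nominal_index = int(np.argmin(np.abs(np.log(factors))))
    return SensitivityGrid(
        param=param, group=MODULE_GROUPS[param], cytokine=cytokine,
        factors=factors, temperatures=temperatures, values=values,
        normalized=normalized, degenerate=degenerate,
        nominal_index=nominal_index, failed_cells=failed)


def temperature_interaction_index(grid: SensitivityGrid) -> float:
    """How strongly the parameter reshapes the temperature response.

    Each factor row is rescaled to its own 37 °C value, giving that
    row's relative temperature-attenuation profile; the index is the
    mean over temperatures of the spread (max − min) of those profiles
    across factors.  A parameter that only rescales the response
    amplitude leaves the profiles identical (index 0); a parameter that
    interacts with the temperature axis separates them.
    """
    vals = grid.values
    ref = vals[:, 0:1]
    ok = np.isfinite(vals).all(axis=1) & (np.abs(ref[:, 0]) > 1e-12)
    profiles = vals[ok] / ref[ok]
    if profiles.shape[0] < 2:
        return 0.0
    spread = profiles.max(axis=0) - profiles.min(axis=0)
    return float(spread[1:].mean())


def temperature_characterization(params: ParameterSet,
                                 spec: EnsembleSpec,
                                 temperatures=DEFAULT_TEMPERATURES,
                                 recovery_hours: float = 6.0
                                 ) -> pd.DataFrame:
    """Per-temperature readouts of the heat-shock response machinery.

    For each temperature: the soluble IKK and IKKK fractions at the end
    of a 1 h heat shock, the peak active-HSF1 (trimer) level, the HSPi
    accumulation over the recovery window, and the peak active IKK
    under immediate TNFα / IL1β stimulation.  Ensemble means over
    ``spec`` (n=1 with σ=0 reduces to the nominal cell).
    """
    sigma0 = all(s == 0 for _, s in spec.lognormal.values())
    if sigma0 or spec.n_cells == 1:
        from .model import steady_state
        states = [steady_state(params)]
    else:
        states = sample_initial_conditions(spec, params)
    rows = []
    for T in temperatures:
        acc = {k: [] for k in ("soluble_ikk", "soluble_ikkk_tnf",
                               "soluble_ikkk_il1", "peak_hsf1_active",
                               "peak_hspi_total", "peak_ikka_tnf",
                               "peak_ikka_il1")}
        for y0 in states:
            protocol = TreatmentProtocol(
                hs_temperature=None if T <= 37.0 else float(T),
                recovery_time=recovery_hours,
                cytokine=CytokineInput("none", duration=1.0))
            traj = run_single_cell(y0, params, protocol)
            S = traj.states
            if T <= 37.0:
                i_end = 0
            else:
                end = traj.phase_boundaries["heat_shock"][1]
                i_end = int(np.argmin(np.abs(traj.times - end)))
            sol_ikk = S[:, list(sp.SOLUBLE_IKK)].sum(1)
            tot_ikk = sol_ikk + S[:, list(sp.INSOLUBLE_IKK)].sum(1)
            kt_sol = S[:, [sp.IKKKT_N, sp.IKKKT_A]].sum(1)
            kt_tot = kt_sol + S[:, sp.IKKKT_D] + S[:, sp.HSPI_IKKKT_D]
            ki_sol = S[:, [sp.IKKKI_N, sp.IKKKI_A]].sum(1)
            ki_tot = ki_sol + S[:, sp.IKKKI_D] + S[:, sp.HSPC_IKKKI_D]
            acc["soluble_ikk"].append(sol_ikk[i_end] / tot_ikk[i_end])
            acc["soluble_ikkk_tnf"].append(kt_sol[i_end] / kt_tot[i_end])
            acc["soluble_ikkk_il1"].append(ki_sol[i_end] / ki_tot[i_end])
            acc["peak_hsf1_active"].append(S[:, sp.HSF1_3].max())
            hspi_tot = (S[:, sp.HSPI] + S[:, sp.HSPI_IKKKT_D] +
                        S[:, sp.HSF1_HSPI])
            acc["peak_hspi_total"].append(hspi_tot.max())
            for kind, key in (("TNF", "peak_ikka_tnf"),
                              ("IL1", "peak_ikka_il1")):
                pstim = TreatmentProtocol(
                    hs_temperature=None if T <= 37.0 else float(T),
                    recovery_time=0.0, cytokine=CytokineInput(kind))
                tr = run_single_cell(y0, params, pstim)
                _, W = tr.window(0.0, 10.0)
                acc[key].append(W[:, sp.IKK_A].max())
        rows.append(dict(temperature=float(T),
                         **{k: float(np.mean(v)) for k, v in acc.items()}))
    return pd.DataFrame(rows)
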