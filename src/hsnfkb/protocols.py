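"""Heat-shock / cytokine treatment protocols and single-cell simulation.

A protocol is a sequence of constant-condition phases: an optional 1 h
heat shock (38–43 °C), a recovery interval at 37 °C, optionally a second
identical heat shock (thermotolerance protocols), and a 10 h cytokine
observation window at 37 °C.  The solver restarts at every phase
boundary so the discontinuous inputs never fall inside a solver step.
Reported time is hours from cytokine onset (pre-stimulation phases carry
negative times and are retained, flagged by the phase metadata).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import species as sp
from .model import (CytokineInput, EQUILIBRATION_HOURS, OUTPUT_DT, T_BASE,
                    integrate_phase, steady_state)
from .params import ParameterSet

__all__ = ["TemperatureProgram", "TreatmentProtocol", "Trajectory",
           "run_single_cell", "apply_hsf1_knockdown",
           "thermotolerance_protocol"]


@dataclass(frozen=True)
class TemperatureProgram:
    """Piecewise-constant temperature program.

    ``segments`` is an ordered list of ``(duration_h, temperature_C)``;
    switching is instantaneous at segment boundaries.
    """

    segments: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for dur, temp in self.segments:
            if dur <= 0:
                raise ValueError("segment durations must be > 0")
            if not (37.0 <= temp <= 43.0):
                raise ValueError(
                    f"temperature {temp} °C outside [37, 43] °C")

    @property
    def total_hours(self) -> float:
        return sum(d for d, _ in self.segments)


@dataclass(frozen=True)
class TreatmentProtocol:
    """One of the study's treatment protocols.

    ``hs_temperature=None`` encodes the 37 °C control (no heat shock).
    If ``repeat_interval`` is set, a second identical heat shock is
    applied ``repeat_interval`` hours after the start of the first
    recovery, and the cytokine is applied immediately after the second
    exposure (``recovery_time`` is ignored for repeats).
    ``hsf1_kd_fraction=0.95`` reproduces the siRNA HSF1 knock-down.
    """

    hs_temperature: float | None = None
    hs_duration: float = 1.0
    recovery_time: float = 0.0
    cytokine: CytokineInput = field(
        default_factory=lambda: CytokineInput("none"))
    repeat_interval: float | None = None
    hsf1_kd_fraction: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.hs_temperature is not None:
            if not (38.0 <= self.hs_temperature <= 43.0):
                raise ValueError(
                    f"heat-shock temperature {self.hs_temperature} °C "
                    "outside [38, 43] °C")
            if self.hs_duration <= 0:
                raise ValueError("hs_duration must be > 0")
        if not (0.0 <= self.recovery_time <= 8.0):
            raise ValueError("recovery_time must be within [0, 8] h")
        if self.repeat_interval is not None:
            if self.hs_temperature is None:
                raise ValueError("repeat protocols need a heat shock")
            if not (2.0 <= self.repeat_interval <= 8.0):
                raise ValueError("repeat_interval must be in [2, 8] h")
        if not (0.0 <= self.hsf1_kd_fraction <= 1.0):
            raise ValueError("hsf1_kd_fraction must be in [0, 1]")

    def temperature_program(self) -> TemperatureProgram:
        """The temperature program covering the whole protocol."""
        segs: list[tuple[float, float]] = []
        obs = max(self.cytokine.duration, 1e-6)
        if self.hs_temperature is None:
            segs.append((obs, T_BASE))
        elif self.repeat_interval is not None:
            segs.append((self.hs_duration, self.hs_temperature))
            segs.append((self.repeat_interval, T_BASE))
            segs.append((self.hs_duration, self.hs_temperature))
            segs.append((obs, T_BASE))
        else:
            segs.append((self.hs_duration, self.hs_temperature))
            if self.recovery_time > 0:
                segs.append((self.recovery_time, T_BASE))
            segs.append((obs, T_BASE))
        return TemperatureProgram(tuple(segs))


def thermotolerance_protocol(hs_temperature: float, interval: float,
                             cytokine: CytokineInput | str = "none",
                             ) -> TreatmentProtocol:
    """Repeated heat-shock protocol: two 1 h exposures separated by
    ``interval`` hours at 37 °C, cytokine immediately after the second."""
    if not (2.0 <= interval <= 8.0):
        raise ValueError("interval must be within [2, 8] h")
    if isinstance(cytokine, str):
        cytokine = CytokineInput(cytokine)
    return TreatmentProtocol(
        hs_temperature=hs_temperature, hs_duration=1.0,
        repeat_interval=interval, cytokine=cytokine,
        label=f"2x1h_{hs_temperature:g}C_{interval:g}h_{cytokine.kind}")


@dataclass
class Trajectory:
    """Single-cell trajectory over all protocol phases.

    ``times`` are hours relative to cytokine onset (uniform grid);
    ``states`` has shape (n_times, 31).  ``phase_boundaries`` maps phase
    names to their (start, end) in the same clock.
    """

    times: np.ndarray
    states: np.ndarray
    protocol: TreatmentProtocol
    phase_boundaries: dict[str, tuple[float, float]]

    def species(self, name: str) -> np.ndarray:
        return self.states[:, sp.SPECIES_INDEX[name]]

    @property
    def nuclear_nfkb(self) -> np.ndarray:
        return self.states[:, sp.NFKB_N]

    def window(self, start: float = 0.0, end: float = 10.0):
        """(times, states) restricted to [start, end] h."""
        m = (self.times >= start - 1e-9) & (self.times <= end + 1e-9)
        return self.times[m], self.states[m]

    @property
    def stimulation_window(self):
        return self.window(0.0, self.protocol.cytokine.duration)


def apply_hsf1_knockdown(initial: np.ndarray, fraction: float,
                         params: ParameterSet | None = None) -> np.ndarray:
    """Scale every HSF1-containing pool by ``1 - fraction``.

    ``fraction=0.95`` reproduces the siRNA knock-down.  If ``params`` is
    given the perturbed state is re-equilibrated at 37 °C before use, so
    each knocked-down cell starts from its own resting state.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("fraction must be within [0, 1]")
    y = np.asarray(initial, float).copy()
    for idx in sp.HSF1_GROUP:
        y[idx] *= (1.0 - fraction)
    if fraction == 0.0:
        return y
    if params is not None:
        y = steady_state(params, y0=y)
    return y


def _phase_grid(duration: float, dt: float) -> np.ndarray:
    n = max(int(round(duration / dt)), 1)
    return np.linspace(0.0, duration, n + 1)


def run_single_cell(initial: np.ndarray, params: ParameterSet,
                    protocol: TreatmentProtocol,
                    dt: float = OUTPUT_DT) -> Trajectory:
    """Simulate one cell through all phases of ``protocol``.

    ``initial`` must be a resting state (e.g. from :func:`steady_state`
    or a sampled, equilibrated heterogeneous cell).  Returns the
    concatenated trajectory on a uniform grid with time 0 at cytokine
    onset.
    """
    y = np.asarray(initial, float)
    if protocol.hsf1_kd_fraction > 0:
        y = apply_hsf1_knockdown(y, protocol.hsf1_kd_fraction, params)

    # Build (name, duration, temperature, cytokine) phases.
    phases: list[tuple[str, float, float, CytokineInput]] = []
    none = CytokineInput("none")
    if protocol.hs_temperature is not None:
        phases.append(("heat_shock", protocol.hs_duration,
                       protocol.hs_temperature, none))
        if protocol.repeat_interval is not None:
            phases.append(("interval", protocol.repeat_interval,
                           T_BASE, none))
            phases.append(("heat_shock_2", protocol.hs_duration,
                           protocol.hs_temperature, none))
        elif protocol.recovery_time > 0:
            phases.append(("recovery", protocol.recovery_time,
                           T_BASE, none))
    stim = protocol.cytokine
    obs = max(stim.duration, dt)
    phases.append(("stimulation", obs, T_BASE, stim))

    onset = sum(d for _, d, _, _ in phases[:-1])
    t_all: list[np.ndarray] = []
    y_all: list[np.ndarray] = []
    boundaries: dict[str, tuple[float, float]] = {}
    clock = 0.0
    for i, (name, dur, temp, cyt) in enumerate(phases):
        grid = _phase_grid(dur, dt)
        t, Y = integrate_phase(y, params, dur, temp, cyt, t_eval=grid)
        y = Y[-1]
        boundaries[name] = (clock - onset, clock + dur - onset)
        if i > 0:  # drop the duplicated phase-boundary point
            t, Y = t[1:], Y[1:]
        t_all.append(t + clock - onset)
        y_all.append(Y)
        clock += dur
    return Trajectory(times=np.concatenate(t_all),
                      states=np.vstack(y_all), protocol=protocol,
                      phase_boundaries=boundaries)
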