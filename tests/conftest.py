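"""Shared fixtures: parameter set, resting state, cached ensembles.

Ensemble simulations are the expensive part of the suite, so one
session-scoped study object owns the equilibrated initial states and
caches every simulated condition; tests request conditions by protocol.
"""

from __future__ import annotations

import numpy as np
import pytest

from hsnfkb import default_parameters, steady_state
from hsnfkb.model import CytokineInput
from hsnfkb.population import (EnsembleSpec, sample_initial_conditions,
                               simulate_ensemble)
from hsnfkb.protocols import TreatmentProtocol

ENSEMBLE_N = 200
ENSEMBLE_SEED = 7


@pytest.fixture(scope="session")
def params():
    return default_parameters()


@pytest.fixture(scope="session")
def resting_state(params):
    return steady_state(params)


class EnsembleStudy:
    """Caches equilibrated initial states and simulated conditions."""

    def __init__(self, params, n_cells=ENSEMBLE_N, seed=ENSEMBLE_SEED):
        self.params = params
        self.spec = EnsembleSpec(n_cells=n_cells, seed=seed)
        self._states = None
        self._cache = {}

    @property
    def states(self):
        if self._states is None:
            self._states = sample_initial_conditions(self.spec,
                                                     self.params)
        return self._states

    def condition(self, label, cytokine="TNF", hs_temperature=None,
                  recovery_time=0.0, repeat_interval=None,
                  hsf1_kd_fraction=0.0):
        if label not in self._cache:
            protocol = TreatmentProtocol(
                hs_temperature=hs_temperature,
                recovery_time=recovery_time,
                cytokine=CytokineInput(cytokine),
                repeat_interval=repeat_interval,
                hsf1_kd_fraction=hsf1_kd_fraction, label=label)
            self._cache[label] = simulate_ensemble(
                self.spec, self.params, protocol,
                initial_states=self.states)
        return self._cache[label]


@pytest.fixture(scope="session")
def study(params):
    return EnsembleStudy(params)
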