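"""Core ODE model: steady state, conservation, temperature response."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hsnfkb import derivatives, hill_transcription, steady_state
from hsnfkb import species as sp
from hsnfkb.model import (CytokineInput, T_BASE, TemperatureError,
                          denaturation_rate, integrate_phase)
from hsnfkb.protocols import TreatmentProtocol, run_single_cell


def test_resting_state_is_a_fixed_point(params, resting_state):
    d = derivatives(resting_state, params)
    scaled = np.abs(d) / np.maximum(resting_state, 1.0)
    assert scaled.max() < 1e-6


def test_steady_state_insensitive_to_initialization(params, resting_state):
    """Two starts with the same conserved totals but scrambled pool
    partitions converge to the same resting state (within 0.1%)."""
    y0 = resting_state.copy()
    # redistribute within conserved pools and inflate turnover species
    y0[sp.IKK_I] += 0.5 * y0[sp.IKK_N]
    y0[sp.IKK_N] *= 0.5
    half = 0.5 * y0[sp.IKBA_NFKB_C]
    y0[sp.IKBA_NFKB_C] -= half
    y0[sp.IKBA_C] += half
    y0[sp.NFKB_C] += half
    y0[sp.M_IKBA] *= 3.0
    y0[sp.M_A20] *= 3.0
    y0[sp.A20] *= 0.2
    other = steady_state(params, y0=y0)
    np.testing.assert_allclose(other, resting_state, rtol=1e-3, atol=0.5)


def test_no_insoluble_ikk_at_rest(resting_state):
    soluble = resting_state[list(sp.SOLUBLE_IKK)].sum()
    insoluble = resting_state[list(sp.INSOLUBLE_IKK)].sum()
    assert insoluble / (soluble + insoluble) < 1e-6


def test_derivatives_input_validation(params, resting_state):
    bad = resting_state.copy()
    bad[0] = -1.0
    with pytest.raises(ValueError, match="negative"):
        derivatives(bad, params)
    with pytest.raises(TemperatureError):
        derivatives(resting_state, params, temperature=45.0)
    with pytest.raises(ValueError, match="cytokine"):
        CytokineInput("IL6")


class TestDenaturationRate:
    def test_zero_at_37(self, params):
        assert denaturation_rate(37.0, params) == pytest.approx(0.0,
                                                                abs=1e-12)

    def test_strictly_increasing(self, params):
        temps = [37.0, 38.0, 41.0, 43.0]
        rates = [denaturation_rate(t, params) for t in temps]
        assert rates[3] > rates[2] > rates[1] >= rates[0]

    def test_linear_in_prefactor(self, params):
        doubled = params.scaled("k_den_max", 2.0)
        for t in (38.0, 40.5, 43.0):
            assert denaturation_rate(t, doubled) == pytest.approx(
                2.0 * denaturation_rate(t, params))

    def test_out_of_range_rejected(self, params):
        for t in (36.9, 43.1):
            with pytest.raises(TemperatureError):
                denaturation_rate(t, params)


class TestHillTranscription:
    def test_basal_at_zero(self, params):
        assert hill_transcription(0.0, params) == pytest.approx(
            params["k_mrna_basal"])

    def test_half_saturation(self, params):
        expected = params["k_mrna_basal"] + params["k_mrna_max"] / 2
        assert hill_transcription(params["K_hill"], params) == \
            pytest.approx(expected)

    def test_saturation(self, params):
        top = params["k_mrna_basal"] + params["k_mrna_max"]
        assert hill_transcription(5 * params["K_hill"], params) > \
            0.99 * top

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    def test_matches_closed_form(self, x):
        params = default_params_cache()
        basal, vmax, k = (params["k_mrna_basal"], params["k_mrna_max"],
                          params["K_hill"])
        expected = basal + vmax * x ** 3 / (k ** 3 + x ** 3)
        assert hill_transcription(x, params) == pytest.approx(expected,
                                                              rel=1e-12)


_cache = {}


def default_params_cache():
    if "p" not in _cache:
        from hsnfkb import default_parameters
        _cache["p"] = default_parameters()
    return _cache["p"]


@pytest.fixture(scope="module")
def hs_trajectory(params, resting_state):
    """1 h 43 °C heat shock + TNFα, all phases retained."""
    protocol = TreatmentProtocol(hs_temperature=43.0, recovery_time=2.0,
                                 cytokine=CytokineInput("TNF"))
    return run_single_cell(resting_state, params, protocol)


def test_non_negative_along_trajectory(hs_trajectory):
    assert (hs_trajectory.states >= 0).all()


def test_conservation_laws_along_trajectory(hs_trajectory):
    S = hs_trajectory.states
    for group, weights in [
            (sp.NFKB_GROUP, None), (sp.IKK_GROUP, None),
            (sp.IKKKT_GROUP, None), (sp.IKKKI_GROUP, None),
            (sp.HSPC_GROUP, None), (sp.HSF1_GROUP, sp.HSF1_WEIGHTS)]:
        w = np.ones(len(group)) if weights is None else np.array(weights)
        totals = S[:, list(group)] @ w
        # 10x the solver's relative tolerance, per the conservation
        # contract over the full multi-phase run
        np.testing.assert_allclose(totals, totals[0], rtol=1e-5)


def test_nfkb_derivative_sum_is_zero(params, resting_state):
    rng = np.random.default_rng(0)
    for _ in range(5):
        y = resting_state * rng.uniform(0.5, 1.5, resting_state.shape)
        d = derivatives(y, params, temperature=41.0,
                        cytokine=CytokineInput("TNF"))
        total_flux = d[list(sp.NFKB_GROUP)].sum()
        scale = np.abs(d[list(sp.NFKB_GROUP)]).max() + 1.0
        assert abs(total_flux) < 1e-8 * scale


def test_zero_denaturation_makes_hs_equal_control(params, resting_state):
    """Temperature enters only through kinase denaturation: with the
    denaturation prefactor at 0 a 43 °C protocol matches the 37 °C
    control."""
    no_den = params.with_values(k_den_max=0.0)
    rest = steady_state(no_den)
    control = run_single_cell(rest, no_den, TreatmentProtocol(
        cytokine=CytokineInput("TNF")))
    heated = run_single_cell(rest, no_den, TreatmentProtocol(
        hs_temperature=43.0, cytokine=CytokineInput("TNF")))
    t_c, v_c = control.window(0, 10)
    t_h, v_h = heated.window(0, 10)
    np.testing.assert_allclose(v_h[:, sp.NFKB_N], v_c[:, sp.NFKB_N],
                               rtol=1e-4, atol=1.0)


def test_soluble_ikk_monotone_in_hs_temperature(params, resting_state):
    fractions = []
    for temp in (38.0, 40.0, 41.0, 42.0, 43.0):
        t, Y = integrate_phase(resting_state, params, 1.0, temp)
        y = Y[-1]
        soluble = y[list(sp.SOLUBLE_IKK)].sum()
        total = soluble + y[list(sp.INSOLUBLE_IKK)].sum()
        fractions.append(soluble / total)
    assert all(a >= b for a, b in zip(fractions, fractions[1:]))
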