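"""Right-hand side and steady state of the combined HSR / NF-κB model.

The model couples a heat-shock-response submodel (HSF1 released from its
inhibitory HSPi complex, trimerizing and driving HSPi transcription with
Hill coefficient n = 3) to a two-cytokine NF-κB signalling submodel
(receptor → IKKK → IKK → IκBα/NF-κB with IκBα and A20 negative feedback).
Temperature acts on one place only: a nonlinear, sigmoidal denaturation
rate of the IKK and IKKK kinases.  Denatured kinases titrate free
chaperones (which both protects remaining kinases less and releases HSF1),
and are repaired in a stimulus-specific way: IKKK_TNF by the inducible
chaperone HSPi, IKK and IKKK_IL1 by the constitutive chaperone HSPc.
Chaperones additionally accelerate the active→inactive→neutral cycling of
IKK.

All species are molecule counts per cell (receptor activities are
occupancies in [0, 1]); time is in hours; rates in 1/h.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from . import species as sp
from .params import PARAM_INDEX, ParameterSet

__all__ = [
    "TemperatureError", "CytokineInput", "denaturation_fraction",
    "denaturation_rate", "hill_transcription", "derivatives",
    "default_initial_state", "steady_state", "integrate_phase",
    "SteadyStateError",
]

T_BASE = 37.0
T_MAX = 43.0

#: default solver settings (stiff, variable-order BDF family via LSODA)
RTOL = 1e-6
ATOL = 1e-2  # molecules
OUTPUT_DT = 0.05  # h


class TemperatureError(ValueError):
    """Temperature outside the calibrated 37–43 °C range."""


class SteadyStateError(RuntimeError):
    """Pre-equilibration failed to reach the resting attractor."""

    def __init__(self, residual: float, tol: float) -> None:
        self.residual = residual
        super().__init__(
            f"steady state not reached: residual {residual:.3e} "
            f"exceeds tolerance {tol:.3e} (1/h)")


@dataclass(frozen=True)
class CytokineInput:
    """Saturating cytokine stimulation (the 10 ng/ml on/off input).

    ``kind`` is ``"TNF"``, ``"IL1"`` or ``"none"``; ``onset``/``duration``
    are in hours relative to the start of the phase the input is applied
    to.  The saturating dose is represented as a receptor-activating
    square input.
    """

    kind: str = "none"
    onset: float = 0.0
    duration: float = 10.0

    def __post_init__(self) -> None:
        if self.kind not in ("TNF", "IL1", "none"):
            raise ValueError(f"unknown cytokine {self.kind!r}")
        if self.onset < 0:
            raise ValueError("cytokine onset must be >= 0")
        if self.duration < 0:
            raise ValueError("cytokine duration must be >= 0")

    @property
    def flags(self) -> tuple[float, float]:
        """(u_tnf, u_il1) input levels while the cytokine is applied."""
        return (1.0 if self.kind == "TNF" else 0.0,
                1.0 if self.kind == "IL1" else 0.0)


def _check_temperature(temperature: float) -> None:
    if not (T_BASE <= temperature <= T_MAX):
        raise TemperatureError(
            f"temperature {temperature} °C outside the calibrated "
            f"[{T_BASE}, {T_MAX}] °C range")


def denaturation_fraction(temperature: float, t_mid: float,
                          w_den: float) -> float:
    """Normalized sigmoidal temperature response in [0, 1].

    A logistic in temperature, shifted so the fraction is exactly 0 at
    37 °C and rescaled so it is exactly 1 at 43 °C.  Strictly increasing
    on [37, 43].
    """
    s = 1.0 / (1.0 + np.exp(-(temperature - t_mid) / w_den))
    s37 = 1.0 / (1.0 + np.exp(-(T_BASE - t_mid) / w_den))
    s43 = 1.0 / (1.0 + np.exp(-(T_MAX - t_mid) / w_den))
    return (s - s37) / (s43 - s37)


def denaturation_rate(temperature: float, params: ParameterSet) -> float:
    """First-order kinase denaturation rate constant (1/h) at ``temperature``.

    Zero at 37 °C, non-decreasing in temperature, equal to ``k_den_max``
    at 43 °C, linear in the prefactor ``k_den_max``.
    """
    _check_temperature(temperature)
    return params["k_den_max"] * denaturation_fraction(
        temperature, params["T_mid"], params["w_den"])


def hill_transcription(hsf1_trimer: float, params: ParameterSet) -> float:
    """HSPi mRNA synthesis flux (molecules/h) as a function of the trimer.

    ``basal + vmax * x**3 / (K**3 + x**3)`` with the Hill coefficient
    structurally fixed at 3 (HSF1 trimerization).
    """
    if hsf1_trimer < 0:
        raise ValueError("HSF1 trimer count must be >= 0")
    x3 = float(hsf1_trimer) ** 3
    k3 = params["K_hill"] ** 3
    return params["k_mrna_basal"] + params["k_mrna_max"] * x3 / (k3 + x3)


@njit(cache=True)
def _rhs(t, y, p, den_rate, u_tnf, u_il1):  # pragma: no cover - compiled
    d = np.zeros(31)

    hsf1 = y[0]; hsf1_hspi = y[1]; hsf1_3 = y[2]
    m_hspi = y[3]; hspi = y[4]; hspc = y[5]
    c_hspi_kt = y[6]; c_hspc_ki = y[7]; c_hspc_ikk = y[8]
    r_tnf = y[9]; r_il1 = y[10]
    ktn = y[11]; kta = y[12]; ktd = y[13]
    kin_ = y[14]; kia = y[15]; kid = y[16]
    ikkn = y[17]; ikka = y[18]; ikki = y[19]; ikkd = y[20]
    nfkb_c = y[21]; nfkb_n = y[22]
    ikba_c = y[23]; ikba_n = y[24]
    cplx_c = y[25]; cplx_n = y[26]; pcplx = y[27]
    m_ikba = y[28]; m_a20 = y[29]; a20 = y[30]

    # ---- HSR ----
    v_on = p[0] * hsf1 * hspi
    v_off = p[1] * hsf1_hspi
    v_tri = p[2] * hsf1 * hsf1 * hsf1
    v_detri = (p[3] + p[4] * hspi) * hsf1_3
    x3 = hsf1_3 * hsf1_3 * hsf1_3
    k3 = p[7] * p[7] * p[7]
    v_txn_hspi = p[5] + p[6] * x3 / (k3 + x3)
    v_mdeg = p[8] * m_hspi
    v_tl = p[9] * m_hspi
    v_hspideg = p[10] * hspi

    # ---- temperature-dependent denaturation, chaperone protected ----
    # Protection scales with the total chaperone pools (free plus
    # engaged); induced HSPi therefore carries thermotolerance.
    hsp_free = hspi + hspc
    hsp_tot = (hspi + c_hspi_kt + hsf1_hspi) + \
        (hspc + c_hspc_ki + c_hspc_ikk)
    f_prot = p[20] / (p[20] + hsp_tot)        # K_protect
    kd = den_rate * f_prot
    vd_ktn = kd * ktn
    vd_kta = kd * kta
    vd_kin = kd * kin_
    vd_kia = kd * kia
    vd_ikkn = kd * ikkn
    vd_ikka = kd * ikka
    vd_ikki = kd * ikki

    # ---- chaperone-mediated repair ----
    vb_t = p[11] * hspi * ktd
    vr_t = p[12] * c_hspi_kt
    vb_i = p[13] * hspc * kid
    vr_i = p[14] * c_hspc_ki
    vb_k = p[15] * hspc * ikkd
    vr_k = p[16] * c_hspc_ikk

    # ---- receptors ----
    dr_tnf = p[21] * u_tnf * (1.0 - r_tnf) - p[22] * r_tnf
    dr_il1 = p[23] * u_il1 * (1.0 - r_il1) - p[24] * r_il1

    # ---- IKKK cycling with A20 inhibition ----
    f_a20_t = p[29] / (p[29] + a20)
    f_a20_i = p[30] / (p[30] + a20)
    va_kt = p[25] * r_tnf * f_a20_t * ktn
    vi_kt = p[26] * kta
    va_ki = p[27] * r_il1 * f_a20_i * kin_
    vi_ki = p[28] * kia

    # ---- IKK cycling, chaperone-assisted; A20 acts on both the IKKK
    # and the IKK activation step of its branch ----
    va_ikk = (p[31] * kta * f_a20_t + p[32] * kia * f_a20_i) * ikkn
    vi_ikk = (p[33] + p[34] * hsp_free) * ikka
    vn_ikk = (p[35] + p[36] * hsp_free) * ikki

    # ---- IκBα / NF-κB core ----
    vph_f = p[37] * ikka * ikba_c
    vph_c = p[38] * ikka * cplx_c
    vpd = p[39] * pcplx
    vas_c = p[40] * ikba_c * nfkb_c
    vas_n = p[41] * ikba_n * nfkb_n
    vdis_c = p[42] * cplx_c
    vdis_n = p[43] * cplx_n
    vimp_n = p[44] * nfkb_c
    vexp_n = p[45] * nfkb_n
    vimp_i = p[46] * ikba_c
    vexp_i = p[47] * ikba_n
    vexp_c = p[48] * cplx_n
    v_txn_ikba = p[49] + p[50] * nfkb_n
    v_mdeg_ikba = p[51] * m_ikba
    v_tl_ikba = p[52] * m_ikba
    vdeg_if = p[53] * ikba_c
    vdeg_ifn = p[53] * ikba_n
    vdeg_ic = p[54] * cplx_c
    vdeg_icn = p[54] * cplx_n
    v_txn_a20 = p[55] + p[56] * nfkb_n
    v_mdeg_a20 = p[57] * m_a20
    v_tl_a20 = p[58] * m_a20
    vdeg_a20 = p[59] * a20

    # ---- assemble ----
    d[0] = -v_on + v_off - 3.0 * v_tri + 3.0 * v_detri
    d[1] = v_on - v_off
    d[2] = v_tri - v_detri
    d[3] = v_txn_hspi - v_mdeg
    d[4] = -v_on + v_off + v_tl - v_hspideg - vb_t + vr_t
    d[5] = -vb_i + vr_i - vb_k + vr_k
    d[6] = vb_t - vr_t
    d[7] = vb_i - vr_i
    d[8] = vb_k - vr_k
    d[9] = dr_tnf
    d[10] = dr_il1
    d[11] = -va_kt + vi_kt - vd_ktn + vr_t
    d[12] = va_kt - vi_kt - vd_kta
    d[13] = vd_ktn + vd_kta - vb_t
    d[14] = -va_ki + vi_ki - vd_kin + vr_i
    d[15] = va_ki - vi_ki - vd_kia
    d[16] = vd_kin + vd_kia - vb_i
    d[17] = -va_ikk + vn_ikk - vd_ikkn + vr_k
    d[18] = va_ikk - vi_ikk - vd_ikka
    d[19] = vi_ikk - vn_ikk - vd_ikki
    d[20] = vd_ikkn + vd_ikka + vd_ikki - vb_k
    d[21] = vpd - vas_c + vdis_c - vimp_n + vexp_n + vdeg_ic
    d[22] = vimp_n - vexp_n - vas_n + vdis_n + vdeg_icn
    d[23] = v_tl_ikba - vas_c + vdis_c - vph_f - vdeg_if - vimp_i + vexp_i
    d[24] = vimp_i - vexp_i - vas_n + vdis_n - vdeg_ifn
    d[25] = vas_c - vdis_c - vph_c + vexp_c - vdeg_ic
    d[26] = vas_n - vdis_n - vexp_c - vdeg_icn
    d[27] = vph_c - vpd
    d[28] = v_txn_ikba - v_mdeg_ikba
    d[29] = v_txn_a20 - v_mdeg_a20
    d[30] = v_tl_a20 - vdeg_a20
    return d


def derivatives(state: np.ndarray, params: ParameterSet,
                temperature: float = T_BASE,
                cytokine: CytokineInput | None = None) -> np.ndarray:
    """Rate of change (molecules/h) of every species at ``state``.

    Validates the preconditions (non-negative state, calibrated
    temperature range, known cytokine) and evaluates the mass-action
    system; the only non-mass-action terms are the Hill transcription of
    HSPi, the saturating A20 inhibition of IKKK activation and the
    saturating chaperone protection of kinase denaturation.
    """
    state = np.asarray(state, float)
    if state.shape != (sp.N_SPECIES,):
        raise ValueError(
            f"state must have {sp.N_SPECIES} components, got {state.shape}")
    if np.any(state < 0):
        bad = sp.SPECIES_NAMES[int(np.argmin(state))]
        raise ValueError(f"negative state component {bad!r}")
    _check_temperature(temperature)
    cytokine = cytokine or CytokineInput("none")
    u_tnf, u_il1 = cytokine.flags
    den = denaturation_rate(temperature, params)
    return _rhs(0.0, state, params.packed(), den, u_tnf, u_il1)


def default_initial_state(params: ParameterSet) -> np.ndarray:
    """A crude positive state with the nominal conserved totals.

    All of each conserved pool is placed in its neutral/free form; the
    steady-state solver partitions the pools.
    """
    y = np.zeros(sp.N_SPECIES)
    t = params.totals
    y[sp.HSF1] = t["HSF1_TOTAL"]
    y[sp.HSPC] = t["HSPC_TOTAL"]
    y[sp.IKKKT_N] = t["IKKKT_TOTAL"]
    y[sp.IKKKI_N] = t["IKKKI_TOTAL"]
    y[sp.IKK_N] = t["IKK_TOTAL"]
    y[sp.IKBA_NFKB_C] = t["NFKB_TOTAL"]
    return y


def integrate_phase(y0: np.ndarray, params: ParameterSet, duration: float,
                    temperature: float = T_BASE,
                    cytokine: CytokineInput | None = None,
                    t_eval: np.ndarray | None = None,
                    rtol: float = RTOL, atol: float = ATOL):
    """Integrate one constant-condition phase; returns ``(t, Y)``.

    ``Y`` has shape (n_times, 31).  Conditions (temperature, cytokine
    on/off) are constant within a phase; protocols stitch phases so
    discontinuities never fall inside a solver step.
    """
    _check_temperature(temperature)
    cytokine = cytokine or CytokineInput("none")
    u_tnf, u_il1 = cytokine.flags
    den = denaturation_rate(temperature, params)
    p = params.packed()
    sol = solve_ivp(
        _rhs, (0.0, duration), np.asarray(y0, float), method="LSODA",
        t_eval=t_eval, rtol=rtol, atol=atol,
        args=(p, den, u_tnf, u_il1))
    if not sol.success:
        raise RuntimeError(f"solver failed: {sol.message}")
    # Clip the tiny negative undershoots the solver tolerance permits.
    Y = sol.y.T.copy()
    np.clip(Y, 0.0, None, out=Y)
    return sol.t, Y


#: residual criterion of the resting attractor, per hour
STEADY_TOL = 1e-6
#: pre-equilibration horizon at 37 °C (h)
EQUILIBRATION_HOURS = 200.0


def steady_state(params: ParameterSet, y0: np.ndarray | None = None,
                 horizon: float = EQUILIBRATION_HOURS,
                 tol: float = STEADY_TOL, max_rounds: int = 5) -> np.ndarray:
    """The 37 °C, cytokine-free resting state.

    Integrates from ``y0`` (default: nominal totals in their neutral
    forms) for up to ``max_rounds`` stretches of ``horizon`` hours of
    model time, stopping once the scaled residual
    ``max |dx/dt| / max(x, 1)`` is below ``tol`` (1/h); raises
    :class:`SteadyStateError` carrying the residual otherwise.
    """
    y = default_initial_state(params) if y0 is None else \
        np.asarray(y0, float)
    resid = np.inf
    for _ in range(max_rounds):
        _, Y = integrate_phase(y, params, horizon, T_BASE,
                               CytokineInput("none"),
                               t_eval=np.array([0.0, horizon]))
        y = Y[-1]
        resid = float(np.max(np.abs(derivatives(y, params)) /
                             np.maximum(y, 1.0)))
        if resid <= tol:
            return y
    raise SteadyStateError(resid, tol)
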