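"""Parameter registry for the combined HSR / NF-κB model.

The model has exactly 60 kinetic parameters (rates, binding constants and
the three constants of the temperature–denaturation response) plus a small
set of structural constants (the Hill coefficient n = 3 of HSF1-trimer
driven transcription and the nominal conserved totals).  Values live in a
TOML config shipped with the package; the code reads the config rather
than hard-coding rates, so a re-calibration is a data change.

Every kinetic parameter carries a pathway tag (``TNF`` / ``IL1`` / ``HSR``
/ ``shared``) and a module group (``IKKK`` / ``IKK`` / ``A20`` / ``IkBa``
/ ``HSR`` / ``core``) used by the one-at-a-time sensitivity scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: canonical ordering of the 60 kinetic parameters; this is the layout of
#: the packed vector handed to the compiled right-hand side.
PARAM_ORDER: tuple[str, ...] = (
    # HSR core (11)
    "k_hsf_hspi_on", "k_hsf_hspi_off",
    "k_trimer", "k_detrimer", "k_detrimer_hsp",
    "k_mrna_basal", "k_mrna_max", "K_hill", "k_mrna_deg",
    "k_translation", "k_hspi_deg",
    # chaperone-mediated kinase repair (6)
    "k_bind_hspi_tnf", "k_repair_tnf",
    "k_bind_hspc_il1", "k_repair_il1",
    "k_bind_hspc_ikk", "k_repair_ikk",
    # temperature / denaturation (4)
    "k_den_max", "T_mid", "w_den", "K_protect",
    # receptors (4)
    "k_r_tnf_act", "k_r_tnf_deact", "k_r_il1_act", "k_r_il1_deact",
    # IKKK (6)
    "k_ikkk_tnf_act", "k_ikkk_tnf_deact",
    "k_ikkk_il1_act", "k_ikkk_il1_deact",
    "K_a20_tnf", "K_a20_il1",
    # IKK (6)
    "k_ikk_act_tnf", "k_ikk_act_il1",
    "k_ikk_inact", "k_ikk_inact_hsp", "k_ikk_reset", "k_ikk_reset_hsp",
    # IκBα / NF-κB core (18)
    "k_phos_free", "k_phos_complex", "k_pdeg",
    "k_assoc_cyt", "k_assoc_nuc",
    "k_complex_dissoc_cyt", "k_complex_dissoc_nuc",
    "k_nfkb_import", "k_nfkb_export",
    "k_ikba_import", "k_ikba_export", "k_complex_export",
    "k_ikba_txn_basal", "k_ikba_txn", "k_ikba_mrna_deg",
    "k_ikba_translation", "k_ikba_deg_free", "k_ikba_deg_complex",
    # A20 feedback (5)
    "k_a20_txn_basal", "k_a20_txn", "k_a20_mrna_deg",
    "k_a20_translation", "k_a20_deg",
)

N_PARAMS = len(PARAM_ORDER)  # 60

PARAM_INDEX: dict[str, int] = {n: i for i, n in enumerate(PARAM_ORDER)}

#: pathway tag per parameter (TNF / IL1 / HSR / shared)
PATHWAY_TAGS: dict[str, str] = {}
PATHWAY_TAGS.update({k: "HSR" for k in PARAM_ORDER[:11]})
PATHWAY_TAGS.update({
    "k_bind_hspi_tnf": "TNF", "k_repair_tnf": "TNF",
    "k_bind_hspc_il1": "IL1", "k_repair_il1": "IL1",
    "k_bind_hspc_ikk": "shared", "k_repair_ikk": "shared",
    "k_den_max": "shared", "T_mid": "shared", "w_den": "shared",
    "K_protect": "shared",
    "k_r_tnf_act": "TNF", "k_r_tnf_deact": "TNF",
    "k_r_il1_act": "IL1", "k_r_il1_deact": "IL1",
    "k_ikkk_tnf_act": "TNF", "k_ikkk_tnf_deact": "TNF",
    "k_ikkk_il1_act": "IL1", "k_ikkk_il1_deact": "IL1",
    "K_a20_tnf": "TNF", "K_a20_il1": "IL1",
    "k_ikk_act_tnf": "TNF", "k_ikk_act_il1": "IL1",
})
PATHWAY_TAGS.update(
    {k: "shared" for k in PARAM_ORDER if k not in PATHWAY_TAGS})

#: module group per parameter, matching the sensitivity-screen panels
MODULE_GROUPS: dict[str, str] = {}
MODULE_GROUPS.update({k: "HSR" for k in PARAM_ORDER[:17]})
MODULE_GROUPS.update({k: "HSR" for k in
                      ("k_den_max", "T_mid", "w_den", "K_protect")})
MODULE_GROUPS.update({k: "IKKK" for k in (
    "k_r_tnf_act", "k_r_tnf_deact", "k_r_il1_act", "k_r_il1_deact",
    "k_ikkk_tnf_act", "k_ikkk_tnf_deact",
    "k_ikkk_il1_act", "k_ikkk_il1_deact")})
MODULE_GROUPS.update({k: "IKK" for k in (
    "k_ikk_act_tnf", "k_ikk_act_il1", "k_ikk_inact", "k_ikk_inact_hsp",
    "k_ikk_reset", "k_ikk_reset_hsp")})
MODULE_GROUPS.update({k: "A20" for k in (
    "K_a20_tnf", "K_a20_il1", "k_a20_txn_basal", "k_a20_txn",
    "k_a20_mrna_deg", "k_a20_translation", "k_a20_deg")})
MODULE_GROUPS.update({k: "IkBa" for k in (
    "k_phos_free", "k_phos_complex", "k_pdeg",
    "k_ikba_txn_basal", "k_ikba_txn", "k_ikba_mrna_deg",
    "k_ikba_translation", "k_ikba_deg_free", "k_ikba_deg_complex")})
MODULE_GROUPS.update(
    {k: "core" for k in PARAM_ORDER if k not in MODULE_GROUPS})

#: structural constants: not kinetic rates, fixed by model structure
HILL_N = 3

#: names of the nominal conserved totals held in the [species] block
TOTAL_NAMES = (
    "NFKB_TOTAL", "IKK_TOTAL", "IKKKT_TOTAL", "IKKKI_TOTAL",
    "HSPC_TOTAL", "HSF1_TOTAL",
)


class ParameterError(ValueError):
    """Raised when a parameter set fails validation."""


@dataclass(frozen=True)
class ParameterSet:
    """The 60 kinetic parameters plus structural totals of the model.

    Attributes
    ----------
    values
        Mapping parameter name -> value (1/h, 1/(molecule·h), molecules or
        °C depending on the parameter; see the shipped config for units).
    totals
        Nominal conserved totals (molecules per cell) for NF-κB, IKK, the
        two IKKKs, HSPc and HSF1.
    hill_n
        Hill coefficient of HSPi transcription; structurally fixed at 3
        (HSF1 acts as a trimer).
    """

    values: dict[str, float]
    totals: dict[str, float]
    hill_n: int = HILL_N

    def __post_init__(self) -> None:
        missing = [k for k in PARAM_ORDER if k not in self.values]
        if missing:
            raise ParameterError(f"missing kinetic parameters: {missing}")
        unknown = [k for k in self.values if k not in PARAM_INDEX]
        if unknown:
            raise ParameterError(f"unknown kinetic parameters: {unknown}")
        if len(self.values) != N_PARAMS:
            raise ParameterError(
                f"expected {N_PARAMS} kinetic parameters, got "
                f"{len(self.values)}")
        for k, v in self.values.items():
            if not np.isfinite(v) or v < 0:
                raise ParameterError(
                    f"parameter {k!r} must be finite and >= 0, got {v}")
        missing_t = [k for k in TOTAL_NAMES if k not in self.totals]
        if missing_t:
            raise ParameterError(f"missing totals: {missing_t}")
        for k, v in self.totals.items():
            if k not in TOTAL_NAMES:
                raise ParameterError(f"unknown total {k!r}")
            if not np.isfinite(v) or v < 0:
                raise ParameterError(
                    f"total {k!r} must be finite and >= 0, got {v}")
        if self.hill_n != HILL_N:
            raise ParameterError(
                f"Hill coefficient is structurally fixed at {HILL_N}")
        # MCF7 fit constraint: IL1 upstream-kinase cycling is not faster
        # than the TNF one.
        if self.values["k_ikkk_il1_act"] > self.values["k_ikkk_tnf_act"]:
            raise ParameterError(
                "IKKK_IL1 cycling must be <= IKKK_TNF cycling "
                "(k_ikkk_il1_act > k_ikkk_tnf_act)")

    def packed(self) -> np.ndarray:
        """The 60 values in canonical order, for the compiled RHS."""
        return np.array([self.values[k] for k in PARAM_ORDER], float)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def with_values(self, **updates: float) -> "ParameterSet":
        """A copy with some kinetic parameters replaced."""
        unknown = [k for k in updates if k not in PARAM_INDEX]
        if unknown:
            raise ParameterError(f"unknown kinetic parameters: {unknown}")
        vals = dict(self.values)
        vals.update(updates)
        return replace(self, values=vals)

    def scaled(self, key: str, factor: float) -> "ParameterSet":
        """A copy with one parameter multiplied by ``factor``."""
        if key not in PARAM_INDEX:
            raise ParameterError(f"unknown kinetic parameter {key!r}")
        return self.with_values(**{key: self.values[key] * factor})

    def pathway_tag(self, key: str) -> str:
        return PATHWAY_TAGS[key]

    def module_group(self, key: str) -> str:
        return MODULE_GROUPS[key]
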