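"""Declarative reaction registry of the model.

One entry per elementary process: reactants, products, rate law and the
kinetic parameters it uses.  ``modifiers`` are species that enter the
rate law without being consumed (catalysts, saturating inhibitors).
The registry is shipped in the parameter config and cross-checked
against the coded right-hand side by the conservation and validation
tests; it is documentation-grade metadata, not code generation.

Rate-law vocabulary:

``mass_action``
    k * product(reactant counts).
``hill``
    basal + vmax * x^3 / (K^3 + x^3) in the HSF1 trimer.
``denaturation``
    k_den_max * phi(T) * K_protect/(K_protect + HSPi + HSPc) * substrate,
    with phi the normalized logistic temperature response.
``a20_inhibited``
    k * receptor * K_a20/(K_a20 + A20) * substrate.
``hsp_assisted``
    (k + k_hsp * (HSPi + HSPc)) * substrate.
``input_relaxation``
    k_act * u(t) * (1 - R) - k_deact * R for a receptor occupancy R.
``zero_order``
    constant synthesis flux k.
``linear_activation``
    k_basal + k * activator.
"""

REACTIONS: tuple[dict, ...] = (
    # --- HSR ---------------------------------------------------------
    dict(name="hsf1_sequestration", reactants=["HSF1", "HSPI"],
         products=["HSF1_HSPI"], rate_law="mass_action",
         parameters=["k_hsf_hspi_on"]),
    dict(name="hsf1_release", reactants=["HSF1_HSPI"],
         products=["HSF1", "HSPI"], rate_law="mass_action",
         parameters=["k_hsf_hspi_off"]),
    dict(name="hsf1_trimerization", reactants=["HSF1", "HSF1", "HSF1"],
         products=["HSF1_3"], rate_law="mass_action",
         parameters=["k_trimer"]),
    dict(name="trimer_dissociation", reactants=["HSF1_3"],
         products=["HSF1", "HSF1", "HSF1"], rate_law="hsp_assisted",
         parameters=["k_detrimer", "k_detrimer_hsp"], modifiers=["HSPI"]),
    dict(name="hspi_transcription", reactants=[], products=["M_HSPI"],
         rate_law="hill", parameters=["k_mrna_basal", "k_mrna_max",
                                      "K_hill"], modifiers=["HSF1_3"]),
    dict(name="hspi_mrna_decay", reactants=["M_HSPI"], products=[],
         rate_law="mass_action", parameters=["k_mrna_deg"]),
    dict(name="hspi_translation", reactants=[], products=["HSPI"],
         rate_law="mass_action", parameters=["k_translation"],
         modifiers=["M_HSPI"]),
    dict(name="hspi_degradation", reactants=["HSPI"], products=[],
         rate_law="mass_action", parameters=["k_hspi_deg"]),
    # --- temperature-dependent kinase denaturation -------------------
    dict(name="ikkkt_n_denaturation", reactants=["IKKKT_N"],
         products=["IKKKT_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikkkt_a_denaturation", reactants=["IKKKT_A"],
         products=["IKKKT_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikkki_n_denaturation", reactants=["IKKKI_N"],
         products=["IKKKI_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikkki_a_denaturation", reactants=["IKKKI_A"],
         products=["IKKKI_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikk_n_denaturation", reactants=["IKK_N"],
         products=["IKK_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikk_a_denaturation", reactants=["IKK_A"],
         products=["IKK_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikk_i_denaturation", reactants=["IKK_I"],
         products=["IKK_D"], rate_law="denaturation",
         parameters=["k_den_max", "T_mid", "w_den", "K_protect"],
         modifiers=["HSPI", "HSPC"]),
    # --- chaperone-mediated repair -----------------------------------
    dict(name="hspi_binds_ikkkt_d", reactants=["HSPI", "IKKKT_D"],
         products=["HSPI_IKKKT_D"], rate_law="mass_action",
         parameters=["k_bind_hspi_tnf"]),
    dict(name="ikkkt_repair", reactants=["HSPI_IKKKT_D"],
         products=["HSPI", "IKKKT_N"], rate_law="mass_action",
         parameters=["k_repair_tnf"]),
    dict(name="hspc_binds_ikkki_d", reactants=["HSPC", "IKKKI_D"],
         products=["HSPC_IKKKI_D"], rate_law="mass_action",
         parameters=["k_bind_hspc_il1"]),
    dict(name="ikkki_repair", reactants=["HSPC_IKKKI_D"],
         products=["HSPC", "IKKKI_N"], rate_law="mass_action",
         parameters=["k_repair_il1"]),
    dict(name="hspc_binds_ikk_d", reactants=["HSPC", "IKK_D"],
         products=["HSPC_IKK_D"], rate_law="mass_action",
         parameters=["k_bind_hspc_ikk"]),
    dict(name="ikk_repair", reactants=["HSPC_IKK_D"],
         products=["HSPC", "IKK_N"], rate_law="mass_action",
         parameters=["k_repair_ikk"]),
    # --- receptors ---------------------------------------------------
    dict(name="tnf_receptor", reactants=[], products=["R_TNF"],
         rate_law="input_relaxation",
         parameters=["k_r_tnf_act", "k_r_tnf_deact"]),
    dict(name="il1_receptor", reactants=[], products=["R_IL1"],
         rate_law="input_relaxation",
         parameters=["k_r_il1_act", "k_r_il1_deact"]),
    # --- IKKK cycling ------------------------------------------------
    dict(name="ikkkt_activation", reactants=["IKKKT_N"],
         products=["IKKKT_A"], rate_law="a20_inhibited",
         parameters=["k_ikkk_tnf_act", "K_a20_tnf"],
         modifiers=["R_TNF", "A20"]),
    dict(name="ikkkt_inactivation", reactants=["IKKKT_A"],
         products=["IKKKT_N"], rate_law="mass_action",
         parameters=["k_ikkk_tnf_deact"]),
    dict(name="ikkki_activation", reactants=["IKKKI_N"],
         products=["IKKKI_A"], rate_law="a20_inhibited",
         parameters=["k_ikkk_il1_act", "K_a20_il1"],
         modifiers=["R_IL1", "A20"]),
    dict(name="ikkki_inactivation", reactants=["IKKKI_A"],
         products=["IKKKI_N"], rate_law="mass_action",
         parameters=["k_ikkk_il1_deact"]),
    # --- IKK cycling -------------------------------------------------
    dict(name="ikk_activation_tnf", reactants=["IKK_N"],
         products=["IKK_A"], rate_law="a20_inhibited",
         parameters=["k_ikk_act_tnf", "K_a20_tnf"],
         modifiers=["IKKKT_A", "A20"]),
    dict(name="ikk_activation_il1", reactants=["IKK_N"],
         products=["IKK_A"], rate_law="a20_inhibited",
         parameters=["k_ikk_act_il1", "K_a20_il1"],
         modifiers=["IKKKI_A", "A20"]),
    dict(name="ikk_inactivation", reactants=["IKK_A"],
         products=["IKK_I"], rate_law="hsp_assisted",
         parameters=["k_ikk_inact", "k_ikk_inact_hsp"],
         modifiers=["HSPI", "HSPC"]),
    dict(name="ikk_reset", reactants=["IKK_I"], products=["IKK_N"],
         rate_law="hsp_assisted",
         parameters=["k_ikk_reset", "k_ikk_reset_hsp"],
         modifiers=["HSPI", "HSPC"]),
    # --- IκBα / NF-κB core -------------------------------------------
    dict(name="ikba_phosphodegradation_free", reactants=["IKBA_C"],
         products=[], rate_law="mass_action", parameters=["k_phos_free"],
         modifiers=["IKK_A"]),
    dict(name="complex_phosphorylation", reactants=["IKBA_NFKB_C"],
         products=["P_IKBA_NFKB"], rate_law="mass_action",
         parameters=["k_phos_complex"], modifiers=["IKK_A"]),
    dict(name="phospho_complex_degradation", reactants=["P_IKBA_NFKB"],
         products=["NFKB_C"], rate_law="mass_action",
         parameters=["k_pdeg"]),
    dict(name="association_cytoplasm", reactants=["IKBA_C", "NFKB_C"],
         products=["IKBA_NFKB_C"], rate_law="mass_action",
         parameters=["k_assoc_cyt"]),
    dict(name="association_nucleus", reactants=["IKBA_N", "NFKB_N"],
         products=["IKBA_NFKB_N"], rate_law="mass_action",
         parameters=["k_assoc_nuc"]),
    dict(name="dissociation_cytoplasm", reactants=["IKBA_NFKB_C"],
         products=["IKBA_C", "NFKB_C"], rate_law="mass_action",
         parameters=["k_complex_dissoc_cyt"]),
    dict(name="dissociation_nucleus", reactants=["IKBA_NFKB_N"],
         products=["IKBA_N", "NFKB_N"], rate_law="mass_action",
         parameters=["k_complex_dissoc_nuc"]),
    dict(name="nfkb_import", reactants=["NFKB_C"], products=["NFKB_N"],
         rate_law="mass_action", parameters=["k_nfkb_import"]),
    dict(name="nfkb_export", reactants=["NFKB_N"], products=["NFKB_C"],
         rate_law="mass_action", parameters=["k_nfkb_export"]),
    dict(name="ikba_import", reactants=["IKBA_C"], products=["IKBA_N"],
         rate_law="mass_action", parameters=["k_ikba_import"]),
    dict(name="ikba_export", reactants=["IKBA_N"], products=["IKBA_C"],
         rate_law="mass_action", parameters=["k_ikba_export"]),
    dict(name="complex_export", reactants=["IKBA_NFKB_N"],
         products=["IKBA_NFKB_C"], rate_law="mass_action",
         parameters=["k_complex_export"]),
    dict(name="ikba_transcription", reactants=[], products=["M_IKBA"],
         rate_law="linear_activation",
         parameters=["k_ikba_txn_basal", "k_ikba_txn"],
         modifiers=["NFKB_N"]),
    dict(name="ikba_mrna_decay", reactants=["M_IKBA"], products=[],
         rate_law="mass_action", parameters=["k_ikba_mrna_deg"]),
    dict(name="ikba_translation", reactants=[], products=["IKBA_C"],
         rate_law="mass_action", parameters=["k_ikba_translation"],
         modifiers=["M_IKBA"]),
    dict(name="ikba_degradation_cyt", reactants=["IKBA_C"], products=[],
         rate_law="mass_action", parameters=["k_ikba_deg_free"]),
    dict(name="ikba_degradation_nuc", reactants=["IKBA_N"], products=[],
         rate_law="mass_action", parameters=["k_ikba_deg_free"]),
    dict(name="complex_turnover_cyt", reactants=["IKBA_NFKB_C"],
         products=["NFKB_C"], rate_law="mass_action",
         parameters=["k_ikba_deg_complex"]),
    dict(name="complex_turnover_nuc", reactants=["IKBA_NFKB_N"],
         products=["NFKB_N"], rate_law="mass_action",
         parameters=["k_ikba_deg_complex"]),
    # --- A20 feedback ------------------------------------------------
    dict(name="a20_transcription", reactants=[], products=["M_A20"],
         rate_law="linear_activation",
         parameters=["k_a20_txn_basal", "k_a20_txn"],
         modifiers=["NFKB_N"]),
    dict(name="a20_mrna_decay", reactants=["M_A20"], products=[],
         rate_law="mass_action", parameters=["k_a20_mrna_deg"]),
    dict(name="a20_translation", reactants=[], products=["A20"],
         rate_law="mass_action", parameters=["k_a20_translation"],
         modifiers=["M_A20"]),
    dict(name="a20_degradation", reactants=["A20"], products=[],
         rate_law="mass_action", parameters=["k_a20_deg"]),
)
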