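# Combined HSR / NF-kB model configuration
# 31 state variables, 60 kinetic parameters

[structural]
hill_n = 3

[totals]  # nominal conserved totals, molecules/cell
NFKB_TOTAL = 100000.0
IKK_TOTAL = 98715.7710107605
IKKKT_TOTAL = 98715.7710107605
IKKKI_TOTAL = 98715.7710107605
HSPC_TOTAL = 24343.00942440838
HSF1_TOTAL = 9897.129058743909

[species]
HSF1 = "free HSF1 monomer"
HSF1_HSPI = "inactive HSF1:HSPi complex"
HSF1_3 = "active HSF1 trimer"
M_HSPI = "HSPi mRNA"
HSPI = "free inducible chaperone"
HSPC = "free constitutive chaperone"
HSPI_IKKKT_D = "HSPi bound to denatured IKKK_TNF"
HSPC_IKKKI_D = "HSPc bound to denatured IKKK_IL1"
HSPC_IKK_D = "HSPc bound to denatured IKK"
R_TNF = "active TNF receptor fraction"
R_IL1 = "active IL1 receptor fraction"
IKKKT_N = "IKKK_TNF neutral"
IKKKT_A = "IKKK_TNF active"
IKKKT_D = "IKKK_TNF denatured (insoluble)"
IKKKI_N = "IKKK_IL1 neutral"
IKKKI_A = "IKKK_IL1 active"
IKKKI_D = "IKKK_IL1 denatured (insoluble)"
IKK_N = "IKK neutral (soluble)"
IKK_A = "IKK active"
IKK_I = "IKK inactive (refractory)"
IKK_D = "IKK denatured (insoluble)"
NFKB_C = "free cytoplasmic NF-kB"
NFKB_N = "free nuclear NF-kB"
IKBA_C = "free cytoplasmic IkBa"
IKBA_N = "free nuclear IkBa"
IKBA_NFKB_C = "cytoplasmic IkBa:NF-kB complex"
IKBA_NFKB_N = "nuclear IkBa:NF-kB complex"
P_IKBA_NFKB = "phospho-IkBa:NF-kB complex"
M_IKBA = "IkBa mRNA"
M_A20 = "A20 mRNA"
A20 = "A20 protein"

[parameters]
k_hsf_hspi_on = { value = 0.0015, unit = "1/(molecule*h)", pathway = "HSR", group = "HSR" }
k_hsf_hspi_off = { value = 0.8, unit = "1/h", pathway = "HSR", group = "HSR" }
k_trimer = { value = 3e-08, unit = "1/(molecule^2*h)", pathway = "HSR", group = "HSR" }
k_detrimer = { value = 3.0, unit = "1/h", pathway = "HSR", group = "HSR" }
k_detrimer_hsp = { value = 0.0002, unit = "1/(molecule*h)", pathway = "HSR", group = "HSR" }
k_mrna_basal = { value = 0.26, unit = "molecules/h", pathway = "HSR", group = "HSR" }
k_mrna_max = { value = 1000.0, unit = "molecules/h", pathway = "HSR", group = "HSR" }
K_hill = { value = 60.0, unit = "molecules", pathway = "HSR", group = "HSR" }
k_mrna_deg = { value = 0.25, unit = "1/h", pathway = "HSR", group = "HSR" }
k_translation = { value = 400.0, unit = "1/h", pathway = "HSR", group = "HSR" }
k_hspi_deg = { value = 0.05, unit = "1/h", pathway = "HSR", group = "HSR" }
k_bind_hspi_tnf = { value = 0.0004, unit = "1/(molecule*h)", pathway = "TNF", group = "HSR" }
k_repair_tnf = { value = 0.5, unit = "1/h", pathway = "TNF", group = "HSR" }
k_bind_hspc_il1 = { value = 0.0002, unit = "1/(molecule*h)", pathway = "IL1", group = "HSR" }
k_repair_il1 = { value = 4.0, unit = "1/h", pathway = "IL1", group = "HSR" }
k_bind_hspc_ikk = { value = 0.0002, unit = "1/(molecule*h)", pathway = "shared", group = "HSR" }
k_repair_ikk = { value = 4.0, unit = "1/h", pathway = "shared", group = "HSR" }
k_den_max = { value = 55.0, unit = "1/h", pathway = "shared", group = "HSR" }
T_mid = { value = 41.3, unit = "degC", pathway = "shared", group = "HSR" }
w_den = { value = 0.48, unit = "degC", pathway = "shared", group = "HSR" }
K_protect = { value = 2000.0, unit = "molecules", pathway = "shared", group = "HSR" }
k_r_tnf_act = { value = 30.0, unit = "1/h", pathway = "TNF", group = "IKKK" }
k_r_tnf_deact = { value = 2.0, unit = "1/h", pathway = "TNF", group = "IKKK" }
k_r_il1_act = { value = 30.0, unit = "1/h", pathway = "IL1", group = "IKKK" }
k_r_il1_deact = { value = 2.0, unit = "1/h", pathway = "IL1", group = "IKKK" }
k_ikkk_tnf_act = { value = 8.0, unit = "1/h", pathway = "TNF", group = "IKKK" }
k_ikkk_tnf_deact = { value = 8.0, unit = "1/h", pathway = "TNF", group = "IKKK" }
k_ikkk_il1_act = { value = 2.0, unit = "1/h", pathway = "IL1", group = "IKKK" }
k_ikkk_il1_deact = { value = 0.3, unit = "1/h", pathway = "IL1", group = "IKKK" }
K_a20_tnf = { value = 300.0, unit = "molecules", pathway = "TNF", group = "A20" }
K_a20_il1 = { value = 700.0, unit = "molecules", pathway = "IL1", group = "A20" }
k_ikk_act_tnf = { value = 2e-05, unit = "1/(molecule*h)", pathway = "TNF", group = "IKK" }
k_ikk_act_il1 = { value = 0.00015, unit = "1/(molecule*h)", pathway = "IL1", group = "IKK" }
k_ikk_inact = { value = 12.0, unit = "1/h", pathway = "shared", group = "IKK" }
k_ikk_inact_hsp = { value = 3e-06, unit = "1/(molecule*h)", pathway = "shared", group = "IKK" }
k_ikk_reset = { value = 2.0, unit = "1/h", pathway = "shared", group = "IKK" }
k_ikk_reset_hsp = { value = 5e-06, unit = "1/(molecule*h)", pathway = "shared", group = "IKK" }
k_phos_free = { value = 0.002, unit = "1/(molecule*h)", pathway = "shared", group = "IkBa" }
k_phos_complex = { value = 0.002, unit = "1/(molecule*h)", pathway = "shared", group = "IkBa" }
k_pdeg = { value = 30.0, unit = "1/h", pathway = "shared", group = "IkBa" }
k_assoc_cyt = { value = 0.03, unit = "1/(molecule*h)", pathway = "shared", group = "core" }
k_assoc_nuc = { value = 0.03, unit = "1/(molecule*h)", pathway = "shared", group = "core" }
k_complex_dissoc_cyt = { value = 0.03, unit = "1/h", pathway = "shared", group = "core" }
k_complex_dissoc_nuc = { value = 0.03, unit = "1/h", pathway = "shared", group = "core" }
k_nfkb_import = { value = 25.0, unit = "1/h", pathway = "shared", group = "core" }
k_nfkb_export = { value = 0.5, unit = "1/h", pathway = "shared", group = "core" }
k_ikba_import = { value = 3.0, unit = "1/h", pathway = "shared", group = "core" }
k_ikba_export = { value = 0.5, unit = "1/h", pathway = "shared", group = "core" }
k_complex_export = { value = 30.0, unit = "1/h", pathway = "shared", group = "core" }
k_ikba_txn_basal = { value = 30.0, unit = "molecules/h", pathway = "shared", group = "IkBa" }
k_ikba_txn = { value = 0.1, unit = "1/(molecule*h)", pathway = "shared", group = "IkBa" }
k_ikba_mrna_deg = { value = 3.0, unit = "1/h", pathway = "shared", group = "IkBa" }
k_ikba_translation = { value = 300.0, unit = "1/h", pathway = "shared", group = "IkBa" }
k_ikba_deg_free = { value = 6.0, unit = "1/h", pathway = "shared", group = "IkBa" }
k_ikba_deg_complex = { value = 0.03, unit = "1/h", pathway = "shared", group = "IkBa" }
k_a20_txn_basal = { value = 1.0, unit = "molecules/h", pathway = "shared", group = "A20" }
k_a20_txn = { value = 0.01, unit = "1/(molecule*h)", pathway = "shared", group = "A20" }
k_a20_mrna_deg = { value = 2.0, unit = "1/h", pathway = "shared", group = "A20" }
k_a20_translation = { value = 100.0, unit = "1/h", pathway = "shared", group = "A20" }
k_a20_deg = { value = 2.0, unit = "1/h", pathway = "shared", group = "A20" }

[[reactions]]
name = "hsf1_sequestration"
reactants = ["HSF1", "HSPI"]
products = ["HSF1_HSPI"]
modifiers = []
parameters = ["k_hsf_hspi_on"]
rate_law = "mass_action"

[[reactions]]
name = "hsf1_release"
reactants = ["HSF1_HSPI"]
products = ["HSF1", "HSPI"]
modifiers = []
parameters = ["k_hsf_hspi_off"]
rate_law = "mass_action"

[[reactions]]
name = "hsf1_trimerization"
reactants = ["HSF1", "HSF1", "HSF1"]
products = ["HSF1_3"]
modifiers = []
parameters = ["k_trimer"]
rate_law = "mass_action"

[[reactions]]
name = "trimer_dissociation"
reactants = ["HSF1_3"]
products = ["HSF1", "HSF1", "HSF1"]
modifiers = ["HSPI"]
parameters = ["k_detrimer", "k_detrimer_hsp"]
rate_law = "hsp_assisted"

[[reactions]]
name = "hspi_transcription"
reactants = []
products = ["M_HSPI"]
modifiers = ["HSF1_3"]
parameters = ["k_mrna_basal", "k_mrna_max", "K_hill"]
rate_law = "hill"

[[reactions]]
name = "hspi_mrna_decay"
reactants = ["M_HSPI"]
products = []
modifiers = []
parameters = ["k_mrna_deg"]
rate_law = "mass_action"

[[reactions]]
name = "hspi_translation"
reactants = []
products = ["HSPI"]
modifiers = ["M_HSPI"]
parameters = ["k_translation"]
rate_law = "mass_action"

[[reactions]]
name = "hspi_degradation"
reactants = ["HSPI"]
products = []
modifiers = []
parameters = ["k_hspi_deg"]
rate_law = "mass_action"

[[reactions]]
name = "ikkkt_n_denaturation"
reactants = ["IKKKT_N"]
products = ["IKKKT_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikkkt_a_denaturation"
reactants = ["IKKKT_A"]
products = ["IKKKT_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikkki_n_denaturation"
reactants = ["IKKKI_N"]
products = ["IKKKI_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikkki_a_denaturation"
reactants = ["IKKKI_A"]
products = ["IKKKI_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikk_n_denaturation"
reactants = ["IKK_N"]
products = ["IKK_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikk_a_denaturation"
reactants = ["IKK_A"]
products = ["IKK_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "ikk_i_denaturation"
reactants = ["IKK_I"]
products = ["IKK_D"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_den_max", "T_mid", "w_den", "K_protect"]
rate_law = "denaturation"

[[reactions]]
name = "hspi_binds_ikkkt_d"
reactants = ["HSPI", "IKKKT_D"]
products = ["HSPI_IKKKT_D"]
modifiers = []
parameters = ["k_bind_hspi_tnf"]
rate_law = "mass_action"

[[reactions]]
name = "ikkkt_repair"
reactants = ["HSPI_IKKKT_D"]
products = ["HSPI", "IKKKT_N"]
modifiers = []
parameters = ["k_repair_tnf"]
rate_law = "mass_action"

[[reactions]]
name = "hspc_binds_ikkki_d"
reactants = ["HSPC", "IKKKI_D"]
products = ["HSPC_IKKKI_D"]
modifiers = []
parameters = ["k_bind_hspc_il1"]
rate_law = "mass_action"

[[reactions]]
name = "ikkki_repair"
reactants = ["HSPC_IKKKI_D"]
products = ["HSPC", "IKKKI_N"]
modifiers = []
parameters = ["k_repair_il1"]
rate_law = "mass_action"

[[reactions]]
name = "hspc_binds_ikk_d"
reactants = ["HSPC", "IKK_D"]
products = ["HSPC_IKK_D"]
modifiers = []
parameters = ["k_bind_hspc_ikk"]
rate_law = "mass_action"

[[reactions]]
name = "ikk_repair"
reactants = ["HSPC_IKK_D"]
products = ["HSPC", "IKK_N"]
modifiers = []
parameters = ["k_repair_ikk"]
rate_law = "mass_action"

[[reactions]]
name = "tnf_receptor"
reactants = []
products = ["R_TNF"]
modifiers = []
parameters = ["k_r_tnf_act", "k_r_tnf_deact"]
rate_law = "input_relaxation"

[[reactions]]
name = "il1_receptor"
reactants = []
products = ["R_IL1"]
modifiers = []
parameters = ["k_r_il1_act", "k_r_il1_deact"]
rate_law = "input_relaxation"

[[reactions]]
name = "ikkkt_activation"
reactants = ["IKKKT_N"]
products = ["IKKKT_A"]
modifiers = ["R_TNF", "A20"]
parameters = ["k_ikkk_tnf_act", "K_a20_tnf"]
rate_law = "a20_inhibited"

[[reactions]]
name = "ikkkt_inactivation"
reactants = ["IKKKT_A"]
products = ["IKKKT_N"]
modifiers = []
parameters = ["k_ikkk_tnf_deact"]
rate_law = "mass_action"

[[reactions]]
name = "ikkki_activation"
reactants = ["IKKKI_N"]
products = ["IKKKI_A"]
modifiers = ["R_IL1", "A20"]
parameters = ["k_ikkk_il1_act", "K_a20_il1"]
rate_law = "a20_inhibited"

[[reactions]]
name = "ikkki_inactivation"
reactants = ["IKKKI_A"]
products = ["IKKKI_N"]
modifiers = []
parameters = ["k_ikkk_il1_deact"]
rate_law = "mass_action"

[[reactions]]
name = "ikk_activation_tnf"
reactants = ["IKK_N"]
products = ["IKK_A"]
modifiers = ["IKKKT_A", "A20"]
parameters = ["k_ikk_act_tnf", "K_a20_tnf"]
rate_law = "a20_inhibited"

[[reactions]]
name = "ikk_activation_il1"
reactants = ["IKK_N"]
products = ["IKK_A"]
modifiers = ["IKKKI_A", "A20"]
parameters = ["k_ikk_act_il1", "K_a20_il1"]
rate_law = "a20_inhibited"

[[reactions]]
name = "ikk_inactivation"
reactants = ["IKK_A"]
products = ["IKK_I"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_ikk_inact", "k_ikk_inact_hsp"]
rate_law = "hsp_assisted"

[[reactions]]
name = "ikk_reset"
reactants = ["IKK_I"]
products = ["IKK_N"]
modifiers = ["HSPI", "HSPC"]
parameters = ["k_ikk_reset", "k_ikk_reset_hsp"]
rate_law = "hsp_assisted"

[[reactions]]
name = "ikba_phosphodegradation_free"
reactants = ["IKBA_C"]
products = []
modifiers = ["IKK_A"]
parameters = ["k_phos_free"]
rate_law = "mass_action"

[[reactions]]
name = "complex_phosphorylation"
reactants = ["IKBA_NFKB_C"]
products = ["P_IKBA_NFKB"]
modifiers = ["IKK_A"]
parameters = ["k_phos_complex"]
rate_law = "mass_action"

[[reactions]]
name = "phospho_complex_degradation"
reactants = ["P_IKBA_NFKB"]
products = ["NFKB_C"]
modifiers = []
parameters = ["k_pdeg"]
rate_law = "mass_action"

[[reactions]]
name = "association_cytoplasm"
reactants = ["IKBA_C", "NFKB_C"]
products = ["IKBA_NFKB_C"]
modifiers = []
parameters = ["k_assoc_cyt"]
rate_law = "mass_action"

[[reactions]]
name = "association_nucleus"
reactants = ["IKBA_N", "NFKB_N"]
products = ["IKBA_NFKB_N"]
modifiers = []
parameters = ["k_assoc_nuc"]
rate_law = "mass_action"

[[reactions]]
name = "dissociation_cytoplasm"
reactants = ["IKBA_NFKB_C"]
products = ["IKBA_C", "NFKB_C"]
modifiers = []
parameters = ["k_complex_dissoc_cyt"]
rate_law = "mass_action"

[[reactions]]
name = "dissociation_nucleus"
reactants = ["IKBA_NFKB_N"]
products = ["IKBA_N", "NFKB_N"]
modifiers = []
parameters = ["k_complex_dissoc_nuc"]
rate_law = "mass_action"

[[reactions]]
name = "nfkb_import"
reactants = ["NFKB_C"]
products = ["NFKB_N"]
modifiers = []
parameters = ["k_nfkb_import"]
rate_law = "mass_action"

[[reactions]]
name = "nfkb_export"
reactants = ["NFKB_N"]
products = ["NFKB_C"]
modifiers = []
parameters = ["k_nfkb_export"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_import"
reactants = ["IKBA_C"]
products = ["IKBA_N"]
modifiers = []
parameters = ["k_ikba_import"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_export"
reactants = ["IKBA_N"]
products = ["IKBA_C"]
modifiers = []
parameters = ["k_ikba_export"]
rate_law = "mass_action"

[[reactions]]
name = "complex_export"
reactants = ["IKBA_NFKB_N"]
products = ["IKBA_NFKB_C"]
modifiers = []
parameters = ["k_complex_export"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_transcription"
reactants = []
products = ["M_IKBA"]
modifiers = ["NFKB_N"]
parameters = ["k_ikba_txn_basal", "k_ikba_txn"]
rate_law = "linear_activation"

[[reactions]]
name = "ikba_mrna_decay"
reactants = ["M_IKBA"]
products = []
modifiers = []
parameters = ["k_ikba_mrna_deg"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_translation"
reactants = []
products = ["IKBA_C"]
modifiers = ["M_IKBA"]
parameters = ["k_ikba_translation"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_degradation_cyt"
reactants = ["IKBA_C"]
products = []
modifiers = []
parameters = ["k_ikba_deg_free"]
rate_law = "mass_action"

[[reactions]]
name = "ikba_degradation_nuc"
reactants = ["IKBA_N"]
products = []
modifiers = []
parameters = ["k_ikba_deg_free"]
rate_law = "mass_action"

[[reactions]]
name = "complex_turnover_cyt"
reactants = ["IKBA_NFKB_C"]
products = ["NFKB_C"]
modifiers = []
parameters = ["k_ikba_deg_complex"]
rate_law = "mass_action"

[[reactions]]
name = "complex_turnover_nuc"
reactants = ["IKBA_NFKB_N"]
products = ["NFKB_N"]
modifiers = []
parameters = ["k_ikba_deg_complex"]
rate_law = "mass_action"

[[reactions]]
name = "a20_transcription"
reactants = []
products = ["M_A20"]
modifiers = ["NFKB_N"]
parameters = ["k_a20_txn_basal", "k_a20_txn"]
rate_law = "linear_activation"

[[reactions]]
name = "a20_mrna_decay"
reactants = ["M_A20"]
products = []
modifiers = []
parameters = ["k_a20_mrna_deg"]
rate_law = "mass_action"

[[reactions]]
name = "a20_translation"
reactants = []
products = ["A20"]
modifiers = ["M_A20"]
parameters = ["k_a20_translation"]
rate_law = "mass_action"

[[reactions]]
name = "a20_degradation"
reactants = ["A20"]
products = []
modifiers = []
parameters = ["k_a20_deg"]
rate_law = "mass_action"
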