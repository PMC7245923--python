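"""Canonical state-vector layout of the combined HSR / NF-κB model.

The model tracks 31 molecular species per cell, in molecule counts
(receptor activities are dimensionless occupancies in [0, 1]).  The
ordering below is the one used by the right-hand side, the solver and
every serialized trajectory; it never changes at run time.
"""

from __future__ import annotations

# --- heat-shock response -------------------------------------------------
HSF1 = 0            # free HSF1 monomer
HSF1_HSPI = 1       # inactive HSF1:HSPi complex
HSF1_3 = 2          # active HSF1 trimer (transcriptionally competent)
M_HSPI = 3          # HSPi mRNA
HSPI = 4            # free inducible chaperone (HSP70-like)
HSPC = 5            # free constitutive chaperone
# chaperone : denatured-kinase repair complexes
HSPI_IKKKT_D = 6    # HSPi bound to denatured IKKK_TNF
HSPC_IKKKI_D = 7    # HSPc bound to denatured IKKK_IL1
HSPC_IKK_D = 8      # HSPc bound to denatured IKK

# --- receptors -----------------------------------------------------------
R_TNF = 9           # active TNF-receptor fraction (0..1)
R_IL1 = 10          # active IL1-receptor fraction (0..1)

# --- cytokine-specific upstream kinases (IKKK) ---------------------------
IKKKT_N = 11        # IKKK_TNF neutral
IKKKT_A = 12        # IKKK_TNF active
IKKKT_D = 13        # IKKK_TNF denatured (insoluble), unbound
IKKKI_N = 14        # IKKK_IL1 neutral
IKKKI_A = 15        # IKKK_IL1 active
IKKKI_D = 16        # IKKK_IL1 denatured (insoluble), unbound

# --- IKK signalosome -----------------------------------------------------
IKK_N = 17          # neutral (resting, soluble)
IKK_A = 18          # active (catalytic towards IκBα)
IKK_I = 19          # inactive (post-activation refractory, soluble)
IKK_D = 20          # denatured (insoluble), unbound

# --- NF-κB core ----------------------------------------------------------
NFKB_C = 21         # free cytoplasmic NF-κB
NFKB_N = 22         # free nuclear NF-κB
IKBA_C = 23         # free cytoplasmic IκBα
IKBA_N = 24         # free nuclear IκBα
IKBA_NFKB_C = 25    # cytoplasmic IκBα:NF-κB complex
IKBA_NFKB_N = 26    # nuclear IκBα:NF-κB complex
P_IKBA_NFKB = 27    # phospho-IκBα:NF-κB, committed to IκBα degradation
M_IKBA = 28         # IκBα mRNA
M_A20 = 29          # A20 mRNA
A20 = 30            # A20 protein

N_SPECIES = 31

SPECIES_NAMES: tuple[str, ...] = (
    "HSF1", "HSF1_HSPI", "HSF1_3", "M_HSPI", "HSPI", "HSPC",
    "HSPI_IKKKT_D", "HSPC_IKKKI_D", "HSPC_IKK_D",
    "R_TNF", "R_IL1",
    "IKKKT_N", "IKKKT_A", "IKKKT_D",
    "IKKKI_N", "IKKKI_A", "IKKKI_D",
    "IKK_N", "IKK_A", "IKK_I", "IKK_D",
    "NFKB_C", "NFKB_N", "IKBA_C", "IKBA_N",
    "IKBA_NFKB_C", "IKBA_NFKB_N", "P_IKBA_NFKB",
    "M_IKBA", "M_A20", "A20",
)

SPECIES_INDEX: dict[str, int] = {n: i for i, n in enumerate(SPECIES_NAMES)}

# Conserved groups (sum over members, with stoichiometric weights) used by
# invariant checks and by initial-condition sampling.
NFKB_GROUP = (NFKB_C, NFKB_N, IKBA_NFKB_C, IKBA_NFKB_N, P_IKBA_NFKB)
IKK_GROUP = (IKK_N, IKK_A, IKK_I, IKK_D, HSPC_IKK_D)
IKKKT_GROUP = (IKKKT_N, IKKKT_A, IKKKT_D, HSPI_IKKKT_D)
IKKKI_GROUP = (IKKKI_N, IKKKI_A, IKKKI_D, HSPC_IKKKI_D)
HSPC_GROUP = (HSPC, HSPC_IKKKI_D, HSPC_IKK_D)
# HSF1 conservation carries weight 3 on the trimer
HSF1_GROUP = (HSF1, HSF1_HSPI, HSF1_3)
HSF1_WEIGHTS = (1.0, 1.0, 3.0)

SOLUBLE_IKK = (IKK_N, IKK_A, IKK_I)
INSOLUBLE_IKK = (IKK_D, HSPC_IKK_D)
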