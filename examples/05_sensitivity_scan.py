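"""One-at-a-time temperature × parameter sensitivity screen (reduced).

Scans one parameter per module group over a multiplicative factor range
crossed with heat-shock temperature, and summarizes each grid by its
temperature-interaction index (how strongly the parameter reshapes the
relative temperature-attenuation profile; 0 means the parameter only
rescales the response).  The expected contrast: IKK-module parameters
control the temperature response far more than IκBα-feedback
parameters.
"""

import numpy as np

from hsnfkb import default_parameters
from hsnfkb.population import EnsembleSpec
from hsnfkb.sensitivity import (scan_parameter,
                                temperature_interaction_index)

params = default_parameters()
spec = EnsembleSpec(n_cells=30, seed=4)
factors = np.array([0.25, 1.0, 4.0])
temperatures = (37.0, 39.0, 41.0, 43.0)

print("param                    group   temperature-interaction index")
for key in ("k_ikkk_tnf_act", "k_ikk_act_tnf", "k_ikk_inact",
            "k_a20_txn", "k_ikba_txn", "k_ikba_translation"):
    grid = scan_parameter(key, params, "TNF", spec, factors=factors,
                          temperatures=temperatures)
    idx = temperature_interaction_index(grid)
    print(f"{key:24s} {grid.group:6s}  {idx:.3f}")
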