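"""Single-cell treatment protocols: control, heat shock, knock-down.

Equilibrates one nominal cell at 37 °C and runs it through the study's
protocols.  Printed numbers are first-peak amplitudes of nuclear NF-κB
in molecules per cell: heat shock suppresses the immediate TNFα
response, recovery restores it, and HSF1 knock-down blocks that
restoration for TNFα but not for IL1β.
"""

from hsnfkb import (CytokineInput, default_parameters, run_single_cell,
                    steady_state)
from hsnfkb.metrics import detect_peaks
from hsnfkb.protocols import TreatmentProtocol

params = default_parameters()
rest = steady_state(params)
print(f"resting nuclear NF-κB: {rest[22]:.0f} molecules")


def first_peak(protocol):
    traj = run_single_cell(rest, params, protocol)
    t, states = traj.window(0.0, 10.0)
    peaks = detect_peaks(t, states[:, 22])
    return peaks[0] if peaks else (float("nan"), 0.0)


for label, protocol in [
        ("TNFα, 37 °C control",
         TreatmentProtocol(cytokine=CytokineInput("TNF"))),
        ("TNFα, 1 h 43 °C + 0 h recovery",
         TreatmentProtocol(hs_temperature=43.0,
                           cytokine=CytokineInput("TNF"))),
        ("TNFα, 1 h 43 °C + 4 h recovery",
         TreatmentProtocol(hs_temperature=43.0, recovery_time=4.0,
                           cytokine=CytokineInput("TNF"))),
        ("TNFα, 43 °C + 4 h, 95% HSF1 knock-down",
         TreatmentProtocol(hs_temperature=43.0, recovery_time=4.0,
                           cytokine=CytokineInput("TNF"),
                           hsf1_kd_fraction=0.95)),
        ("IL1β, 37 °C control",
         TreatmentProtocol(cytokine=CytokineInput("IL1"))),
        ("IL1β, 43 °C + 4 h, 95% HSF1 knock-down",
         TreatmentProtocol(hs_temperature=43.0, recovery_time=4.0,
                           cytokine=CytokineInput("IL1"),
                           hsf1_kd_fraction=0.95))]:
    t_peak, amp = first_peak(protocol)
    print(f"{label:45s} first peak {amp:8.0f} molecules at "
          f"t = {t_peak:.2f} h")
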