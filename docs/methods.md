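# Methods

This note documents the model, its calibration, the numerical choices
and the limits of what the package's synthetic data and tests can show.

## Model structure

One cell is a 31-dimensional ODE system in molecule counts (time in
hours, rates in 1/h). The species split into:

* **HSR module (6)** — free HSF1 monomer, inactive HSF1:HSPi complex,
  active HSF1 trimer, HSPi mRNA, free inducible chaperone HSPi, free
  constitutive chaperone HSPc.
* **Repair complexes (3)** — HSPi bound to denatured IKKK_TNF, HSPc
  bound to denatured IKKK_IL1, HSPc bound to denatured IKK.
* **Receptors (2)** — TNF and IL1 receptor activities as dimensionless
  occupancies in [0, 1] relaxing towards the saturating square input.
* **Upstream kinases (6)** — IKKK_TNF and IKKK_IL1, each
  neutral/active/denatured.
* **IKK signalosome (4)** — neutral, active, inactive (refractory),
  denatured (insoluble).
* **NF-κB core (10)** — free cytoplasmic/nuclear NF-κB, free
  cytoplasmic/nuclear IκBα, cytoplasmic/nuclear IκBα:NF-κB complexes,
  phospho-IκBα:NF-κB, IκBα mRNA, A20 mRNA, A20 protein.

All reactions are mass action except (a) Hill transcription of HSPi in
the HSF1 trimer with n = 3 (structural constant — the trimer is the
transcription factor), (b) saturating A20 inhibition
K_A20/(K_A20 + A20) of the IKKK *and* IKK activation steps of each
branch, and (c) saturating chaperone protection of kinase denaturation.
Without the A20 factor on IKK activation the system retains enough
residual IKK activity after the first peak to hold NF-κB nuclear
indefinitely; with it the model produces the observed damped
oscillations under TNFα and the single adapted translocation under
IL1β (whose upstream kinase cycles an order of magnitude more slowly,
low-pass-filtering the feedback; the config enforces
`k_ikkk_il1_act ≤ k_ikkk_tnf_act`).

Exact conservation laws (used as integrator checks): total NF-κB,
total IKK, both IKKK totals, total HSPc, and total HSF1 (trimer counted
×3). HSPi and IκBα/A20 turn over.

### Temperature coupling

Temperature enters the equations in exactly one place: a first-order
denaturation rate applied to all soluble IKK and IKKK forms,

```
k_den(T) = k_den_max · φ(T) · K_protect / (K_protect + HSP_total)
φ(T)     = (σ((T−T_mid)/w) − σ₀) / (σ₄₃ − σ₀),   σ logistic
```

with φ pinned to 0 at 37 °C and 1 at 43 °C, strictly increasing, and
`k_den` linear in the prefactor. Consequently, setting
`k_den_max = 0` makes every heat-shock protocol exactly equivalent to
the 37 °C control (a regression test asserts this).

`HSP_total` is the **total** chaperone pool, free plus engaged. An
earlier design using only free chaperones produced a runaway: titration
of the free pool during the shock accelerated denaturation and turned
the graded 38–43 °C soluble-IKK response into an all-or-nothing switch.
With total-pool protection the response stays graded, and the HSPi
accumulated after a first shock directly lowers the damage rate of a
second one — this, plus concurrent repair, is the package's mechanism
of thermotolerance.

Denatured kinases are the chaperone substrate: they bind free HSPi
(IKKK_TNF) or HSPc (IKK, IKKK_IL1), which (i) titrates HSPi away from
the HSF1:HSPi complex, releasing HSF1, and (ii) feeds the repair
flux (complex → neutral kinase + chaperone). HSF1 activation is
therefore slaved to kinase damage, and becomes step-like in
temperature (near-basal ≤ 40 °C, high ≥ 41 °C) because the free HSPi
pool is small compared to the kinase pools: the cubic trimerization
plus the Hill term sharpen the transition further. Chaperones also
accelerate the IKK active→inactive→neutral cycle (weak terms
`k_ikk_inact_hsp`, `k_ikk_reset_hsp`; large values were found to
suppress post-recovery responses outright, so the defaults are small).

### Protocols

Simulations are phase-stitched: the stiff solver restarts at every
discontinuity (temperature step, cytokine on/off), so events never fall
inside a solver step. The canonical protocol is (i) 1 h heat shock at
38–43 °C, (ii) recovery at 37 °C (0–8 h), (iii) 10 h cytokine window at
37 °C; repeated-shock protocols insert a second identical 1 h exposure
with the cytokine applied immediately after it. Reported time is hours
from cytokine onset; pre-stimulation phases carry negative times and
are kept, flagged by phase metadata. HSF1 knock-down scales every
HSF1-containing pool by (1 − fraction), 0.95 by default, and
re-equilibrates the cell before the protocol.

### Ensembles

Heterogeneity is extrinsic only: per cell, the IKK, IKKK_TNF, IKKK_IL1,
HSPc and HSF1 totals are drawn log-normal (μ = 11.5/11.5/11.5/10.1/9.2,
σ = 0.15; medians e^μ ≈ 98 700, 24 300 and 9 900 molecules) with
independent draws for the two IKKK pools (a `correlate_ikkk` flag
switches to a shared draw); total NF-κB is fixed at 10⁵. Every cell is
equilibrated at 37 °C for 200 h of model time before phase (i), so each
starts from its own resting state. Per-cell RNG substreams are spawned
from the root seed, making results independent of execution order.

## Calibration

The shipped parameter values are the package's own calibration: the 60
rates were tuned (nominal cell first, ensembles as confirmation)
against the characteristic quantitative behaviour of the MCF7 system —

* TNFα control: first nuclear-NF-κB peak ≈ 0.5 h after stimulation,
  damped oscillations with period ≈ 1.5–2 h, 1–2 mean-trajectory peaks;
  IL1β control: one dominant translocation;
* first-peak attenuation immediately after 1 h at 41/42 °C: 56%/31% of
  control for TNFα (ensemble means at n = 200 land at 57%/28–31%
  depending on seed), no appreciable attenuation for IL1β at 41 °C;
* TNFα recovery after 43 °C monotone over 0/1/2/4 h and still below
  control at 4 h; IL1β fully recovered by 4 h;
* insoluble IKK maximal at the end of the shock, < 5% of total by 4 h;
  IKKK_TNF recovering more slowly than IKKK_IL1;
* 95% HSF1 knock-down freezing TNFα (but not IL1β) recovery;
* thermotolerance: a second 43 °C shock 4 h after the first leaves the
  TNFα response indistinguishable from the single-shock/4 h-recovery
  response, while a 2 h interval does not.

Counts are model currency; only ratios and kinetics were calibrated.

"Indistinguishable" is operationalized as ensemble-mean first peaks
differing by less than 10% of the reference mean. A pooled-SD criterion
was considered and rejected: with only four totals randomized at
σ = 0.15, per-cell first-peak amplitudes have SDs of 2–9% of the mean,
so ±0.5 SD would demand sub-2% equality — far beyond what the
imaging-level "not significant" calls it mirrors could resolve.

## Numerics

LSODA (stiff-capable, variable order) with rtol 10⁻⁶ and atol 10⁻²
molecules; output grid 0.05 h; the compiled (numba) right-hand side
makes one 15 h multi-phase cell ≈ 10 ms, so 200-cell ensembles run in
seconds. Tiny negative solver undershoots are clipped at output.
Steady state is declared when max|dx/dt|/max(x, 1) < 10⁻⁶ h⁻¹ after up
to five 200 h stretches; failure raises with the residual. Conservation
is verified in tests to 10× the solver's relative tolerance across full
multi-phase runs.

Desk-scale defaults: the test suite runs its ensembles at n = 200 and
the sensitivity screen on a reduced grid (two parameters per contrasted
group, factors {¼, 1, 4}, 4 temperatures, n = 50); the library defaults
are n = 1000 ensembles and 7 log2-spaced factors spanning [1/8, 8]
(the symmetric reading of an "8-fold range").

## Trajectory metrics

Peak calling: quadratic Savitzky–Golay smoothing (window 5 frames),
then local maxima with prominence above
max(0.2 × condition-set median first-peak amplitude, 4 × σ̂) and at
least 30 min apart, where σ̂ is a per-trace noise scale from the median
absolute second difference (second differences cancel smooth trends, so
σ̂ ≈ 0 on noise-free model output). The condition-set median is found
in a provisional per-trace pass, making the pipeline scale-equivariant:
scaling all trajectories by c scales AUC/amplitudes by c and changes no
count, call or rank statistic. AUC is the trapezoid of the
baseline-subtracted signal floored at 0 over the 10 h window; the
baseline is the pre-stimulation mean (first 3 frames if no
pre-stimulation samples exist); time-to-first-response is the first
crossing of baseline + max(3 × pre-stimulation SD, half the prominence
threshold). Heat-map display divides all conditions of a comparison
set by one shared maximum (×3), rows ordered by response time then
AUC.

Statistics follow the field's conventions: D'Agostino–Pearson
normality per group, tie-corrected Kruskal–Wallis, Dunn's pairwise
pooled-rank z tests with Bonferroni adjustment over all pairs (the
convention of the common commercial implementation; adjusted p never
below unadjusted), chi-square without continuity correction on
responder contingency tables, and the usual `*/**/***/****/ns` tiers.
Dunn's test is implemented in-package (no maintained dependency
provides it here) and is checked against a brute-force rank oracle.

## Synthetic imaging data

The generator emulates nuclear-fluorescence time-lapse traces: per
cell, a translocation count from the regime's distribution, a
first-peak amplitude from a lower-truncated normal whose
post-truncation mean equals the calibrated mean exactly (truncation at
20 a.u. ≈ a detectable-translocation floor; calibration errors > 5%
of the mean raise), a response delay, geometric damping of successive
peaks, log-normal-in-time pulses (asymmetric rise/decay) on a flat
baseline, and additive Gaussian noise (default SD 5 a.u., frame
interval 5 min, 121 frames over 10 h — a typical cadence, chosen by
the package). Calibrated anchors: TNFα control 101 ± 44 a.u., ~50% of
cells ≤ 3 peaks and none > 5; IL1β control 80% single-translocation;
TNFα after 4 h recovery ~90% of cells ≥ 5 peaks (50% after 2 h).
Regime parameters with no published value (delays, damping, pulse
shape, suppressed-regime scales) are synthetic conventions, labelled
as such in the code.

What passing tests on these fixtures shows: the metrics pipeline
recovers planted counts/amplitudes/timings under realistic noise, and
the statistics behave on data with the reported summary structure.
What it cannot show: distributional identity with real imaging data —
no photobleaching, background drift, segmentation error, or cell-cycle
structure is modelled.

## Known limitations

* The kinetic parameters are a calibration, not a fit to raw data; any
  quantity not in the calibration-target list above is an
  extrapolation of the structure, not a validated prediction.
* Heterogeneity is extrinsic only — no reaction noise, division or
  parameter variability — so ensemble spreads are narrower than
  imaging data (amplitude CV ~5–10% vs ~40% observed).
* Receptor-level detail (internalization, adaptor complexes) is
  collapsed into two-state receptor activities and generic IKKKs.
* The temperature function is only calibrated on 37–43 °C; inputs
  outside that range are rejected rather than extrapolated.
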