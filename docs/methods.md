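# Methods

## The model

`celiacqsp` implements a quantitative systems pharmacology (QSP) model of
the immune response to dietary gluten in celiac disease (CD). The disease
state is described by 16 ordinary differential equations,

    dx/dt = N · v(x),    x(0) = x0,

where `x` collects the species concentrations, `v(x)` the reaction
velocities and `N` the integer stoichiometric matrix (16 species × 31
processes). Time is measured in days; concentrations are in arbitrary
units whose scale is pinned by the observable normalisation (below).

The network couples two arms:

* **Innate arm.** Gluten peptides in the lumen bind IEC receptors and
  activate them (r5). Activated IECs secrete zonulin (r31), which opens
  tight junctions, and IL-15 (r7). IL-15 activates intraepithelial
  lymphocytes into natural killers (r11) and arrests their apoptosis
  (r10). Activated IELs, IF-21 and antibodies drive IEC apoptosis (r4,
  r6); antibodies additionally inhibit IEC maturation (r3).
* **Adaptive arm.** Zonulin and the epithelial deficit additively increase
  paracellular transport of peptides into the lamina propria (r13), where
  TG-2 deamidates them (r33). Native and deamidated peptides (the latter
  with a 5-fold lower EC50) activate DQ2/DQ8 APCs (r18), which are
  differentiated from monocytes partly under IL-15 control (r16).
  Activated APCs secrete IL-15 and activate T cells through a transient
  compartment (r22, r34) that models the delay from T-cell activation and
  B-cell affinity maturation. Activated T cells and activated IELs secrete
  IF-21 (r23), a single pool standing for IFN-γ + IL-21 (their synthesis,
  action and degradation are similar; the pool's degradation constant is
  the mean of the two). Antibody synthesis (r25) depends on activated
  T cells and the lamina peptide level only.

Merged/simplified species: Th1 and Th17 are one T-cell variable; IFN-γ and
IL-21 are one IF-21 variable; the TG-2–peptide complex is folded into the
deamidated-peptide pool `dGlut`; TG-2 itself is a constant level (a
parameter), not a dynamic species. This yields exactly 16 state variables
and 54 parameters.

**Healthy variant.** Healthy subjects carry no DQ2/DQ8 APCs and mount
neither response: the APC equations are removed (14 states) and the IEC-
and IEL-activation velocities are identically zero. Consequently the
healthy model relaxes, on any diet, to a state with zero activated cells,
cytokines, zonulin and antibodies and a full epithelium — which anchors the
villous-area scale.

## Observables and normalisation

* `villous_area_pct = 100 · IEC / IEC_healthy`. The mature-IEC level is
  the model's only villous-mass proxy; every villous-area statement the
  model makes is driven by IEC death and maturation.
* `antibody_pct = 100 · Ab / Ab_ref`, with `Ab_ref` the antibody level at
  the untreated gluten-diet steady state (so the untreated patient reads
  100% by construction).

Calibration anchors: villous area 100% (healthy), 50% (gluten-free diet,
GFD) and 10% (gluten diet); antibody ~0% on a GFD; antibody decay below 5%
within 2–3 months of a gluten→GFD switch and rise above 10% within 2 weeks
of a GFD→gluten switch.

## Rate-law choices

Each law realises one stated regulatory fact with the fewest parameters:

* IEC activation uses a steep Hill term (h = 4) in lumen gluten,
  modelling the receptor-occupancy threshold. The half-occupancy constant
  is placed *below* the trace-gluten level of a GFD (< 20 ppm
  contamination), i.e. the patient innate arm is constitutively active on
  any diet. This is a deliberate design decision forced jointly by three
  facts: villous damage persists on a GFD (50% of healthy, attributed to
  IELs and IFN-γ), complete APC blockade on a gluten diet leaves the villi
  at essentially the GFD level (51%), and the antibody response under
  complete TG-2 inhibition collapses at native/deamidated EC50 ratios ≥ 80.
  With an activation threshold *above* GFD gluten levels, the GFD damage
  would have to flow through the APC arm, whose single saturating response
  cannot simultaneously be high at GFD peptide levels and low at the
  (larger) ratio-80 native-only drive.
* Paracellular transport is `(kz·Zon + ki·max(0, 1 − IEC/IEC_healthy)) ·
  Glut_lum`: additive zonulin and epithelial-deficit contributions, exactly
  zero for a zonulin-free, intact epithelium.
* APC activation sums two *cooperative* (Hill-2) antigen terms,
  `x²/(EC50² + x²)`, for native and deamidated peptides, with EC50s in a
  fixed 1:5 ratio by default (the native EC50 is a "calculated" parameter
  tied to the deamidated one). The sigmoidal onset — response vanishing
  quadratically at low antigen — is essential, not cosmetic: with simple
  Michaelis terms the native arm has its *maximal* marginal sensitivity at
  zero concentration, which makes the antibody level rise slightly at
  small TG-2-inhibitor doses (non-monotone dose-response) and bounds the
  achievable contrast between the ratio-5 and ratio-80 EC50-scan states
  well above the observed collapse. Cooperative binding restores strict
  monotonicity and lets an 80-fold EC50 ratio silence the antibody arm,
  while the EC50 parameters keep their exact meaning as half-activation
  concentrations.
* Activated-IEL apoptosis is inhibited by IL-15 (`kd/(1 + IL15/Ki)`), IEL
  activation is a Hill function of IL-15 (h = 2).
* T-cell activation is amplified (not gated) by IF-21; antibody synthesis
  saturates in the lamina peptide level.
* All soluble species degrade first-order.

## Parameters

The 54 parameters carry provenance tags mirroring their origin: 17
literature, 2 assumed (the two Hill exponents), 4 calculated (GFD inflow
from the contamination ratio, healthy IEC level, IEC maturation flux =
`kd_iec · IEC_healthy`, native EC50 = 5 × deamidated EC50) and 31 fitted.
The packaged values of the fitted parameters were obtained with the
package's own Hooke–Jeeves search (log10 space, staged with successively
smaller initial steps, shrink 0.5) against a weighted SSE over the anchors
above plus the predicted endpoints of the five interventions and the
EC50-scan collapse point, with hinge penalties enforcing dose–response
monotonicity.

Fitted parameters ship with 95% confidence intervals used by the
robustness scan. They are one-dimensional profiles of the calibration SSE
(F-threshold rule, most conservative degrees of freedom) searched within a
factor-2 box around each estimate: the anchor set is far smaller than the
fitted-parameter count, so most directions are only weakly identified and
their intervals truncate at the box — an honest statement that the
printed anchors pin combinations of parameters rather than each parameter
individually.

Key defaults: gluten-diet inflow 10 au/d and GFD inflow 0.02 au/d (a
1:500 contamination ratio, consistent with < 20 ppm gluten in naturally
gluten-free foodstuffs against a normal diet); antibody degradation
0.04 /d (IgG-scale half-life ≈ 17 d), which sets the 2–3 month decay
window; cytokine turnover of order 2 /d; epithelial turnover 0.2 /d.

## Interventions

Drugs are parameter changes, not PK/PD models; `strength` ∈ [0, 1] is an
abstract effect size with 1 = complete effect:

| kind                   | parameter effect at strength s      |
|------------------------|-------------------------------------|
| tg2_inhibitor          | TG-2 level × (1 − s)                |
| ifng_antibody          | IF-21 degradation × 1/(1 − s)       |
| il15_antibody          | IL-15 degradation × 1/(1 − s)       |
| permeability_inhibitor | IEC activation constant × (1 − s)   |
| dq2_blocker            | APC activation constant × (1 − s)   |

At strength 1 the degradation scale is capped at 10⁶ (finite ODE; the
cytokine level is then numerically zero, the intended limiting case).
Endpoints are the new steady states reached from the untreated gluten-diet
state; a fixed treatment duration would be arbitrary,
so steady state is the defined endpoint.

The EC50-ratio scan fixes the deamidated EC50, sets the native EC50 to an
increasing multiple r ≥ 1, re-validates the model at each r by a 1-D re-fit
of the antibody synthesis constant (restoring the untreated antibody
level — a fixed-point rescale, since the level is nearly proportional to
the constant), and records the residual antibody under complete TG-2
inhibition.

## Numerics

* Integration: LSODA with rtol 1e-8, atol 1e-10. The solver may dip a few
  atol below zero; trajectories are clipped at zero on output. Every rate
  law consuming a species vanishes with that species, so the flow is
  non-negative up to solver error.
* Steady states: Powell-hybrid root solving on the (scaled) right-hand
  side from a supplied guess, with rejection of negative or non-steady
  roots and an integrate-then-polish fallback (up to ~16 simulated years).
  Steady states are verified against long integrations to 0.5% per
  component.
* Calibration: Hooke–Jeeves pattern search in log10 parameter space
  (defaults: step 0.25, shrink 0.5, tol 1e-4, ≤ 10⁴ iterations), box
  bounds enforced by clipping. Simulation failures return a finite penalty
  (1e6) so the search retreats. The SSE is deterministic given data.
* Confidence intervals: profile likelihood with the threshold
  `SSE_min · (1 + F₀.₉₅(1, n − p)/(n − p))`, others re-optimised with a
  reduced-budget search; profiles that never cross inside the search box
  are reported at the box bound and flagged. For a linear model this
  reproduces the exact t-based interval.
* Robustness: independent uniform draws inside each 95% CI box (the
  simplest faithful reading of sampling "from the confidence intervals"),
  references recomputed per draw, failed draws recorded rather than fatal,
  fully reproducible per seed.

## Synthetic observations

`synth_observations` simulates a design (lists of condition/observable
pairs) at known parameters and applies multiplicative lognormal noise with
a prescribed coefficient of variation and unit median. It emulates the
*shape* of the data the model was historically fitted to — scalar
steady-state and transient read-outs under different diets and
interventions — but not their biological replication structure
(inter-patient variability, assay-specific error, censoring). Passing
parameter-recovery tests on such data therefore demonstrates
identifiability and correctness of the estimation machinery, not clinical
validity of the parameter values.

## Problem sizes in the shipped tests

The test-suite and acceptance runs use the full 16-state model throughout;
steady states take milliseconds, so no reduction is needed. Sampled
checks use 100 random states (stoichiometry oracle), 100 CI-box draws
(non-negativity), 25–50 robustness draws and a 7-point EC50 grid; the
parameter-recovery and CI-coverage tests use 1–2 free parameters on small
designs to keep the default run in minutes.

## Known limitations

* Oral-tolerance breakdown, transcellular (vesicular) peptide transport
  and non-DQ2/DQ8 response routes are intentionally outside the model.
* Meals are a constant inflow, not discrete events; no spatial intestinal
  geometry.
* Drugs have no pharmacokinetics; `strength` is not a dose.
* The packaged rate laws realise the documented regulatory facts with
  minimal functional forms, and the packaged parameter values are this
  package's own calibration against the quantitative anchors above. Quantities far from those anchors (e.g. absolute
  cytokine levels) are not identifiable and should be read only through
  the normalised observables.
* Endpoint predictions of the cytokine antibodies on villous area are the
  least robust to parameter uncertainty;
  the robustness scan exists to make that visible.
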