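# celiacqsp

A quantitative systems pharmacology (QSP) model of the immune response in
celiac disease (CD), for researchers exploring candidate therapies of
autoimmune small-intestine disorders in silico.

Celiac disease is an autoimmune disorder of genetically predisposed
(HLA DQ2/DQ8) individuals in which dietary gluten triggers intestinal
villous atrophy; the only established treatment is a lifelong gluten-free
diet (GFD). `celiacqsp` models the innate arm (gluten-activated epithelium,
zonulin-driven permeability, IL-15, natural killers) and the adaptive arm
(TG-2 deamidation of gluten peptides, DQ2/DQ8 antigen-presenting cells,
T cells, antibodies) as a 16-state kinetic network,

    dx/dt = N · v(x; p),

with stoichiometric matrix `N`, non-negative rate laws `v` and 54 kinetic
parameters `p`. Disease severity is read out as two normalised
observables: the **villous area** (% of a healthy subject, proxied by the
mature epithelial-cell level) and the **antibody level** (% of the
untreated gluten-diet steady state). Candidate drugs — a TG-2 inhibitor,
anti-IFN-γ and anti-IL-15 antibodies, a permeability inhibitor and
DQ2-blocking gluten-peptide analogues — are modelled as parameter changes
and scored by the steady state they drive the patient to.

Parameters are calibrated by minimising a sum-of-squares error with the
Hooke–Jeeves pattern search; 95% confidence intervals come from profile
likelihood, and a robustness scan samples the confidence boxes to expose
prediction uncertainty. See `docs/methods.md` for the model, assumptions
and numerical choices.

## Worked example

```python
from celiacqsp import (
    InterventionSpec, compute_references, default_parameters,
    intervention_endpoint, ec50_ratio_scan,
)

params = default_parameters()          # packaged, calibrated 54-parameter set
refs = compute_references(params)      # healthy + gluten-diet steady states

for kind in ("tg2_inhibitor", "il15_antibody", "dq2_blocker"):
    obs = intervention_endpoint(params, InterventionSpec(kind, 1.0), refs=refs)
    print(f"{kind:16s} antibody {obs.antibody_pct:5.1f}%  "
          f"villous area {obs.villous_area_pct:5.1f}%")

print(ec50_ratio_scan(params, [5, 80], refs=refs)
      [["ratio", "antibody_pct"]].to_string(index=False))
```

prints (values recomputed at run time)

```
tg2_inhibitor    antibody  76.8%  villous area  14.7%
il15_antibody    antibody  68.5%  villous area  45.1%
dq2_blocker      antibody   0.0%  villous area  49.8%
 ratio  antibody_pct
   5.0     76.812974
  80.0      0.587315
```

Complete TG-2 inhibition leaves most of the antibody response intact
(deamidation makes peptides more immunogenic but native peptides still
activate APCs) and barely improves the villi, whereas blocking antigen
presentation (DQ2 blocker) abolishes antibodies and restores the villous
area to GFD-like levels. The scan's second row shows the TG-2 inhibitor
*would* work if deamidated peptides were ≥ 80-fold more potent than native
ones: the residual antibody level collapses.

The same operations are available from the command line:

    celiacqsp steady --variant healthy
    celiacqsp treat --kind dq2_blocker --strength 1 --grid 0,0.5,1
    celiacqsp simulate --protocol gluten:0,gfd:30 --horizon 365
    celiacqsp scan-ec50 --ratios 1,5,10,20,40,80,160
    celiacqsp robustness --kind tg2_inhibitor --n-draws 50 --seed 1
    celiacqsp export-sbml --variant patient

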