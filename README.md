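# spt07a-pbpk

Whole-body physiologically-based pharmacokinetic (PBPK) modelling and
in-vitro-to-in-vivo extrapolation (IVIVE) for **SPT-07A**, a D-borneol in
clinical development for ischemic stroke. SPT-07A is cleared almost
entirely by UGT-mediated glucuronidation, with substantial extrahepatic
(renal and intestinal) metabolism — exactly the situation where empirical
allometry is unreliable and a mechanistic, organ-resolved model earns its
keep. The package is written for DMPK scientists who want to go from
microsomal assay data to human concentration–time predictions with every
intermediate step exposed, tested, and overridable.

## What it computes

**From in vitro to organ clearance.** Substrate-depletion time courses are
fitted as ln C = ln C₀ − k·t; the unbound microsomal intrinsic clearance is

    CLint,u = k / (Mic · fu,mic)        [µL/min/mg protein]

which is scaled to the whole organ with microsomal protein content
(MPPGL/MPPGK/MPPGI, mg/g) and organ weight (OW, g/kg),

    CLint,in vivo,u = CLint,u · MPPGx · OW / 1000    [mL/min/kg]

and converted to a blood clearance with the well-stirred model
(fu,b = fu,p/Rb, Q = organ blood flow per kg):

    CLb = Q · fu,b · CLint,in vivo,u / (Q + fu,b · CLint,in vivo,u)

UGT isoform contributions use the relative activity factor method
(RAF = probe clearance in microsomes / in the recombinant enzyme;
fm = RAF · rhCLint,u / CLint,u,mic).

**The whole-body model.** Fourteen compartments (lung, heart, brain,
muscle, skin, kidney, spleen, stomach, liver, intestine, rest of body,
adipose, arterial and venous blood) connected by the tabulated blood
flows, with perfusion-rate-limited tissues (venous outflow concentration
C_t/(K_t:pl/Rb)), a permeability-limited two-pool adipose (vascular V₁,
extravascular V₂, exchange conductance PS), and elimination in liver,
kidney, and intestine at rate CLint,in vivo,u · W · fu,p · C_t/K_t:pl.
Rat, dog, and human physiologies (0.25 / 8.5 / 70 kg) ship as package
data; PS scales between species linearly with body weight.

On top of the core model: noncompartmental analysis (Cmax, AUC, CL,
λz, t½), virtual-population simulation with 5th–95th percentile bands,
one-at-a-time parameter sensitivity, Dedrick interspecies scaling
(single-species and two-species variants with fixed or fitted allometric
exponents), and synthetic-data generators that emulate every assay the
workflow consumes.

## Worked example

```python
import numpy as np, pandas as pd
import spt07a_pbpk as pk
from spt07a_pbpk.pbpk import SAMPLING_SCHEDULES

cfg = pk.load_species("human")
table = pk.build_clearance_table(cfg)
for organ in ("liver", "kidney", "intestine"):
    print(f"{organ:9s} {table.cl_b[organ]:8.3f} {table.f_cl[organ]:8.1%} {table.er[organ]:6.2f}")
print(f"total CLb = {table.cl_b_tot:.1f} mL/min/kg")

model = pk.build_model(cfg)
regimen = pk.DoseRegimen("iv_infusion", 10_000.0, infusion_duration=60.0)  # 10 mg / 1 h
sched = np.asarray(SAMPLING_SCHEDULES["human"], float)
res = pk.simulate(model, regimen, t_end=720.0, dt_out=720.0, t_eval=sched)
profile = pd.DataFrame({"time_min": sched,
                        "conc_ng_ml": np.interp(sched, res.times, res.plasma)})
s = pk.pk_summary(profile, dose_per_kg=10_000.0 / 70.0)
print(f"Cmax = {s.cmax:.1f} ng/mL at t = {s.tmax:.0f} min")
print(f"AUCinf = {s.auc_inf:.2f} ug*min/mL, CL = {s.cl:.1f} mL/min/kg, t1/2 = {s.t_half:.0f} min")
```

prints

```
liver       20.364    76.5%   0.94
kidney       6.140    23.1%   0.35
intestine    0.109     0.4%   0.01
total CLb = 26.6 mL/min/kg
Cmax = 69.8 ng/mL at t = 60 min
AUCinf = 5.98 ug*min/mL, CL = 23.9 mL/min/kg, t1/2 = 182 min
```

Reading: human liver dominates SPT-07A elimination (76.5% of a 26.6
mL/min/kg total blood clearance, hepatic extraction ratio 0.94 — a
high-extraction, flow-limited drug), the kidney contributes 23.1%, and a
10 mg one-hour infusion peaks at ~70 ng/mL at the end of the infusion
with a terminal half-life of ~3 h governed by slow adipose washout.

The same pipelines are reachable from a thin CLI
(`spt07a-pbpk ivive|simulate|population|sensitivity|dedrick|synthesize|validate`),
e.g.

```sh
spt07a-pbpk simulate --species human --dose-mg 10 --infusion-min 60 --out profile.csv
spt07a-pbpk sensitivity --out sensitivity.csv
```

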