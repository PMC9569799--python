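# radfate

A coupled simulator of DNA double-strand-break (DSB) repair kinetics and
p53-mediated cell fate for cells in G0/G1 exposed to ionizing radiation.

Densely ionizing (high-LET) radiation produces *complex* DSBs — breaks
accompanied by additional strand breaks within ~10 bp — which, together
with heterochromatic location, route damage into the slow,
resection-dependent branch of non-homologous end joining (NHEJ). Because
the p53 damage-response network senses the *live* number of unrepaired
DSBs, repair kinetics — not just the initial damage count — shapes cell
fate: cycle arrest, apoptosis, and TGFβ secretion. `radfate` models that
chain end to end:

1. **damage** — synthetic DSB sets (Poisson in dose, uniform in a
   spherical nucleus, Bernoulli complexity/chromatin labels) and a 10 bp
   strand-break pairing/complexity classifier.
2. **compartments** — the slow-fraction model
   `F_slow = HC + (1 − HC)·DSB_complex,EC`, the X-ray–referenced excess
   slow fraction `ExF_slow = (F_slow − F_slow^X)/(1 − F_slow^X)`, the
   fitted complexity map `ExF_slow = 0.8268·DSB_c + 0.0705`, per-DSB
   pathway assignment, and least-squares fitting utilities.
3. **repair** — a stochastic per-end protein-recruitment state machine
   (Ku70/80 → DNA-PKcs → synapsis within 100 nm → autophosphorylation →
   either XRCC4/LigIV ligation, or CtIP/EXO1/Artemis resection, pol μ/λ
   fill-in and ligation), with Brownian end diffusion in a reflecting
   nucleus and per-step firing probability `1 − exp(−k·Δt)`.
4. **p53net** — the p53 network (ATM Hill activation
   `dATM_act/dt = k·ATM_0·DSB²/(DSB² + M²)`, p53 arrester/killer
   phosphoforms, Mdm2/Wip1 negative feedback, p21→cyclin E arrest,
   Bax/Akt apoptosis, p21–GADD45–p38–TGFβ secretion) integrated
   deterministically (LSODA) or exactly stochastically (Gillespie),
   driven by the repair module's unrepaired-DSB count.
5. **fate** — per-cell readouts (apoptosis, arrest duration, cumulative
   TGFβ) and the dose × slow-fraction × M factorial ensemble sweep.

## Worked example

```python
import radfate as rf
from radfate.p53net import build_network, simulate_deterministic
from radfate.repair import RepairParams

damage = rf.generate_damage(2.0, seed=3)                      # 2 Gy, 40 DSB/Gy
damage = rf.assign_pathways(damage, seed=103, forced_f_slow=0.2)
repair = rf.simulate_repair(damage, RepairParams(t_max=72*3600), seed=203)
traj   = simulate_deterministic(build_network(), repair, t_max=72.0)
```

Running `python examples/03_p53_oscillations.py` (the same computation)
prints:

```
65 DSBs, last repaired at 15.2 h
p53_arrester  peaks at 1.1, 8.7 h (max 121 copies)
Mdm2          peaks at 2.9 h (max 98 copies)
Wip1          peaks at 2.5, 10.1 h (max 51 copies)
```

65 DSBs were drawn for this 2 Gy exposure; with 20% of them in the slow
compartment the damage clears by ~15 h, and while it persists the
phosphorylated p53 pulses repeat every ~8 h (here 1.1 h → 8.7 h), the
relaxation oscillation generated by the ATM–p53–Mdm2/Wip1 feedback
loops. `examples/` contains one short script per capability (damage
classification, repair curves and their biexponential read, single-cell
stochastic fate, the ensemble sweep); each prints what it computes and
what the numbers mean. A thin CLI mirrors the pipeline
(`radfate damage|repair|p53|fate|sweep|fixtures`).

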