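# Methods

## Scope and model chain

`radfate` simulates the response of a G0/G1 cell to ionizing radiation
through three coupled layers: a parametric damage generator, a
stochastic NHEJ repair simulator, and a p53 regulatory network driven
by the live unrepaired-DSB count. The repair layer feeds the network
one-way; the model contains no feedback from signalling onto repair
rates.

## Damage generation and complexity

The generator replaces a Monte Carlo track-structure chain with its
summary statistics: the DSB count is Poisson with mean `dose ×
dsb_yield` (default 40 DSB/Gy, a standard mammalian yield), positions
are uniform in a spherical nucleus (default radius 5 µm), and each DSB
independently receives a complexity label (probability
`complex_fraction`) and a chromatin label (probability `hc_fraction`,
default 0.2). LET enters only through `complex_fraction`: densely
ionizing radiation is emulated by raising the complex share, not by
spatially clustering breaks. What the generator deliberately does not
reproduce: chromosome-territory geometry, correlated lesion clusters
along tracks, base damage, or SSB-only lesions. Consequently, tests
passing on this generator demonstrate the *pipeline's* behavior under
the stated statistical assumptions, not fidelity to any measured damage
spectrum.

When explicit strand-break lists are supplied, DSBs are called by
greedy left-to-right pairing of opposing-strand breaks within an
inclusive 10 bp window (nearest partner, ties to the lower index, each
break used once), and a DSB is complex iff any additional break lies
within 10 bp of the pair midpoint. The midpoint anchor is a
convention choice; the window is deliberately inclusive, the most
conservative reading of "within 10 bp".

## Compartment model

`F_slow = HC + (1 − HC)·DSB_complex,EC` with both factors independent;
the X-ray–referenced excess slow fraction `ExF_slow` removes the
cell-line-specific HC algebraically. The fitted complexity map
(slope 0.8268, intercept 0.0705) is clipped to [0, 1] since it predicts
a probability. Sweep mode assigns pathways per-DSB as Bernoulli(F_slow)
rather than by deterministic quota, preserving the cell-to-cell
variability the stochastic fate ensemble relies on.

## Repair state machine

Both pathways share Ku70/80 binding (`k1 = 1/0.1 s⁻¹`), DNA-PKcs
recruitment (`k2 = 1/3 s⁻¹`), synapsis, and DNA-PK autophosphorylation
(`k3 = 1/72 s⁻¹`). The fast branch then recruits XRCC4/Ligase IV
(`k4 = 1/180 s⁻¹`) and ligates (`k5 = 1/240 s⁻¹`). The slow branch
requires CtIP (`k7 = 1/7 s⁻¹`) and EXO1 (`k8 = 1/1.2 s⁻¹`) clocks
started at Ku binding, Artemis arriving with DNA-PKcs, then two
resection stages (`k9 = 1/1000`, `k10 = 1/450 s⁻¹`), pol µ/λ fill-in
(`k11 = 1/14400 s⁻¹`) and ligation (`k12 = 1/6545 s⁻¹`). `k6` is
carried as an alternate long-time constant but unused by the default
chain. This k-to-step mapping honors the stated recruitment-order
constraints but is one admissible reading; it is configurable in
`RepairParams`. With Artemis inactive the slow branch stalls before
resection permanently.

Numerics: each step fires with probability `1 − exp(−k·Δt)`, exact for
exponential waiting. The base step is 0.01 s (resolving `k1`); by
default the step grows adaptively so that `k_max·Δt ≤ 0.02` for the
fastest currently-active rate, capped at 60 s, and at 1 s while
unsynapsed DNA-PK-bound ends exist (synapsis search resolution).
Fixed-step mode is available; halving the accuracy cap changes
ensemble-mean half-times by well under 2%. Unsynapsed ends diffuse at
1 nm²/s with radial reflection at the nuclear envelope; synapsed pairs
advance as one entity with a single post-synapsis clock per step.
Their diffusion coefficient (100 nm²/s) is carried in the parameters
but pair positions are not propagated: in this model no observable
depends on them (no aberration scoring). Synapsis joins the nearest
eligible end within 100 nm, so wrong-partner joins occur at high DSB
density and are logged (`correct_partner`).

## p53 network

The network is a single list of elementary channels (mass-action, with
Hill-type transcriptional modifiers) shared verbatim by both engines;
the deterministic engine integrates the mean-field equations (LSODA,
forcing discontinuities aligned with integrator restarts), the
stochastic engine runs the exact Gillespie direct method with the
piecewise-constant DSB count interleaved as external events.

Input stage: ATM activates by intermolecular autophosphorylation — a
small DSB-gated seed channel (`k·ATM_i·DSB²/(DSB²+M²)`, the documented
Hill form, exponent 2) plus an autocatalytic channel
(`k_auto·ATM_i·ATM_p·Hill(DSB)`) that makes activation switch-like once
seeded. `ATM_0` is read as the instantaneous inactive pool, so
activation halts when the pool empties and total ATM is conserved; `M`
is configured in Gy-equivalents (defaults 0.14, converted at 40
DSB/Gy). Wip1 deactivates ATM_p cooperatively (Hill, n = 4), giving the
ATM module a sharp off-switch. Active ATM phosphorylates p53 to the
arrester form and the arrester further to the killer form; Wip1
reverses both; Mdm2 degrades free p53 strongly and the phosphoforms
weakly. The arrester induces Mdm2, Wip1 and p21 transcription; p21
represses cyclin-E synthesis (arrest) and drives GADD45 → p38 → TGFβ
secretion; the killer induces Bax and represses the pro-survival Akt
pool, which otherwise clears Bax.

The emergent dynamics: while the DSB count is above roughly half of
`M`-scaled threshold, the ATM–p53–Wip1 loop executes relaxation
oscillations with ≈ 8 h period; each pulse converts a small amount of
arrester to the long-lived killer form (τ ≈ 55 h), so the killer level
integrates the pulse train. Longer damage persistence (higher dose,
larger slow fraction, smaller M) means more pulses, more killer, and a
higher chance of crossing the switch-like Bax/Akt thresholds —
apoptosis percentages therefore order monotonically in dose, F_slow,
and 1/M without any per-condition tuning.

Parameter provenance: every constant lives in
`src/radfate/data/p53_params.tsv` (name, value, unit, source tag);
nothing is hard-coded. The set was calibrated once, as a whole, to the
stated target behaviors — ~8 h pulse period at 2 Gy/20% slow, ATM_p
amplitude within 10% between 2 and 8 Gy, near-zero apoptosis without
irradiation, and monotone fate orderings — and is not adjusted per
run. Copy-number scales are deliberately modest (10²–10³) so that
single-cell stochasticity is visible; `ReactionNetwork.scaled(omega)`
rescales toward the thermodynamic limit for engine-agreement studies.

## Fate readouts

Apoptosis: first upward crossing of Bax above 5× its basal level
before 72 h, treated as irreversible. Arrest: total time cyclin E
spends below 10% of basal. TGFβ: trapezoidal time integral
(copy·hours). The 72 h horizon is the sweep's readout time. Ensembles
use counter-based per-cell seeds
(`SeedSequence(master, spawn_key=(condition, cell))`), so results are
independent of execution order and bit-reproducible.

## Numerical and statistical choices

- Oscillation period: mean of all peak-to-peak intervals of
  phosphorylated p53 (prominence ≥ 15 copies), pooled over several
  damage realizations. At 2 Gy/20% slow the damage window supports only
  2–3 pulses per cell, so pooling across realizations is required for a
  stable estimate; the first interval is retained because transcription
  of Wip1 saturates in every pulse, making the first cycle statistically
  like the rest.
- Engine agreement (SSA vs ODE) is assessed over the first-pulse window
  at 10× copy scaling. Beyond ~1.5 periods the stochastic ensemble
  dephases — the mean of many oscillators decays even though each cell
  keeps oscillating — so mean-field agreement is only meaningful while
  the ensemble is phase-coherent.
- Biexponential reads of repair curves: the slow chain is a serial sum
  of four exponential stages; its survival is generalized-Erlang, whose
  4 h tail stage extrapolates to amplitude ≈ 1.8 at t = 0. A free
  least-squares two-exponential fit therefore overestimates the slow
  fraction by ~10–15% relative (≈ +0.03 at F_slow = 0.2 up to ≈ +0.12
  at 0.8); this is a property of the estimator, verified against a
  brute-force scan of the SSE landscape, not an implementation defect.
  The fitted fraction should be read as an upper bound.
- Problem sizes in the shipped tests and acceptance script (e.g. 25
  cells per sweep condition, 300–500 SSA runs, 1000-DSB Artemis sets)
  were chosen as the smallest ensembles whose statistical tolerances
  (3σ binomial/Monte-Carlo) remain meaningful.

## Known limitations

- No HR, alt-EJ, or cell-cycle-phase dependence; G0/G1 NHEJ only.
- Damage has no spatial correlation structure; misjoining rates at
  physiological densities are therefore lower bounds.
- The p53 network is a reduced, calibrated representation of the
  described topology: suitable for studying how repair kinetics shapes
  fate orderings, not for quantitative comparison with measured
  protein time courses.
- TGFβ is a scalar secretion readout; no tissue-level fibrosis or
  immune modelling.
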