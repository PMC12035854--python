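# fibrinpull

Forced unfolding of double-stranded fibrin oligomers, end to end: a
coarse-grained pulling simulator, sawtooth force–extension analysis, and a
machine-learning classifier that assigns unfolding events to structural
transition types.

Fibrin oligomers — two-stranded, half-staggered assemblies of fibrin
monomers — are the building blocks of blood clots. Under a stretching
force they unfold stepwise: the D–D interfaces between abutting monomers
open, and the globular γ-nodules unravel in stages, each step releasing
contour length and producing one tooth of a sawtooth force–extension
curve. Atomic force microscopy measures those sawtooth curves but cannot
see *which* structural transition produced each force peak. This package
implements the computational side of that problem for people who analyze
single-molecule pulling data: simulate the unfolding, extract and filter
the events, and decompose the measured (force, distance) distribution
into per-transition-type components.

## What is inside

- **`sop`, `pulling`** — the self-organized polymer (SOP) model: one bead
  per residue at the Cα position with potential
  `U = U_FENE + U_ANG + U_NB_att + U_NB_rep`
  (FENE bonds, `k` = 14 N/m, `R₀` = 2 Å; soft `ε(σ/r)⁶` repulsion on 1–3
  pairs and non-native pairs, `ε` = 4.2 kJ/mol, `σ` = 3.8 Å; 12-6
  Lennard-Jones native contacts, reference distance < 8 Å, well depth
  2.5–5.4 kJ/mol), integrated by overdamped Brownian dynamics at 298 K in
  water-like friction under a cantilever force ramp `f(t) = k_sp·v·t`
  (defaults `k_sp` = 110 pN/nm, `v` = 1 μm/s, i.e. 110 nN/s). Native-contact
  telemetry attributes force peaks to transition types and strands.
- **`fx`** — event extraction from force–extension curves: baseline-
  subtracted peak forces, peak-to-peak distances, rising-slope stiffness
  `K = df/dx`, and the selection rules used for AFM data (exclude > 500 pN
  absolute, > 200 pN over baseline, > 30 nm peak-to-peak; keep curves with
  ≥ 100 nm total extension), plus Freedman–Diaconis histograms and
  Gaussian-kernel density estimates with the Scott bandwidth `h = s·M^(−1/5)`.
- **`em`, `bigamma`** — a five-component mixture of bivariate Gamma
  distributions over (peak force `f`, peak-to-peak distance `x`), one
  component per transition type `j` = 0…4, fitted by
  Expectation-Maximization. Each component is built by trivariate
  reduction, `F = β(Y₀+Y₁)`, `X = β′(Y₀+Y₂)` with Gamma-distributed
  `Y₀ ~ Γ(λ)`, `Y₁ ~ Γ(α)`, `Y₂ ~ Γ(α′)`, so both marginals are Gamma and
  λ controls the force–distance dependence. The M step updates the moment
  block (μ_f, μ_x, σ_f, σ_x, σ_fx, π) by responsibility-weighted moments
  and converts it to (α, α′, β, β′, λ); iteration stops when every
  component's mean force moves < 0.1 pN.
- **`synthetic`** — generators for all inputs: mixture event samples whose
  default table carries the per-type simulation statistics (mean forces
  36.3/50.9/80.2/63.4/80.1 pN, mean distances 4.2/13.8/13.1/15.2/17.7 nm,
  priors 0.11/0.35/0.10/0.09/0.35 for types 0–4), sawtooth curves, and toy
  Cα structures (linear / helix / two-strand).
- **`pipeline`, `cli`** — orchestration with one global seed, plus a thin
  `fibrinpull` command (`synth`, `simulate`, `analyze-fx`, `fit-em`,
  `classify`, `report`, `pipeline`).

## Worked example

`examples/04_em_parameter_recovery.py` samples 5000 events from the
five-type mixture, perturbs all means by +10 % and lets EM walk back:

```
converged in 15 EM iterations

type  mu_f fit  mu_f true   mu_x fit  mu_x true   prior fit  prior true
  0       36.9      36.3       4.26       4.2      0.113       0.11
  1       52.0      50.9      14.06      13.8      0.385       0.35
  2       80.6      80.2      13.18      13.1      0.104       0.10
  3       66.1      63.4      15.06      15.2      0.103       0.09
  4       82.5      80.1      18.24      17.7      0.294       0.35

largest mean-force deviation 2.7 pN (4.3%)
```

Reading: each fitted row is one transition type — 0 is the D–D interface
opening, 1–3 the staged γ-nodule unraveling, 4 the mixed two-strand
events. The fitted means land on the generating values to a few percent;
the residuals concentrate in the strongly overlapping components (types
1, 3 and 4), which is the intrinsic identifiability limit of the mixture,
not noise in the optimizer. The other examples cover the sampler
calibration, sawtooth event extraction with the selection rules, a toy
two-strand pulling run with contact rupture, and the full pipeline with
its L1 density diagnostics.

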