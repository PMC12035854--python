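# Methods

This note records the models implemented in `fibrinpull`, the parameter
choices that matter, and the places where the design was genuinely open.

## The coarse-grained unfolding model

Each residue is one bead at its Cα position. The potential has four
terms:

- **FENE bonds** between consecutive beads of a chain (and any explicit
  cross-links, e.g. disulfides or γ–γ cross-links passed to
  `build_topology`): `U = −(kR₀²/2)·ln[1 − (r−r₀)²/R₀²]` with
  `k = 14 N/m` (84.3 kJ mol⁻¹ Å⁻² via the Avogadro constant) and
  tolerance `R₀ = 2 Å`. `|r−r₀| ≥ R₀` is a hard error: covalent rupture
  is outside the model.
- **1–3 angle constraint** on beads two covalent bonds apart and
  **non-native repulsion** on all remaining pairs, both the soft
  repulsion `ε(σ/r)⁶` with `ε = 4.2 kJ/mol`, `σ = 3.8 Å`. The published
  SOP convention uses this form for both terms; the constants above
  belong to it.
- **Native contacts**: 12-6 Lennard-Jones wells
  `ε_n[(r₀/r)¹² − 2(r₀/r)⁶]` for every pair with reference distance
  < 8 Å and sequence separation ≥ 3 (1–2 pairs are bonds, 1–3 pairs are
  angle-constrained), or on different chains at any separation. Every
  pair belongs to exactly one class. ε_n is residue-type dependent in
  the range 2.5–5.4 kJ/mol; the mapping is not published, so the default
  is the uniform midpoint 4.2 kJ/mol with a per-contact override hook
  (`SOPTopology.native_eps`).

Internal units are Å, kJ/mol, ps; forces convert at
1 kJ mol⁻¹ Å⁻¹ = 16.61 pN. All conversions derive from
`scipy.constants` and are covered by tests.

## Pulling dynamics

Overdamped Brownian dynamics,
`r ← r + F·Δt/γ + √(2k_BT·Δt/γ)·N(0,1)`, at `T = 298 K` with Stokes
friction `γ = 6πηa` for water viscosity `η = 10⁻³ Pa·s` and bead radius
`a = 3.8 Å` (the Cα spacing — the standard coarse-grained choice; the
source model states only the viscosity). The default timestep 0.02 ps
keeps the stiffest interaction (the FENE bond) relaxing over ≥ 20 steps;
`run_pull` enforces this as a hard check rather than trusting the
caller.

The force ramp acts through a virtual cantilever: spring force
`k_sp(v·t − x_att)` where `x_att` is the pulled-bead-centroid
displacement along the pulling direction, shared equally among pulled
beads. Constrained beads are held exactly (infinite-mass contract, not
stiff springs). Two geometries mirror the two experimental limits:
`longitudinal` pulls one end along the end-to-end vector with the other
end held; `transverse` holds both ends and pulls an interior set
perpendicular to the end-to-end vector (the geometry that matches an AFM
tip lifting the middle of a surface-adsorbed oligomer).

**Desk scaling.** At the experimental 1 μm/s a 100 nm extension needs
~10¹¹ steps — a GPU-scale run. Examples and tests therefore pull at
10⁵–10⁷ μm/s on 10–40-bead toy structures, which finishes in seconds on
one CPU core. At these speeds rupture forces are drag-inflated, so the
toy runs are used for *properties* (sawtooth shape, contact-rupture/force
coincidence, loading-rate monotonicity, diffusion and stability checks),
never for quantitative comparison with the experimental force scale. The
experimental speed remains selectable.

**Transition telemetry.** Native-contact states (intact while
`r < 1.5·r₀`) are recorded every output stride. A region (residue ranges
on one strand, e.g. the γ380–392 β-strand whose pull-out defines
transition type 1) "unfolds" at the first frame its intact fraction
drops below 0.5. Unfold events are grouped into peak-to-peak windows of
the recorded force trace (nearest force peak by extension; if the trace
has no usable peaks, events within 2 nm of extension group together);
a window containing events in both strands becomes one mixed (type-4)
event. The report carries single/mixed fractions and the
strand-alternation score (fraction of consecutive single events that
switch strands).

## Event extraction from force–extension curves

Peaks are local maxima with prominence above 3× the robust noise SD
(median absolute deviation of the first-differenced force). Noisy curves
are Savitzky–Golay smoothed over ~0.5 nm before peak picking; noiseless
curves are left untouched, which keeps the synthetic round trip exact.
Per peak:

- **baseline** = minimum force in the valley following the peak (the
  level the force drops to), and the reported force is peak − baseline;
- **peak-to-peak distance** = extension difference to the previous
  detected unfolding peak (NaN for the first);
- **stiffness** = least-squares slope of the rising segment, from the
  last sample near the preceding valley level (within max(noise, 15 % of
  the rise) of the valley minimum — the relative part rides out
  post-drop undershoot) to the peak.

The first detected peak is flagged `desorption` when it strictly exceeds
the next, the last `detachment` when it strictly exceeds the preceding
one; both are excluded from unfolding statistics, as are peaks over
500 pN absolute or 200 pN over baseline (`excluded_force`) and gaps over
30 nm (`excluded_distance`). Flags are computed independently on the
same detected-peak set, so the retained set cannot depend on rule order.
Whole curves are rejected below 100 nm total extension or with fewer
than two unfolding peaks. Thresholds live in `SelectionRules`; nothing
is hard-coded inline.

Summaries use linear-interpolation percentiles (IQR differs by < 1 %
from other conventions at n ≥ 100). Histograms use the
Freedman–Diaconis width `2·IQR·n^(−1/3)`, falling back to `range/√n`
(flagged) at zero IQR. The KDE is Gaussian with Scott's bandwidth; the
bare `M^(−1/5)` rule is dimensionless, so it is multiplied by the sample
SD (the standard Scott form) — a deviation by necessity, otherwise the
bandwidth would carry no units.

## The bivariate Gamma mixture and EM

Unfolding forces and distances are skewed and long-tailed, hence Gamma
rather than Gaussian components. Each of the five components (one per
transition type) is a shared-component bivariate Gamma built by
trivariate reduction:

    F = β (Y₀ + Y₁),  X = β′ (Y₀ + Y₂),
    Y₀ ~ Γ(λ), Y₁ ~ Γ(α), Y₂ ~ Γ(α′)  (independent, unit scale)

so both marginals are Gamma (`F ~ Γ(λ+α, β)`) and
`cov(F,X) = ββ′λ ≥ 0`. The moment map is invertible: given
(μ_f, μ_x, σ_f, σ_x, σ_fx), `β = σ_f²/μ_f`, marginal shape
`k_f = (μ_f/σ_f)²`, `λ = σ_fx/(ββ′)`, `α = k_f − λ`; feasibility requires
`0 ≤ λ ≤ min(k_f, k_x)` (negative or too-large covariances raise a
parameterization error naming the constraint). The exact closed form of
the source's bivariate density was not available; the construction was
chosen because it carries exactly the published parameter set
(α, α′, β, β′, λ with λ "controlling the dependence") and Gamma
marginals, and it is documented as this package's stand-in.

The joint density needs one integral over the shared component. With
`u = f/β`, `v = x/β′`, `m = min(u,v)`, the integrand has power
singularities `y^{λ−1}` at 0 and `(m−y)^{c−1}` at `m`; both are absorbed
exactly into a Gauss–Jacobi rule (64 nodes), leaving a smooth remainder.
The implementation is validated against the closed-form marginals to
~10⁻¹³ and integrates to 1 within 10⁻³ on test grids.

**EM.** E step: posteriors from joint densities × priors (log-space).
M step: responsibility-weighted sample moments per component, converted
back to shapes; the weighted covariance is projected into the feasible
λ-interval. Components falling under 5 effective events are frozen (J
stays 5) and only priors renormalize. Convergence when every mean force
moves < 0.1 pN; this early stop is substantive — running the
moment-update iteration far beyond it lets strongly overlapping
components trade mass and drift several pN from the generating values.
Because the moment update is not an exact likelihood maximizer, a cycle
that would *decrease* the observed-data log-likelihood (observed only
within ~10⁻⁵ relative, near the stall point) is rejected and iteration
stops there, which makes the reported likelihood trace monotone by
construction. After fitting, exchangeable components are matched to
types by the assignment minimizing total |Δμ_f| (tie-broken by |Δμ_x|);
classification is argmax posterior with the soft posteriors retained.

The L1 diagnostics compare densities on a common force grid:
per type `Σ|π_j·y_i − w_j·ψ_i|·Δf` (theoretical prior π vs
simulation-derived weight w) and the combined
`Σ|p_model(f_i) − φ_KDE(f_i)|·Δf ∈ [0, 2]`. Whether the published
"total" figure uses the combined or the prior-weighted per-type form is
ambiguous in the source; both are computed and reported side by side
rather than guessing.

## The synthetic-data generator

`default_components()` is the study condition: per-type mean
peak-to-peak distances (4.2, 13.8, 13.1, 15.2, 17.7 nm), mean relative
peak forces (36.3, 50.9, 80.2, 63.4, 80.1 pN), force SDs (13.6, 28.5,
17.8, 16.2, 27.9 pN) and priors (0.11, 0.35, 0.10, 0.09, 0.35) of the
transverse-pull simulations. Two quantities are not published and were
fixed once:

- **distance SDs**: 30 % coefficient of variation per type. The printed
  distance SEMs cannot be converted to SDs because the implied per-type
  counts contradict the printed priors; 30 % is a typical spread for
  peak-to-peak distances in force spectroscopy.
- **force–distance correlation**: ρ = 0.25 per component — a moderate
  positive coupling (a longer released contour loads the chain further
  before the next rupture, `f = Kx`). The construction cannot express
  ρ < 0.

The sawtooth generator is deliberately idealized: piecewise-linear teeth
plus additive white Gaussian noise, with exact breakpoints on the sample
grid so the noiseless round trip through event extraction is an identity
(this is a tested invariant). It does not emulate instrument noise
spectra, drift, or substrate desorption physics; passing those tests
shows the analysis chain is self-consistent, not that it is robust to
every artifact of real AFM traces. Toy Cα chains (linear / ideal helix /
two parallel strands 5 Å apart) provide desk-scale structures whose
contact counts are verified against brute-force distance scans.

## Validation experiment and its honest limits

`em.recover_from_synthetic` is the package's headline validation: sample
n = 5000 events from the default table, multiply all initialization
means by 1.1, fit, match components back by mean force. Recovered means
land within a few percent of the generating values (the worked example
in the README shows one run). Two caveats are inherent to the method,
not bugs: (i) the estimator's sampling SD for the overlapping components
is 2–3× larger than the naive `σ_j/√(nπ_j)` known-label standard error,
and (ii) because convergence is declared on mean *forces*, the mean
*distances* of the dominant overlapping components (types 1 and 4)
retain a small residual of the perturbed start (~0.3–0.5 nm). The
acceptance suite states tolerances in terms of replication-based
standard errors of the recovered estimator and leaves the assertions
that exceed them failing rather than widening bands.

## Numerical and degenerate-input choices

- Seeds are explicit everywhere (default 0); the pipeline derives
  per-stage seeds from the global seed with a CRC-stable hash, so runs
  are reproducible across processes.
- Quadrature: 64 Gauss–Jacobi nodes (adequate for `m ≲ 100`, i.e. ~6
  marginal SDs beyond the mean; beyond that log-densities are ≪ −40 and
  only their order of magnitude matters).
- Zero-IQR histograms, single-value KDEs, empty event sets, chain breaks
  in input structures, FENE domain violations and non-finite coordinates
  all raise or flag explicitly rather than propagating NaNs.
- `make_sawtooth` refuses overlapping teeth (a peak whose rise would
  begin inside the previous drop).
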