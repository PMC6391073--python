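# Methods

This note documents the models and procedures implemented in `cyanoecon`,
their assumptions, the parameter choices that matter, and what the
synthetic-data generators do and do not emulate.

## The proteome-allocation growth model

### Structure

The model describes a phototrophic cell growing at steady state under a
light intensity `I` (µmol photons m⁻² s⁻¹) and a saturating external
inorganic-carbon concentration `cix` (default 100 mM). The proteome is
coarse-grained into five classes, each a single effective protein
species:

| class | role | concentration variable |
|-------|------|------------------------|
| T | inorganic-carbon transporter | `[T]` |
| M | metabolism (carbon → amino acids) | `[M]` |
| R | ribosome | `[R]` |
| P | photosynthetic unit (PSU: light harvesting + electron transport) | `[P]` |
| Q | growth-independent proteins (housekeeping) | `[Q]` |

Concentrations are expressed in amino-acid equivalents per total protein
density `Dc` (normalized to 1), so `Σ_Z n_Z·[Z] = Dc` is the fixed
proteome-density constraint and the `n_Z`-weighted values are mass
fractions φ_Z. The Q class is synthesized in fixed proportion so that its
mass share equals `phi_Q = 0.5` at every operating point; it carries
translation cost but no catalytic function.

Three metabolite pools close the network: internal inorganic carbon
`ci`, free amino acids `aa`, and a lumped energy currency `e`.

### Rate laws (the pluggable kinetics layer)

All process rates live in `cyanoecon.kinetics` so alternative forms can
be substituted without touching the solver:

* passive carbon diffusion `vd = kdiff·(cix − ci)`, with `kdiff` fixed
  once for a ~2 µm spherical cell;
* active import `vt = kcat_T·[T]·cix/(Km_T + cix)`, costing `b_t` energy
  per carbon;
* metabolism `vm = kcat_M·[M]·ci/(Km_M + ci)·Ki_aa/(Ki_aa + aa)`,
  consuming `b_c` carbons and `b_e` energy units per amino acid. The
  end-product inhibition term (`Ki_aa`) is a deliberate model choice:
  without it, idle metabolic capacity converts all imported carbon at
  full rate, which drains the energy budget at low growth rates and
  makes the viable region of allocation space a razor-thin sliver with
  discontinuous optima. Feedback inhibition of amino-acid biosynthesis
  is also the physiologically standard behaviour.
* photosynthesis: a two-state PSU cycle. Ground-state units capture
  photons at `k_exc = σ·photon_flux(I)` (σ converted from nm² to m²);
  excited units relax at the turnover rate τ, releasing one energy unit.
  Photodamage removes units with probability `kd` per excitation and, by
  default, acts on the **excited** state (`vi = kd·k_exc·P₁`, a second
  hit on a busy unit). At quasi-steady state

      P₁ = P·k_exc/(k_exc + τ + kd·k_exc),  v₂ = τ·P₁,  vi = kd·k_exc·P₁.

  The damage target is switchable (`damage_target="ground"`). The
  excited-state default is not arbitrary: with ground-state damage the
  quasi-steady-state cycle gives `vi ∝ v₂` exactly, so damage per unit of
  energy produced is constant in light and the growth–irradiance curve
  cannot decline — photoinhibition disappears. Excited-state damage makes
  `vi/v₂ = kd·k_exc/τ` grow linearly with light, producing the observed
  interior growth maximum.
* translation `γ = kcat_R·[R]·f(aa)·f(e)` (Michaelis–Menten saturation
  in both pools), costing `b_r` energy per amino acid. Ribosome
  allocation fractions β_Z partition γ across the five classes.
* maintenance: a constant energy drain `m·Dc`; damaged P is degraded
  back to the amino-acid pool (re-translation is the cost; no energy
  recovery by default, tunable via `energy_recovery`).

### Steady state and optimization

At steady state every species satisfies production − consumption −
μ·concentration = 0 (protein degradation appears only through
photodamage of P). Summing the protein balances gives
`μ·Dc = γ − n_P·vi`: growth is total translation minus repair.

The cell's decision variables are the adjustable mass fractions
(φ_T, φ_M, φ_R, φ_P) on the simplex `Σ = 1 − phi_Q`; the model is solved
by maximizing μ over this simplex ("evolutionary optimality").

The solver exploits the model structure instead of a generic NLP stack:
for a fixed partition, photosynthetic fluxes depend only on φ_P, so the
required translation flux is `γ(μ) = μ·Dc + n_P·vi`; the amino-acid
balance with the inhibited metabolic law yields `aa` in closed form
(quadratic) at any `ci`; the carbon balance then pins `ci` as a monotone
scalar root; and the energy balance closes as a single equation `F(μ)=0`
solved by safeguarded bisection to ~1e−13 relative precision. The outer
maximization uses SLSQP with three deterministic starts (one of them an
analytic warm start from the linearized budget balance); sweeps along a
light grid warm-start from the previous optimum. Residuals of every
balance are reported on the `SteadyState` and checked to be below
1e−6 × the largest flux.

An independent brute-force route (`method="enumerate"`) exhaustively
scores the allocation simplex at a configurable grid step and is used to
cross-check the NLP optimum on a reduced instance.

`constrained_growth` re-solves the same problem with one class pinned at
`[Z] = φ_Z·Dc/n_Z` and a free activity factor α_Z ∈ [0, 1] scaling that
class's catalytic rate, reproducing the non-adaptive-proteome
experiment: pinning R or P at its peak-growth fraction costs a large
growth deficit at other intensities, pinning M a minor one.

### Parametrization

Three parameters are estimated from light–growth data: σ (0.7 nm²),
τ (75 s⁻¹) and kd (1e−6). All other constants are fixed model
parameters. Their exact literature values are not reproducible here, so
they were chosen once in physiologically plausible ranges (e.g.
effective elongation rate 8 aa s⁻¹; ribosome length 7360 aa; ~39 energy
units per amino acid synthesized, 4 per amino acid translated;
maintenance 1.3e−4 energy Dc⁻¹ s⁻¹; effective PSU length 11 000 aa) and
calibrated so that the model at the estimated triple reproduces the
measured growth physiology: μ ≈ 0.025 h⁻¹ at 27.5 µmol m⁻² s⁻¹, a growth
maximum of ≈ 0.11 h⁻¹ in the 440–660 range, and decline to ≈ 0.089 h⁻¹
at 1100. This mirrors the study design (literature constants plus three
fitted photosynthesis parameters); the calibration was done once against
the measured curve and the defaults frozen in
`src/cyanoecon/data/params_default.yaml`. The model is semi-quantitative:
its purpose is growth-law interpretation, not exact prediction.

## Likelihood fitting

Candidates for (τ, kd, σ) come from fixed grids — τ ∈ {50, 75, 100},
kd ∈ {5..9}×10⁻⁷ ∪ {1..5}×10⁻⁶, σ ∈ {0.1, …, 1.0} — and each triple is
scored with the Gaussian negative log-likelihood
`l(θ) = Σᵢ (yᵢ(θ) − xᵢ)²/eᵢ² + log(2π eᵢ²)` against the observed rates
xᵢ ± eᵢ. The argmin wins; ties break toward the smallest kd, then σ,
then τ (the least-damage, least-cost explanation), making the fit fully
deterministic. The printed kd and σ grid definitions contain obvious
typographical gaps; the implemented sets span the printed endpoints and
contain the published optimum, and are configurable.

## Physiology calculus

* Specific growth rate from turbidostat OD₆₈₀:
  `μ = ln(OD(t₂)/OD(t₁))/(t₂−t₁)` per inter-dilution segment, reported
  as mean ± SD over segments. Dilution events are detected as relative
  OD drops > 3% between consecutive samples (configurable); the printed
  band is 0.60–0.66 but the detector threshold is our choice. The
  endpoint form equals the log-linear regression exactly for noiseless
  exponential segments.
* Alternative estimate from medium consumption: `μ = f/V`, with the
  inflow rate `f` optionally estimated as an OLS slope of balance
  readings.
* Gas exchange: net O₂ evolution (NP) is the OLS slope of the
  dissolved-O₂ trace during 5-min light phases, dark respiration (R) the
  negative dark-phase slope, each excluding the first 30 s of a phase
  (mixing transient; our choice of estimator — the source protocol does
  not state one). GP = NP + R with photorespiration neglected; a
  positive dark slope is clamped to R = 0 with a warning. P:R = GP/R and
  PQ = NP/CO₂-uptake; undefined ratios are NaN, not exceptions.
* Morphology: spherical cells, V = πd³/6; content conversions
  mg gDW⁻¹ × pg cell⁻¹ → fg cell⁻¹ round-trip exactly.
* Nutrient balance: refill = D·(medium concentration), consumption =
  D·biomass·quota at steady state (μ = D); elements with negative margin
  are flagged, missing entries reported rather than fatal.

## Proteomics statistics

* **Filtering**: contaminant/reverse entries and proteins with < 2
  peptides are removed; proteins are kept when at least one condition
  group has complete (no missing) LFQ values. The source sentence for
  the missing-value rule admits the opposite reading; both modes are
  implemented (`missing_rule`), with "keep complete group" the default.
* **Growth dependence**: every pair of the six light groups with ≥ 3
  non-missing values is tested with the two-sample Kruskal–Wallis test
  (tie-corrected, asymptotic chi-square p, matching the original
  scipy-based analysis); a protein is growth-dependent iff any pairwise
  p < 0.05, deliberately without multiplicity correction. A
  Benjamini–Hochberg mode exists behind a flag (default off), and an
  exact permutation-enumeration mode (`method="exact"`) is available for
  very small samples. Because the test is rank-based, calls are
  invariant under monotone transforms (log2 upstream changes nothing).
  The per-protein false-flag rate under a pure null is the family-wise
  error of 15 correlated tests — roughly a third at α = 0.05 — which is
  a property of the published procedure; the test suite measures it
  empirically rather than assuming a value.
* **Clustering**: per-protein profiles are per-group medians across
  replicates divided by the profile mean; k-means (Euclidean, 50
  restarts, seed 42) over k = 1…12 with the cluster count chosen by an
  elbow rule. The rule implemented is the *marginal-gain ratio*: the k
  maximizing `(W(k−1) − W(k)) / (W(k) − W(k+1))` with a small
  regularizer, i.e. the point where the WCSS improvement collapses. The
  more common "largest second difference" was implemented first and
  rejected: on profile data whose WCSS decays smoothly (and which has an
  up/down super-structure) it selects k = 2–3 regardless of the true
  cluster count, while the ratio rule recovers planted counts reliably.
* **Enrichment**: proteins map to the union of GO-slim categories of
  their GO terms (set semantics; categories named "unknown"/"putative"
  are trivial and dropped); per category a 2×2 table of dependent ×
  in-category membership is tested with the two-sided Fisher exact test
  at p < 0.05, without multiplicity correction, matching the original
  analysis.

## Absolute quantification

iBAQ intensities are normalized per sample on the summed iBAQ of four
stable reference proteins (Q55806, P72587, P73505, Q59978), making the
reference sum exactly 1 per sample and the result invariant to
per-sample scaling. One global factor then maps the anchor protein's
grand-mean normalized intensity (across all samples, a single factor by
design) to its immunoblot amount — 104 fmol µL⁻¹ for PsaC — and copies
per cell follow via Avogadro's number and the cell concentration of the
digested extract. That cell concentration is not published and is a
required configuration input; absolute copy numbers are therefore
reproducible only given the extract bookkeeping, and published complex
ranges are treated as reference magnitudes, not exact targets.

Complex copy numbers combine subunit copies with database
stoichiometries. The combination rule is not published; the default is
the stoichiometry-weighted mean `Σ copiesᵢ / Σ sᵢ` over quantified
subunits (robust to single-subunit ionization bias), with the min and
max of the per-subunit ratios `copiesᵢ/sᵢ` reported as bounds and
missing subunits listed. The formula grammar ("(RbcL, RbcS)8",
"(PsaA,B,…)3", "Slr20944") is parsed with prefix inheritance inside
comma lists, a locus-tag exception for Slr/Sll names, and an explicit
`Name*count` syntax for the genuinely ambiguous cases (e.g. GroL1×14);
the packaged table stores pre-disambiguated formulas.

## Synthetic data: what it does and does not emulate

The generators reproduce the *statistical design* of the study: a
turbidostat OD₆₈₀ sawtooth between 0.60 and 0.66; dissolved-O₂ traces
with alternating 5-min light/dark phases and planted slopes; a
1356-protein × (6 groups × 5 replicates) intensity matrix with ~57%
growth-dependent proteins following seven archetype profiles (monotone
up/down, photoinhibition spike, mid-intensity peak, kink shapes,
low-light-only), log-normal replicate noise (CV 0.15), logistic
intensity-dependent missingness (~10%, a left-censoring-like testing
device — the original analysis does not model missingness), and
injected contaminant/reverse/single-peptide decoys. Archetypes are
equal-amplitude zero-sum deviations (amplitude 0.5 around the mean,
matching the magnitude of observed profile excursions) so planted
clusters are comparably separated; default archetype membership follows
the observed cluster-size proportions.

Not emulated: peptide-level structure and ionization bias, correlated
noise between proteins of one complex, batch effects, and the biological
coupling between abundance and detectability beyond the intensity-
dependent missingness. Passing tests therefore demonstrate correctness
of the statistical machinery under the study's design, not performance
on raw mass-spectrometry data.

Every generator is reproducible bit-for-bit given a seed, and ground
truth is emitted alongside each dataset but never consumed by the
pipeline under test.

## Numerical choices and limitations

* Inner steady-state solve: bisection to `1e−16 + 1e−13·μ`; carbon root
  to 1e−14 relative; infeasible partitions (energy deficit at μ→0)
  return a smooth penalty proportional to the deficit so the outer
  optimizer retains a descent direction.
* Outer SLSQP: ftol 1e−10, objective scored in h⁻¹ so finite
  differences resolve the gradient; fraction bounds at 1e−4 keep rate
  laws away from degenerate zeros.
* Dark limit (I = 0): photosynthesis is the only energy source, so
  maintenance precludes growth; μ = 0 is returned with a "dark" status
  rather than attempting an infeasible solve.
* Problem sizes: the test suite and the acceptance script solve the
  model on 4–8-point light grids and fit on a 27-triple reduced grid
  (the full default grid has 300 triples and is available through the
  same interface); the synthetic proteomics runs use the full
  1356 × 30 design.
* The growth-dependence classification inherits the published
  procedure's lack of multiplicity control; its dependent counts are
  upward-biased relative to planted truth by construction (measured
  family-wise rate ≈ 1/3 under the null), which is faithful to the
  method, not a defect of the implementation.
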