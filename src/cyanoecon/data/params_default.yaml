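# Default parameter set of the coarse-grained phototrophic growth model.
# The triple (sigma, tau, kd) carries the values estimated from the
# light--growth measurements; all other constants are fixed model
# parameters with literature-plausible magnitudes, calibrated once so that
# the model at the estimated triple reproduces the measured growth curve
# (see docs/methods.md, "Parametrization").
parameters:
  sigma:
    value: 0.7
    units: nm^2
    note: effective absorption cross-section per photosynthetic unit (fitted)
  tau:
    value: 75.0
    units: 1/s
    note: photosynthetic-unit turnover rate (fitted)
  kd:
    value: 1.0e-6
    units: dimensionless
    note: photodamage probability per excitation (fitted)
  kdiff:
    value: 3.0e-7
    units: 1/(s mM)
    note: passive carbon diffusion, fixed for a ~2 um spherical cell
  kcat_T:
    value: 20.0
    units: carbon/s per transporter
    note: bicarbonate transporter turnover
  Km_T:
    value: 15.0
    units: mM
    note: transporter half-saturation for external inorganic carbon
  kcat_M:
    value: 10.0
    units: aa/s per enzyme complex
    note: effective turnover of the lumped metabolic reaction
  Km_M:
    value: 10.0
    units: normalized concentration
    note: metabolic half-saturation for internal carbon
  Ki_aa:
    value: 0.05
    units: normalized concentration
    note: end-product inhibition of metabolism by the amino-acid pool
  kcat_R:
    value: 8.0
    units: aa/s per ribosome
    note: effective elongation rate of the lumped ribosome
  Km_aa:
    value: 1.0e-3
    units: normalized concentration
    note: ribosome half-saturation for the amino-acid pool
  Km_e:
    value: 1.0e-3
    units: normalized concentration
    note: ribosome half-saturation for the energy pool
  m:
    value: 1.3e-4
    units: energy/(Dc s)
    note: maintenance energy drain
  phi_Q:
    value: 0.5
    units: dimensionless
    note: growth-independent proteome mass fraction
  Dc:
    value: 1.0
    units: aa-equivalents (normalized)
    note: total protein density; concentrations are fractions of Dc
  n_T:
    value: 1700.0
    units: aa
  n_M:
    value: 2500.0
    units: aa
  n_R:
    value: 7360.0
    units: aa
    note: summed protein length of the ribosome
  n_P:
    value: 11000.0
    units: aa
    note: effective protein length of one photosynthetic unit
  n_Q:
    value: 300.0
    units: aa
  b_c:
    value: 5.0
    units: carbon/aa
    note: carbon cost per amino acid (genome-scale approximation)
  b_e:
    value: 39.0
    units: energy/aa
    note: anabolic energy cost per amino acid (genome-scale approximation)
  b_r:
    value: 4.0
    units: energy/aa
    note: GTP cost of translation per amino acid
  b_t:
    value: 0.5
    units: energy/carbon
    note: energy cost of active carbon import
  damage_target:
    value: excited
    note: PSU state hit by photodamage ("excited" or "ground")
  energy_recovery:
    value: 0.0
    note: fraction of translation energy recovered on P degradation
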