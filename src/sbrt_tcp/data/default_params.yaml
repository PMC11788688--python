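# Default model-parameter config.
#
# ohri / gucken / santiago carry the published logistic dose-response
# parameters.  The liu and klement blocks are SYNTHETIC placeholder values:
# the original fitted coefficients are not republished here, so these were
# chosen once to give a clinically plausible lung-SBRT dose-response
# (steep probit transition near BED ~ 60 Gy for liu, a cure-rate plateau
# and a dominant negative dose coefficient for klement).  Replace them with
# the original publication's values for a faithful external validation.
#
# bed_column selects which stored BED10 column feeds each model
# (bed_dmax_gy = maximum/isocenter BED, bed_pd_gy = prescription BED).

ohri:
  tcd50_gy: 0.0
  k_gy: 31.0
  size_coefficient_gy_per_cm: 10.0
  bed_column: bed_dmax_gy

gucken:
  tcd50_gy: -1.0
  k_gy: 80.0
  bed_column: bed_dmax_gy

santiago:
  tcd50_gy: -60.2
  k_gy: 113.3
  bed_column: bed_dmax_gy

liu:
  alpha_per_gy: 0.3          # LQ linear sensitivity (1/Gy)
  alpha_beta_gy: 20.0        # alpha/beta used for the Liu regrowth BED
  t_p_regrowth_days: 3.0     # doubling time during treatment (regrowth BED)
  t_p_postrx_days: 3.0       # doubling time after treatment (probit term)
  delta: 0.01                # post-treatment regrowth speed (dimensionless)
  k_cr: 1.0                  # critical clonogen number defining control
  sigma_k: 0.6               # Gaussian width of the clonogen-number distribution
  cell_density_per_cm3: 1.0e+7
  tau_unit_days: 365.25      # follow-up years -> days
  bed_column: bed_dmax_gy

klement:
  theta: 0.4                 # scalar cure parameter; plateau TCP = exp(-theta)
  rho: 1.5                   # Weibull shape
  eta_intercept: -1.5
  eta_coefficients:          # on standardised covariates (binaries +/-0.5)
    male: 0.10
    age: 0.10
    central: 0.30
    chemo_prior: 0.20
    diameter_cm: 0.40
    bed: -0.80
  binary_covariates: [male, central, chemo_prior]
  covariate_refs: null       # null -> standardise against the scored cohort
  tau_unit_scale: 1.0        # follow-up already in years
  bed_column: bed_dmax_gy
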