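# Reference-case parameter set for the COPD smoking-cessation model.
#
# Scalar probabilities, utilities and costs are the published reference-case
# values (costs in nominal 2010 GBP per patient-year; probabilities are annual).
#
# The stage-progression and mortality tables are NOT published as printed
# numbers; the blocks under `progression_components` and `mortality_components`
# are a synthetic reconstruction.  The package builds the tables from them at
# load time via multiplicative hazards on the rate scale:
#   progression p[stage, band, status] = 1 - exp(-modifier[status] * rate(baseline))
#   death       p[stage, band, status, exac] =
#       1 - exp(-excess[stage] * smoking[status] * exac[flag] * rate(all_cause))
# with rate(p) = -ln(1 - p).
#
# Age classes are 10-year wide; entry ages run 40-89 and are uniform within
# each class.  Age bands key the progression/mortality tables; the last band
# is open-ended up to max_age.

severity_distribution:
  GOLD1: 0.3508
  GOLD2: 0.4817
  GOLD3: 0.1396
  GOLD4: 0.0279

# 10-year entry-age classes (lower bounds); per-stage class weights.
# Synthetic reconstruction: weights chosen so mean entry ages are ~57 (GOLD1),
# ~60.5 (GOLD2), ~64.6 (GOLD3 and GOLD4, identical distributions), ~60 overall.
age_classes: [40, 50, 60, 70, 80]
age_distribution:
  GOLD1: [0.32, 0.30, 0.24, 0.09, 0.05]
  GOLD2: [0.22, 0.27, 0.27, 0.16, 0.08]
  GOLD3: [0.12, 0.22, 0.30, 0.24, 0.12]
  GOLD4: [0.12, 0.22, 0.30, 0.24, 0.12]

quit_prob: 0.047
relapse_prob: 0.026

# Annual probability of >=1 exacerbation, per stage (same for both smoking
# statuses in the reference case; sensitivity scenarios may split them).
exacerbation_prob:
  GOLD1: 0.25
  GOLD2: 0.3945
  GOLD3: 0.441
  GOLD4: 0.657

# QALY weight per year lived in a stage, by exacerbation status.
utility:
  stable:
    GOLD1: 0.8971
    GOLD2: 0.7511
    GOLD3: 0.7481
    GOLD4: 0.5493
  exacerbated:
    GOLD1: 0.8951
    GOLD2: 0.7364
    GOLD3: 0.7261
    GOLD4: 0.5357

# Disease-related cost (direct + indirect), GBP per patient-year.
annual_cost:
  GOLD1: 220.0
  GOLD2: 726.0
  GOLD3: 3758.0
  GOLD4: 9470.0

discount_rate: 0.035
max_age: 110
discount_from_cycle_one: false

# Age bands keying the progression and mortality tables (lower bounds).
age_bands: [40, 50, 60, 70, 80, 90, 100]

# Synthetic reconstruction of the mortality-table components.
mortality_components:
  # Annual all-cause death probability of the general population, per age band.
  all_cause: [0.002, 0.0048, 0.0118, 0.031, 0.08, 0.186, 0.35]
  # Relative excess mortality of COPD patients vs the general population,
  # per stage, with upper/lower sensitivity limits bracketing the central
  # hazards at +/-30%.
  copd_excess:
    central: {GOLD1: 1.2, GOLD2: 1.5, GOLD3: 2.6, GOLD4: 4.2}
    upper: {GOLD1: 1.56, GOLD2: 1.95, GOLD3: 3.38, GOLD4: 5.46}
    lower: {GOLD1: 0.84, GOLD2: 1.05, GOLD3: 1.82, GOLD4: 2.94}
  smoking_hazard: {SMOKER: 1.45, EX_SMOKER: 1.0}
  exacerbation_hazard: {stable: 1.0, exacerbated: 1.25}

# Synthetic reconstruction of the progression-table components: baseline
# annual probability of moving to the next stage for a current smoker, per
# stage x age band; ex-smokers progress at half the rate (lung-function
# decline roughly twice as fast in continuing smokers).
progression_components:
  baseline:
    GOLD1: [0.03, 0.035, 0.04, 0.045, 0.05, 0.05, 0.05]
    GOLD2: [0.045, 0.05, 0.055, 0.06, 0.065, 0.065, 0.065]
    GOLD3: [0.012, 0.015, 0.018, 0.022, 0.026, 0.026, 0.026]
  smoking_modifier: {SMOKER: 1.0, EX_SMOKER: 0.5}
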