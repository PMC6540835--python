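# Survey configuration template for apexds.
#
# Units are fixed package-wide: distances/strip widths in metres, transect
# lengths in kilometres, areas in square kilometres.

# Strip half-width: detections farther than w metres from the line are
# off-strip and must not appear in the observation table.
w: 600.0

# Sides of the line searched: 1 when pilot and observer search the same side
# of the aircraft (the usual aerial setup), 2 for ground transects.
sides: 1

# Size of the study area the abundance estimate refers to.
area_km2: 8000.0

# Detection-function form: half_normal (apex on the line, usually needs left
# truncation for aerial data) or two_piece_normal (estimated apex).
form: two_piece_normal

# Covariates of the detection-scale model (MCDS) - column names from the
# observation CSV. Categorical columns are dummy-coded automatically.
covariates: [cover]

# Covariates of the double-observer mark-recapture model (MRDS fits).
mr_covariates: []

# Left truncation in metres, or "auto" to truncate a half-normal fit at the
# apex of a two-piece normal fit to the same data. Ignored by two-piece fits.
left_truncation: 0.0

# Seed for anything stochastic (simulation, bootstrap).
seed: 1
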