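# Hebridean-series diagnostic rules, version 1.0
#
# Numeric bounds transcribed from the subgroup diagnoses, widened by half a
# unit in the last printed place (0.005 on ratios, 0.5 deg on angles) because
# the diagnosed ranges are quoted at two decimals from rounded measurements.
# Hedged bounds ("generally", "typically", "often", "approximately") are soft
# predicates that contribute to a candidate's score; unhedged bounds on the
# defining ratio of a subgroup pair (the B2.1/B2.2 l/w split) are hard gates.
#
# metrics available to predicates:
#   L (cm), W (cm), lw_ratio, mesaxony, total_div (deg), iii_over_L (%),
#   r_iii_ii, r_iii_iv, alpha, beta
# ops: gt, ge, lt, le, between (lo/hi inclusive)

version: "1.0"

engine:
  # records whose hallux state is one of these keys are restricted to the
  # listed candidate subgroups (a reversed hallux is unique to HBR_B4, an
  # anterolateral padded hallux to HBR_B1.2)
  hallux_restrictions:
    posterior: [HBR_B4]
    anterolateral: [HBR_B1.2]
  # broad, rounded digits enclosing sinuous inner margins are the defining
  # morphology of HBR_B2.3
  shape_inner_margin_restriction:
    digit_shape: broad_round
    inner_margins_present: true
    subgroups: [HBR_B2.3]

subgroups:
  HBR_B1.1:
    series: HBR_B1
    size_gate: [large, giant]
    allowed_digit_shapes: [parallel_sided]
    combination: all
    metric_predicates:
      - {metric: L, op: between, lo: 39.5, hi: 55.5, basis: "track length typically 40-55 cm"}
      - {metric: lw_ratio, op: between, lo: 1.215, hi: 1.665, basis: "weak-moderate l/w 1.22-1.66"}
      - {metric: mesaxony, op: between, lo: 0.355, hi: 0.525, basis: "mesaxony 0.36-0.52"}
      - {metric: total_div, op: between, lo: 39.5, hi: 60.5, basis: "ii-iv divarication generally 40-60 deg"}
    flag_predicates: []
    suggested_ichnotaxon: "Megalosauripus isp."

  HBR_B1.2:
    series: HBR_B1
    size_gate: [large, giant]
    allowed_digit_shapes: [sub_parallel, parallel_sided, broad_round]
    hallux_required: anterolateral
    combination: all
    metric_predicates: []
    flag_predicates:
      - {flag: heel_impressed, value: true, basis: "deeply impressed padded hallux and heel"}
    suggested_ichnotaxon: "indeterminate"

  HBR_B1.3:
    series: HBR_B1
    # "approximately 30 cm" straddles the medium/large bin boundary
    size_gate: [medium, large]
    allowed_digit_shapes: [sub_parallel]
    combination: all
    metric_predicates:
      - {metric: L, op: between, lo: 27.5, hi: 34.5, basis: "approximately 30 cm track length"}
      - {metric: lw_ratio, op: between, lo: 1.255, hi: 1.325, basis: "low l/w 1.26-1.32"}
      - {metric: mesaxony, op: between, lo: 0.505, hi: 0.555, basis: "moderate mesaxony 0.51-0.55"}
      - {metric: total_div, op: gt, value: 59.5, basis: "ii-iv divarication >60 deg"}
    flag_predicates: []
    suggested_ichnotaxon: "Megalosauripus isp."

  HBR_B1.4:
    series: HBR_B1
    size_gate: [large]
    allowed_digit_shapes: [parallel_sided, sub_parallel]
    combination: all
    metric_predicates:
      - {metric: L, op: between, lo: 29.5, hi: 40.5, basis: "track lengths in the 30-40 cm range"}
      - {metric: lw_ratio, op: gt, value: 1.495, basis: "elongated l/w >1.50"}
      - {metric: mesaxony, op: between, lo: 0.495, hi: 0.715, basis: "mesaxony 0.50-0.71"}
      - {metric: total_div, op: lt, value: 45.5, basis: "narrow ii-iv divarication <45 deg"}
    flag_predicates: []
    suggested_ichnotaxon: "Therangospodus-like"

  HBR_B2.1:
    series: HBR_B2
    size_gate: [small, medium]
    allowed_digit_shapes: [spindle]
    combination: all
    metric_predicates:
      - {metric: lw_ratio, op: gt, value: 1.295, hard: true, basis: "l/w ratios >1.30"}
      - {metric: mesaxony, op: gt, value: 0.495, basis: "mesaxony often >0.50"}
      - {metric: total_div, op: between, lo: 29.5, hi: 60.5, basis: "ii-iv divarication approx 30-60 deg"}
      - {metric: L, op: between, lo: 14.5, hi: 25.5, basis: "lengths typically approx 15-25 cm"}
    flag_predicates: []
    suggested_ichnotaxon: "Eubrontes-like"

  HBR_B2.2:
    series: HBR_B2
    size_gate: [small, medium]
    allowed_digit_shapes: [spindle]
    combination: all
    metric_predicates:
      - {metric: lw_ratio, op: le, value: 1.305, hard: true, basis: "subequal-low l/w <=1.30"}
      - {metric: mesaxony, op: between, lo: 0.445, hi: 0.605, basis: "strictly moderate mesaxony approx 0.50"}
      - {metric: total_div, op: gt, value: 59.5, basis: "ii-iv divarication often >60 deg"}
      - {metric: L, op: between, lo: 12.5, hi: 20.5, basis: "small track lengths 13.2-19.9 cm"}
    flag_predicates: []
    suggested_ichnotaxon: "Eubrontes-like"

  HBR_B2.3:
    series: HBR_B2
    size_gate: [small, medium]
    allowed_digit_shapes: [broad_round]
    combination: all
    metric_predicates:
      - {metric: lw_ratio, op: between, lo: 0.905, hi: 1.455, basis: "weak to sub-moderate l/w 0.91-1.45"}
      - {metric: mesaxony, op: between, lo: 0.395, hi: 0.595, basis: "relatively moderate mesaxony 0.40-0.59"}
      - {metric: L, op: between, lo: 13.0, hi: 20.0, basis: "13.5-19.5 cm long"}
    flag_predicates:
      - {flag: inner_margins_present, value: true, basis: "sinuous slender inner digit margins within broad round digits"}
    suggested_ichnotaxon: "indeterminate"

  HBR_B3.1:
    series: HBR_B3
    size_gate: [tiny, small]
    hard_length_max: 15.0
    allowed_digit_shapes: [gracile]
    combination: {at_least: 2}
    metric_predicates:
      - {metric: lw_ratio, op: gt, value: 1.495, basis: "pronounced l/w >1.50"}
      - {metric: mesaxony, op: gt, value: 0.695, basis: "mesaxonic indices >0.7"}
      - {metric: total_div, op: lt, value: 50.5, basis: "ii-iv divarication <50 deg"}
    flag_predicates:
      - {flag: digits_well_separated, value: false, basis: "digits often poorly separated"}
    suggested_ichnotaxon: "Grallator-like"

  HBR_B3.2:
    series: HBR_B3
    size_gate: [tiny, small]
    hard_length_max: 15.0
    allowed_digit_shapes: [gracile]
    combination: {at_least: 2}
    metric_predicates:
      - {metric: lw_ratio, op: lt, value: 1.405, basis: "weak to moderate l/w <1.40"}
      - {metric: mesaxony, op: lt, value: 0.705, basis: "mesaxonic indices typically <0.7"}
      - {metric: total_div, op: gt, value: 49.5, basis: "ii-iv divarication usually >50 deg"}
    flag_predicates:
      - {flag: digits_well_separated, value: true, basis: "digits often well separated"}
    suggested_ichnotaxon: "Grallator-like with Carmelopodus characters"

  HBR_B4:
    series: HBR_B4
    size_gate: [tiny]
    allowed_digit_shapes: [gracile]
    hallux_tolerated: [absent, posterior, uncertain]
    combination: all
    metric_predicates:
      - {metric: lw_ratio, op: le, value: 1.205, basis: "subequal l/w 0.90-1.19"}
      - {metric: mesaxony, op: between, lo: 0.445, hi: 0.555, basis: "moderate mesaxony approx 0.50"}
      - {metric: total_div, op: gt, value: 59.5, basis: "ii-iv often widely divergent >60 deg"}
    flag_predicates:
      - {flag: digits_well_separated, value: false, basis: "lateral digits converge centrally under digit iii"}
    suggested_ichnotaxon: "Trisauropodiscus-like"
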