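# Frozen default configuration for the nine stock problems.
# The in-code catalog is diffed against this file in the test suite so that
# accidental changes to the shipped defaults are caught.
global:
  relative_target: 0.2
  gap: 0.01
  edge_factor: 0.5
problems:
  "1a":
    planning_unit_source: intact
    cost_recipe: uniform
    feature_recipe: direct
    locked_in_recipe: none
    boundary_penalty: 1.0e-05
    conservation_area_mask: false
    include_lek_abundance: false
  "1b":
    planning_unit_source: intact
    cost_recipe: transposed_sagebrush_connectivity
    feature_recipe: direct
    locked_in_recipe: none
    boundary_penalty: 0.0
    conservation_area_mask: false
    include_lek_abundance: false
  "1c":
    planning_unit_source: intact
    cost_recipe: transposed_future_cover
    feature_recipe: direct
    locked_in_recipe: none
    boundary_penalty: 0.0
    conservation_area_mask: false
    include_lek_abundance: false
  "1d":
    planning_unit_source: intact
    cost_recipe: soil_moisture
    feature_recipe: direct
    locked_in_recipe: none
    boundary_penalty: 1.0e-05
    conservation_area_mask: false
    include_lek_abundance: false
  "2a":
    planning_unit_source: merged
    cost_recipe: transposed_soil_moisture
    feature_recipe: ecological_potential
    locked_in_recipe: intact
    boundary_penalty: 0.1
    conservation_area_mask: false
    include_lek_abundance: true
  "2b":
    planning_unit_source: degraded
    cost_recipe: transposed_soil_moisture
    feature_recipe: ecological_potential
    locked_in_recipe: none
    boundary_penalty: 0.0
    conservation_area_mask: false
    include_lek_abundance: true
  "3a":
    planning_unit_source: intact
    cost_recipe: transposed_lek_connectivity
    feature_recipe: direct
    locked_in_recipe: none
    boundary_penalty: 0.0
    conservation_area_mask: true
    include_lek_abundance: false
  "3b":
    planning_unit_source: degraded
    cost_recipe: transposed_soil_moisture
    feature_recipe: ecological_potential
    locked_in_recipe: prior_solution
    boundary_penalty: 2.5
    conservation_area_mask: true
    include_lek_abundance: true
  "3c":
    planning_unit_source: degraded
    cost_recipe: shifted_connectivity_loss
    feature_recipe: ecological_potential
    locked_in_recipe: prior_solution
    boundary_penalty: 1.5
    conservation_area_mask: true
    include_lek_abundance: true
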