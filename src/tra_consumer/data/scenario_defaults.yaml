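# Bundled scenario-defaults registry (SYNTHETIC FIXTURE).
#
# The authoritative scenario-default tables of the screening tool are not
# reproduced here. Entries are synthetic fixtures (provenance:
# fixture-nonauthoritative) except for individual field values that are
# anchored to printed numbers in the open benchmarking literature, which
# carry field_provenance: printed-in-paper. Edit freely; nothing downstream
# assumes these values are authoritative.
scenarios:
  PC9a-wall-paint:
    scenario_class: product
    is_aerosol: false
    product_amount: 2500.0
    weight_fraction: 0.3
    room_volume: 20.0
    dilution_fraction: 1.0
    event_duration: 2.0
    events_per_day: 1.0
    skin_contact_area: 428.0
    thickness_layer: 0.01
    contact_density: 1.0
    transfer_factor: 1.0
    ingested_amount: 0.0
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
    field_provenance:
      room_volume: printed-in-paper      # 20 m3 default room
      thickness_layer: printed-in-paper  # 0.01 cm for liquids
  PC9a-spray-paint:
    scenario_class: product
    is_aerosol: true
    product_amount: 300.0
    weight_fraction: 0.5
    room_volume: 20.0
    event_duration: 0.33
    events_per_day: 1.0
    skin_contact_area: 0.0
    thickness_layer: 0.01
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
    field_provenance:
      weight_fraction: printed-in-paper  # default 0.5 for the spray scenario
  PC1-2-tile-glue:
    scenario_class: product
    is_aerosol: false
    product_amount: 1000.0
    weight_fraction: 0.1
    room_volume: 20.0
    event_duration: 2.0
    skin_contact_area: 428.0
    thickness_layer: 0.01
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
  AC13-plastic-flooring:
    scenario_class: article
    is_aerosol: false
    product_amount: 594.0
    weight_fraction: 0.1
    room_volume: 20.0
    event_duration: 8.0
    skin_contact_area: 8750.0
    thickness_layer: 0.01
    contact_density: 1.0
    transfer_factor: 1.0
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
    field_provenance:
      weight_fraction: printed-in-paper     # flooring default 10%
      thickness_layer: printed-in-paper     # flooring retains 0.01 cm
      skin_contact_area: printed-in-paper   # closes the printed 8750 mg/day
  AC13-plastic-larger-articles:
    scenario_class: article
    is_aerosol: false
    product_amount: 594.0
    weight_fraction: 1.0
    room_volume: 20.0
    event_duration: 8.0
    skin_contact_area: 0.0
    thickness_layer: 0.001
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
    field_provenance:
      product_amount: printed-in-paper  # backs out printed 29700 mg/m3 (V=20)
      event_duration: printed-in-paper  # 8-hour scenario
  AC5-clothing:
    scenario_class: article
    is_aerosol: false
    product_amount: 37.0
    weight_fraction: 1.0
    room_volume: 20.0
    event_duration: 8.0
    skin_contact_area: 17500.0
    thickness_layer: 0.001
    population: {label: adult, body_weight: 60.0, inhalation_rate: 1.0}
    provenance: fixture-nonauthoritative
    field_provenance:
      product_amount: printed-in-paper   # backs out printed 1850 mg/m3 (V=20)
      thickness_layer: printed-in-paper  # articles default to 0.001 cm
  AC5-bedding:
    scenario_class: article
    is_aerosol: false
    ingested_amount: 0.001
    weight_fraction: 1.0
    mouthed_area: 10.0
    event_duration: 1.0
    thickness_layer: 0.01
    population: {label: child, body_weight: 10.0, inhalation_rate: 0.5}
    provenance: fixture-nonauthoritative
    field_provenance:
      ingested_amount: printed-in-paper  # closes printed 0.1 mg/kg/day (10 kg)
      mouthed_area: printed-in-paper     # 10 cm2 mouthed-object area
  AC13-toys-plastic:
    scenario_class: article
    is_aerosol: false
    ingested_amount: 0.0043
    weight_fraction: 1.0
    mouthed_area: 10.0
    event_duration: 1.0
    thickness_layer: 0.001
    population: {label: child, body_weight: 10.0, inhalation_rate: 0.5}
    provenance: fixture-nonauthoritative
    field_provenance:
      ingested_amount: printed-in-paper  # closes printed 0.43 mg/kg/day (10 kg)
  AC5-toys-cuddly:
    scenario_class: article
    is_aerosol: false
    ingested_amount: 0.010
    weight_fraction: 1.0
    mouthed_area: 10.0
    event_duration: 1.0
    thickness_layer: 0.01
    population: {label: child, body_weight: 10.0, inhalation_rate: 0.5}
    provenance: fixture-nonauthoritative
    field_provenance:
      ingested_amount: printed-in-paper  # closes printed 1 mg/kg/day (10 kg)
      thickness_layer: printed-in-paper  # cuddly toys retain 0.01 cm
  AC8-printed-paper:
    scenario_class: article
    is_aerosol: false
    ingested_amount: 0.030
    weight_fraction: 1.0
    mouthed_area: 10.0
    event_duration: 1.0
    thickness_layer: 0.001
    population: {label: child, body_weight: 10.0, inhalation_rate: 0.5}
    provenance: fixture-nonauthoritative
    field_provenance:
      ingested_amount: printed-in-paper  # closes printed 3 mg/kg/day (10 kg)
  AC-article-oral-max:
    scenario_class: article
    is_aerosol: false
    ingested_amount: 0.043
    weight_fraction: 1.0
    mouthed_area: 10.0
    event_duration: 1.0
    thickness_layer: 0.001
    population: {label: child, body_weight: 10.0, inhalation_rate: 0.5}
    provenance: fixture-nonauthoritative
    field_provenance:
      ingested_amount: printed-in-paper  # top of printed 0.1-4.3 mg/kg/day range
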