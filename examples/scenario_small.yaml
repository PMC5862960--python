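# A small synthetic study: one island, one resident shark, two receivers.
seed: 7
duration_days: 3
step_min: 1.0
range_m: 900.0

grid:
  origin: [20.0, -157.6]
  n_rows: 120
  n_cols: 120
  cell_deg: 0.015

islands:
  - center: [20.8, -156.6]
    land_radius_km: 8.0
    shelf_width_km: 15.0

receivers:
  - id: R1
    position: [20.73, -156.45]
    depth_m: 15.0
    island: A
    use_class: shallow-recreation
    deployments: [["2014-01-01", "2014-03-01"]]
  - id: R2
    position: [20.66, -156.50]
    depth_m: 140.0
    island: A
    use_class: deep
    deployments: [["2014-01-01", "2014-03-01"]]

sharks:
  - id: S1
    sex: F
    total_length_cm: 320
    island: A
    tagged_at: "2014-01-01"
    battery_days: 3650
    movement:
      attraction_center: [20.73, -156.45]
      attraction_per_h: 0.5
      noise_km: 0.5
      excursion_rate_per_day: 0.0
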