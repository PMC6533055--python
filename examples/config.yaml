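# Example end-to-end configuration for `thalmap simulate|map|cv|burden|report`.
# With no `paths:` section, map/cv/burden read the files that `simulate`
# wrote into run.output_dir; point `paths:` at your own inputs to run on
# real survey tables (see docs/column_dictionary.md).

run:
  output_dir: thalmap_out
  seed: 42
  K: 100                    # conditional realisations per form
  grid:
    origin_lon: 98.0        # SW cell edge, WGS84 decimal degrees
    origin_lat: 8.0
    cell_size: 0.5
    n_rows: 12
    n_cols: 12
  # countries: [Thailand, Myanmar, Lao PDR, Cambodia, Malaysia]

synthetic:
  n_sites: 90
  total_population: 7.0e7
  n_provinces: 12
  clustering: 1.0
  crude_birth_rate: 0.0105

# paths:
#   surveys: my_surveys.csv
#   surveys_percent: false        # set true if freq_* columns are percentages
#   population: population.asc
#   provinces_labels: provinces.asc

model:
  smoothness: 1.0
  n_restarts: 4
  variance_bounds: [1.0e-8, 100.0]
  range_bounds_km: [5.0, 5000.0]
  nugget_bounds: [1.0e-10, 10.0]

burden:
  F: 0.0                    # population coefficient of consanguinity
  level: 0.95
  crude_birth_rate: 0.0105  # births per person-year (cbr_per_1000: true for per-1000)

cv:
  k: 10
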