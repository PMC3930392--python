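# Example configuration for `fibroquant run-all --config pipeline_config.yaml`.
# Generate matching inputs first:
#   fibroquant synth --scale small --seed 7 --out fixtures/
slides:
  - stain: fap
    image: fixtures/fap.tif                 # DAB + hematoxylin IHC slide
    control: fixtures/fap_control.tif       # hematoxylin-only negative control
    annotations: fixtures/fap_exclusions.geojson  # exclude vessels/artifacts
    patient_id: P01
    sample_id: P01_S1
  - stain: sox11
    image: fixtures/sox11.tif
    control: fixtures/sox11_control.tif
    annotations: fixtures/sox11_exclusions.geojson
    patient_id: P01
    sample_id: P01_S1

# patient-level clinical labels (patient_id, expression_set, outcome)
cohort_csv: fixtures/cohort.csv

output_dir: run
tile_size_mm: 0.25          # ROI edge length
min_valid_fraction: 0.5     # drop tiles mostly covered by exclusions
# microns_per_pixel: 0.5    # only needed when images lack resolution tags

# transmission-scale positive-pixel cutoffs (0-255); calibrate per study
thresholds:
  weak: 220.0
  medium: 175.0
  strong: 100.0

segmentation:
  threshold_intensity: 220.0   # nuclear hematoxylin cutoff (transmission)
  min_area_um2: 8.0
  max_area_um2: 400.0
  min_peak_distance_um: 2.0    # watershed marker spacing
  smooth_sigma_px: 1.75

n_boot: 2000
seed: 17
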