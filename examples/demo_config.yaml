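# End-to-end synthetic demo: simulate -> correct -> classify -> agree-cover.
seed: 7
synthetic:
  width: 128
  height: 128
  cell_size: 2.0          # m
  patch_scale: 4.0        # within-bed patch autocorrelation length, m
  trend_scale: 80.0       # bed-scale gradient length, m (set via reference below)
  target_cover: 0.4
  land_band_width: 8
  noise_sd: 0.0010        # per-band Rrs noise, sr^-1
  path_at_reference: 0.01 # injected atmospheric path signal at the NIR band
  reference:
    dialect: density_polygons
    scheme: chesapeake
    polygon_size: 16      # cells per reference-tile side
radiometry:
  enabled: true
  rayleigh_exponent: 4.75
  reference_band_nm: 908.0
  dark_percentile: 1.0
classification:
  window_size: 1
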