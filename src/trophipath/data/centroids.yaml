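# Trophic-pattern centroid table.
#
# The means of entropy (dits), relative density (%) and the four
# compartment-by-caliber vessel counts (units) are the published
# per-subtype cohort statistics; necrosis_fraction and
# perivascular_fraction means are the expected values of this package's
# generative model for each subtype.
#
# The SD column is the standardization scale used by the nearest-
# centroid classifier and therefore holds the WITHIN-pattern per-slide
# dispersion of each metric: for the count metrics and density this
# coincides with the published cohort SDs (the generator reproduces
# them), while for entropy the published cohort SD also absorbs
# between-case heterogeneity far larger than the per-slide spread of
# the spatial statistic, so the entry here is the generative model's
# observed dispersion (with margin).  Edit freely for field data.
centroids:
- pattern: proliferative_vascular
  subtype: micropapillary
  means:
    entropy_dits: 3.59
    density_pct: 0.05
    n_small_center: 30.6
    n_small_periphery: 128.0
    n_large_center: 11.93
    n_large_periphery: 43.4
    necrosis_fraction: 0.025
    perivascular_fraction: 0.038
  sds:
    entropy_dits: 0.1
    density_pct: 0.02
    n_small_center: 26.44
    n_small_periphery: 115.1
    n_large_center: 10.59
    n_large_periphery: 38.11
    necrosis_fraction: 0.015
    perivascular_fraction: 0.01
- pattern: hypoxic
  subtype: solid
  means:
    entropy_dits: 3.28
    density_pct: 0.01
    n_small_center: 10.03
    n_small_periphery: 42.59
    n_large_center: 4.44
    n_large_periphery: 14.26
    necrosis_fraction: 0.23
    perivascular_fraction: 0.06
  sds:
    entropy_dits: 0.1
    density_pct: 0.01
    n_small_center: 14.48
    n_small_periphery: 63.15
    n_large_center: 6.45
    n_large_periphery: 20.64
    necrosis_fraction: 0.065
    perivascular_fraction: 0.027
- pattern: proliferative
  subtype: acinar
  means:
    entropy_dits: 2.3
    density_pct: 0.03
    n_small_center: 19.71
    n_small_periphery: 75.04
    n_large_center: 7.27
    n_large_periphery: 26.28
    necrosis_fraction: 0.025
    perivascular_fraction: 0.2
  sds:
    entropy_dits: 0.1
    density_pct: 0.02
    n_small_center: 23.87
    n_small_periphery: 88.18
    n_large_center: 7.35
    n_large_periphery: 31.37
    necrosis_fraction: 0.015
    perivascular_fraction: 0.067
- pattern: vascular
  subtype: papillary
  means:
    entropy_dits: 3.22
    density_pct: 0.02
    n_small_center: 13.3
    n_small_periphery: 53.308
    n_large_center: 4.84
    n_large_periphery: 18.69
    necrosis_fraction: 0.025
    perivascular_fraction: 0.084
  sds:
    entropy_dits: 0.1
    density_pct: 0.01
    n_small_center: 7.14
    n_small_periphery: 18.781
    n_large_center: 2.37
    n_large_periphery: 7.02
    necrosis_fraction: 0.015
    perivascular_fraction: 0.012
- pattern: inactive
  subtype: lepidic
  means:
    entropy_dits: 1.19
    density_pct: 0.03
    n_small_center: 9.04
    n_small_periphery: 42.04
    n_large_center: 9.22
    n_large_periphery: 14.42
    necrosis_fraction: 0.025
    perivascular_fraction: 0.34
  sds:
    entropy_dits: 0.1
    density_pct: 0.02
    n_small_center: 2.08
    n_small_periphery: 52.54
    n_large_center: 5.01
    n_large_periphery: 16.74
    necrosis_fraction: 0.015
    perivascular_fraction: 0.076
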