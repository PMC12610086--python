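# Subtype generator profiles.
#
# Metric means/SDs (entropy in dits, vessel counts in units, relative
# area density in %) are the published per-subtype cohort statistics the
# generator targets.  n_mitoses, n_cluster_sites, the necrosis ranges
# and the clustering weights are generator parameters of this package:
# n_mitoses sets the absolute mitotic burden consistent with each
# subtype's entropy level, n_cluster_sites the number of distinct
# perivascular hot-spot seeds, and clustering_weight is the output of
# trophipath.synthetic.calibrate_clustering_weight at the default
# configuration (500 um grid cell, 1500 mm^2 tumor).
subtypes:
  micropapillary:
    pattern: proliferative_vascular
    n_slides: 15
    entropy_dits: {mean: 3.59, sd: 0.99}
    density_pct: {mean: 0.05, sd: 0.02}
    n_small_center: {mean: 30.60, sd: 26.44}
    n_small_periphery: {mean: 128.00, sd: 115.10}
    n_large_center: {mean: 11.93, sd: 10.59}
    n_large_periphery: {mean: 43.40, sd: 38.11}
    n_mitoses: {mean: 15000, sd: 3000}
    necrosis_fraction_range: [0.0, 0.05]
    n_cluster_sites: 30
    clustering_weight: 0.1214
  solid:
    pattern: hypoxic
    n_slides: 84
    entropy_dits: {mean: 3.28, sd: 1.68}
    density_pct: {mean: 0.01, sd: 0.01}
    n_small_center: {mean: 10.03, sd: 14.48}
    n_small_periphery: {mean: 42.59, sd: 63.15}
    n_large_center: {mean: 4.44, sd: 6.45}
    n_large_periphery: {mean: 14.26, sd: 20.64}
    n_mitoses: {mean: 12000, sd: 3000}
    necrosis_fraction_range: [0.10, 0.40]
    n_cluster_sites: 12
    clustering_weight: 0.268
  papillary:
    pattern: vascular
    n_slides: 13
    entropy_dits: {mean: 3.22, sd: 1.88}
    density_pct: {mean: 0.02, sd: 0.01}
    n_small_center: {mean: 13.30, sd: 7.14}
    n_small_periphery: {mean: 53.308, sd: 18.781}
    n_large_center: {mean: 4.84, sd: 2.37}
    n_large_periphery: {mean: 18.69, sd: 7.02}
    n_mitoses: {mean: 10000, sd: 2500}
    necrosis_fraction_range: [0.0, 0.05]
    n_cluster_sites: 10
    clustering_weight: 0.2767
  lepidic:
    pattern: inactive
    n_slides: 21
    entropy_dits: {mean: 1.19, sd: 1.51}
    density_pct: {mean: 0.03, sd: 0.02}
    n_small_center: {mean: 9.04, sd: 2.08}
    n_small_periphery: {mean: 42.04, sd: 52.54}
    n_large_center: {mean: 9.22, sd: 5.01}
    n_large_periphery: {mean: 14.42, sd: 16.74}
    n_mitoses: {mean: 800, sd: 300}
    necrosis_fraction_range: [0.0, 0.05]
    n_cluster_sites: 5
    clustering_weight: 0.9777
  acinar:
    pattern: proliferative
    n_slides: 74
    entropy_dits: {mean: 2.30, sd: 1.80}
    density_pct: {mean: 0.03, sd: 0.02}
    n_small_center: {mean: 19.71, sd: 23.87}
    n_small_periphery: {mean: 75.04, sd: 88.18}
    n_large_center: {mean: 7.27, sd: 7.35}
    n_large_periphery: {mean: 26.28, sd: 31.37}
    n_mitoses: {mean: 8000, sd: 2500}
    necrosis_fraction_range: [0.0, 0.05]
    n_cluster_sites: 12
    clustering_weight: 0.7016
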