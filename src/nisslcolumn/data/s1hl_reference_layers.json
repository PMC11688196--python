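{
  "description": "Per-layer reference parameters for the juvenile rat S1HL cortical column: mean layer heights, Nissl-positive cell densities, and the two soma-diameter populations (Gaussian mean +/- sd) per layer. Mixture weights are not part of this reference set; the generator default is 0.5.",
  "layers": [
    {"label": "LI",   "height_um": 129, "density_cells_mm3": 32568,  "pop1_mean_um": 5.20, "pop1_sd_um": 1.20, "pop2_mean_um": 8.14,  "pop2_sd_um": 2.33},
    {"label": "LII",  "height_um": 129, "density_cells_mm3": 90226,  "pop1_mean_um": 5.96, "pop1_sd_um": 1.38, "pop2_mean_um": 10.33, "pop2_sd_um": 2.11},
    {"label": "LIII", "height_um": 373, "density_cells_mm3": 85094,  "pop1_mean_um": 6.09, "pop1_sd_um": 1.52, "pop2_mean_um": 10.74, "pop2_sd_um": 2.18},
    {"label": "LIV",  "height_um": 152, "density_cells_mm3": 103016, "pop1_mean_um": 6.04, "pop1_sd_um": 1.40, "pop2_mean_um": 10.14, "pop2_sd_um": 1.91},
    {"label": "LV",   "height_um": 517, "density_cells_mm3": 72005,  "pop1_mean_um": 5.35, "pop1_sd_um": 1.03, "pop2_mean_um": 10.51, "pop2_sd_um": 3.00},
    {"label": "LVIa", "height_um": 452, "density_cells_mm3": 89198,  "pop1_mean_um": 5.36, "pop1_sd_um": 1.18, "pop2_mean_um": 10.01, "pop2_sd_um": 1.83},
    {"label": "LVIb", "height_um": 165, "density_cells_mm3": 71153,  "pop1_mean_um": 4.80, "pop1_sd_um": 0.99, "pop2_mean_um": 9.12,  "pop2_sd_um": 2.69}
  ]
}
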