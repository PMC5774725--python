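{
  "description": "Group-level distribution parameters (mean, sd) of the 10 magnetic-field-map predictors of ventricular depolarization for the combined study cohort. Group A: ischemic heart disease patients; Group B: age-matched / non-ischemic chest-pain controls; Group C: young healthy volunteers. Units: MMR unitless, angle deg, interval ms, pd cm, peak pT.",
  "groups": {
    "A": {
      "size": 70,
      "predictors": {
        "QR_MMR":      [1.39, 0.53],
        "QR_angle":    [108.15, 15.59],
        "QR_interval": [39.52, 5.52],
        "QR_pd":       [11.44, 1.2],
        "QR_peak":     [33.88, 12.42],
        "RS_MMR":      [1.03, 0.46],
        "RS_angle":    [-67.12, 15.02],
        "RS_interval": [42.14, 6.80],
        "RS_pd":       [11.48, 0.83],
        "RS_peak":     [37.50, 12.76]
      }
    },
    "B": {
      "size": 69,
      "predictors": {
        "QR_MMR":      [1.35, 0.57],
        "QR_angle":    [110.78, 11.90],
        "QR_interval": [39.49, 5.50],
        "QR_pd":       [11.31, 0.78],
        "QR_peak":     [42.03, 13.35],
        "RS_MMR":      [0.88, 0.34],
        "RS_angle":    [-63.00, 11.44],
        "RS_interval": [42.18, 6.21],
        "RS_pd":       [11.25, 0.74],
        "RS_peak":     [46.32, 14.94]
      }
    },
    "C": {
      "size": 37,
      "predictors": {
        "QR_MMR":      [1.98, 0.92],
        "QR_angle":    [119.0, 8.67],
        "QR_interval": [37.11, 6.97],
        "QR_pd":       [9.63, 0.84],
        "QR_peak":     [70.44, 26.46],
        "RS_MMR":      [0.68, 0.23],
        "RS_angle":    [-56.68, 9.63],
        "RS_interval": [44.57, 8.97],
        "RS_pd":       [9.79, 0.95],
        "RS_peak":     [88.29, 29.52]
      }
    }
  }
}
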