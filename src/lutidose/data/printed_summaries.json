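{
  "_comment": [
    "Summary rows (medians, IQRs, Wilcoxon p-values, folds) exactly as printed",
    "in the published trial tables/abstract. Used by the report layer to flag",
    "agreement between recomputed and printed summaries; never used as a",
    "computation input."
  ],
  "dose_endpoints": {
    "tumor_dose": {"median_without": 0.28, "median_with": 0.74, "iqr_without": 0.34, "iqr_with": 0.79, "p": 0.03, "fold": 2.6},
    "kidney_dose": {"median_without": 0.05, "median_with": 0.11, "iqr_without": 0.01, "iqr_with": 0.04, "p": 0.01, "fold": 2.4},
    "stomach_dose": {"median_without": 0.2, "median_with": 0.5, "iqr_without": 0.05, "iqr_with": 0.37, "p": 0.01, "fold": 2.1},
    "marrow_dose": {"median_without": 0.03, "median_with": 0.05, "iqr_without": 0.002, "iqr_with": 0.014, "p": 0.01, "fold": 1.4},
    "ratio_kidney": {"median_without": 8.3, "median_with": 7.8, "iqr_without": 9.5, "iqr_with": 8.1, "p": 0.22},
    "ratio_stomach": {"median_without": 1.5, "median_with": 1.1, "iqr_without": 2.1, "iqr_with": 1.5, "p": 0.19},
    "ratio_marrow": {"median_without": 9.2, "median_with": 19.1, "iqr_without": 11.4, "iqr_with": 15.7, "p": 0.44}
  },
  "stability": {
    "5": {"median_without": 94.1, "median_with": 99.5, "iqr_without": 2.7, "iqr_with": 1.5, "fold": 1.1},
    "15": {"median_without": 80.3, "median_with": 92.1, "iqr_without": 19.3, "iqr_with": 2.7, "fold": 1.1},
    "30": {"median_without": 64.5, "median_with": 78.5, "iqr_without": 9.8, "iqr_with": 4.9, "fold": 1.2},
    "60": {"median_without": 41.1, "median_with": 64.15, "iqr_without": 11.2, "iqr_with": 10.0, "fold": 1.6}
  },
  "rounding": {"dose_decimals": 2, "ratio_decimals": 1, "stability_decimals": 1}
}
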