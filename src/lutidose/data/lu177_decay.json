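{
  "_comment": [
    "Lu-177 decay data, condensed from published nuclear-data compilations",
    "(ICRP-107-style evaluation; half-life 6.647 d).",
    "The beta spectrum is a 25-bin approximation of the allowed-shape spectrum",
    "(relativistic Fermi function, daughter Z=72, A=177; branches 498.3 keV",
    "79.4%, 385.3 keV 9.0%, 177.0 keV 11.6%); binned mean 134.1 keV.",
    "Conversion/Auger electron lines add ~13.8 keV per decay for a total mean",
    "electron energy of ~147.9 keV per decay.",
    "Photons: principal gammas 112.95 and 208.37 keV plus minor gammas and",
    "Hf K/L X-rays.",
    "schema: {half_life_s, electrons:[{E_keV, yield}], photons:[{E_keV, yield}]}"
  ],
  "version": "1.0",
  "nuclide": "Lu-177",
  "half_life_s": 574300.8,
  "electrons": [
    {"E_keV": 9.89, "yield": 0.107651, "kind": "beta_bin"},
    {"E_keV": 29.877, "yield": 0.100017, "kind": "beta_bin"},
    {"E_keV": 49.864, "yield": 0.09217, "kind": "beta_bin"},
    {"E_keV": 69.61, "yield": 0.082229, "kind": "beta_bin"},
    {"E_keV": 89.343, "yield": 0.076767, "kind": "beta_bin"},
    {"E_keV": 109.336, "yield": 0.069382, "kind": "beta_bin"},
    {"E_keV": 129.335, "yield": 0.062531, "kind": "beta_bin"},
    {"E_keV": 149.341, "yield": 0.056423, "kind": "beta_bin"},
    {"E_keV": 169.358, "yield": 0.051279, "kind": "beta_bin"},
    {"E_keV": 189.358, "yield": 0.046986, "kind": "beta_bin"},
    {"E_keV": 209.341, "yield": 0.042738, "kind": "beta_bin"},
    {"E_keV": 229.081, "yield": 0.037493, "kind": "beta_bin"},
    {"E_keV": 248.8, "yield": 0.034207, "kind": "beta_bin"},
    {"E_keV": 268.774, "yield": 0.029914, "kind": "beta_bin"},
    {"E_keV": 288.744, "yield": 0.025711, "kind": "beta_bin"},
    {"E_keV": 308.709, "yield": 0.021652, "kind": "beta_bin"},
    {"E_keV": 328.667, "yield": 0.017799, "kind": "beta_bin"},
    {"E_keV": 348.617, "yield": 0.014214, "kind": "beta_bin"},
    {"E_keV": 368.33, "yield": 0.010717, "kind": "beta_bin"},
    {"E_keV": 387.982, "yield": 0.008169, "kind": "beta_bin"},
    {"E_keV": 407.854, "yield": 0.005676, "kind": "beta_bin"},
    {"E_keV": 427.653, "yield": 0.003564, "kind": "beta_bin"},
    {"E_keV": 447.296, "yield": 0.00189, "kind": "beta_bin"},
    {"E_keV": 466.493, "yield": 0.000716, "kind": "beta_bin"},
    {"E_keV": 483.657, "yield": 0.000102, "kind": "beta_bin"},
    {"E_keV": 7.0, "yield": 0.107, "kind": "auger"},
    {"E_keV": 47.6, "yield": 0.0939, "kind": "ce_k_113"},
    {"E_keV": 101.7, "yield": 0.055, "kind": "ce_l_113"},
    {"E_keV": 110.2, "yield": 0.017, "kind": "ce_m_113"},
    {"E_keV": 143.1, "yield": 0.0053, "kind": "ce_k_208"},
    {"E_keV": 197.7, "yield": 0.0014, "kind": "ce_l_208"},
    {"E_keV": 206.0, "yield": 0.0004, "kind": "ce_m_208"}
  ],
  "photons": [
    {"E_keV": 112.95, "yield": 0.0617},
    {"E_keV": 208.366, "yield": 0.1036},
    {"E_keV": 249.674, "yield": 0.00205},
    {"E_keV": 321.316, "yield": 0.00219},
    {"E_keV": 71.646, "yield": 0.00155},
    {"E_keV": 55.79, "yield": 0.03},
    {"E_keV": 63.24, "yield": 0.009},
    {"E_keV": 8.0, "yield": 0.014}
  ]
}
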