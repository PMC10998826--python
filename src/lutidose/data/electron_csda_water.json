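{
  "_comment": [
    "CSDA range of electrons in liquid water (ESTAR-style published table).",
    "Energies in keV, ranges in g/cm^2. Interpolated log-log in nucdata."
  ],
  "version": "1.0",
  "medium": "water",
  "density_g_cm3": 1.0,
  "E_keV": [10, 15, 20, 30, 40, 50, 60, 70, 80, 100, 150, 200, 250, 300, 350, 400, 450, 500, 550, 600],
  "range_g_cm2": [2.515e-4, 5.147e-4, 8.566e-4, 1.756e-3, 2.919e-3, 4.320e-3,
                  5.940e-3, 7.762e-3, 9.773e-3, 1.431e-2, 2.817e-2, 4.487e-2,
                  6.371e-2, 8.421e-2, 1.060e-1, 1.288e-1, 1.523e-1, 1.766e-1,
                  2.013e-1, 2.264e-1]
}
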