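{
  "_comment": [
    "Photon mass attenuation (mu/rho, with coherent) and mass energy-absorption",
    "(mu_en/rho) coefficients for liquid water (XCOM/NIST-style published",
    "table). Energies in keV, coefficients in cm^2/g. Log-log interpolation."
  ],
  "version": "1.0",
  "medium": "water",
  "density_g_cm3": 1.0,
  "E_keV": [8, 10, 15, 20, 30, 40, 50, 60, 80, 100, 150, 200, 300, 400, 500],
  "mu_rho_cm2_g": [10.37, 5.329, 1.673, 0.8096, 0.3756, 0.2683, 0.2269,
                   0.2059, 0.1837, 0.1707, 0.1505, 0.1370, 0.1186, 0.1061, 0.0969],
  "mu_en_rho_cm2_g": [9.556, 4.944, 1.374, 0.5503, 0.1557, 0.0695, 0.04223,
                      0.03190, 0.02597, 0.02546, 0.02764, 0.02967, 0.03192,
                      0.03279, 0.03299]
}
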