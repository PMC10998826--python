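# Absorbed doses (Gy/GBq) of tumors and organs, and tumor-to-organ dose ratios,
# per patient/lesion, without and with neprilysin-inhibitor premedication.
# Transcribed from the published phase-0 trial table. Empty tumor cells mean no
# measurable tumor (or, patient 2, blood-pool overlay preventing dosimetry).
# Organ doses are per patient; they repeat on second-lesion rows exactly as
# printed. Ratio columns are the printed tumor-to-organ ratios (printed from
# unrounded doses, hence consistent with the printed doses only within
# rounding).
patient,lesion,arm,tumor_dose,kidney_dose,stomach_dose,marrow_dose,ratio_kidney,ratio_stomach,ratio_marrow
1,1,without,,0.04,0.30,0.02,,,
1,1,with,,0.07,0.48,0.02,,,
2,1,without,,0.05,0.26,0.04,,,
2,1,with,,0.13,0.43,0.04,,,
3,1,without,,0.05,0.03,0.03,,,
3,1,with,,0.12,0.05,0.04,,,
4,1,without,0.03,0.05,0.23,0.03,0.6,0.1,1.1
4,1,with,0.05,0.12,0.50,0.05,0.4,0.1,1.0
4,2,without,0.05,0.05,0.23,0.03,1.0,0.2,1.8
4,2,with,0.07,0.12,0.50,0.05,0.6,0.1,1.4
5,1,without,,0.03,1.15,0.02,,,
5,1,with,,0.07,1.53,0.03,,,
6,1,without,0.99,0.05,0.19,0.04,19.8,5.2,24.8
6,1,with,1.26,0.11,0.30,0.06,11.5,4.2,21.4
7,1,without,0.22,0.04,0.17,0.03,5.5,1.3,7.3
7,1,with,0.75,0.10,0.88,0.04,7.5,0.9,20.3
7,2,without,0.47,0.04,0.17,0.03,11.8,2.8,15.7
7,2,with,1.12,0.10,0.88,0.04,11.2,1.3,30.3
8,1,without,0.33,0.03,0.20,0.03,11.0,1.7,11.0
8,1,with,0.73,0.09,0.39,0.04,8.1,1.9,17.8
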