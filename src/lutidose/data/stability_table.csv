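# In-vivo stability of the Lu-177-labelled minigastrin analogue: percent intact
# peptide in blood plasma by radio-HPLC, per patient, without (without) and with
# (with) neprilysin-inhibitor premedication, at 5/15/30/60 min post injection.
# Transcribed from the published phase-0 trial table. Non-evaluable entries keep
# the footnoted reason ("activity_too_low" or "hplc_malfunction").
# NOTE: the published table typesets rows as run-on digit strings; the printed
# 5/15/30-min medians do not equal the median of the per-patient values under
# standard conventions, so some cells may be affected by typesetting ambiguity.
# Values are transcribed as parsed, without corrective guessing.
patient,arm,time_min,percent_intact,evaluable,reason
1,without,5,71.0,True,
2,without,5,95.5,True,
3,without,5,,False,activity_too_low
4,without,5,96.1,True,
5,without,5,94.3,True,
6,without,5,96.5,True,
7,without,5,93.9,True,
8,without,5,92.4,True,
1,with,5,91.4,True,
2,with,5,99.4,True,
3,with,5,98.3,True,
4,with,5,,False,hplc_malfunction
5,with,5,99.6,True,
6,with,5,99.9,True,
7,with,5,100.0,True,
8,with,5,98.3,True,
1,without,15,69.9,True,
2,without,15,80.3,True,
3,without,15,91.4,True,
4,without,15,90.5,True,
5,without,15,88.8,True,
6,without,15,90.2,True,
7,without,15,71.4,True,
8,without,15,68.1,True,
1,with,15,92.2,True,
2,with,15,96.7,True,
3,with,15,92.1,True,
4,with,15,,False,hplc_malfunction
5,with,15,91.6,True,
6,with,15,99.2,True,
7,with,15,92.0,True,
8,with,15,88.9,True,
1,without,30,64.5,True,
2,without,30,72.3,True,
3,without,30,74.8,True,
4,without,30,67.6,True,
5,without,30,,False,activity_too_low
6,without,30,60.3,True,
7,without,30,50.1,True,
8,without,30,,False,activity_too_low
1,with,30,78.5,True,
2,with,30,85.7,True,
3,with,30,80.6,True,
4,with,30,,False,hplc_malfunction
5,with,30,85.5,True,
6,with,30,77.9,True,
7,with,30,75.3,True,
8,with,30,79.9,True,
1,without,60,37.9,True,
2,without,60,47.1,True,
3,without,60,44.3,True,
4,without,60,34.3,True,
5,without,60,,False,activity_too_low
6,without,60,53.7,True,
7,without,60,26.0,True,
8,without,60,,False,activity_too_low
1,with,60,63.5,True,
2,with,60,70.3,True,
3,with,60,64.8,True,
4,with,60,,False,hplc_malfunction
5,with,60,75.6,True,
6,with,60,,False,hplc_malfunction
7,with,60,54.8,True,
8,with,60,58.8,True,
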