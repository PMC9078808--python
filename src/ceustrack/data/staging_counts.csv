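stage,modality,gold_n,detected_n
T1,CEUS,19,17
T2-T3,CEUS,45,41
T4,CEUS,38,35
N0,CEUS,42,39
N1,CEUS,16,11
N2,CEUS,21,15
N3,CEUS,23,11
M0,CEUS,68,68
M1,CEUS,34,31
T1,CT,19,13
T2-T3,CT,45,34
T4,CT,38,30
N0,CT,42,31
N1,CT,16,12
N2,CT,21,16
N3,CT,23,17
M0,CT,68,68
M1,CT,34,29
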