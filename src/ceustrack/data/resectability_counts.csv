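modality,tp,fn,tn,fp
CEUS,87,4,9,2
CT,81,10,7,4
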