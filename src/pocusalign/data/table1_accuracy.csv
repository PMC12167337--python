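participant,modality,accuracy
1,POCUS,0.82
1,X-ray,1.0
2,POCUS,0.82
2,X-ray,1.0
3,POCUS,0.64
3,X-ray,0.91
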