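model,wc,ac
M1,0.700,0.395
M2,0.694,0.398
M3,0.691,0.390
M4,0.679,0.395
M5,0.692,0.391
M6,0.692,0.389
M7,0.691,0.389
M8,0.694,0.395
M9,0.689,0.391
Mix1,0.689,0.391
Mix2,0.690,0.390
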