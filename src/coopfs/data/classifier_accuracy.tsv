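dataset	XGBoost	SVM
D1	95.62	96.45
D2	95.13	96.87
D3	100.00	100.00
D4	100.00	100.00
D5	92.84	91.99
D6	99.74	100.00
D7	93.65	94.48
D8	97.41	98.20
D9	92.38	93.89
D10	96.77	98.04
D11	84.92	86.35
D12	99.85	100.00
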