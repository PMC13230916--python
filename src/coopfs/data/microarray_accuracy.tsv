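method	D1	D2	D3	D4	D5	D6	D7	D8	D9	D10	D11	D12
F-GA	90.12	94.67	100.00	100.00	93.51	100.00	93.36	96.65	94.67	96.42	73.37	100.00
F-GWO	89.04	92.20	99.81	100.00	91.59	100.00	92.29	96.11	92.53	95.77	71.85	99.25
F-HBA	89.74	92.47	100.00	100.00	91.50	100.00	92.56	96.37	92.99	95.90	72.41	99.73
F-HHO	93.67	93.07	99.95	100.00	89.35	100.00	93.44	97.08	91.31	96.64	77.03	99.84
F-JAYA	89.14	90.67	99.86	100.00	88.48	100.00	92.81	96.24	90.21	95.73	70.80	99.57
F-RIME	89.88	93.20	100.00	100.00	90.89	100.00	92.86	96.40	92.76	95.96	72.14	99.61
F-SSA	88.46	85.93	99.49	99.91	85.76	99.95	92.05	96.05	87.74	94.74	69.50	98.98
F-WOA	90.61	88.13	99.29	99.96	86.68	100.00	92.70	96.30	88.48	95.24	74.48	99.29
F-TJO	89.58	89.53	86.09	99.74	76.99	99.82	94.43	94.63	82.52	93.08	75.14	97.15
F-PRO	94.12	94.07	99.60	99.96	82.51	100.00	93.59	97.25	91.04	97.04	84.37	98.57
F-Rao	87.08	89.73	94.96	99.38	76.74	99.19	91.90	92.79	85.70	94.81	76.34	97.82
SC-MBO-BLS	92.51	88.87	96.47	99.79	82.68	99.15	91.05	97.18	86.32	93.95	78.40	98.16
TSHFSACO	94.48	94.07	100.00	100.00	77.50	100.00	98.55	97.30	71.09	96.84	77.52	98.31
IGWO	93.88	96.07	99.16	99.64	76.08	99.60	94.59	97.80	82.20	96.81	80.17	97.29
TSMMOPSO-F1	90.80	93.80	99.73	99.24	75.95	100.00	93.36	97.41	85.31	96.81	73.59	96.43
TMPA-HC	96.45	96.87	100.00	100.00	91.99	100.00	94.48	98.20	93.89	98.04	86.35	100.00
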