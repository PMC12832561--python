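soc	n	ror	ror_lo	ror_hi	prr	chi2	ebgm	ebgm05	ic	ic025
general disorders and administration site conditions	1481	0.99	0.94	1.05	0.99	0.05	0.99	0.95	-0.01	-0.09
gastrointestinal disorders	1257	1.85	1.74	1.96	1.72	415.8	1.72	1.64	0.78	0.7
psychiatric disorders	983	2.16	2.02	2.31	2.03	541.95	2.03	1.92	1.02	0.92
respiratory, thoracic and mediastinal disorders	898	2.34	2.19	2.51	2.2	617.68	2.2	2.08	1.14	1.04
nervous system disorders	736	1.02	0.95	1.1	1.02	0.26	1.02	0.96	0.03	-0.09
investigations	600	1.14	1.05	1.24	1.13	10.17	1.13	1.06	0.18	0.06
injury, poisoning and procedural complications	460	0.55	0.5	0.6	0.57	164.7	0.57	0.53	-0.81	-0.95
musculoskeletal and connective tissue disorders	378	0.83	0.75	0.92	0.84	12.48	0.84	0.77	-0.25	-0.41
infections and infestations	309	0.67	0.6	0.75	0.68	47.6	0.68	0.62	-0.55	-0.71
metabolism and nutrition disorders	300	1.66	1.48	1.86	1.63	75.59	1.63	1.48	0.71	0.54
skin and subcutaneous tissue disorders	262	0.55	0.49	0.63	0.57	90.67	0.57	0.51	-0.81	-1
cardiac disorders	248	1.1	0.97	1.25	1.1	2.28	1.1	0.99	0.14	-0.05
vascular disorders	115	0.62	0.52	0.74	0.62	26.59	0.62	0.54	-0.68	-0.95
neoplasms benign, malignant and unspecified (incl cysts and polyps)	101	0.44	0.36	0.54	0.45	70.61	0.45	0.38	-1.16	-1.45
eye disorders	70	0.4	0.32	0.51	0.41	61.44	0.41	0.33	-1.29	-1.64
renal and urinary disorders	56	0.35	0.27	0.46	0.36	66.28	0.36	0.29	-1.49	-1.87
social circumstances	34	0.91	0.65	1.28	0.91	0.27	0.91	0.69	-0.13	-0.62
immune system disorders	32	0.33	0.24	0.47	0.34	42.45	0.34	0.25	-1.57	-2.08
blood and lymphatic system disorders	31	0.21	0.15	0.3	0.21	92.08	0.21	0.16	-2.23	-2.75
reproductive system and breast disorders	27	0.38	0.26	0.56	0.39	26.62	0.39	0.28	-1.37	-1.92
surgical and medical procedures	27	0.23	0.16	0.34	0.23	69.45	0.23	0.17	-2.11	-2.65
hepatobiliary disorders	26	0.33	0.22	0.49	0.33	35.16	0.33	0.24	-1.59	-2.14
ear and labyrinth disorders	24	0.65	0.44	0.97	0.65	4.46	0.65	0.47	-0.62	-1.19
product issues	19	0.14	0.09	0.22	0.14	101.5	0.14	0.1	-2.83	-3.48
endocrine disorders	6	0.27	0.12	0.61	0.28	11.49	0.28	0.14	-1.86	-2.95
congenital, familial and genetic disorders	1	0.04	0.01	0.27	0.04	24.15	0.04	0.01	-4.7	-6.74
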