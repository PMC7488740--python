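# 38 DNA dinucleotide local-property values (repDNA-style property set, v1).
# Raw values; each row is standardized (zero mean, unit variance over the 16
# dinucleotides) when loaded. Users may substitute their own table with the
# same column layout.
property	AA	AC	AG	AT	CA	CC	CG	CT	GA	GC	GG	GT	TA	TC	TG	TT
Base stacking	-5.37	-10.51	-6.78	-6.57	-6.57	-8.26	-9.61	-6.78	-9.81	-14.59	-8.26	-10.51	-3.82	-9.81	-6.57	-5.37
Protein induced deformability	2.9	2.3	2.1	1.6	9.8	6.1	12.1	2.1	4.5	4.0	6.1	2.3	6.3	4.5	9.8	2.9
B-DNA twist	35.5	33.1	30.6	43.2	37.7	35.3	31.3	30.6	39.6	38.4	35.3	33.1	31.6	39.6	37.7	35.5
Dinucleotide GC content	0	1	1	0	1	2	2	1	1	2	2	1	0	1	1	0
A-philicity	1.04	0.76	0.64	1.28	0.76	0.85	0.99	0.64	1.17	1.02	0.85	0.76	0.72	1.17	0.76	1.04
Propeller twist	-18.66	-13.10	-14.00	-15.01	-9.45	-8.11	-10.03	-14.00	-13.48	-11.08	-8.11	-13.10	-11.85	-13.48	-9.45	-18.66
Duplex stability free energy	-1.00	-1.44	-1.28	-0.88	-1.45	-1.84	-2.17	-1.28	-1.30	-2.24	-1.84	-1.44	-0.58	-1.30	-1.45	-1.00
Duplex stability disrupt energy	1.9	1.3	1.6	1.5	1.9	3.1	3.6	1.6	1.6	3.1	3.1	1.3	0.9	1.6	1.9	1.9
DNA denaturation	66.5	108.8	85.1	72.3	64.9	99.3	115.8	85.1	80.3	112.0	99.3	108.8	50.5	80.3	64.9	66.5
Bending stiffness	35	60	60	20	60	130	85	60	60	85	130	60	20	60	60	35
Protein DNA twist	35.1	31.5	31.9	29.3	37.3	32.9	36.1	31.9	36.3	33.6	32.9	31.5	37.8	36.3	37.3	35.1
Stabilising energy of Z-DNA	3.9	4.6	3.4	5.9	1.3	2.4	0.7	3.4	3.4	4.0	2.4	4.6	2.5	3.4	1.3	3.9
Aida BA transition	0.34	0.70	0.43	0.62	0.74	0.50	0.89	0.43	0.28	0.93	0.50	0.70	0.61	0.28	0.74	0.34
Breslauer dG	-1.9	-1.3	-1.6	-1.5	-1.9	-3.1	-3.6	-1.6	-1.6	-3.1	-3.1	-1.3	-0.9	-1.6	-1.9	-1.9
Breslauer dH	-9.1	-6.5	-7.8	-8.6	-5.8	-11.0	-11.9	-7.8	-5.6	-11.1	-11.0	-6.5	-6.0	-5.6	-5.8	-9.1
Breslauer dS	-24.0	-17.3	-20.8	-23.9	-12.9	-26.6	-27.8	-20.8	-13.5	-26.7	-26.6	-17.3	-16.9	-13.5	-12.9	-24.0
Electron interaction	0.2	0.7	0.4	0.5	0.3	1.0	1.2	0.4	0.6	1.4	1.0	0.7	0.1	0.6	0.3	0.2
Hartman trans free energy	1.1	1.6	1.3	1.4	0.9	2.0	2.5	1.3	1.5	2.3	2.0	1.6	0.8	1.5	0.9	1.1
Helix-coil transition	0.9	1.2	1.0	1.1	0.8	1.5	1.7	1.0	1.1	1.6	1.5	1.2	0.7	1.1	0.8	0.9
Ivanov BA transition	1.07	0.78	0.83	1.02	0.36	0.68	0.31	0.83	0.81	0.62	0.68	0.78	0.65	0.81	0.36	1.07
Lisser BZ transition	3.2	5.4	4.1	4.4	2.5	6.1	7.4	4.1	4.6	6.9	6.1	5.4	2.2	4.6	2.5	3.2
Polar interaction	0.5	1.1	0.8	0.9	0.6	1.4	1.8	0.8	1.0	1.7	1.4	1.1	0.4	1.0	0.6	0.5
SantaLucia dG	-1.00	-1.44	-1.28	-0.88	-1.45	-1.84	-2.17	-1.28	-1.30	-2.24	-1.84	-1.44	-0.58	-1.30	-1.45	-1.00
SantaLucia dH	-7.9	-8.4	-7.8	-7.2	-8.5	-8.0	-10.6	-7.8	-8.2	-9.8	-8.0	-8.4	-7.2	-8.2	-8.5	-7.9
SantaLucia dS	-22.2	-22.4	-21.0	-20.4	-22.7	-19.9	-27.2	-21.0	-22.2	-24.4	-19.9	-22.4	-21.3	-22.2	-22.7	-22.2
Sarai flexibility	13.7	10.3	11.5	12.9	14.6	9.9	10.7	11.5	12.4	10.1	9.9	10.3	16.2	12.4	14.6	13.7
Stability	-0.9	-1.6	-1.4	-1.1	-1.5	-2.0	-2.4	-1.4	-1.4	-2.2	-2.0	-1.6	-0.6	-1.4	-1.5	-0.9
Stacking energy	-5.37	-10.51	-6.78	-6.57	-6.57	-8.26	-9.61	-6.78	-9.81	-14.59	-8.26	-10.51	-3.82	-9.81	-6.57	-5.37
Sugimoto dG	-1.2	-1.5	-1.5	-0.9	-1.7	-2.1	-2.8	-1.5	-1.5	-2.3	-2.1	-1.5	-0.9	-1.5	-1.7	-1.2
Sugimoto dH	-8.0	-9.4	-6.6	-5.6	-8.2	-10.9	-11.8	-6.6	-8.8	-10.5	-10.9	-9.4	-6.6	-8.8	-8.2	-8.0
Sugimoto dS	-21.9	-25.5	-16.4	-15.2	-21.0	-28.4	-29.0	-16.4	-23.5	-26.4	-28.4	-25.5	-18.4	-23.5	-21.0	-21.9
Watson-Crick interaction	1.9	2.6	2.2	2.0	2.4	3.3	3.8	2.2	2.5	3.6	3.3	2.6	1.8	2.5	2.4	1.9
Twist	35.62	34.4	27.7	31.5	34.5	33.67	29.8	27.7	36.9	40.0	33.67	34.4	36.0	36.9	34.5	35.62
Tilt	-1.4	-0.1	-1.7	0.0	0.5	-0.1	0.0	1.7	-1.5	0.0	0.1	0.1	0.0	1.5	-0.5	1.4
Roll	0.7	0.7	4.5	1.1	4.7	3.6	5.4	4.5	1.9	0.3	3.6	0.7	3.3	1.9	4.7	0.7
Shift	-0.03	-0.13	0.09	0.0	0.09	0.05	0.0	-0.09	-0.02	0.0	-0.05	0.13	0.0	0.02	-0.09	0.03
Slide	-0.08	-0.58	-0.25	-0.59	0.53	-0.22	0.41	-0.25	-0.01	-0.38	-0.22	-0.58	0.05	-0.01	0.53	-0.08
Rise	3.16	3.41	3.63	3.89	3.23	3.06	3.60	3.63	3.47	3.98	3.06	3.41	3.21	3.47	3.23	3.16
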