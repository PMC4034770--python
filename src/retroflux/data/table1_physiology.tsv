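# Basic characterization of plants grown in normal (N) or low (L) light, or transferred to high light for 6 h (N→H, L→H).
# mean ± SD; letters mark significance groups (t-test) and are carried as opaque labels.
parameter	unit	treatment	mean	sd	significance
chlorophyll	mg/g fw	N	1.22	0.10	a
chlorophyll	mg/g fw	N→H	1.15	0.10	a
chlorophyll	mg/g fw	L	0.75	0.08	b
chlorophyll	mg/g fw	L→H	0.80	0.10	b
phi_psii	r.U.	N	0.76	0.01	a
phi_psii	r.U.	N→H	0.62	0.04	c
phi_psii	r.U.	L	0.72	0.02	b
phi_psii	r.U.	L→H	0.49	0.05	c
protein	mg/g fw	N	10.19	1.01	a
protein	mg/g fw	N→H	11.49	0.96	a
protein	mg/g fw	L	4.94	0.14	c
protein	mg/g fw	L→H	5.58	0.33	b
rna	µg/g fw	N	13.92	6.60	a
rna	µg/g fw	N→H	17.27	7.91	a
rna	µg/g fw	L	5.31	3.11	b
rna	µg/g fw	L→H	5.89	3.02	b
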