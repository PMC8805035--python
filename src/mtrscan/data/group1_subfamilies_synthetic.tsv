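species	MtrC	MtrF	OmcA	UndA	MtrG	MtrH
Shewanella synthspecies00	1	0	1	0	0	0
Shewanella synthspecies01	1	1	1	0	0	1
Shewanella synthspecies02	1	1	0	1	1	0
Shewanella synthspecies03	1	0	1	0	0	1
Shewanella synthspecies04	1	1	1	0	0	0
Shewanella synthspecies05	1	1	0	1	1	0
Shewanella synthspecies06	1	0	1	0	0	1
Shewanella synthspecies07	1	1	1	0	0	0
Shewanella synthspecies08	1	1	0	1	1	0
Shewanella synthspecies09	1	0	1	0	0	1
Shewanella synthspecies10	1	1	1	0	0	0
Shewanella synthspecies11	1	1	0	1	1	0
Shewanella synthspecies12	1	0	1	0	0	1
Shewanella synthspecies13	1	1	1	0	0	0
Shewanella synthspecies14	1	1	0	1	1	0
Shewanella synthspecies15	1	0	1	0	0	1
Shewanella synthspecies16	1	1	1	0	0	0
Shewanella synthspecies17	1	1	0	1	0	0
Shewanella synthspecies18	1	0	1	0	0	1
Shewanella synthspecies19	1	1	0	0	0	0
Shewanella synthspecies20	1	1	0	1	0	0
Shewanella synthspecies21	1	0	1	0	0	1
Shewanella synthspecies22	1	1	0	0	0	0
Shewanella synthspecies23	1	0	1	1	0	0
Shewanella synthspecies24	1	0	1	0	0	1
Shewanella synthspecies25	1	1	0	0	0	0
Shewanella synthspecies26	1	0	1	0	0	0
Shewanella synthspecies27	1	0	1	0	0	1
Shewanella synthspecies28	1	1	0	0	0	0
Shewanella synthspecies29	1	0	1	0	0	0
Shewanella synthspecies30	1	0	1	0	0	1
Shewanella synthspecies31	1	1	0	1	0	0
Shewanella synthspecies32	1	0	1	0	0	0
Shewanella synthspecies33	1	0	1	0	0	1
Shewanella synthspecies34	1	1	0	1	0	0
Shewanella synthspecies35	1	0	1	0	0	0
Shewanella synthspecies36	1	0	1	0	0	1
Shewanella synthspecies37	1	1	0	1	0	0
Shewanella synthspecies38	1	0	1	0	0	0
Shewanella synthspecies39	1	0	1	0	0	1
Ferrimonas synthspecies40	1	1	0	1	0	0
Ferrimonas synthspecies41	1	0	1	0	0	0
Ferrimonas synthspecies42	1	0	1	0	0	1
Ferrimonas synthspecies43	1	1	0	1	0	0
Ferrimonas synthspecies44	1	0	1	0	0	0
Paraferrimonas synthspecies45	1	0	1	0	0	1
Paraferrimonas synthspecies46	1	1	0	1	0	0
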