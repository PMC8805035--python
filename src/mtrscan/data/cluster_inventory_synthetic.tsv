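cluster_id	group	n_accessory_mtrC
SYN0001	1	1
SYN0002	1	2
SYN0003	1	3
SYN0004	1	1
SYN0005	1	2
SYN0006	1	3
SYN0007	1	1
SYN0008	1	2
SYN0009	1	3
SYN0010	1	1
SYN0011	1	2
SYN0012	1	3
SYN0013	1	1
SYN0014	1	2
SYN0015	1	3
SYN0016	1	1
SYN0017	1	2
SYN0018	1	3
SYN0019	1	1
SYN0020	1	2
SYN0021	1	3
SYN0022	1	1
SYN0023	1	2
SYN0024	1	3
SYN0025	1	1
SYN0026	1	2
SYN0027	1	3
SYN0028	1	1
SYN0029	1	2
SYN0030	1	3
SYN0031	1	1
SYN0032	1	2
SYN0033	1	3
SYN0034	1	1
SYN0035	1	2
SYN0036	1	3
SYN0037	1	1
SYN0038	1	2
SYN0039	1	3
SYN0040	1	1
SYN0041	1	2
SYN0042	1	3
SYN0043	1	1
SYN0044	1	2
SYN0045	1	3
SYN0046	1	1
SYN0047	1	2
SYN0048	1	3
SYN0049	1	1
SYN0050	1	2
SYN0051	1	3
SYN0052	1	1
SYN0053	1	2
SYN0054	1	3
SYN0055	1	1
SYN0056	1	2
SYN0057	1	3
SYN0058	1	1
SYN0059	1	2
SYN0060	1	3
SYN0061	1	1
SYN0062	1	2
SYN0063	1	3
SYN0064	1	1
SYN0065	1	2
SYN0066	1	3
SYN0067	1	1
SYN0068	1	2
SYN0069	1	3
SYN0070	1	1
SYN0071	1	2
SYN0072	1	3
SYN0073	1	0
SYN0074	1	0
SYN0075	2	0
SYN0076	2	0
SYN0077	2	0
SYN0078	2	0
SYN0079	2	0
SYN0080	2	0
SYN0081	2	0
SYN0082	2	0
SYN0083	2	0
SYN0084	2	0
SYN0085	2	0
SYN0086	2	0
SYN0087	2	0
SYN0088	2	0
SYN0089	2	0
SYN0090	2	0
SYN0091	2	0
SYN0092	2	0
SYN0093	2	0
SYN0094	2	0
SYN0095	2	0
SYN0096	2	0
SYN0097	2	0
SYN0098	2	0
SYN0099	2	0
SYN0100	2	0
SYN0101	2	0
SYN0102	2	0
SYN0103	2	0
SYN0104	2	0
SYN0105	3	1
SYN0106	3	2
SYN0107	3	3
SYN0108	3	1
SYN0109	3	2
SYN0110	3	3
SYN0111	3	0
SYN0112	3	0
SYN0113	3	0
SYN0114	3	0
SYN0115	3	0
SYN0116	3	0
SYN0117	3	0
SYN0118	3	0
SYN0119	3	0
SYN0120	3	0
SYN0121	3	0
SYN0122	3	0
SYN0123	3	0
SYN0124	3	0
SYN0125	3	0
SYN0126	4	0
SYN0127	4	0
SYN0128	4	0
SYN0129	4	0
SYN0130	4	0
SYN0131	4	0
SYN0132	4	0
SYN0133	4	0
SYN0134	4	0
SYN0135	4	0
SYN0136	4	0
SYN0137	4	0
SYN0138	4	0
SYN0139	4	0
SYN0140	4	0
SYN0141	4	0
SYN0142	4	0
SYN0143	4	0
SYN0144	5	0
SYN0145	5	0
SYN0146	5	0
SYN0147	5	0
SYN0148	5	0
SYN0149	5	0
SYN0150	5	0
SYN0151	5	0
SYN0152	6	0
SYN0153	6	0
SYN0154	6	0
SYN0155	6	0
SYN0156	6	0
SYN0157	6	0
SYN0158	6	0
SYN0159	6	0
SYN0160	6	0
SYN0161	6	0
SYN0162	6	0
SYN0163	6	0
SYN0164	6	0
SYN0165	6	0
SYN0166	6	0
SYN0167	6	0
SYN0168	6	0
SYN0169	6	0
SYN0170	7	0
SYN0171	7	0
SYN0172	7	0
SYN0173	7	0
SYN0174	7	0
SYN0175	7	0
SYN0176	7	0
SYN0177	7	0
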