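species	accession	partition	size	pctA	pctC	pctG	pctT	pctAT	at_skew	gc_skew
C. borneensis	OR466573	whole	16943	32.13	27.79	15.11	24.97	57.10	0.125	-0.296
C. lopis	OQ446559	whole	16176	32.31	28.62	14.94	24.12	56.44	0.145	-0.314
C. lopis	AP008922	whole	16177	32.36	28.61	14.90	24.12	56.48	0.146	-0.315
C. chitala	ON764424	whole	16248	32.00	27.95	15.31	24.74	56.74	0.128	-0.292
C. chitala	KX894524	whole	16375	32.05	27.84	15.21	24.84	56.89	0.127	-0.293
C. ornata	AP008923	whole	16164	32.30	27.77	14.87	25.07	57.37	0.126	-0.303
C. blanci	AP008921	whole	16272	32.15	27.73	15.30	24.80	56.96	0.129	-0.289
C. borneensis	OR466573	PCGs	11427	29.98	28.71	14.55	26.75	56.73	0.057	-0.327
C. lopis	OQ446559	PCGs	11420	30.11	29.16	14.30	26.44	56.54	0.065	-0.342
C. lopis	AP008922	PCGs	11419	30.14	29.14	14.27	26.45	56.59	0.065	-0.342
C. chitala	ON764424	PCGs	11422	29.96	28.77	14.49	26.78	56.74	0.056	-0.330
C. chitala	KX894524	PCGs	11407	30.04	28.79	14.43	26.74	56.78	0.058	-0.332
C. ornata	AP008923	PCGs	11419	30.10	28.43	14.18	27.30	57.40	0.049	-0.334
C. blanci	AP008921	PCGs	11419	29.93	28.33	14.76	26.98	56.91	0.052	-0.315
C. borneensis	OR466573	rRNAs	2673	35.28	25.22	20.09	19.42	54.70	0.290	-0.113
C. lopis	OQ446559	rRNAs	2673	35.20	26.15	20.01	18.63	53.83	0.308	-0.133
C. lopis	AP008922	rRNAs	2674	35.27	26.14	19.97	18.62	53.89	0.309	-0.134
C. chitala	ON764424	rRNAs	2658	34.91	24.76	20.32	20.02	54.93	0.271	-0.098
C. chitala	KX894524	rRNAs	2660	34.85	24.77	20.34	20.04	54.89	0.270	-0.098
C. ornata	AP008923	rRNAs	2674	35.45	24.87	19.82	19.86	55.31	0.282	-0.113
C. blanci	AP008921	rRNAs	2673	35.28	25.03	20.13	19.57	54.84	0.286	-0.109
C. borneensis	OR466573	tRNAs	1554	29.92	21.11	21.88	27.09	57.01	0.050	0.018
C. lopis	OQ446559	tRNAs	1553	29.68	21.06	22.15	27.11	56.79	0.045	0.025
C. lopis	AP008922	tRNAs	1555	29.84	20.96	22.06	27.14	56.98	0.047	0.025
C. chitala	ON764424	tRNAs	1570	29.62	21.46	22.10	26.82	56.43	0.050	0.015
C. chitala	KX894524	tRNAs	1553	29.68	21.31	22.28	26.72	56.41	0.053	0.022
C. ornata	AP008923	tRNAs	1554	29.28	21.04	22.46	27.22	56.50	0.036	0.033
C. blanci	AP008921	tRNAs	1555	29.52	21.41	22.19	26.88	56.40	0.047	0.018
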