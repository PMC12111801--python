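ligand_id	cid	name	class	bbb	PPARA	PPARB	PPARG	RXRA	RXRB	RXRG
vitA_1	445354	Retinol	vitaminA	True	-7.014	-7.825	-9.024	-7.992	-8.181	-8.129
vitA_2	6419707	Retinoate	vitaminA	False	-8.453	-7.825	-7.543	-8.310	-9.383	-9.680
vitA_3	638015	Retinal	vitaminA	False	-8.021	-6.080	-7.497	-8.913	-7.593	-7.880
vitA_4	449171	Retinoic acid	vitaminA	True				-9.790	-9.700	-9.509
Kb_1	4071895	2-hydroxybutyrate	Kb	False	-6.327	-5.505	-5.391	-5.829	-5.428	-5.542
Kb_2	180	acetone	Kb	False	-5.023	-4.554	-4.615	-4.373	-4.389	-4.490
Kb_3	6971017	acetoacetate	Kb	False	-6.571	-5.395	-6.229	-6.382	-5.711	-5.823
SCFA_1	283	Methanoate (Formiate)	SCFA	False	-5.019	-3.795	-4.432	-3.392	-3.427	-4.199
SCFA_2	175	Ethanoate (Acetate)	SCFA	False	-5.573	-4.312	-4.934	-5.303	-4.643	-4.762
SCFA_3	176	Ethanoic (Acetic) acid	SCFA	False	-5.573	-4.312	-4.934	-5.303	-4.643	-4.762
SCFA_4	104745	Propanoate	SCFA	False	-4.115	-2.710	-3.432	-4.449	-3.204	-4.131
SCFA_5	1032	Propanoic (Propionic) acid	SCFA	True	-4.112	-2.708	-3.430	-4.447	-3.202	-4.129
SCFA_6	264	Butanoic (Butyric) acid	SCFA	True	-6.320	-5.000	-5.590	-6.094	-5.576	-5.670
SCFA_7	7991	Pentanoic (Valeric) acid	SCFA	True	-5.633	-4.942	-4.846	-5.577	-4.631	-5.271
SCFA_8	8892	Hexanoic acid (Caproic acid)	SCFA	True	-5.126	-3.836	-4.998	-5.347	-4.956	-4.486
MCFA_1	119389	Octanoate (Caprylate)	MCFA	True	-5.318	-3.839	-4.974	-5.415	-4.839	-5.405
MCFA_2	379	Octanoic (caprylic) acid	MCFA	True	-5.315	-3.836	-4.971	-5.412	-4.836	-5.402
MCFA_3	8158	Nonanoic (pelargonic) acid	MCFA	True	-5.559	-4.129	-3.245	-5.725	-4.448	-5.551
MCFA_4	2969	Decanoic (capric) acid	MCFA	True	-2.473	-1.548	-3.480	-3.678	-3.478	-3.765
MCFA_5	4149208	Dodecanoate (laurate)	MCFA	True	-2.521	-2.652	-1.423	-4.770	-3.904	-4.077
LCFA_1	11005	Tetradecanoic (Myristic) acid	LCFA	True	-2.847	-1.169	-1.731	-4.993	-4.607	-4.769
LCFA_2	13849	pentadecanoic acid	LCFA	True	-2.991	-1.823	-1.844	-5.786	-5.031	-5.088
LCFA_3	504166	Hexadecanoate (Palmitate)	LCFA	True	-3.578	-2.276	-1.883	-5.878	-5.398	-5.662
LCFA_4	985	Hexadecanoic (Palmitic acid)	LCFA	True	-3.575	-2.273	-1.880	-5.875	-5.395	-5.659
LCFA_5	10465	Heptadecanoic acid	LCFA	True	-4.241	-2.703	-2.175	-6.517	-6.103	-6.162
LCFA_6	3033836	Octadecanoate (Stearate)	LCFA	False	-3.581	-3.511	-2.928	-3.219	-1.485	-2.856
LCFA_7	5281	Octadecanoic (Stearic) acid	LCFA	False	-3.578	-3.508	-2.925	-3.216	-1.482	-2.853
LCFA_8	12591	Nonadecanoic acid	LCFA	False	-3.937	-1.175	-2.888	-3.040	-1.611	-2.890
MUFA_1	19499	but-2-enoic acid	MUFA	True	-4.408	-3.736	-4.482	-4.874	-4.560	-4.792
MUFA_2	19499	but-2-enoic acid	MUFA	True	-4.126	-3.308	-3.926	-4.709	-3.794	-3.850
MUFA_3	151007	dodec-5-enoic acid	MUFA	True	-5.090	-2.392	-4.630	-4.986	-4.335	-4.942
MUFA_4	151007	(Z)-dodec-5-enoic acid (Lauroleinic acid)	MUFA	True	-3.088	-2.366	-1.959	-4.607	-4.275	-4.506
MUFA_5	5461012	(Z)-hexadec-9-enoate (Palmitoleate)	MUFA	True	-3.621	-2.500	-2.775	-5.762	-5.211	-6.290
MUFA_6	4668	hexadec-9-enoic acid	MUFA	True	-4.056	-2.681	-2.772	-6.277	-5.741	-5.630
MUFA_7	4668	hexadec-9-enoic acid (Palmitoleic acid)	MUFA	True	-3.618	-2.497	-2.538	-5.759	-5.208	-6.287
MUFA_8	5461069	(Z)-octadec-11-enoate (Vaccenate)	MUFA	False	-4.755	-2.254	-3.408	-6.545	-6.377	-6.270
MUFA_9	5460221	(Z)-octadec-9-enoate (Oleate)	MUFA	True	-4.130	-3.831	-2.946	-3.632	-3.445	-6.620
MUFA_10	12745	octadec-10-enoic acid	MUFA	False	-4.334	-2.947	-3.766	-7.002	-5.919	-5.977
MUFA_11	12745	octadec-10-enoic acid (cis-10-Oleic acid)	MUFA	False	-3.945	-2.531	-3.234	-6.013	-5.900	-4.571
MUFA_12	965	octadec-9-enoic acid	MUFA	False	-4.777	-3.983	-2.943	-6.762	-3.442	-6.617
MUFA_13	965	octadec-9-enoic acid (cis-9-Oleic acid)	MUFA	False	-4.127	-3.828	-3.848	-3.629	-6.084	-6.617
PUFA_1	3931	(9Z,12Z)-octadeca-9,12-dienoic acid (Linoleic acid)	PUFA	True	-5.805	-3.795	-6.315	-7.147	-6.515	-6.805
PUFA_2	3931	octadeca-9,12-dienoic acid	PUFA	True	-5.435	-3.479	-5.907	-7.089	-6.513	-6.43
PUFA_3	3931	octadeca-9,12-dienoic acid	PUFA	True	-5.342	-2.787	-5.761	-7.02	-6.476	-6.394
PUFA_4	3931	octadeca-9,12-dienoic acid	PUFA	True	-5.141	-2.386	-3.474	-6.558	-6.263	-6.364
PUFA_5	860	octadeca-9,12,15-trienoic acid	PUFA	True	-6.388	-4.839	-6.407	-7.015	-6.713	-6.859
PUFA_6	860	octadeca-9,12,15-trienoic acid	PUFA	True	-5.267	-4.74	-6.128	-7.001	-6.539	-6.804
PUFA_7	860	octadeca-9,12,15-trienoic acid	PUFA	True	-5.123	-4.262	-3.892	-6.772	-6.51	-6.712
PUFA_8	860	octadeca-9,12,15-trienoic acid	PUFA	True	-4.992	-4.247	-3.867	-6.74	-6.301	-6.548
PUFA_9	860	octadeca-9,12,15-trienoic acid	PUFA	True	-4.992	-4.16	-3.307	-6.62	-5.864	-6.526
PUFA_10	860	(9Z,12Z,15Z)-octadeca-9,12,15-trienoic acid (alpha-Linolenic acid)	PUFA	True	-4.973	-4.129	-3.286	-6.501	-5.773	-6.265
PUFA_11	860	octadeca-9,12,15-trienoic acid	PUFA	True	-4.786	-2.834	-3.028	-6.173	-5.633	-6.028
PUFA_12	860	octadeca-9,12,15-trienoic acid	PUFA	True	-4.58	-2.706	-3.001	-3.615	-4.045	-5.125
PUFA_13	445580	(4Z,7Z,10Z,13Z,16Z,19Z)-docosa-4,7,10,13,16,19-hexaenoic acid (DHA)	PUFA	False	-7.014	-7.416	-8.724	-8.746	-9.264	-9.512
PUFA_14	446284	(5Z,8Z,11Z,14Z,17Z)-eicosa-5,8,11,14,17-pentaenoic acid (EPA)	PUFA	False	-8.815	-7.433	-6.911	-8.441	-6.812	-7.845
indole_1	798	indole	indole	True	-5.934	-5.692	-5.840	-6.131	-6.164	-6.177
indole_2	10256	1H-indole-3-carbaldehyde	indole	True	-7.272	-6.528	-6.521	-6.647	-6.598	-6.685
indole_3	800	2-(1H-indol-3-yl)acetaldehyde	indole	True	-7.715	-6.991	-7.035	-7.227	-7.234	-7.160
indole_4	1150	2-(1H-indol-3-yl)ethanamine	indole	True	-7.231	-8.007	-6.737	-7.497	-7.657	-7.232
indole_5	10685	2-(1H-indol-3-yl)ethanol	indole	True	-6.942	-6.926	-6.405	-7.085	-6.977	-7.102
indole_6	14558	3-(1H-indol-3-yl)prop-2-enoic acid	indole	True	-8.258	-7.067	-6.570	-6.679	-6.889	-6.594
indole_7	14558	3-(1H-indol-3-yl)prop-2-enoic acid	indole	True	-7.733	-6.943	-6.094	-6.329	-6.251	-5.938
indole_8	14558	3-(1H-indol-3-yl)prop-2-enoic acid	indole	True	-5.135	-4.448	-4.461	-5.225	-5.464	-5.033
indole_9	14558	3-(1H-indol-3-yl)prop-2-enoic acid	indole	True	-4.749	-3.815	-3.898	-4.963	-4.891	-4.967
indole_10	73863	2-(1H-indol-3-yl)-2-oxo-acetic acid	indole	True	-8.016	-7.400	-7.097	-7.119	-6.917	-6.937
indole_11	3744	3-(1H-indol-3-yl)propanoic acid	indole	True	-8.599	-7.499	-6.597	-6.801	-6.851	-6.737
indole_12	803	3-(1H-indol-3-yl)-2-oxo-propanoic acid	indole	True	-8.790	-7.815	-7.243	-7.006	-7.045	-7.008
indole_13	6932058	1H-indole-3-carboxylate	indole	False	-7.624	-6.243	-6.505	-6.643	-6.749	-6.465
indole_14	801	2-(1H-indol-3-yl)acetate (Indolacetate)	indole	False	-7.827	-7.306	-6.719	-7.047	-7.065	-7.283
indole_15	3080590	2-(2-oxoindolin-3-yl)acetic acid	indole	False	-7.619	-6.742	-7.175	-7.063	-7.151	-6.989
indole_16	92904	2-hydroxy-3-(1H-indol-3-yl)propanoic acid	indole	False	-8.578	-8.014	-6.787	-7.225	-7.066	-7.210
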