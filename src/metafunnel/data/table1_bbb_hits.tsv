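block	cid	name	PPARA	PPARB	PPARG	RXRA	RXRB	RXRG
biocyc	397	Indole-3-acetamide	-8.22	-7.61		-7.97	-7.98	-7.83
biocyc	995	Phenanthrene		-7.31		-8.54	-8.50	-8.48
biocyc	6780	Anthraquinone		-7.48		-8.02	-8.23	-8.09
biocyc	6986	P-menthan-3-one					-7.00	-6.80
biocyc	7108	Phenothiazine		-7.12		-8.11	-8.09	-7.91
biocyc	7460	Alpha-phellandrene						-7.05
biocyc	8400	Benzoin		-7.05		-7.80	-7.36	-7.22
biocyc	11142	Beta-phellandrene						-6.80
biocyc	26049	3-carene					-7.01	-7.10
biocyc	28649	Stilbene oxide		-7.10		-7.13		-7.25
biocyc	62349	Menthone lactone		-7.16		-7.25	-7.24	-7.18
biocyc	70117	3-chlorobenzyl alcohol					-6.94
biocyc	234817	Pinoresinol			-8.17
biocyc	363863	Maackiain			-7.90	-7.84
biocyc	439901	4'-o-methylisoflavone	-8.25	-7.33	-7.73			-7.10
biocyc	445354	Retinol; vitamin a			-9.02	-7.99	-8.18	-8.13
biocyc	494912	Nsc636229			-7.55		-7.55	-7.01
biocyc	623060	Medicarpin(p)			-8.06	-7.06
biocyc	3326923	Ibuprofen anion	-8.71	-7.76
biocyc	4055279	1-phenylpropan-2-ylazanium					-6.85
biocyc	5377291	Hinokiresinol		-7.29		-7.32	-6.96	-7.33
biocyc	6440617	(z)-hinokiresinol			-8.52	-8.78	-7.71	-7.06
biocyc	10966551	4'-hydroxyisoflavone		-7.63	-8.05	-7.81	-7.33	-7.86
biocyc	25246088	Cis-12,13-epoxy-9-octadecenoic acid				-7.30		-7.23
biocyc	77916059	Noroxomaritidine				-8.48	-8.62	-6.92
biocyc	146037227	Oxomaritinamine				-7.99	-7.81
pubmed	322	4-trans-4-Hydroxycinnamic acid				-7.29
pubmed	800	2-(1H-indol-3-yl)acetaldehyde		-6.99		-7.23	-7.23	-7.16
pubmed	803	Indole-3-pyruvic acid	-8.79	-7.82	-7.24		-7.05	-7.01
pubmed	1150	Tryptamine		-8.01		-7.50	-7.66	-7.23
pubmed	3744	3-Indolepropionic acid	-8.60	-7.50			-6.85
pubmed	10394	3-(4-Hydroxyphenyl)propionic acid				-7.40
pubmed	10685	Tryptophol					-6.98	-7.10
pubmed	14558	Indol-3-acrylic acid	-8.26	-7.07			-6.89
pubmed	73863	3-Indoleglyoxylic acid	-8.02	-7.40	-7.10		-6.92
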