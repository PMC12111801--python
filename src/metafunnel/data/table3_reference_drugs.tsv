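ligand_id	cid	name	action	git	bbb	receptor	score
anta_gw6471_1	446738	GW 6471	antagonist	Low	False	PPARA	-8.79
anta_gw6471_2	446738	GW 6471	antagonist	Low	False	PPARA	-8.51
anta_gw6471_3	446738	GW 6471	antagonist	Low	False	PPARA	-8.35
anta_gsk0660_1	46233311	GSK0660	antagonist	Low	False	PPARB	-5.21
anta_gsk0660_2	46233311	GSK0660	antagonist	Low	False	PPARB	-4.87
anta_bexarotene_g	82146	Bexarotene	antagonist	High	False	PPARG	-9.16
anta_resveratrol_1	445154	Resveratrol	antagonist	High	True	PPARG	-8.46
anta_resveratrol_2	445154	Resveratrol	antagonist	High	True	PPARG	-4.53
anta_diclofenac	3033	Diclofenac	antagonist	High	True	PPARG	-7.75
ago_fenofibrate	3339	Fenofibrate	agonist	High	True	PPARA	-7.82
ago_clofibrate	2796	Clofibrate	agonist	High	True	PPARA	-6.50
ago_elafibranor_a	9864881	Elafibranor	agonist	High	False	PPARA	-6.57
ago_l796449	9891946	L-796449	agonist	Low	False	PPARB	-9.24
ago_seladelpar	11236126	Seladelpar	agonist	Low	False	PPARB	-8.15
ago_mesalamine	4075	Mesalamine	agonist	High	False	PPARG	-5.83
ago_indomethacin	3715	Indomethacin	agonist	High	True	PPARG	-9.25
ago_pioglitazone_1	4829	Pioglitazone	agonist	High	False	PPARG	-8.19
ago_pioglitazone_2	4829	Pioglitazone	agonist	High	False	PPARG	-7.71
ago_pioglitazone_3	4829	Pioglitazone	agonist	High	False	PPARG	-6.71
ago_pioglitazone_4	4829	Pioglitazone	agonist	High	False	PPARG	-5.90
ago_rosiglitazone_1	77999	Rosiglitazone	agonist	High	False	PPARG	-8.13
ago_rosiglitazone_2	77999	Rosiglitazone	agonist	High	False	PPARG	-7.76
ago_rosiglitazone_3	77999	Rosiglitazone	agonist	High	False	PPARG	-7.37
ago_rosiglitazone_4	77999	Rosiglitazone	agonist	High	False	PPARG	-7.01
ago_elafibranor_g	9864881	Elafibranor	agonist	High	False	PPARG	-7.29
anta_sulindac	1548887	Sulindac	antagonist	High	False	RXRA	-8.88
anta_lg100268_a	3922	LG-100268	antagonist	High	True	RXRA	-9.43
anta_lg100268_b	3922	LG-100268	antagonist	High	True	RXRB	-8.85
anta_lg100268_g	3922	LG-100268	antagonist	High	True	RXRG	-8.26
ago_fluorobexarotene	25195496	Fluorobexarotene	agonist	High	False	RXRA	-10.60
ago_bexarotene_a	82146	Bexarotene	activator	High	False	RXRA	-9.92
ago_bexarotene_b	82146	Bexarotene	activator	High	False	RXRB	-10.06
ago_bexarotene_g	82146	Bexarotene	activator	High	False	RXRG	-10.22
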