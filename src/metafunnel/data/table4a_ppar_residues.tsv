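receptor	consensus_column	residue	gt75	role
PPARA	85	C276	True	agonist
PPARA	86	Q277	True	agonist
PPARA	89	S280	True	agonist
PPARA	123	Y314	True	agonist
PPARA	127	F318	False	agonist
PPARA	139	M330	False	agonist
PPARA	141	V332	False	agonist
PPARA	163	I354	True	agonist
PPARA	164	K358	False	agonist
PPARA	249	H440	True	agonist
PPARA	253	V444	False	agonist
PPARA	292	L460	True	agonist
PPARA	273	Y464	True	agonist
PPARB	85	C285	True	agonist
PPARB	86	Q286	False	agonist
PPARB	89	T289	True	agonist
PPARB	123	H323	False	agonist
PPARB	127	F327	False	agonist
PPARB	139	L330	False	agonist
PPARB	141	V341	False	agonist
PPARB	163	I363	False	agonist
PPARB	164	I364	False	agonist
PPARB	249	H449	True	agonist
PPARB	253	M453	False	agonist
PPARB	292	L469	False	agonist
PPARB	273	Y473	False	agonist
PPARG	85	C285	True	agonist
PPARG	88	R288	True	agonist
PPARG	89	S289	False	agonist
PPARG	126	L326	False	agonist
PPARG	127	Y327	False	agonist
PPARG	130	L330	False	agonist
PPARG	141	L341	False	agonist
PPARA	62	T253	False	antagonist
PPARA	63	L254	False	antagonist
PPARA	65	A256	False	antagonist
PPARA	66	K257	False	antagonist
PPARA	87	C278	False	antagonist
PPARA	91	E282	False	antagonist
PPARB	87	C287	False	antagonist
PPARB	91	E291	False	antagonist
PPARB	95	E295	False	antagonist
PPARA	29	M220	False	specific
PPARA	59	E251	False	specific
PPARA	62	T253	False	specific
PPARA	63	L254	False	specific
PPARA	65	A256	False	specific
PPARA	67	L258	False	specific
PPARA	265	L456	False	specific
PPARB	152	F352	False	specific
PPARG	26	F226	False	specific
PPARG	78	A278	False	specific
PPARG	96	I296	False	specific
PPARG	156	L356	False	specific
PPARG	160	F360	False	specific
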