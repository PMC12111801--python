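receptor	consensus_column	residue	gt75	role
RXRA	50	I268	True	agonist
RXRA	54	A272	False	agonist
RXRA	88	N306	False	agonist
RXRA	91	L309	False	agonist
RXRA	95	F313	True	agonist
RXRA	124	V342	False	agonist
RXRA	127	L345	True	agonist
RXRA	128	F346	False	agonist
RXRA	131	V349	False	agonist
RXRA	214	C432	True	agonist
RXRA	217	H435	False	agonist
RXRA	218	L436	True	agonist
RXRA	221	F439	True	agonist
RXRB	50	L339	True	agonist
RXRB	54	A343	False	agonist
RXRB	88	N377	True	agonist
RXRB	92	I381	False	agonist
RXRB	95	F384	True	agonist
RXRB	124	V413	False	agonist
RXRB	127	I416	True	agonist
RXRB	128	F417	False	agonist
RXRB	131	V420	False	agonist
RXRB	214	C503	True	agonist
RXRB	217	H506	False	agonist
RXRB	218	L507	True	agonist
RXRB	221	F510	False	agonist
RXRG	50	V266	True	agonist
RXRG	54	I269	False	agonist
RXRG	88	N307	True	agonist
RXRG	92	L311	False	agonist
RXRG	95	F314	True	agonist
RXRG	124	V343	False	agonist
RXRG	127	L346	True	agonist
RXRG	128	F347	False	agonist
RXRG	131	V350	False	agonist
RXRG	214	C433	True	agonist
RXRG	217	H436	False	agonist
RXRG	218	L437	True	agonist
RXRG	221	F440	True	agonist
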